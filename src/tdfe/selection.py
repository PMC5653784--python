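"""Selecting singular value vectors, genes, and compounds.

Feature extraction proceeds in three stages once a product tensor has been
decomposed: (i) find the time-mode singular vector that tracks the
treatment days (Pearson correlation) and the sample-mode vectors that
separate the sample classes (one-way ANOVA with Benjamini–Hochberg
correction); (ii) rank core-tensor entries constrained to those vectors
and collect the gene / compound singular vectors they involve; (iii)
attribute a chi-squared tail probability to every gene (or compound) from
its squared standardized loadings on the collected vectors, adjust by BH,
and keep features below the false-discovery threshold.  Compounds are
alternatively selected as the cluster of loadings farthest from the
origin, since every tested compound is bioactive and a null model over
compounds is not meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sp_stats

from .hosvd import HOSVDFactors


@dataclass
class TimeVectorSelection:
    """Pearson correlation of each time-mode singular vector with the days."""

    correlations: np.ndarray
    p_values: np.ndarray
    chosen: int  # 1-based component index
    degenerate: np.ndarray  # True where the vector had zero variance


@dataclass
class ClassVectorSelection:
    """ANOVA class association of each sample-mode singular vector."""

    p_values: np.ndarray
    adjusted: np.ndarray
    chosen: list[int]  # 1-based component indices
    threshold: float


@dataclass
class GeneSelection:
    """Chi-squared feature scores over a set of gene singular vectors."""

    scores: np.ndarray
    p_values: np.ndarray
    adjusted: np.ndarray
    selected: np.ndarray  # boolean mask
    sigma: np.ndarray  # per-vector standard deviation used to standardize
    vector_set: list[int]
    threshold: float
    labels: list[str] | None = None

    @property
    def selected_labels(self) -> list[str]:
        if self.labels is None:
            raise ValueError("no labels attached to this selection")
        return [l for l, s in zip(self.labels, self.selected) if s]


@dataclass
class CompoundSelection:
    """Outlying compounds on the chosen compound singular vector(s)."""

    scores: np.ndarray
    selected: np.ndarray  # boolean mask
    method: str
    params: dict
    vector_set: list[int]
    degenerate: bool = False  # True when all scores tie and nothing is selected
    labels: list[str] | None = None

    @property
    def selected_labels(self) -> list[str]:
        if self.labels is None:
            raise ValueError("no labels attached to this selection")
        return [l for l, s in zip(self.labels, self.selected) if s]


@dataclass
class SelectionResult:
    """Joint gene and compound selection for one analysis."""

    genes: GeneSelection | None = None
    compounds: CompoundSelection | None = None


def select_time_vector(
    factors: HOSVDFactors,
    mode: int,
    time_values: Sequence[float],
    log_days: bool = False,
    override: int | None = None,
) -> TimeVectorSelection:
    """Correlate each singular vector of ``mode`` with the day values.

    The chosen component maximizes ``|r|`` unless ``override`` pins a
    specific one (vector choices are sometimes made by eye from the
    correlation plots, so every automatic choice can be overridden).
    Zero-variance vectors get ``r = 0`` with a degeneracy flag, never NaN.
    """
    u = factors.factors[mode]
    t = np.asarray(time_values, dtype=float)
    if log_days:
        t = np.log(t)
    if u.shape[1] != t.size:
        raise ValueError("mode extent and time-value count differ")
    if t.size < 3:
        raise ValueError("at least three time points are required")
    r = np.zeros(u.shape[0])
    p = np.ones(u.shape[0])
    degenerate = np.zeros(u.shape[0], dtype=bool)
    for l, row in enumerate(u):
        if np.ptp(row) == 0 or np.ptp(t) == 0:
            degenerate[l] = True
            continue
        res = sp_stats.pearsonr(row, t)
        r[l], p[l] = res.statistic, res.pvalue
    chosen = int(override) if override is not None else int(np.abs(r).argmax()) + 1
    if not 1 <= chosen <= u.shape[0]:
        raise IndexError(f"override {chosen} out of range 1..{u.shape[0]}")
    return TimeVectorSelection(r, p, chosen, degenerate)


def select_class_vectors(
    factors: HOSVDFactors,
    mode: int,
    labels: Sequence[str],
    threshold: float = 0.05,
    override: Sequence[int] | None = None,
) -> ClassVectorSelection:
    """One-way ANOVA of each sample-mode singular vector against class labels.

    P-values are BH-adjusted across all tested vectors of the mode; the
    chosen set is everything below ``threshold`` (or the manual override).
    """
    u = factors.factors[mode]
    labels = list(labels)
    if u.shape[1] != len(labels):
        raise ValueError("mode extent and label count differ")
    classes = sorted(set(labels))
    groups_idx = [[j for j, lab in enumerate(labels) if lab == c] for c in classes]
    if len(classes) < 2:
        raise ValueError("at least two classes are required")
    for c, idx in zip(classes, groups_idx):
        if len(idx) < 2:
            raise ValueError(f"class {c!r} has fewer than two members")
    p = np.ones(u.shape[0])
    for l, row in enumerate(u):
        groups = [row[idx] for idx in groups_idx]
        if all(np.ptp(g) == 0 for g in groups) and np.ptp(row) == 0:
            p[l] = 1.0
            continue
        stat = sp_stats.f_oneway(*groups)
        p[l] = 1.0 if np.isnan(stat.pvalue) else float(stat.pvalue)
    adjusted = benjamini_hochberg(p)
    if override is not None:
        chosen = [int(l) for l in override]
        for l in chosen:
            if not 1 <= l <= u.shape[0]:
                raise IndexError(f"override {l} out of range 1..{u.shape[0]}")
    else:
        chosen = [int(l) + 1 for l in np.flatnonzero(adjusted < threshold)]
    return ClassVectorSelection(p, adjusted, chosen, threshold)


def benjamini_hochberg(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted P-values, in input order.

    Sort ascending, multiply the k-th smallest by ``n / k``, enforce
    monotonicity by a cumulative minimum from the largest rank down, and
    cap at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("a flat sequence of P-values is required")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("P-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    adjusted_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.empty(n)
    adjusted[order] = np.clip(adjusted_sorted, None, 1.0)
    return adjusted


def chi2_feature_scores(
    u_rows: np.ndarray, vector_set: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scores ``sum_l (u_l / sigma_l)^2`` and chi-squared tail P-values.

    ``sigma_l`` is the standard deviation of the components of singular
    vector ``l`` over the scored axis, so each term is a squared z-score
    and the degrees of freedom equal the number of summed vectors.
    """
    rows = np.asarray([int(l) - 1 for l in vector_set])
    if rows.size == 0:
        raise ValueError("vector_set must be nonempty")
    if rows.min() < 0 or rows.max() >= u_rows.shape[0]:
        raise IndexError("vector index out of range")
    u = u_rows[rows]
    sigma = u.std(axis=1)
    if np.any(sigma == 0):
        bad = [int(rows[i]) + 1 for i in np.flatnonzero(sigma == 0)]
        raise ValueError(f"singular vector(s) {bad} have zero standard deviation")
    scores = ((u / sigma[:, None]) ** 2).sum(axis=0)
    p = sp_stats.chi2.sf(scores, df=rows.size)
    return scores, p, sigma


def gene_pvalues(
    factors: HOSVDFactors,
    gene_mode: int,
    vector_set: Sequence[int],
    threshold: float = 0.01,
    labels: Sequence[str] | None = None,
) -> GeneSelection:
    """Chi-squared gene selection over the collected gene singular vectors.

    Every gene is scored by its squared standardized loadings summed over
    ``vector_set`` (1-based components), tail probabilities are taken from
    the chi-squared distribution with ``len(vector_set)`` degrees of
    freedom, BH-adjusted over all genes, and genes with adjusted
    ``P < threshold`` are selected.
    """
    scores, p, sigma = chi2_feature_scores(factors.factors[gene_mode], vector_set)
    adjusted = benjamini_hochberg(p)
    selected = adjusted < threshold
    return GeneSelection(
        scores,
        p,
        adjusted,
        selected,
        sigma,
        [int(l) for l in vector_set],
        threshold,
        list(labels) if labels is not None else None,
    )


def select_compounds(
    factors: HOSVDFactors,
    compound_mode: int,
    vector_set: Sequence[int],
    method: str = "gap",
    max_fraction: float = 0.25,
    z_k: float = 2.0,
    threshold: float = 0.01,
    labels: Sequence[str] | None = None,
) -> CompoundSelection:
    """Pick the outlying compounds on the chosen compound singular vector(s).

    The per-compound score is the Euclidean distance from the origin over
    ``vector_set`` (``|u|`` for a single vector).  Methods:

    - ``"gap"`` (default): sort scores descending, split at the largest
      consecutive gap within the leading ``ceil(max_fraction * n)``
      positions, and keep the far-from-origin cluster.  Cluster membership
      has no unique definition, so the method and parameters are recorded
      in the output.
    - ``"zscore"``: keep scores exceeding ``mean + z_k * sd``.
    - ``"chi2"``: the same chi-squared scoring used for genes, BH-adjusted,
      selecting adjusted ``P < threshold``.

    All-equal scores yield an empty selection with a degeneracy flag.
    """
    rows = np.asarray([int(l) - 1 for l in vector_set])
    if rows.size == 0:
        raise ValueError("vector_set must be nonempty")
    u = factors.factors[compound_mode][rows]
    scores = np.sqrt((u**2).sum(axis=0))
    n = scores.size
    label_list = list(labels) if labels is not None else None
    if np.ptp(scores) == 0:
        return CompoundSelection(
            scores, np.zeros(n, bool), method, {}, [int(l) for l in vector_set],
            degenerate=True, labels=label_list,
        )
    if method == "gap":
        order = np.argsort(-scores, kind="stable")
        s_sorted = scores[order]
        limit = max(1, int(np.ceil(max_fraction * n)))
        limit = min(limit, n - 1)
        gaps = s_sorted[:limit] - s_sorted[1 : limit + 1]
        n_keep = int(np.argmax(gaps)) + 1
        selected = np.zeros(n, bool)
        selected[order[:n_keep]] = True
        params = {"max_fraction": max_fraction, "n_keep": n_keep}
    elif method == "zscore":
        cut = scores.mean() + z_k * scores.std()
        selected = scores > cut
        params = {"z_k": z_k, "cut": float(cut)}
    elif method == "chi2":
        _, p, _ = chi2_feature_scores(factors.factors[compound_mode], vector_set)
        adjusted = benjamini_hochberg(p)
        selected = adjusted < threshold
        params = {"threshold": threshold}
    else:
        raise ValueError(f"unknown method {method!r}")
    return CompoundSelection(
        scores, selected, method, params, [int(l) for l in vector_set],
        labels=label_list,
    )


def gene_table(selection: GeneSelection) -> "pandas.DataFrame":  # noqa: F821
    """Per-gene TSV-ready table (symbol, score, P, adjusted P, selected)."""
    import pandas as pd

    labels = selection.labels or [str(i) for i in range(selection.scores.size)]
    return pd.DataFrame(
        {
            "symbol": labels,
            "score": selection.scores,
            "p_value": selection.p_values,
            "adjusted_p": selection.adjusted,
            "selected": selection.selected,
        }
    )


def compound_table(selection: CompoundSelection) -> "pandas.DataFrame":  # noqa: F821
    """Per-compound TSV-ready table (name, score, selected, method, params)."""
    import pandas as pd

    labels = selection.labels or [str(i) for i in range(selection.scores.size)]
    return pd.DataFrame(
        {
            "compound": labels,
            "score": selection.scores,
            "selected": selection.selected,
            "method": selection.method,
            "params": repr(selection.params),
        }
    )
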