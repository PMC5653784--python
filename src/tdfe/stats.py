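"""Evaluation statistics: target-overlap tests, enrichment, binding affinity.

Predicted drug-target gene sets are compared with reference target sets in
a 2x2 contingency table (rows: reference status, columns: predicted
status) evaluated by Fisher's exact test — with the conditional
maximum-likelihood odds ratio as the headline effect size, alongside the
sample odds ratio ``ad/bc`` — and by the uncorrected chi-squared test.
Gene-set over-representation against GMT libraries replaces a web
enrichment service so the pipeline runs offline.  Docking energies are
converted to dissociation-style affinities via ``Ki = exp(-dG / RT)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from scipy.stats import contingency as sp_contingency

from .selection import benjamini_hochberg


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for predicted-vs-reference membership over a gene universe.

    Rows are reference status (absent / present), columns predicted status
    (absent / present): ``a`` neither, ``b`` predicted only, ``c``
    reference only, ``d`` both.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in counts):
            raise ValueError("counts must be non-negative integers")
        if sum(counts) == 0:
            raise ValueError("the table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclass
class OverlapResult:
    """Association statistics for one 2x2 overlap table."""

    fisher_p: float
    or_mle: float  # NaN when a margin is zero (odds ratio undefined)
    or_sample: float
    chi2_p: float | None = None
    or_defined: bool = True


def overlap_table(
    predicted: Iterable[str],
    reference: Iterable[str],
    universe: Iterable[str],
) -> ContingencyTable2x2:
    """Cross-tabulate predicted and reference gene sets over a universe."""
    universe = set(universe)
    predicted = set(predicted)
    reference = set(reference)
    stray = (predicted | reference) - universe
    if stray:
        raise ValueError(f"{len(stray)} element(s) outside the universe, "
                         f"e.g. {sorted(stray)[:3]}")
    d = len(predicted & reference)
    b = len(predicted - reference)
    c = len(reference - predicted)
    a = len(universe) - b - c - d
    return ContingencyTable2x2(a, b, c, d)


def fisher_exact(
    table: ContingencyTable2x2, compute_odds_ratio: bool = True
) -> OverlapResult:
    """Two-sided Fisher's exact test with the conditional-MLE odds ratio.

    The two-sided P sums hypergeometric probabilities of all tables with
    the observed margins that are no more probable than the observed one.
    The headline odds ratio maximizes the noncentral hypergeometric
    likelihood conditional on the margins (the estimate printed by
    standard exact-test routines); the sample odds ratio ``ad/bc`` is
    reported alongside.  A zero margin makes the odds ratio undefined:
    ``P = 1`` and the result is flagged.  ``compute_odds_ratio=False``
    skips the (iterative) MLE when only the P-value is needed.
    """
    arr = table.as_array()
    if 0 in table.margins:
        return OverlapResult(1.0, math.nan, _sample_or(table), or_defined=False)
    p = float(sp_stats.fisher_exact(arr, alternative="two-sided").pvalue)
    or_mle = math.nan
    if compute_odds_ratio:
        or_mle = float(sp_contingency.odds_ratio(arr, kind="conditional").statistic)
    return OverlapResult(p, or_mle, _sample_or(table))


def _sample_or(table: ContingencyTable2x2) -> float:
    if table.b * table.c == 0:
        return math.inf if table.a * table.d > 0 else math.nan
    return table.a * table.d / (table.b * table.c)


@dataclass
class Chi2Result:
    statistic: float
    pvalue: float


def chi_square_2x2(
    table: ContingencyTable2x2, correction: bool = False
) -> Chi2Result:
    """Chi-squared test of independence on a 2x2 table, uncorrected by default.

    ``chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))`` with 1 degree of
    freedom; the Yates continuity correction is available but off, since
    the evaluation convention here is the uncorrected statistic.
    """
    if 0 in table.margins:
        raise ValueError("all margins must be positive for the chi-squared test")
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    diff = abs(a * d - b * c)
    if correction:
        diff = max(diff - n / 2, 0)
    denom = math.prod(table.margins)
    chi2 = n * diff**2 / denom
    return Chi2Result(float(chi2), float(sp_stats.chi2.sf(chi2, df=1)))


def evaluate_overlap(table: ContingencyTable2x2) -> OverlapResult:
    """Fisher and uncorrected chi-squared tests together (one table row)."""
    res = fisher_exact(table)
    if 0 not in table.margins:
        res.chi2_p = chi_square_2x2(table).pvalue
    return res


@dataclass(frozen=True)
class AffinityParams:
    """Constants for the energy-to-affinity conversion.

    ``R`` in J/(mol K), ``T`` in kelvin, and the thermochemical
    kcal-to-joule factor (binding energies are quoted in kcal/mol).
    """

    R: float = 8.31
    T: float = 300.0
    kcal_to_J: float = 4184.0

    def __post_init__(self) -> None:
        if self.R <= 0 or self.T <= 0 or self.kcal_to_J <= 0:
            raise ValueError("R, T and kcal_to_J must all be positive")


def delta_g_to_ki(delta_g: float, params: AffinityParams = AffinityParams()) -> float:
    """Dissociation-style affinity ``Ki = exp(-dG / RT)`` in mol/L.

    ``delta_g`` is the docking binding energy as a positive magnitude in
    kcal/mol; larger energies give tighter (smaller) Ki.
    """
    if delta_g < 0:
        raise ValueError("binding energies are quoted as positive magnitudes")
    return math.exp(-delta_g * params.kcal_to_J / (params.R * params.T))


def format_ki(ki_molar: float) -> str:
    """Format a molar affinity at two significant figures in M/mM/uM/nM/pM."""
    if not ki_molar > 0:
        raise ValueError("Ki must be positive")
    # choose the largest unit whose mantissa is at least 0.1
    for unit, scale in (("M", 1.0), ("mM", 1e-3), ("uM", 1e-6), ("nM", 1e-9)):
        if ki_molar / scale >= 0.0995:
            return f"{float(f'{ki_molar / scale:.2g}'):g} {unit}"
    return f"{float(f'{ki_molar / 1e-12:.2g}'):g} pM"


@dataclass
class GeneSetLibrary:
    """Named gene sets (GMT-style), symbols uppercased, names unique."""

    sets: dict[str, list[str]]
    source_file: str | None = None

    def __post_init__(self) -> None:
        self.sets = {
            name: sorted({g.upper() for g in genes}) for name, genes in self.sets.items()
        }


def read_gmt(path: str | Path) -> GeneSetLibrary:
    """Read a GMT gene-set library (name, description, member genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{line_no}: GMT lines need >= 3 fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}: duplicate set name {name!r}")
            sets[name] = [g for g in fields[2:] if g]
    return GeneSetLibrary(sets, source_file=str(path))


def gene_set_enrichment(
    selected: Iterable[str],
    library: GeneSetLibrary,
    universe: Iterable[str],
    threshold: float = 0.01,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per library set.

    For each set, the P-value is the probability of an overlap at least as
    large as observed when ``len(selected)`` genes are drawn from the
    universe without replacement; BH adjustment runs across the sets.  Sets
    are restricted to the universe before testing.  Returns a table with
    columns (set, set_size, overlap, p_value, adjusted_p, selected).
    """
    if not library.sets:
        raise ValueError("the gene-set library is empty")
    universe = {g.upper() for g in universe}
    selected = {g.upper() for g in selected}
    if not selected <= universe:
        raise ValueError("selected genes must lie inside the universe")
    N, n = len(universe), len(selected)
    names, sizes, overlaps, pvals = [], [], [], []
    for name, genes in library.sets.items():
        members = set(genes) & universe
        K = len(members)
        k = len(members & selected)
        p = 1.0 if n == 0 else float(sp_stats.hypergeom.sf(k - 1, N, K, n))
        names.append(name)
        sizes.append(K)
        overlaps.append(k)
        pvals.append(min(p, 1.0))
    adjusted = benjamini_hochberg(pvals)
    return pd.DataFrame(
        {
            "set": names,
            "set_size": sizes,
            "overlap": overlaps,
            "p_value": pvals,
            "adjusted_p": adjusted,
            "selected": adjusted < threshold,
        }
    )


@dataclass
class TargetOverlapReport:
    """Pooled predicted-vs-reference evaluation plus multi-targeting counts."""

    table: ContingencyTable2x2
    result: OverlapResult
    multi_targeting: dict[str, int]
    per_compound: dict[str, ContingencyTable2x2] = field(default_factory=dict)


def target_overlap_report(
    predicted: Mapping[str, Iterable[str]],
    reference: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> TargetOverlapReport:
    """Assemble the pooled overlap evaluation across compounds.

    Predicted and reference target genes are pooled by union across
    compounds (a gene counts as predicted/known if any selected compound
    lists it), cross-tabulated over the universe and tested.  The
    multi-targeting count of a gene is the number of compounds whose
    reference target set contains it.
    """
    universe = set(universe)
    pooled_pred: set[str] = set()
    pooled_ref: set[str] = set()
    per_compound: dict[str, ContingencyTable2x2] = {}
    for name, genes in predicted.items():
        pooled_pred |= set(genes)
    counts: dict[str, int] = {}
    for name, genes in reference.items():
        genes = set(genes)
        pooled_ref |= genes
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
        if name in predicted:
            per_compound[name] = overlap_table(predicted[name], genes, universe)
    table = overlap_table(pooled_pred, pooled_ref, universe)
    return TargetOverlapReport(table, evaluate_overlap(table), counts, per_compound)


def overlap_report_frame(
    rows: Mapping[str, ContingencyTable2x2]
) -> pd.DataFrame:
    """Evaluation-table-shaped TSV-ready frame: counts, P_F, P_chi2, ORs."""
    records = []
    for name, table in rows.items():
        res = evaluate_overlap(table)
        records.append(
            {
                "condition": name,
                "a": table.a,
                "b": table.b,
                "c": table.c,
                "d": table.d,
                "fisher_p": res.fisher_p,
                "chi2_p": res.chi2_p,
                "odds_ratio_mle": res.or_mle,
                "odds_ratio_sample": res.or_sample,
            }
        )
    return pd.DataFrame.from_records(records)
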