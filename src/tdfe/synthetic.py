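"""Synthetic drug-response tensors and disease matrices with planted truth.

The generator emulates the two inputs of the integrated analysis: a
compound x time x gene treatment tensor in which a small set of signal
genes responds monotonically with time under a few active compounds, and a
samples x gene disease matrix in which the *same* signal genes (with the
same signs) separate disease from control samples.  Sharing the signal
genes across the two datasets encodes the working premise of the method:
treatment-responsive expression alteration coincident with disease
progression.  The planted structure is rank-1 across modes, which a
higher-order SVD provably concentrates into a single core entry, so the
core-entry ranking, vector selection, and feature extraction stages are
all exercised meaningfully; an optional second, orthogonal planted factor
tests multi-vector selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotated_tensor import AnnotatedTensor


@dataclass
class SyntheticConfig:
    """Study conditions for the planted-signal generator.

    Effect sizes are standardized (in units of the noise standard
    deviation); the defaults plant a twofold alteration against unit
    Gaussian noise — strong-responder genes in a curated toxicogenomic
    course — across 4 active compounds out of 30 and 60 signal genes out
    of 2000, with the four DrugMatrix-style sampling days.
    """

    n_compounds: int = 30
    n_times: int = 4
    n_samples_per_class: int = 20
    n_classes: int = 2
    n_genes: int = 2000
    n_signal_genes: int = 60
    n_active_compounds: int = 4
    drug_effect: float = 2.0
    disease_effect: float = 2.0
    noise_sd: float = 1.0
    time_values: Sequence[float] = (0.25, 1.0, 3.0, 5.0)
    seed: int = 0
    noise_model: str = "normal"  # or "lognormal"
    two_factor: bool = False

    def __post_init__(self) -> None:
        if self.n_signal_genes > self.n_genes:
            raise ValueError("n_signal_genes exceeds n_genes")
        if self.n_active_compounds > self.n_compounds:
            raise ValueError("n_active_compounds exceeds n_compounds")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if len(self.time_values) != self.n_times:
            raise ValueError("time_values length must equal n_times")
        if self.noise_model not in ("normal", "lognormal"):
            raise ValueError("noise_model must be 'normal' or 'lognormal'")
        if self.two_factor and (
            2 * self.n_signal_genes > self.n_genes
            or 2 * self.n_active_compounds > self.n_compounds
        ):
            raise ValueError("two_factor needs room for a disjoint second factor")


@dataclass
class SyntheticTruth:
    """Planted identities: which genes and compounds carry signal."""

    signal_genes: np.ndarray  # sorted indices
    active_compounds: np.ndarray  # sorted indices
    gene_signs: np.ndarray  # +-1 per signal gene, aligned with signal_genes
    signal_genes_2: np.ndarray = field(default_factory=lambda: np.array([], int))
    active_compounds_2: np.ndarray = field(default_factory=lambda: np.array([], int))


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _noise(rng: np.random.Generator, config: SyntheticConfig, shape) -> np.ndarray:
    if config.noise_model == "lognormal":
        # zero-mean, sd-matched log-normal noise mirroring expression scale
        raw = rng.lognormal(mean=0.0, sigma=1.0, size=shape)
        raw = (raw - np.exp(0.5)) / np.sqrt((np.e - 1) * np.e)
        return config.noise_sd * raw
    return rng.normal(0.0, config.noise_sd, size=shape)


def centered_time_profile(time_values: Sequence[float]) -> np.ndarray:
    """Days centred and scaled to unit (population) variance."""
    t = np.asarray(time_values, dtype=float)
    return (t - t.mean()) / t.std()


def simulate_drug_tensor(
    config: SyntheticConfig,
) -> tuple[AnnotatedTensor, SyntheticTruth]:
    """Baseline-plus-noise treatment tensor with a planted monotone response.

    ``x[j1, j2, i] = eps + drug_effect * a[j1] * tau[j2] * s[i]`` with
    ``a`` the active-compound indicator, ``tau`` the centred scaled day
    value and ``s`` a random ``+-1`` sign on signal genes (0 elsewhere);
    deterministic under the config seed.
    """
    rng = _rng(config, 0)
    pick = _rng(config, 1)
    signal = np.sort(pick.choice(config.n_genes, config.n_signal_genes, replace=False))
    active = np.sort(
        pick.choice(config.n_compounds, config.n_active_compounds, replace=False)
    )
    signs = pick.choice([-1.0, 1.0], size=config.n_signal_genes)

    a = np.zeros(config.n_compounds)
    a[active] = 1.0
    tau = centered_time_profile(config.time_values)
    s = np.zeros(config.n_genes)
    s[signal] = signs

    shape = (config.n_compounds, config.n_times, config.n_genes)
    x = _noise(rng, config, shape)
    x += config.drug_effect * a[:, None, None] * tau[None, :, None] * s[None, None, :]

    truth = SyntheticTruth(signal, active, signs)
    if config.two_factor:
        # disjoint second factor with a time profile orthogonal to tau
        remaining_g = np.setdiff1d(np.arange(config.n_genes), signal)
        remaining_c = np.setdiff1d(np.arange(config.n_compounds), active)
        signal2 = np.sort(pick.choice(remaining_g, config.n_signal_genes, replace=False))
        active2 = np.sort(
            pick.choice(remaining_c, config.n_active_compounds, replace=False)
        )
        tau2 = _orthogonal_profile(tau)
        a2 = np.zeros(config.n_compounds)
        a2[active2] = 1.0
        s2 = np.zeros(config.n_genes)
        s2[signal2] = pick.choice([-1.0, 1.0], size=config.n_signal_genes)
        x += config.drug_effect * a2[:, None, None] * tau2[None, :, None] * s2[None, None, :]
        truth.signal_genes_2 = signal2
        truth.active_compounds_2 = active2

    tensor = AnnotatedTensor(
        x,
        mode_roles=["compound", "time", "gene"],
        mode_labels=[
            [f"compound_{j:03d}" for j in range(config.n_compounds)],
            [f"{t:g}d" for t in config.time_values],
            [f"GENE{i:05d}" for i in range(config.n_genes)],
        ],
        time_values={1: list(config.time_values)},
    )
    return tensor, truth


def _orthogonal_profile(tau: np.ndarray) -> np.ndarray:
    """A unit-variance profile orthogonal to ``tau`` (quadratic-like)."""
    q = tau**2
    q = q - q.mean()
    q = q - (q @ tau) / (tau @ tau) * tau
    return q / q.std()


def simulate_disease_matrix(
    config: SyntheticConfig, truth: SyntheticTruth
) -> AnnotatedTensor:
    """Disease expression matrix reusing the drug tensor's signal genes.

    ``x[j3, i] = eps + disease_effect * c[j3] * s[i]`` where ``c`` marks
    samples of the disease class (the last class) and ``s`` carries the
    same signal genes and signs as the paired treatment tensor.
    """
    rng = _rng(config, 2)
    n_samples = config.n_samples_per_class * config.n_classes
    class_names = ["control"] + [
        f"disease_{k}" if config.n_classes > 2 else "disease"
        for k in range(1, config.n_classes)
    ]
    labels = [c for c in class_names for _ in range(config.n_samples_per_class)]
    c = np.array([0.0 if lab == "control" else 1.0 for lab in labels])

    s = np.zeros(config.n_genes)
    s[truth.signal_genes] = truth.gene_signs
    x = _noise(rng, config, (n_samples, config.n_genes))
    x += config.disease_effect * c[:, None] * s[None, :]
    if config.two_factor and truth.signal_genes_2.size:
        s2 = np.zeros(config.n_genes)
        s2[truth.signal_genes_2] = 1.0
        x += config.disease_effect * c[:, None] * s2[None, :]

    return AnnotatedTensor(
        x,
        mode_roles=["sample", "gene"],
        mode_labels=[
            [f"sample_{j:03d}" for j in range(n_samples)],
            [f"GENE{i:05d}" for i in range(config.n_genes)],
        ],
        class_labels={0: labels},
    )


@dataclass
class RecoveryMetrics:
    """Precision/recall of a selection against the planted truth."""

    gene_precision: float
    gene_recall: float
    compound_precision: float
    compound_recall: float
    empty_gene_selection: bool = False
    empty_compound_selection: bool = False


def _precision_recall(selected: np.ndarray, true_idx: np.ndarray) -> tuple[float, float, bool]:
    sel = set(np.flatnonzero(selected).tolist())
    true = set(true_idx.tolist())
    if not sel:
        return 0.0, 0.0 if true else 1.0, True
    tp = len(sel & true)
    recall = tp / len(true) if true else 1.0
    return tp / len(sel), recall, False


def recovery_metrics(selection, truth: SyntheticTruth) -> RecoveryMetrics:
    """Exact set precision/recall for genes and compounds.

    ``selection`` is a :class:`tdfe.selection.SelectionResult`; empty
    selections report precision 0 with a flag rather than NaN.
    """
    true_genes = np.concatenate([truth.signal_genes, truth.signal_genes_2])
    true_compounds = np.concatenate([truth.active_compounds, truth.active_compounds_2])
    gp, gr, g_empty = _precision_recall(selection.genes.selected, true_genes)
    cp, cr, c_empty = _precision_recall(selection.compounds.selected, true_compounds)
    return RecoveryMetrics(gp, gr, cp, cr, g_empty, c_empty)
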