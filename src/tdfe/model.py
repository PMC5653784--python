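"""Model/Results interface driving the full integrated analysis.

:class:`DrugDiseaseTensorFE` couples a compound x time x gene treatment
tensor with one or more disease expression datasets, forms the
standardized product tensor, decomposes it by higher-order SVD, and — via
``fit()`` — runs the unsupervised feature-extraction chain: time-vector
selection, class-vector selection, constrained core-entry ranking, and
chi-squared gene / outlier compound selection.  ``fit`` returns a
:class:`DrugDiseaseTensorFEResults` carrying every intermediate together
with a ``summary()`` table, in the style of the statistical modelling
packages this one sits alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .annotated_tensor import (
    AnnotatedTensor,
    build_product_tensor,
    standardize_gene_fibers,
)
from .hosvd import HOSVDFactors, TopCoreResult, hosvd, top_core_entries
from .selection import (
    ClassVectorSelection,
    CompoundSelection,
    GeneSelection,
    SelectionResult,
    TimeVectorSelection,
    gene_pvalues,
    select_class_vectors,
    select_compounds,
    select_time_vector,
)

#: gene-mode components retained by default; constrained core ranking never
#: reaches deeper than a few hundred components in practice
DEFAULT_GENE_COMPONENTS = 200


class DrugDiseaseTensorFE:
    """Integrated tensor-decomposition feature extraction.

    Parameters
    ----------
    drug_tensor
        Compound x time x gene treatment tensor (day values attached to
        the time mode).
    disease_parts
        One or more disease expression datasets sharing the drug tensor's
        gene labels (sample class labels attached where available).
    standardize
        ``"parts"`` (default) standardizes every input dataset's gene
        fibers before multiplication; ``"product"`` standardizes only the
        product; ``"both"`` does both; ``"none"`` neither.  Whether the
        product should be re-standardized after multiplication is a
        genuinely open choice, so both behaviours are exposed.
    gene_components
        Cap on gene-mode components kept by the decomposition.
    shared_roles
        Mode roles identified across disease parts (e.g. ``("region",)``
        when two sample sets share a tissue-region mode).
    """

    def __init__(
        self,
        drug_tensor: AnnotatedTensor,
        disease_parts: AnnotatedTensor | Sequence[AnnotatedTensor],
        standardize: str = "parts",
        gene_components: int | None = DEFAULT_GENE_COMPONENTS,
        shared_roles: Sequence[str] = (),
    ) -> None:
        if standardize not in ("parts", "product", "both", "none"):
            raise ValueError("standardize must be parts|product|both|none")
        if isinstance(disease_parts, AnnotatedTensor):
            disease_parts = [disease_parts]
        self.drug_tensor = drug_tensor
        self.disease_parts = list(disease_parts)
        self.standardize = standardize
        self.gene_components = gene_components
        self.shared_roles = tuple(shared_roles)

        parts = [drug_tensor, *self.disease_parts]
        if standardize in ("parts", "both"):
            parts = [standardize_gene_fibers(p) for p in parts]
        product = build_product_tensor(parts, shared_roles=self.shared_roles)
        if standardize in ("product", "both"):
            product = standardize_gene_fibers(product)
        self.product = product

    @classmethod
    def from_synthetic(cls, config, **kwargs) -> tuple["DrugDiseaseTensorFE", "SyntheticTruth"]:  # noqa: F821
        """Build the model from the synthetic generator's paired outputs."""
        from .synthetic import simulate_disease_matrix, simulate_drug_tensor

        drug, truth = simulate_drug_tensor(config)
        disease = simulate_disease_matrix(config, truth)
        return cls(drug, disease, **kwargs), truth

    # -- mode bookkeeping ---------------------------------------------------

    def _mode(self, role: str) -> int:
        modes = [k for k, r in enumerate(self.product.mode_roles) if r == role]
        if not modes:
            raise ValueError(f"the product tensor has no {role!r} mode")
        return modes[0]

    def fit(
        self,
        n_components: Mapping[int, int] | None = None,
        time_component: int | None = None,
        class_components: Mapping[int, Sequence[int]] | Sequence[int] | None = None,
        class_threshold: float = 0.05,
        n_top_core: int = 10,
        gene_fdr: float = 0.01,
        compound_method: str = "gap",
        compound_kwargs: Mapping | None = None,
        log_days: bool = False,
    ) -> "DrugDiseaseTensorFEResults":
        """Decompose the product tensor and run the selection chain.

        Automatic choices (argmax-|r| time vector, BH-significant class
        vectors) can be pinned via ``time_component`` and
        ``class_components``; ``n_top_core`` core entries constrained to
        those vectors supply the gene and compound singular vectors for
        feature scoring.
        """
        product = self.product
        gene_mode = product.order - 1
        counts: dict[int, int | None] = dict(n_components or {})
        if self.gene_components is not None:
            rank = min(product.shape[gene_mode],
                       int(np.prod(product.shape)) // product.shape[gene_mode])
            counts.setdefault(gene_mode, min(self.gene_components, rank))
        factors = hosvd(product, counts or "full")

        time_mode = self._mode("time")
        time_sel = select_time_vector(
            factors,
            time_mode,
            product.time_values[time_mode],
            log_days=log_days,
            override=time_component,
        )

        sample_modes = [k for k, r in enumerate(product.mode_roles) if r == "sample"]
        class_sels: dict[int, ClassVectorSelection] = {}
        overrides: dict[int, Sequence[int]] = {}
        if class_components is not None:
            if isinstance(class_components, Mapping):
                overrides = dict(class_components)
            elif len(sample_modes) == 1:
                overrides = {sample_modes[0]: list(class_components)}
            else:
                raise ValueError("map class_components by mode for multi-sample tensors")
        for mode in sample_modes:
            if mode in product.class_labels:
                class_sels[mode] = select_class_vectors(
                    factors,
                    mode,
                    product.class_labels[mode],
                    threshold=class_threshold,
                    override=overrides.get(mode),
                )

        fixed: dict[int, Sequence[int]] = {time_mode: [time_sel.chosen]}
        for mode, sel in class_sels.items():
            if sel.chosen:
                fixed[mode] = sel.chosen
        top = top_core_entries(product, factors, fixed=fixed, K=n_top_core)

        compound_mode = self._mode("compound")
        gene_vectors = top.involved.get(gene_mode, [])
        # Compound vectors are kept only when they dominate the top core
        # entries: weight each candidate by its summed G^2 over the entries
        # that involve it and drop vectors far below the leading one.  With
        # one compound vector shared by all top entries (the common case)
        # exactly that vector survives; when several contribute comparably
        # they are all carried forward.
        weights: dict[int, float] = {}
        for e in top.entries:
            l1 = e.indices[compound_mode]
            weights[l1] = weights.get(l1, 0.0) + e.value**2
        w_max = max(weights.values()) if weights else 0.0
        compound_vectors = sorted(
            l for l, w in weights.items() if w >= 0.5 * w_max
        )
        genes = gene_pvalues(
            factors,
            gene_mode,
            gene_vectors,
            threshold=gene_fdr,
            labels=product.gene_labels,
        )
        compounds = select_compounds(
            factors,
            compound_mode,
            compound_vectors,
            method=compound_method,
            labels=product.mode_labels[compound_mode],
            **dict(compound_kwargs or {}),
        )
        return DrugDiseaseTensorFEResults(
            model=self,
            factors=factors,
            time_selection=time_sel,
            class_selections=class_sels,
            top_core=top,
            selection=SelectionResult(genes=genes, compounds=compounds),
            time_mode=time_mode,
            compound_mode=compound_mode,
            gene_mode=gene_mode,
        )


@dataclass
class DrugDiseaseTensorFEResults:
    """Everything the fitted feature extraction produced."""

    model: DrugDiseaseTensorFE
    factors: HOSVDFactors
    time_selection: TimeVectorSelection
    class_selections: dict[int, ClassVectorSelection]
    top_core: TopCoreResult
    selection: SelectionResult
    time_mode: int
    compound_mode: int
    gene_mode: int

    @property
    def genes(self) -> GeneSelection:
        return self.selection.genes

    @property
    def compounds(self) -> CompoundSelection:
        return self.selection.compounds

    @property
    def selected_genes(self) -> list[str]:
        return self.genes.selected_labels

    @property
    def selected_compounds(self) -> list[str]:
        return self.compounds.selected_labels

    def recovery(self, truth) -> "RecoveryMetrics":  # noqa: F821
        """Precision/recall against a synthetic planted truth."""
        from .synthetic import recovery_metrics

        return recovery_metrics(self.selection, truth)

    def summary(self) -> str:
        """Human-readable account of the fitted selection chain."""
        prod = self.model.product
        lines = [
            "Tensor-decomposition unsupervised feature extraction",
            "=" * 52,
            f"product tensor shape : {prod.shape}",
            f"mode roles           : {tuple(prod.mode_roles)}",
            f"components kept      : {self.factors.n_components}",
            (
                f"time vector (mode {self.time_mode})  : "
                f"l = {self.time_selection.chosen}, "
                f"r = {self.time_selection.correlations[self.time_selection.chosen - 1]:+.3f}"
            ),
        ]
        for mode, sel in self.class_selections.items():
            shown = ", ".join(str(l) for l in sel.chosen) or "(none)"
            lines.append(
                f"class vectors (mode {mode}): l = {shown} "
                f"at BH < {sel.threshold:g}"
            )
        lines.append(
            "top core entries     : "
            + "; ".join(
                f"G{e.indices} = {e.value:.3g}" for e in self.top_core.entries[:5]
            )
            + (" ..." if len(self.top_core.entries) > 5 else "")
        )
        g = self.genes
        lines += [
            f"gene vectors used    : {g.vector_set}",
            f"genes selected       : {int(g.selected.sum())} / {g.selected.size} "
            f"at BH < {g.threshold:g}",
            f"compound vectors used: {self.compounds.vector_set}",
            f"compounds selected   : {int(self.compounds.selected.sum())} "
            f"/ {self.compounds.selected.size} ({self.compounds.method})",
        ]
        if self.compounds.selected.any():
            names = ", ".join(self.selected_compounds[:8])
            more = "" if self.compounds.selected.sum() <= 8 else ", ..."
            lines.append(f"  -> {names}{more}")
        return "\n".join(lines)

    # -- plotting -----------------------------------------------------------

    def plot_time_vectors(self, ax=None):
        """Line plot of each time-mode singular vector against the days."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        days = np.asarray(self.model.product.time_values[self.time_mode], float)
        u = self.factors.factors[self.time_mode]
        for l, row in enumerate(u, start=1):
            r = self.time_selection.correlations[l - 1]
            ax.plot(days, row, marker="o", label=f"l={l} (r={r:+.2f})")
        ax.set_xlabel("days after treatment")
        ax.set_ylabel("singular vector component")
        ax.legend(fontsize="small")
        return ax

    def plot_compound_scores(self, ax=None, bins=30):
        """Histogram of compound loadings with the selected outliers marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        scores = self.compounds.scores
        ax.hist(scores, bins=bins, color="lightgray", edgecolor="black")
        for s in scores[self.compounds.selected]:
            ax.axvline(s, color="red", lw=1)
        ax.set_xlabel("distance from origin on compound vector(s)")
        ax.set_ylabel("compounds")
        return ax
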