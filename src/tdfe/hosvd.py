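"""Higher-order SVD (Tucker) decomposition with on-demand core entries.

The decomposition of an order-``m`` tensor ``x`` is

    x[j1..jm] = sum over (l1..lm) of G(l1..lm) * prod_k u[k][lk, jk]

where ``u[k]`` holds the left singular vectors of the mode-``k`` unfolding
(rows = component index ``lk``) and ``G`` is the core tensor.  At
genome scale the full core is far too large to materialize (for a
355 x 4 x 216 x 3961 product tensor it would match the tensor itself), so
only the factor matrices are stored and individual core entries — or small
constrained blocks of them — are computed on demand by contracting the
tensor with the chosen singular vectors.  Component indices ``l`` are
1-based throughout, matching the usual notation of the field.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotated_tensor import AnnotatedTensor, unfold

#: modes whose extent exceeds this prefer the Gram-matrix SVD route
_GRAM_THRESHOLD = 2048


@dataclass
class HOSVDFactors:
    """Per-mode orthonormal singular vector matrices of an HOSVD.

    ``factors[k]`` has shape ``(n_components_k, N_k)`` with the component
    index first, so ``factors[k][l - 1]`` is the ``l``-th singular vector of
    mode ``k``.  Rows are orthonormal; a deterministic sign convention
    (largest-magnitude entry positive, first such entry on ties) makes the
    decomposition a pure function of its input.
    """

    factors: list[np.ndarray]
    singular_values: list[np.ndarray]
    source_shape: tuple[int, ...]

    @property
    def n_components(self) -> tuple[int, ...]:
        return tuple(f.shape[0] for f in self.factors)

    def vector(self, mode: int, component: int) -> np.ndarray:
        """Singular vector ``u_{l}`` of ``mode`` (``component`` is 1-based)."""
        n = self.factors[mode].shape[0]
        if not 1 <= component <= n:
            raise IndexError(
                f"component {component} out of range 1..{n} for mode {mode}"
            )
        return self.factors[mode][component - 1]

    def max_orthonormality_error(self) -> float:
        err = 0.0
        for f in self.factors:
            g = f @ f.T
            err = max(err, float(np.abs(g - np.eye(g.shape[0])).max()))
        return err


@dataclass(frozen=True)
class CoreEntry:
    """One core-tensor coefficient ``G(l1, ..., lm)`` (1-based indices)."""

    indices: tuple[int, ...]
    value: float


def _fix_signs(u: np.ndarray) -> np.ndarray:
    """Flip rows so the largest-magnitude entry of each is positive.

    ``argmax`` returns the first maximizer, so ties resolve to the lowest
    index; the convention makes repeated runs bit-identical.
    """
    u = u.copy()
    lead = np.abs(u).argmax(axis=1)
    flip = u[np.arange(u.shape[0]), lead] < 0
    u[flip] *= -1.0
    return u


def _left_singular(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Left singular vectors and singular values of ``a`` (rows x cols).

    When the row count is large relative to the column count the economy
    SVD is taken on the Gram matrix of the smaller side and mapped back,
    which is equivalent up to numerically rank-deficient directions and
    much cheaper for gene modes.
    """
    n, m = a.shape
    if n > _GRAM_THRESHOLD and n > 4 * m:
        gram = a.T @ a  # m x m
        w, v = np.linalg.eigh(gram)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        w = np.clip(w, 0.0, None)
        s = np.sqrt(w)
        keep = s > s[0] * 1e-12 if s.size and s[0] > 0 else np.zeros_like(s, bool)
        u = np.zeros((n, m))
        u[:, keep] = (a @ v[:, keep]) / s[keep]
        return u.T, s
    u, s, _ = np.linalg.svd(a, full_matrices=False)
    return u.T, s


def _resolve_components(
    n_components: int | str | Sequence[int | None] | Mapping[int, int] | None,
    shape: tuple[int, ...],
) -> list[int]:
    ranks = [min(n, int(np.prod(shape)) // n) for n in shape]
    if n_components in (None, "full"):
        return ranks
    if isinstance(n_components, int):
        req = [min(n_components, r) for r in ranks]
        return req
    if isinstance(n_components, Mapping):
        seq: list[int | None] = [n_components.get(k) for k in range(len(shape))]
    else:
        seq = list(n_components)
        if len(seq) != len(shape):
            raise ValueError("one component count per mode is required")
    out = []
    for k, (want, rank) in enumerate(zip(seq, ranks)):
        if want is None:
            out.append(rank)
        elif want > rank:
            raise ValueError(
                f"mode {k}: {want} components requested but the economy rank "
                f"is {rank}"
            )
        else:
            out.append(int(want))
    return out


def hosvd(
    tensor: AnnotatedTensor | np.ndarray,
    n_components: int | str | Sequence[int | None] | Mapping[int, int] | None = "full",
) -> HOSVDFactors:
    """Higher-order SVD: per-mode left singular vectors of each unfolding.

    Parameters
    ----------
    tensor
        The (standardized product) tensor to decompose.
    n_components
        ``"full"`` keeps every attainable component per mode; an int caps
        all modes at that many (never exceeding the economy rank); a
        sequence or ``{mode: count}`` mapping sets per-mode limits, where
        requesting more than the economy rank is an error.
    """
    x = tensor.values if isinstance(tensor, AnnotatedTensor) else np.asarray(tensor, float)
    if not np.isfinite(x).all():
        raise ValueError("tensor contains non-finite values")
    counts = _resolve_components(n_components, x.shape)
    factors: list[np.ndarray] = []
    sigmas: list[np.ndarray] = []
    for k, keep in enumerate(counts):
        u, s = _left_singular(unfold(x, k))
        factors.append(_fix_signs(u[:keep]))
        sigmas.append(s[:keep])
    return HOSVDFactors(factors, sigmas, x.shape)


def core_entry(
    tensor: AnnotatedTensor | np.ndarray,
    factors: HOSVDFactors,
    indices: Sequence[int],
) -> CoreEntry:
    """Core coefficient ``G(l1..lm)`` by full contraction with the chosen vectors."""
    x = tensor.values if isinstance(tensor, AnnotatedTensor) else np.asarray(tensor, float)
    if len(indices) != x.ndim:
        raise ValueError("one component index per mode is required")
    out = x
    for mode, l in enumerate(indices):
        vec = factors.vector(mode, int(l))
        out = np.tensordot(vec, out, axes=([0], [0]))
    return CoreEntry(tuple(int(l) for l in indices), float(out))


def core_block(
    tensor: AnnotatedTensor | np.ndarray,
    factors: HOSVDFactors,
    allowed: Sequence[Sequence[int]],
) -> np.ndarray:
    """Dense block of core entries for per-mode lists of 1-based components."""
    x = tensor.values if isinstance(tensor, AnnotatedTensor) else np.asarray(tensor, float)
    out = x
    for mode, idx in enumerate(allowed):
        rows = np.asarray([int(l) - 1 for l in idx])
        if rows.size == 0:
            raise ValueError(f"mode {mode}: empty component set")
        if rows.min() < 0 or rows.max() >= factors.factors[mode].shape[0]:
            raise IndexError(f"mode {mode}: component index out of range")
        u = factors.factors[mode][rows]  # (len(idx), N_mode)
        # contract the current leading axis, append the component axis last
        out = np.tensordot(u, out, axes=([1], [0]))
        out = np.moveaxis(out, 0, -1)
    return out


@dataclass
class TopCoreResult:
    """Largest-|G| core entries under per-mode constraints."""

    entries: list[CoreEntry]
    #: distinct component indices per unconstrained mode among the entries
    involved: dict[int, list[int]]
    constrained_modes: tuple[int, ...]


def top_core_entries(
    tensor: AnnotatedTensor | np.ndarray,
    factors: HOSVDFactors,
    fixed: Mapping[int, Iterable[int]] | None = None,
    K: int = 10,
) -> TopCoreResult:
    """The ``K`` core entries of largest magnitude satisfying constraints.

    ``fixed`` maps a mode to the component indices it may take (e.g. the
    time mode pinned to its time-dependent vector and the sample mode to
    the class-separating vectors); unconstrained modes range over all their
    components.  Entries are sorted by decreasing ``|G|`` with ties broken
    by lexicographic index order.  Alongside the entries, the distinct
    component indices of each unconstrained mode are reported — these are
    the gene / compound singular vectors carried into feature selection.
    """
    if K < 1:
        raise ValueError("K must be at least 1")
    fixed = {int(k): sorted(int(l) for l in v) for k, v in (fixed or {}).items()}
    for mode, lset in fixed.items():
        if not lset:
            raise ValueError(f"mode {mode}: empty constraint set")
    m = len(factors.factors)
    allowed = [
        fixed.get(k, list(range(1, factors.factors[k].shape[0] + 1))) for k in range(m)
    ]
    block = core_block(tensor, factors, allowed)
    flat = block.reshape(-1)
    order = np.argsort(-np.abs(flat), kind="stable")
    # stable sort on C-order flattening gives lexicographic tie-breaking
    take = order[: min(K, flat.size)]
    entries = []
    for pos in take:
        sub = np.unravel_index(pos, block.shape)
        idx = tuple(allowed[k][sub[k]] for k in range(m))
        entries.append(CoreEntry(idx, float(flat[pos])))
    involved: dict[int, list[int]] = {}
    for k in range(m):
        if k not in fixed:
            involved[k] = sorted({e.indices[k] for e in entries})
    return TopCoreResult(entries, involved, tuple(sorted(fixed)))
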