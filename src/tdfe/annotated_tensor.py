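"""Labelled dense expression tensors and the operations that build them.

The central container is :class:`AnnotatedTensor`: a dense real array in
which every axis ("mode") has a biological role — compound, time point,
sample, tissue region — except the last, which is always the gene mode.
Expression integrated across independent experiments is represented as a
*product tensor*: the elementwise product of two or more datasets over
their shared gene index (and optionally other shared modes), which couples
a drug-treatment time course with a disease case/control matrix without
introducing any dataset weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

MODE_ROLES = ("compound", "time", "sample", "region", "gene")


@dataclass
class AnnotatedTensor:
    """Dense order-``m`` expression array with labelled modes.

    Parameters
    ----------
    values
        Real array of order ``m``; the last axis indexes genes.
    mode_roles
        One role per axis, drawn from ``{"compound", "time", "sample",
        "region", "gene"}``.  Exactly one ``"gene"`` mode is allowed and it
        must be last.
    mode_labels
        One identifier list per axis (compound names, day strings, sample
        ids, gene symbols); lengths must match the array extents.
    class_labels
        Optional mapping ``axis -> per-element categorical labels`` for
        sample modes (e.g. ``{"0": ["control", "disease", ...]}``).
    time_values
        Optional mapping ``axis -> numeric day values`` for time-like modes.
    """

    values: np.ndarray
    mode_roles: Sequence[str]
    mode_labels: Sequence[Sequence[str]]
    class_labels: Mapping[int, Sequence[str]] = field(default_factory=dict)
    time_values: Mapping[int, Sequence[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mode_roles = list(self.mode_roles)
        self.mode_labels = [list(lab) for lab in self.mode_labels]
        self.class_labels = {int(k): list(v) for k, v in dict(self.class_labels).items()}
        self.time_values = {
            int(k): np.asarray(v, dtype=float) for k, v in dict(self.time_values).items()
        }
        if self.values.ndim != len(self.mode_roles):
            raise ValueError(
                f"{self.values.ndim} array axes but {len(self.mode_roles)} mode roles"
            )
        unknown = set(self.mode_roles) - set(MODE_ROLES)
        if unknown:
            raise ValueError(f"unknown mode roles: {sorted(unknown)}")
        if self.mode_roles.count("gene") != 1 or self.mode_roles[-1] != "gene":
            raise ValueError("exactly one gene mode is required and it must be last")
        if len(self.mode_labels) != self.values.ndim:
            raise ValueError("one label list per mode is required")
        for k, labels in enumerate(self.mode_labels):
            if len(labels) != self.values.shape[k]:
                raise ValueError(
                    f"mode {k} has extent {self.values.shape[k]} but "
                    f"{len(labels)} labels"
                )
        for k, labels in self.class_labels.items():
            if len(labels) != self.values.shape[k]:
                raise ValueError(f"class labels for mode {k} have wrong length")
        for k, tv in self.time_values.items():
            if len(tv) != self.values.shape[k]:
                raise ValueError(f"time values for mode {k} have wrong length")
        if not np.isfinite(self.values).all():
            idx = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(f"non-finite value at index {tuple(int(i) for i in idx)}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def order(self) -> int:
        return self.values.ndim

    @property
    def gene_labels(self) -> list[str]:
        return self.mode_labels[-1]

    def modes_with_role(self, role: str) -> list[int]:
        return [k for k, r in enumerate(self.mode_roles) if r == role]


def standardize_gene_fibers(tensor: AnnotatedTensor) -> AnnotatedTensor:
    """Standardize every gene-mode fiber to zero sum and sum of squares ``N_gene``.

    Each fiber (the expression profile over genes at one fixed combination
    of the other modes) is centred and rescaled so that ``sum_i x = 0`` and
    ``sum_i x**2 = N_gene``.  Fibers that are constant before centring (flat
    probesets) become all-zero; annotations are carried over unchanged.
    """
    x = tensor.values
    n_genes = x.shape[-1]
    if n_genes < 2:
        raise ValueError("gene mode needs at least two genes to standardize")
    centered = x - x.mean(axis=-1, keepdims=True)
    ss = np.einsum("...i,...i->...", centered, centered)[..., None]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = centered * np.sqrt(n_genes / ss)
    out[np.broadcast_to(ss == 0, out.shape)] = 0.0  # constant fibers -> zero
    return replace(tensor, values=out)


def product_layout(
    roles_per_part: Sequence[Sequence[str]],
    labels_per_part: Sequence[Sequence[Sequence[str]]],
    shared_roles: Sequence[str] = (),
) -> tuple[list[str], list[tuple[int, int]], list[str]]:
    """Decide the mode order of a product tensor without materializing it.

    Non-gene modes appear in first-occurrence order across the parts, the
    gene mode once at the end; a mode whose role is in ``shared_roles`` is
    identified across all parts that carry it (labels must agree) and
    appears once.  Returns ``(output_roles, output_sources, subscripts)``
    where ``output_sources[j] = (part, axis)`` names the first part carrying
    output mode ``j`` and ``subscripts`` are einsum letters per part.
    """
    shared_roles = set(shared_roles)
    letters = iter("abcdefghjklmnopqrstuvwxyz")
    gene_letter = "i"
    out_roles: list[str] = []
    out_sources: list[tuple[int, int]] = []
    out_letters: list[str] = []
    shared_letter: dict[str, str] = {}
    shared_labels: dict[str, Sequence[str]] = {}
    subscripts: list[str] = []
    for p, (roles, labels) in enumerate(zip(roles_per_part, labels_per_part)):
        sub = ""
        for axis, role in enumerate(roles):
            if role == "gene":
                sub += gene_letter
                continue
            if role in shared_roles:
                if role in shared_letter:
                    if list(labels[axis]) != list(shared_labels[role]):
                        raise ValueError(
                            f"shared mode '{role}' has mismatched labels in part {p}"
                        )
                    sub += shared_letter[role]
                    continue
                shared_letter[role] = next(letters)
                shared_labels[role] = labels[axis]
                sub += shared_letter[role]
            else:
                sub += next(letters)
            out_roles.append(role)
            out_sources.append((p, axis))
            out_letters.append(sub[-1])
        subscripts.append(sub)
    out_roles.append("gene")
    out_sources.append((0, len(roles_per_part[0]) - 1))
    out_letters.append(gene_letter)
    einsum = ",".join(subscripts) + "->" + "".join(out_letters)
    return out_roles, out_sources, [einsum]


def build_product_tensor(
    parts: Sequence[AnnotatedTensor],
    shared_roles: Sequence[str] = (),
) -> AnnotatedTensor:
    """Elementwise product of expression datasets over the shared gene index.

    All parts must carry identical gene-label lists (intersect beforehand
    with :func:`tdfe.io.intersect_gene_symbols`).  Modes whose role appears
    in ``shared_roles`` are identified across parts — their extents and
    labels must agree — and occur once in the output.  Every output entry is
    the product of the corresponding entries of all parts, e.g.
    ``x~[j1,j2,j3,i] = x[j1,j2,i] * x[j3,i]``.
    """
    if not parts:
        raise ValueError("at least one part is required")
    genes0 = parts[0].gene_labels
    for p, part in enumerate(parts[1:], start=1):
        if part.gene_labels != genes0:
            raise ValueError(
                f"part {p} gene labels differ from part 0 "
                f"({len(part.gene_labels)} vs {len(genes0)} symbols)"
            )
    roles, sources, (einsum,) = product_layout(
        [p.mode_roles for p in parts], [p.mode_labels for p in parts], shared_roles
    )
    values = np.einsum(einsum, *[p.values for p in parts])
    labels = [parts[p].mode_labels[a] for p, a in sources]
    class_labels: dict[int, Sequence[str]] = {}
    time_values: dict[int, Sequence[float]] = {}
    for out_axis, (p, a) in enumerate(sources):
        if a in parts[p].class_labels:
            class_labels[out_axis] = parts[p].class_labels[a]
        if a in parts[p].time_values:
            time_values[out_axis] = parts[p].time_values[a]
    return AnnotatedTensor(values, roles, labels, class_labels, time_values)


def unfold(tensor: AnnotatedTensor | np.ndarray, mode: int) -> np.ndarray:
    """Mode-``k`` matricization: ``N_k`` rows, remaining modes as columns.

    Column ordering: the remaining modes keep their original order with the
    first of them varying fastest (Fortran order over the non-unfolded
    axes).  Any fixed convention works for extracting left singular
    vectors; this one is used consistently throughout.
    """
    x = tensor.values if isinstance(tensor, AnnotatedTensor) else np.asarray(tensor)
    if not -x.ndim <= mode < x.ndim:
        raise ValueError(f"mode {mode} out of range for order-{x.ndim} tensor")
    return np.moveaxis(x, mode, 0).reshape(x.shape[mode], -1, order="F")


def product_shape(
    shapes: Sequence[Sequence[int]],
    roles_per_part: Sequence[Sequence[str]],
    shared_roles: Sequence[str] = (),
) -> tuple[int, ...]:
    """Output shape of :func:`build_product_tensor` for given part shapes."""
    fake_labels = [
        [[f"m{p}a{a}x{j}" for j in range(n)] for a, n in enumerate(shape)]
        for p, shape in enumerate(shapes)
    ]
    # shared/gene modes must present identical labels across parts
    shared = set(shared_roles) | {"gene"}
    first: dict[str, list[str]] = {}
    for p, roles in enumerate(roles_per_part):
        for a, role in enumerate(roles):
            if role in shared:
                if role not in first:
                    first[role] = [f"{role}{j}" for j in range(shapes[p][a])]
                fake_labels[p][a] = first[role]
    _, sources, _ = product_layout(roles_per_part, fake_labels, shared_roles)
    return tuple(shapes[p][a] for p, a in sources)
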