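"""Reading and writing the pipeline's file formats.

Supported formats: the GEO series-matrix dialect (``!``-prefixed metadata
lines around a tab-separated data block delimited by
``!series_matrix_table_begin`` / ``!series_matrix_table_end``, optionally
gzip-compressed), two-column probe-to-symbol TSV maps, and a hierarchical
HDF5 container for labelled tensors and decomposition factors.  Gene
spaces from different platforms or species are aligned by uppercased gene
symbol, averaging probes that collapse onto one symbol and restricting to
symbols present in every table.
"""

from __future__ import annotations

import gzip
import io as _io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

from .annotated_tensor import AnnotatedTensor
from .hosvd import HOSVDFactors

log = logging.getLogger("tdfe")

TABLE_BEGIN = "!series_matrix_table_begin"
TABLE_END = "!series_matrix_table_end"


@dataclass
class ExpressionTable:
    """Probes/genes x samples matrix with per-sample metadata."""

    matrix: np.ndarray
    row_ids: list[str]
    sample_ids: list[str]
    sample_metadata: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.row_ids), len(self.sample_ids)):
            raise ValueError("matrix shape does not match row/sample id counts")
        if any(not str(r) for r in self.row_ids):
            raise ValueError("row ids must be nonempty strings")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.row_ids, columns=self.sample_ids)


def _unquote(s: str) -> str:
    s = s.strip()
    if len(s) >= 2 and s[0] == '"' and s[-1] == '"':
        return s[1:-1]
    return s


def read_series_matrix(path: str | Path) -> ExpressionTable:
    """Parse a GEO series-matrix file (plain or gzipped)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    metadata: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    saw_begin = saw_end = False
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(TABLE_BEGIN):
                in_table, saw_begin = True, True
                continue
            if line.startswith(TABLE_END):
                in_table, saw_end = False, True
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!"):
                key, _, rest = line[1:].partition("\t")
                values = [_unquote(v) for v in rest.split("\t")] if rest else []
                metadata.setdefault(key, []).extend(values)
    if not (saw_begin and saw_end):
        raise ValueError(f"{path}: missing series-matrix table delimiters")
    if not table_lines:
        raise ValueError(f"{path}: empty data block")
    frame = pd.read_csv(
        _io.StringIO("\n".join(table_lines)), sep="\t", index_col=0, dtype=str
    )
    frame.index = [_unquote(str(r)) for r in frame.index]
    frame.columns = [_unquote(str(c)) for c in frame.columns]
    values = frame.apply(pd.to_numeric, errors="coerce")
    n_missing = int(values.isna().sum().sum())
    if n_missing:
        log.warning("%s: %d non-numeric cell(s) recorded as missing", path, n_missing)
    return ExpressionTable(
        values.to_numpy(float),
        list(frame.index),
        list(frame.columns),
        metadata,
    )


def write_series_matrix(table: ExpressionTable, path: str | Path) -> None:
    """Write an :class:`ExpressionTable` in the series-matrix dialect.

    Values are printed with 17 significant digits so a write/read
    round-trip is lossless to double precision.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for key, values in table.sample_metadata.items():
            row = "\t".join(f'"{v}"' for v in values)
            fh.write(f"!{key}\t{row}\n" if values else f"!{key}\n")
        fh.write(TABLE_BEGIN + "\n")
        fh.write("\t".join(['"ID_REF"'] + [f'"{s}"' for s in table.sample_ids]) + "\n")
        for rid, row in zip(table.row_ids, table.matrix):
            cells = "\t".join(f"{v:.17g}" for v in row)
            fh.write(f'"{rid}"\t{cells}\n')
        fh.write(TABLE_END + "\n")


def read_symbol_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV probe -> gene symbol map (header optional)."""
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: a two-column probe\\tsymbol TSV is required")
    first = str(frame.iloc[0, 0]).lower()
    if first in ("probe", "probe_id", "id", "id_ref"):
        frame = frame.iloc[1:]
    return {str(p): str(s) for p, s in zip(frame.iloc[:, 0], frame.iloc[:, 1])}


def intersect_gene_symbols(
    tables: Sequence[ExpressionTable],
    symbol_maps: Sequence[Mapping[str, str] | None],
) -> tuple[list[str], list[np.ndarray]]:
    """Align expression tables on shared uppercased gene symbols.

    ``symbol_maps[t]`` maps probe ids of table ``t`` to gene symbols
    (``None`` means the row ids already are symbols).  Probes mapping to
    one symbol are averaged; the output is restricted to symbols present
    in every table, in sorted order.  Returns the shared symbol list and
    one genes x samples matrix per table.
    """
    if len(tables) != len(symbol_maps):
        raise ValueError("one symbol map (or None) per table is required")
    collapsed: list[pd.DataFrame] = []
    for t, (table, mapping) in enumerate(zip(tables, symbol_maps)):
        frame = table.to_frame()
        if mapping is None:
            symbols = [str(r).upper() for r in frame.index]
        else:
            symbols = [str(mapping.get(str(r), "")).upper() for r in frame.index]
        frame = frame.set_axis(symbols, axis=0)
        frame = frame.loc[[s for s in frame.index if s]]
        collapsed.append(frame.groupby(level=0).mean())
    shared = set(collapsed[0].index)
    for frame in collapsed[1:]:
        shared &= set(frame.index)
    if not shared:
        counts = ", ".join(str(len(f.index)) for f in collapsed)
        raise ValueError(f"no shared gene symbols across tables (sizes: {counts})")
    symbols = sorted(shared)
    return symbols, [f.loc[symbols].to_numpy(float) for f in collapsed]


# ---------------------------------------------------------------------------
# HDF5 persistence


def _write_strings(group: h5py.Group, name: str, values: Sequence[str]) -> None:
    group.create_dataset(name, data=np.array([str(v) for v in values], dtype=object),
                         dtype=h5py.string_dtype())


def _read_strings(dataset: h5py.Dataset) -> list[str]:
    return [v.decode() if isinstance(v, bytes) else str(v) for v in dataset[()]]


def save_tensor(tensor: AnnotatedTensor, path: str | Path) -> None:
    """Save an :class:`AnnotatedTensor` into an HDF5 container."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("values", data=tensor.values)
        _write_strings(fh, "mode_roles", tensor.mode_roles)
        labels = fh.create_group("mode_labels")
        for k, lab in enumerate(tensor.mode_labels):
            _write_strings(labels, str(k), lab)
        cls = fh.create_group("class_labels")
        for k, lab in tensor.class_labels.items():
            _write_strings(cls, str(k), lab)
        tv = fh.create_group("time_values")
        for k, vals in tensor.time_values.items():
            tv.create_dataset(str(k), data=np.asarray(vals, float))


def load_tensor(path: str | Path) -> AnnotatedTensor:
    with h5py.File(path, "r") as fh:
        values = fh["values"][()]
        roles = _read_strings(fh["mode_roles"])
        labels = [_read_strings(fh["mode_labels"][str(k)]) for k in range(values.ndim)]
        class_labels = {int(k): _read_strings(v) for k, v in fh["class_labels"].items()}
        time_values = {int(k): v[()] for k, v in fh["time_values"].items()}
    return AnnotatedTensor(values, roles, labels, class_labels, time_values)


def save_factors(factors: HOSVDFactors, path: str | Path) -> None:
    """Save :class:`HOSVDFactors` into an HDF5 container."""
    with h5py.File(path, "w") as fh:
        fh.attrs["source_shape"] = np.asarray(factors.source_shape, dtype=np.int64)
        fgrp = fh.create_group("factors")
        sgrp = fh.create_group("singular_values")
        for k, (u, s) in enumerate(zip(factors.factors, factors.singular_values)):
            fgrp.create_dataset(str(k), data=u)
            sgrp.create_dataset(str(k), data=s)


def load_factors(path: str | Path) -> HOSVDFactors:
    with h5py.File(path, "r") as fh:
        shape = tuple(int(n) for n in fh.attrs["source_shape"])
        factors = [fh["factors"][str(k)][()] for k in range(len(shape))]
        sigmas = [fh["singular_values"][str(k)][()] for k in range(len(shape))]
    return HOSVDFactors(factors, sigmas, shape)


# ---------------------------------------------------------------------------
# Converting tensors to/from series-matrix tables


def drug_tensor_to_table(tensor: AnnotatedTensor) -> ExpressionTable:
    """Flatten a compound x time x gene tensor into genes x (compound, time) columns."""
    if tensor.mode_roles != ["compound", "time", "gene"]:
        raise ValueError("a compound x time x gene tensor is required")
    n_c, n_t, n_g = tensor.shape
    sample_ids, compounds, times = [], [], []
    for jc, comp in enumerate(tensor.mode_labels[0]):
        for jt, tp in enumerate(tensor.mode_labels[1]):
            sample_ids.append(f"{comp}|{tp}")
            compounds.append(comp)
            times.append(str(tensor.time_values.get(1, [jt] * n_t)[jt]))
    matrix = tensor.values.reshape(n_c * n_t, n_g).T
    return ExpressionTable(
        matrix,
        list(tensor.gene_labels),
        sample_ids,
        {"Sample_characteristics_ch1_compound": compounds,
         "Sample_characteristics_ch1_time_days": times},
    )


def table_to_drug_tensor(table: ExpressionTable) -> AnnotatedTensor:
    """Reassemble the tensor written by :func:`drug_tensor_to_table`."""
    compounds = table.sample_metadata["Sample_characteristics_ch1_compound"]
    times = [float(t) for t in table.sample_metadata["Sample_characteristics_ch1_time_days"]]
    comp_order = list(dict.fromkeys(compounds))
    time_order = sorted(dict.fromkeys(times))
    n_c, n_t, n_g = len(comp_order), len(time_order), len(table.row_ids)
    values = np.empty((n_c, n_t, n_g))
    for col, (comp, tp) in enumerate(zip(compounds, times)):
        values[comp_order.index(comp), time_order.index(tp)] = table.matrix[:, col]
    time_labels = [f"{t:g}d" for t in time_order]
    return AnnotatedTensor(
        values,
        ["compound", "time", "gene"],
        [comp_order, time_labels, list(table.row_ids)],
        time_values={1: time_order},
    )


def disease_matrix_to_table(tensor: AnnotatedTensor) -> ExpressionTable:
    """Flatten a samples x gene matrix into genes x samples columns."""
    if tensor.mode_roles != ["sample", "gene"]:
        raise ValueError("a samples x gene matrix is required")
    classes = tensor.class_labels.get(0, ["" for _ in tensor.mode_labels[0]])
    return ExpressionTable(
        tensor.values.T,
        list(tensor.gene_labels),
        list(tensor.mode_labels[0]),
        {"Sample_characteristics_ch1_class": list(classes)},
    )


def table_to_disease_matrix(table: ExpressionTable) -> AnnotatedTensor:
    """Reassemble the matrix written by :func:`disease_matrix_to_table`."""
    classes = table.sample_metadata.get(
        "Sample_characteristics_ch1_class", [""] * len(table.sample_ids)
    )
    return AnnotatedTensor(
        table.matrix.T,
        ["sample", "gene"],
        [list(table.sample_ids), list(table.row_ids)],
        class_labels={0: list(classes)} if any(classes) else {},
    )
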