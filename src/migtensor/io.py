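"""Flow-record ingestion and the origin x destination x period tensor.

Long-format records (one row per origin, destination, period, count) are
assembled into a three-way count array ``X`` of shape ``(I, I, K)`` together
with a binary weight tensor ``W`` of the same shape.  ``W`` zeroes every
diagonal cell ``(i, i, k)``: within-unit counts carry no movement
information and are excluded from every downstream fit.  Additional cells
(e.g. censored small flows) may be declared missing, which also zeroes
their weight.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FlowRecord",
    "GeoIndex",
    "FlowTensor",
    "AggregateMatrix",
    "read_records",
    "write_records",
    "build_tensor",
    "tensor_to_records",
    "add_external_node",
    "aggregate_window",
    "write_model",
    "read_model",
]

DEFAULT_DIALECT = {
    "origin": "origin",
    "dest": "dest",
    "period": "period",
    "count": "count",
}


class FlowRecord(NamedTuple):
    """One observed flow: ``count`` movers from ``origin`` to ``dest`` in ``period``."""

    origin: str
    dest: str
    period: object
    count: float


@dataclasses.dataclass(frozen=True)
class GeoIndex:
    """Bijection between geography labels and contiguous 0-based indices."""

    labels: tuple

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("geography labels must be unique")

    @property
    def position(self) -> dict:
        return {lab: i for i, lab in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, label) -> int:
        return self.position[label]

    def __contains__(self, label) -> bool:
        return label in self.position

    @classmethod
    def from_labels(cls, labels: Iterable) -> "GeoIndex":
        return cls(tuple(labels))


@dataclasses.dataclass
class FlowTensor:
    """An ``(I, I, K)`` count array with its binary weight (mask) tensor.

    ``values[i, j, k]`` is the flow from geography ``i`` to ``j`` in period
    ``k``.  ``mask`` is 1 where a cell is observed and enters the fitting
    objective, 0 on the diagonal and on any declared-missing cell.
    """

    values: np.ndarray
    mask: np.ndarray
    geo: GeoIndex
    periods: tuple

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=float)
        v, m = self.values, self.mask
        if v.ndim != 3 or v.shape[0] != v.shape[1]:
            raise ValueError(f"values must be (I, I, K), got {v.shape}")
        if m.shape != v.shape:
            raise ValueError("mask and values must share a shape")
        if v.shape[0] != len(self.geo):
            raise ValueError("geo index length does not match tensor")
        if v.shape[2] != len(self.periods):
            raise ValueError("period labels do not match tensor depth")
        if np.any(v < 0):
            raise ValueError("flow counts must be nonnegative")
        i = np.arange(v.shape[0])
        if np.any(m[i, i, :] != 0):
            raise ValueError("mask must be zero on the diagonal")

    @property
    def n_geo(self) -> int:
        return self.values.shape[0]

    @property
    def n_periods(self) -> int:
        return self.values.shape[2]

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def masked_values(self) -> np.ndarray:
        """Values with every masked-out cell set to zero."""
        return self.values * self.mask

    def masked_sumsq(self) -> float:
        """Sum of squares over observed cells (the norm in relative residuals)."""
        return float(np.sum(self.mask * self.values**2))


@dataclasses.dataclass
class AggregateMatrix:
    """Time-aggregated flow matrix with zero diagonal, e.g. a pre/post-event window."""

    values: np.ndarray
    window: tuple
    geo: GeoIndex

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("aggregate matrix must be square")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("aggregate matrix must have zero diagonal")


def read_records(path, dialect: dict | None = None) -> list[FlowRecord]:
    """Read long-format flow records from a delimited text file.

    Parameters
    ----------
    path : path-like
        CSV/TSV file with a header row.
    dialect : dict, optional
        Maps the canonical names ``origin``, ``dest``, ``period``, ``count``
        to the column names used in the file.

    Rows with a missing count are rejected (never imputed); a negative
    count raises a :class:`ValueError` naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such flow file: {path}")
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        unknown = set(dialect) - set(DEFAULT_DIALECT)
        if unknown:
            raise KeyError(f"unknown dialect keys: {sorted(unknown)}")
        cols.update(dialect)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype={cols["origin"]: str, cols["dest"]: str})
    missing_cols = [c for c in cols.values() if c not in df.columns]
    if missing_cols:
        raise KeyError(
            f"columns {missing_cols} not found in {path.name}; "
            f"available: {list(df.columns)}"
        )
    records = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        r = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        count = r[cols["count"]]
        if pd.isna(count):
            raise ValueError(f"missing count on line {row_number} of {path.name}")
        count = float(count)
        if count < 0:
            raise ValueError(
                f"negative count {count:g} on line {row_number} of {path.name}"
            )
        records.append(
            FlowRecord(
                origin=str(r[cols["origin"]]),
                dest=str(r[cols["dest"]]),
                period=r[cols["period"]],
                count=count,
            )
        )
    return records


def write_records(records: Sequence[FlowRecord], path, dialect: dict | None = None) -> None:
    """Write records to CSV in the long format :func:`read_records` accepts."""
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    df = pd.DataFrame(records, columns=["origin", "dest", "period", "count"])
    df.columns = [cols["origin"], cols["dest"], cols["period"], cols["count"]]
    df.to_csv(path, index=False)


def build_tensor(
    records: Sequence[FlowRecord],
    geo: GeoIndex | str = "infer",
    periods: Sequence | str = "infer",
    duplicate_policy: str = "sum",
    missing_cells: Sequence[tuple] | None = None,
) -> FlowTensor:
    """Assemble long-format records into a :class:`FlowTensor`.

    With ``geo="infer"`` the geography set is the union of origins and
    destinations, sorted lexicographically; with ``periods="infer"`` the
    periods are sorted ascending.  Duplicate ``(origin, dest, period)``
    cells are summed under ``duplicate_policy="sum"`` or rejected under
    ``"error"``.  Self-loop records (origin == dest) are stored in
    ``values`` but the diagonal mask keeps them out of every objective.
    ``missing_cells`` is an optional list of ``(origin, dest, period)``
    triples whose mask entries are zeroed (e.g. censored flows).
    """
    if duplicate_policy not in {"sum", "error"}:
        raise ValueError("duplicate_policy must be 'sum' or 'error'")
    records = list(records)
    if geo == "infer":
        labels = sorted({r.origin for r in records} | {r.dest for r in records})
        geo = GeoIndex.from_labels(labels)
    if periods == "infer":
        periods = tuple(sorted({r.period for r in records}))
    else:
        periods = tuple(periods)
    pos = geo.position
    period_pos = {p: k for k, p in enumerate(periods)}
    I, K = len(geo), len(periods)
    values = np.zeros((I, I, K))
    seen: set[tuple] = set()
    n_self = 0
    for r in records:
        if r.origin not in pos:
            raise KeyError(f"origin {r.origin!r} not in geography index")
        if r.dest not in pos:
            raise KeyError(f"dest {r.dest!r} not in geography index")
        if r.period not in period_pos:
            raise KeyError(f"period {r.period!r} not in period labels")
        cell = (r.origin, r.dest, r.period)
        if duplicate_policy == "error":
            if cell in seen:
                raise ValueError(f"duplicate record for cell {cell}")
            seen.add(cell)
        if r.origin == r.dest:
            n_self += 1
        values[pos[r.origin], pos[r.dest], period_pos[r.period]] += r.count
    if n_self:
        warnings.warn(
            f"{n_self} self-loop record(s) stored but masked out of the objective",
            stacklevel=2,
        )
    mask = np.ones((I, I, K))
    idx = np.arange(I)
    mask[idx, idx, :] = 0.0
    for origin, dest, period in missing_cells or []:
        mask[pos[origin], pos[dest], period_pos[period]] = 0.0
    return FlowTensor(values=values, mask=mask, geo=geo, periods=periods)


def tensor_to_records(t: FlowTensor, include_masked: bool = True) -> list[FlowRecord]:
    """Flatten a tensor back to long-format records (nonzero cells only)."""
    out = []
    for i, o in enumerate(t.geo.labels):
        for j, d in enumerate(t.geo.labels):
            for k, p in enumerate(t.periods):
                if not include_masked and t.mask[i, j, k] == 0:
                    continue
                v = t.values[i, j, k]
                if v != 0:
                    out.append(FlowRecord(o, d, p, float(v)))
    return out


def add_external_node(
    records: Sequence[FlowRecord],
    internal: set,
    label: str = "EXTERNAL",
) -> list[FlowRecord]:
    """Collapse all geographies outside ``internal`` into one aggregate node.

    Flows between an internal geography and any external one are relabeled
    to ``label`` and merged by summation.  Flows external on both ends are
    self-loops of the aggregate node and are dropped (with a logged count).
    """
    internal = set(internal)
    if label in internal:
        raise ValueError(f"aggregate label {label!r} collides with an internal id")
    merged: dict[tuple, float] = {}
    order: list[tuple] = []
    n_dropped = 0
    for r in records:
        o_in, d_in = r.origin in internal, r.dest in internal
        if not o_in and not d_in:
            n_dropped += 1
            continue
        o = r.origin if o_in else label
        d = r.dest if d_in else label
        key = (o, d, r.period)
        if key not in merged:
            merged[key] = 0.0
            order.append(key)
        merged[key] += r.count
    if n_dropped:
        logger.info("dropped %d record(s) external on both ends", n_dropped)
    return [FlowRecord(o, d, p, merged[(o, d, p)]) for (o, d, p) in order]


def aggregate_window(t: FlowTensor, start, end) -> AggregateMatrix:
    """Sum tensor slabs over ``[start, end]`` with the diagonal zeroed.

    This is the aggregated weight matrix used for pre/post-event
    comparisons: ``sum_k W_k - diag(sum_k W_k)``.
    """
    try:
        k0 = t.periods.index(start)
        k1 = t.periods.index(end)
    except ValueError as exc:
        raise KeyError(f"window bounds must be existing periods: {exc}") from exc
    if k0 > k1:
        raise ValueError(f"empty window: start {start!r} is after end {end!r}")
    agg = t.values[:, :, k0 : k1 + 1].sum(axis=2)
    np.fill_diagonal(agg, 0.0)
    return AggregateMatrix(values=agg, window=(start, end), geo=t.geo)


# ---------------------------------------------------------------------------
# model serialization (factor matrices as labeled CSV, metadata as JSON)

def write_model(model, directory) -> None:
    """Serialize a fitted CP model to a directory of labeled CSV + JSON files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    geo_labels = list(model.geo.labels) if model.geo is not None else [
        str(i) for i in range(model.A.shape[0])
    ]
    period_labels = list(model.periods) if model.periods is not None else [
        str(k) for k in range(model.C.shape[0])
    ]
    comp_cols = [f"component_{f + 1}" for f in range(model.n_components)]
    fmt = "%.17g"
    for name, mat, index in [
        ("origin_factors", model.A, geo_labels),
        ("dest_factors", model.B, geo_labels),
        ("temporal_factors", model.C, period_labels),
    ]:
        df = pd.DataFrame(mat, index=index, columns=comp_cols)
        df.to_csv(directory / f"{name}.csv", float_format=fmt)
    meta = {
        "n_components": int(model.n_components),
        "weights": [float(w) for w in model.weights],
        "objective_trace": [float(v) for v in model.objective_trace],
        "seed": model.seed,
        "n_restarts": model.n_restarts,
        "converged": bool(model.converged),
        "periods": [str(p) for p in period_labels],
    }
    (directory / "model.json").write_text(json.dumps(meta, indent=2))


def read_model(directory):
    """Inverse of :func:`write_model`; lossless to double precision."""
    from .decomposition import CPModel

    directory = Path(directory)
    meta_path = directory / "model.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"no model.json in {directory}")
    meta = json.loads(meta_path.read_text())
    dfs = {}
    for name in ("origin_factors", "dest_factors", "temporal_factors"):
        f = directory / f"{name}.csv"
        if not f.exists():
            raise FileNotFoundError(f"missing factor file {f}")
        dfs[name] = pd.read_csv(f, index_col=0)
    geo = GeoIndex.from_labels([str(x) for x in dfs["origin_factors"].index])
    periods = tuple(str(x) for x in dfs["temporal_factors"].index)
    return CPModel(
        A=dfs["origin_factors"].to_numpy(),
        B=dfs["dest_factors"].to_numpy(),
        C=dfs["temporal_factors"].to_numpy(),
        weights=np.asarray(meta["weights"], dtype=float),
        geo=geo,
        periods=periods,
        objective_trace=list(meta["objective_trace"]),
        seed=meta.get("seed"),
        n_restarts=meta.get("n_restarts"),
        converged=meta.get("converged", False),
    )
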