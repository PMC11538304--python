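"""Interpretation of ranked CP components as migration systems.

Each rank-one component (lambda_f, a_f, b_f, c_f) is read as one
migration system: a_f scores geographies as origins, b_f as
destinations, c_f is the system's per-period activity.  This module
turns components into membership probabilities, top-k member lists,
origin-destination association matrices, temporal shock flags, and
whole-region classifications.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from sklearn.neighbors import KNeighborsClassifier

from .decomposition import CPModel

__all__ = [
    "MigrationSystem",
    "AssociationMatrix",
    "SystemsReport",
    "extract_system",
    "association_matrix",
    "shock_scan",
    "classify_geographies",
    "systems_report",
]

UNASSIGNED = -1


@dataclasses.dataclass
class MigrationSystem:
    """One ranked migration system extracted from a CP model.

    Membership vectors are the unit-norm factor columns; the probability
    vectors are their within-system L1 normalizations, read as the
    probability that a geography participates in the system as origin or
    destination.  Top lists hold the ``k_top`` strongest members, ties
    broken by label order.
    """

    index: int
    weight: float
    origin_membership: np.ndarray
    dest_membership: np.ndarray
    origin_prob: np.ndarray
    dest_prob: np.ndarray
    temporal: np.ndarray
    top_origins: list
    top_dests: list
    geo_labels: list
    period_labels: list

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "weight": float(self.weight),
            "origin_membership": [float(x) for x in self.origin_membership],
            "dest_membership": [float(x) for x in self.dest_membership],
            "origin_prob": [float(x) for x in self.origin_prob],
            "dest_prob": [float(x) for x in self.dest_prob],
            "temporal": [float(x) for x in self.temporal],
            "top_origins": list(self.top_origins),
            "top_dests": list(self.top_dests),
            "geo_labels": list(self.geo_labels),
            "period_labels": [str(p) for p in self.period_labels],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MigrationSystem":
        return cls(
            index=d["index"],
            weight=d["weight"],
            origin_membership=np.asarray(d["origin_membership"]),
            dest_membership=np.asarray(d["dest_membership"]),
            origin_prob=np.asarray(d["origin_prob"]),
            dest_prob=np.asarray(d["dest_prob"]),
            temporal=np.asarray(d["temporal"]),
            top_origins=list(d["top_origins"]),
            top_dests=list(d["top_dests"]),
            geo_labels=list(d["geo_labels"]),
            period_labels=list(d["period_labels"]),
        )


@dataclasses.dataclass
class AssociationMatrix:
    """Rank-one who-sends-to-whom matrix over a system's top members.

    Entry (i, j) is the product of the i-th strongest origin membership
    and the j-th strongest destination membership; every 2x2 minor
    vanishes by construction.
    """

    rows: list
    cols: list
    values: np.ndarray

    def to_dict(self) -> dict:
        return {
            "rows": list(self.rows),
            "cols": list(self.cols),
            "values": [[float(x) for x in row] for row in self.values],
        }


def _labels(model: CPModel) -> tuple:
    geo = (
        list(model.geo.labels)
        if model.geo is not None
        else [str(i) for i in range(model.A.shape[0])]
    )
    periods = (
        list(model.periods)
        if model.periods is not None
        else list(range(model.C.shape[0]))
    )
    return geo, periods


def _top_k(membership: np.ndarray, labels: list, k: int) -> list:
    """Labels of the k largest entries; ties broken by label order; zeros excluded."""
    order = sorted(range(len(labels)), key=lambda i: (-membership[i], str(labels[i])))
    order = [i for i in order if membership[i] > 0]
    return [labels[i] for i in order[:k]]


def extract_system(model: CPModel, f: int, k_top: int = 10) -> MigrationSystem:
    """Extract component ``f`` (0-based) as an interpreted migration system."""
    if not 0 <= f < model.n_components:
        raise IndexError(f"component {f} out of range for F={model.n_components}")
    if k_top < 1:
        raise ValueError("k_top must be >= 1")
    geo, periods = _labels(model)
    a, b, c = model.A[:, f], model.B[:, f], model.C[:, f]
    sa, sb = a.sum(), b.sum()
    if sa == 0 or sb == 0:
        raise ValueError(f"component {f} has a zero membership vector")
    return MigrationSystem(
        index=f,
        weight=float(model.weights[f]),
        origin_membership=a.copy(),
        dest_membership=b.copy(),
        origin_prob=a / sa,
        dest_prob=b / sb,
        temporal=c.copy(),
        top_origins=_top_k(a, geo, k_top),
        top_dests=_top_k(b, geo, k_top),
        geo_labels=geo,
        period_labels=periods,
    )


def association_matrix(system: MigrationSystem, k: int = 10) -> AssociationMatrix:
    """Outer product of the top-k origin and destination membership sub-vectors."""
    if k > len(system.geo_labels):
        raise ValueError("k exceeds the number of geographies")
    pos = {lab: i for i, lab in enumerate(system.geo_labels)}
    rows = system.top_origins[:k]
    cols = system.top_dests[:k]
    a = np.array([system.origin_membership[pos[r]] for r in rows])
    b = np.array([system.dest_membership[pos[c]] for c in cols])
    return AssociationMatrix(rows=rows, cols=cols, values=np.outer(a, b))


def shock_scan(system: MigrationSystem, min_ratio: float = 3.0) -> list:
    """Flag periods whose activity spikes relative to the rest of the profile.

    Period k is flagged when ``c(k) >= min_ratio * median(c over the other
    periods)``; the score is that ratio.  Returns ``(period, score)``
    pairs sorted by score descending — an abrupt displacement event (e.g.
    a hurricane) shows up as a single dominant flag.
    """
    c = np.asarray(system.temporal, dtype=float)
    K = len(c)
    if K < 3:
        raise ValueError("need at least 3 periods to scan for shocks")
    flags = []
    for k in range(K):
        others = np.delete(c, k)
        med = float(np.median(others))
        if med > 0:
            ratio = c[k] / med
        else:
            ratio = np.inf if c[k] > 0 else 0.0
        if ratio >= min_ratio:
            flags.append((system.period_labels[k], float(ratio)))
    flags.sort(key=lambda t: -t[1])
    return flags


def classify_geographies(
    model: CPModel,
    n_systems: int | None = None,
    method: str = "argmax",
    knn_k: int = 5,
    seed_threshold: float = 0.5,
) -> tuple:
    """Assign every geography to one system as origin and one as destination.

    ``argmax`` labels each geography with the component maximizing its
    membership (origins via A, destinations via B).  ``knn`` first keeps
    as seeds the geographies whose winning membership reaches
    ``seed_threshold`` times the largest membership in that component,
    then labels the remainder by majority vote of the ``knn_k`` nearest
    seeds in membership-row space (Euclidean).  A geography with all-zero
    memberships gets the UNASSIGNED label (-1).

    Returns ``(origin_labels, dest_labels)`` as integer arrays of
    component indices.
    """
    if n_systems is None:
        n_systems = model.n_components
    if n_systems > model.n_components:
        raise ValueError("n_systems exceeds the number of fitted components")
    if method not in {"argmax", "knn"}:
        raise ValueError("method must be 'argmax' or 'knn'")

    def _assign(M: np.ndarray) -> np.ndarray:
        M = M[:, :n_systems]
        labels = np.argmax(M, axis=1)
        labels[M.max(axis=1) == 0] = UNASSIGNED
        if method == "argmax":
            return labels
        col_max = M.max(axis=0)
        winning = M[np.arange(M.shape[0]), np.clip(labels, 0, None)]
        is_seed = (labels != UNASSIGNED) & (
            winning >= seed_threshold * col_max[np.clip(labels, 0, None)]
        )
        if is_seed.sum() == 0:
            return labels
        rest = ~is_seed & (labels != UNASSIGNED)
        if rest.any():
            knn = KNeighborsClassifier(n_neighbors=min(knn_k, int(is_seed.sum())))
            knn.fit(M[is_seed], labels[is_seed])
            labels[rest] = knn.predict(M[rest])
        return labels

    return _assign(model.A.copy()), _assign(model.B.copy())


@dataclasses.dataclass
class SystemsReport:
    """All systems of a model: memberships, associations, shocks, ranked by weight."""

    systems: list
    associations: list
    shocks: list
    k_top: int

    def to_dict(self) -> dict:
        return {
            "k_top": self.k_top,
            "systems": [s.to_dict() for s in self.systems],
            "associations": [a.to_dict() for a in self.associations],
            "shocks": [[[str(p), float(s)] for p, s in fl] for fl in self.shocks],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SystemsReport":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls(
            systems=[MigrationSystem.from_dict(s) for s in d["systems"]],
            associations=[
                AssociationMatrix(
                    rows=a["rows"], cols=a["cols"], values=np.asarray(a["values"])
                )
                for a in d["associations"]
            ],
            shocks=[[(p_, s_) for p_, s_ in fl] for fl in d["shocks"]],
            k_top=d["k_top"],
        )


def systems_report(
    model: CPModel, k_top: int = 10, shock_min_ratio: float = 3.0
) -> SystemsReport:
    """One MigrationSystem, AssociationMatrix and shock list per component."""
    systems, associations, shocks = [], [], []
    for f in range(model.n_components):
        s = extract_system(model, f, k_top=k_top)
        systems.append(s)
        associations.append(association_matrix(s, k=min(k_top, len(s.geo_labels))))
        shocks.append(
            shock_scan(s, min_ratio=shock_min_ratio) if len(s.temporal) >= 3 else []
        )
    return SystemsReport(
        systems=systems, associations=associations, shocks=shocks, k_top=k_top
    )
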