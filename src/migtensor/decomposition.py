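"""Diagonal-masked nonnegative canonical polyadic decomposition.

The model expresses an origin x destination x period flow tensor X as a
sum of F nonnegative rank-one components,

    X(i, j, k)  ~  sum_f  lambda_f * a_f(i) * b_f(j) * c_f(k),

where a_f scores each geography's involvement as an origin in system f,
b_f does the same for destinations, and c_f is the system's temporal
intensity profile.  The fit minimizes the squared error over *observed*
cells only,

    || W  had  ( X - sum_f a_f o b_f o c_f ) ||_F^2 ,
    A >= 0, B >= 0, C >= 0,

with W a binary weight tensor that is zero on every diagonal cell
(within-unit counts are not movement) and on any declared-missing cell.

The solver is an expectation-maximization / block-coordinate scheme:
masked cells are imputed with the current reconstruction, then one sweep
of HALS (hierarchical alternating least squares) columnwise nonnegative
updates is applied per mode on the completed tensor.  Each HALS column
update is an exact nonnegative coordinate minimizer, and the imputation
step is a majorization of the masked objective, so the outer objective
trace is non-increasing.  Columns are normalized to unit Euclidean norm
after convergence, the absorbed scale lambda_f = ||a_f||*||b_f||*||c_f||
becomes the component's importance, and components are returned sorted
by lambda.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy.linalg import khatri_rao
from sklearn.base import BaseEstimator

from .io import FlowTensor, GeoIndex

__all__ = [
    "CPModel",
    "RankScan",
    "MaskedNCPD",
    "reconstruct",
    "masked_objective",
    "fit_ncpd",
    "normalize_factors",
    "rank_scan",
    "stability_check",
    "congruence",
]


@dataclasses.dataclass
class CPModel:
    """A normalized, importance-ranked CP model of a flow tensor.

    Columns of ``A`` (origin memberships), ``B`` (destination memberships)
    and ``C`` (temporal intensities) have unit Euclidean norm; ``weights``
    holds the absorbed scales lambda_f, sorted non-increasing.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    weights: np.ndarray
    geo: GeoIndex | None = None
    periods: tuple | None = None
    objective_trace: list = dataclasses.field(default_factory=list)
    seed: int | None = None
    n_restarts: int | None = None
    converged: bool = False

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        F = self.A.shape[1]
        if self.B.shape[1] != F or self.C.shape[1] != F or self.weights.shape != (F,):
            raise ValueError("factor matrices disagree on the number of components")
        if self.A.shape[0] != self.B.shape[0]:
            raise ValueError("origin and destination factors must share geographies")
        for name, M in (("A", self.A), ("B", self.B), ("C", self.C)):
            if np.any(M < 0):
                raise ValueError(f"factor {name} has negative entries")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")

    @property
    def n_components(self) -> int:
        return self.A.shape[1]

    @property
    def shape(self) -> tuple:
        return (self.A.shape[0], self.B.shape[0], self.C.shape[0])

    def reconstruct(self) -> np.ndarray:
        return reconstruct(self)

    def component(self, f: int) -> tuple:
        """(lambda_f, a_f, b_f, c_f) for one system."""
        return self.weights[f], self.A[:, f], self.B[:, f], self.C[:, f]


@dataclasses.dataclass
class RankScan:
    """Relative masked residual as a function of candidate rank."""

    F_values: list
    rel_residual: list
    models: list | None = None

    def elbow(self, min_drop_ratio: float = 2.0) -> int | None:
        """Rank at which the residual decrease flattens.

        The drop at rank F is the residual decrease from the previous
        scanned rank to F.  The elbow is the rank whose drop exceeds the
        following drop by the largest ratio, provided that ratio reaches
        ``min_drop_ratio``; ``None`` if no rank qualifies (a featureless,
        near-linear decay).
        """
        drops = -np.diff(self.rel_residual)  # drops[i] belongs to F_values[i + 1]
        if len(drops) < 2:
            return None
        eps = 1e-15
        ratios = np.maximum(drops[:-1], 0.0) / np.maximum(drops[1:], eps)
        best = int(np.argmax(ratios))
        if ratios[best] < min_drop_ratio:
            return None
        return self.F_values[best + 1]


def _as_values_mask(t) -> tuple:
    if isinstance(t, FlowTensor):
        return t.values, t.mask, t.geo, t.periods
    values = np.asarray(t, dtype=float)
    if values.ndim != 3:
        raise ValueError("expected a 3-way array or FlowTensor")
    mask = np.ones_like(values)
    i = np.arange(min(values.shape[0], values.shape[1]))
    mask[i, i, :] = 0.0
    return values, mask, None, None


def reconstruct(model: CPModel) -> np.ndarray:
    """Dense low-rank reconstruction sum_f lambda_f a_f o b_f o c_f."""
    return np.einsum(
        "f,if,jf,kf->ijk", model.weights, model.A, model.B, model.C, optimize=True
    )


def masked_objective(t, model: CPModel) -> float:
    """Squared Frobenius error over observed cells; masked cells contribute nothing."""
    values, mask, _, _ = _as_values_mask(t)
    if values.shape != (model.A.shape[0], model.B.shape[0], model.C.shape[0]):
        raise ValueError(
            f"tensor shape {values.shape} does not match model {model.shape}"
        )
    resid = values - reconstruct(model)
    return float(np.sum(mask * resid**2))


def normalize_factors(
    A: np.ndarray, B: np.ndarray, C: np.ndarray, **meta
) -> CPModel:
    """Normalize factor columns to unit Euclidean norm and rank by scale.

    lambda_f is the product of the raw column norms; components are sorted
    by lambda non-increasing (stable).  A component with any all-zero
    column carries no flow and is dropped with a warning.
    """
    A = np.asarray(A, dtype=float).copy()
    B = np.asarray(B, dtype=float).copy()
    C = np.asarray(C, dtype=float).copy()
    na = np.linalg.norm(A, axis=0)
    nb = np.linalg.norm(B, axis=0)
    nc = np.linalg.norm(C, axis=0)
    keep = (na > 0) & (nb > 0) & (nc > 0)
    if not np.all(keep):
        warnings.warn(
            f"dropping {int(np.sum(~keep))} degenerate component(s) with a zero factor",
            stacklevel=2,
        )
    A, B, C = A[:, keep], B[:, keep], C[:, keep]
    na, nb, nc = na[keep], nb[keep], nc[keep]
    lam = na * nb * nc
    A /= na
    B /= nb
    C /= nc
    order = np.argsort(-lam, kind="stable")
    return CPModel(
        A=A[:, order], B=B[:, order], C=C[:, order], weights=lam[order], **meta
    )


class MaskedNCPD(BaseEstimator):
    """Nonnegative CP decomposition of a flow tensor with masked (diagonal) cells.

    Parameters
    ----------
    n_components : int
        Number of rank-one components F (migration systems) to extract.
    max_iter : int, default 500
        Maximum outer (impute + HALS sweep) iterations per restart.
    tol : float, default 1e-8
        Convergence threshold on the relative decrease of the masked
        objective between outer iterations.
    n_restarts : int, default 10
        Independent random initializations; the restart with the lowest
        final objective wins.  Restarts whose objectives agree to within
        numerical precision (1e-12 of the observed sum of squares) are
        ties, broken by restart order.
    random_state : int or None
        Seed for all initializations; fits are deterministic given it.
    init_factors : tuple of (A, B, C) raw factor matrices, optional
        Warm start used as the first restart.  Matrices with fewer than
        ``n_components`` columns are padded with small random columns.
        The remaining restarts stay random, and selection is still by
        objective, so a warm start only wins when it is at least as good.

    Attributes
    ----------
    model_ : CPModel
        Normalized, lambda-ranked fitted model.
    origin_factors_, dest_factors_, temporal_factors_ : ndarray
        Unit-norm factor matrices A (I x F), B (I x F), C (K x F).
    weights_ : ndarray
        Component scales lambda, non-increasing.
    objective_trace_ : list of float
        Masked objective after initialization and each outer iteration of
        the winning restart; non-increasing.
    reconstruction_err_ : float
        Relative masked residual sqrt(SSE) / sqrt(sum of observed X^2).
    n_iter_ : int
        Outer iterations used by the winning restart.
    converged_ : bool
        Whether the winning restart met ``tol`` before ``max_iter``.
    """

    def __init__(
        self,
        n_components: int = 1,
        max_iter: int = 500,
        tol: float = 1e-8,
        n_restarts: int = 10,
        random_state: int | None = None,
        init_factors: tuple | None = None,
    ):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.init_factors = init_factors

    # -- solver internals --------------------------------------------------

    @staticmethod
    def _unfoldings(X: np.ndarray) -> tuple:
        I, J, K = X.shape
        X1 = X.reshape(I, J * K)                      # row i, col j*K + k
        X2 = X.transpose(1, 0, 2).reshape(J, I * K)   # row j, col i*K + k
        X3 = X.transpose(2, 0, 1).reshape(K, I * J)   # row k, col i*J + j
        return X1, X2, X3

    @staticmethod
    def _hals_sweep(M: np.ndarray, Xn: np.ndarray, K1: np.ndarray, K2: np.ndarray):
        """One pass of exact nonnegative column updates for one factor.

        Minimizes ``||Xn - M @ khatri_rao(K1, K2).T||^2`` over each column
        of ``M`` in turn, clipping at zero.  Skips a column whose Gram
        diagonal vanishes (the companion factors are degenerate there).
        """
        G = (K1.T @ K1) * (K2.T @ K2)           # Gram of the Khatri-Rao product
        P = Xn @ khatri_rao(K1, K2)
        for f in range(M.shape[1]):
            g = G[f, f]
            if g <= 0:
                continue
            col = M[:, f] + (P[:, f] - M @ G[:, f]) / g
            np.maximum(col, 0.0, out=col)
            M[:, f] = col
        return M

    def _fit_single(self, Xw, mask, rng, init=None):
        """One restart: EM imputation + HALS sweeps.  Xw has masked cells zeroed."""
        I, J, K = Xw.shape
        F = self.n_components
        scale = np.sqrt(Xw.max() if Xw.max() > 0 else 1.0)
        if init is not None:
            A, B, C = (M.copy() for M in init)
        else:
            A = rng.uniform(0.1, 1.0, size=(I, F)) * scale ** (2 / 3)
            B = rng.uniform(0.1, 1.0, size=(J, F)) * scale ** (2 / 3)
            C = rng.uniform(0.1, 1.0, size=(K, F)) * scale ** (2 / 3)
        hole = 1.0 - mask
        baseline = float(np.sum(Xw**2))
        recon = np.einsum("if,jf,kf->ijk", A, B, C, optimize=True)
        obj = float(np.sum(mask * (Xw - recon) ** 2))
        trace = [obj]
        revived = np.zeros(F, dtype=bool)
        converged = False
        for _ in range(self.max_iter):
            Xc = Xw + hole * recon                      # E-step: impute masked cells
            X1, X2, X3 = self._unfoldings(Xc)
            A = self._hals_sweep(A, X1, B, C)
            B = self._hals_sweep(B, X2, A, C)
            C = self._hals_sweep(C, X3, A, B)
            # revive a fully-degenerate component once with a tiny column
            for f in range(F):
                if (
                    not revived[f]
                    and (A[:, f].max() == 0 or B[:, f].max() == 0 or C[:, f].max() == 0)
                ):
                    eps = 1e-8 * max(np.sqrt(baseline), 1.0)
                    for M in (A, B, C):
                        if M[:, f].max() == 0:
                            M[:, f] = rng.uniform(0.1, 1.0, size=M.shape[0]) * eps
                    revived[f] = True
            recon = np.einsum("if,jf,kf->ijk", A, B, C, optimize=True)
            obj = float(np.sum(mask * (Xw - recon) ** 2))
            prev = trace[-1]
            trace.append(obj)
            if prev - obj <= self.tol * max(prev, 1e-300):
                converged = True
                break
            if obj <= 1e-28 * max(baseline, 1.0):
                converged = True
                break
        return A, B, C, trace, converged

    # -- public API --------------------------------------------------------

    def fit(self, X, y=None):
        """Fit the masked nonnegative CP model to a FlowTensor or 3-way array."""
        values, mask, geo, periods = _as_values_mask(X)
        if not np.all(np.isfinite(values)):
            raise ValueError("flow tensor contains non-finite values")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.n_components > values.shape[0]:
            warnings.warn(
                f"n_components={self.n_components} exceeds the number of "
                f"geographies ({values.shape[0]})",
                stacklevel=2,
            )
        Xw = values * mask
        if not np.any(Xw > 0):
            raise ValueError("nothing to fit: all observed cells are zero")

        ss = np.random.SeedSequence(self.random_state)
        children = ss.spawn(self.n_restarts)
        warm = self._padded_init(Xw.shape, np.random.default_rng(children[0]))
        sumsq = float(np.sum(mask * values**2))
        tie_tol = 1e-12 * sumsq  # objectives closer than this are numerically equal
        best = None
        for r, child in enumerate(children):
            rng = np.random.default_rng(child)
            init = warm if r == 0 else None
            A, B, C, trace, converged = self._fit_single(Xw, mask, rng, init=init)
            if best is None or trace[-1] < best[3][-1] - tie_tol:
                best = (A, B, C, trace, converged)
        A, B, C, trace, converged = best
        A, B, C = self._prune_mask_null(A, B, C, mask)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # degenerate drop already surfaced via trace
            model = normalize_factors(
                A,
                B,
                C,
                geo=geo,
                periods=periods,
                objective_trace=trace,
                seed=self.random_state,
                n_restarts=self.n_restarts,
                converged=converged,
            )
        self.model_ = model
        self.origin_factors_ = model.A
        self.dest_factors_ = model.B
        self.temporal_factors_ = model.C
        self.weights_ = model.weights
        self.objective_trace_ = model.objective_trace
        self.n_iter_ = len(trace) - 1
        self.converged_ = converged
        self.reconstruction_err_ = float(np.sqrt(trace[-1] / sumsq))
        return self

    def _padded_init(self, shape, rng):
        """Raw warm-start factors from ``init_factors``, padded to n_components."""
        if self.init_factors is None:
            return None
        I, J, K = shape
        F = self.n_components
        out = []
        for M, n in zip(self.init_factors, (I, J, K)):
            M = np.asarray(M, dtype=float)
            if M.shape[0] != n:
                raise ValueError("init_factors do not match the tensor shape")
            if M.shape[1] > F:
                raise ValueError("init_factors have more columns than n_components")
            if M.shape[1] < F:
                scale = 1e-2 * np.mean(np.linalg.norm(M, axis=0))
                pad = rng.uniform(0.1, 1.0, size=(n, F - M.shape[1])) * max(scale, 1e-12)
                M = np.hstack([M, pad])
            out.append(np.maximum(M, 0.0))
        return tuple(out)

    @staticmethod
    def _prune_mask_null(A, B, C, mask):
        """Drop components carrying no energy on observed cells.

        A rank-one term whose origin and destination supports meet only
        on masked (diagonal) cells is invisible to the objective and
        therefore unidentifiable; reporting it as a system would be
        meaningless.
        """
        keep = []
        for f in range(A.shape[1]):
            comp = np.einsum("i,j,k->ijk", A[:, f], B[:, f], C[:, f])
            total = float(np.sum(comp**2))
            observed = float(np.sum(mask * comp**2))
            if total == 0 or observed > 1e-10 * total:
                keep.append(f)
            else:
                warnings.warn(
                    "dropping a component supported only on masked cells",
                    stacklevel=3,
                )
        keep = np.asarray(keep, dtype=int)
        return A[:, keep], B[:, keep], C[:, keep]

    def reconstruct(self) -> np.ndarray:
        return reconstruct(self.model_)

    def score(self, X, y=None) -> float:
        """Negative masked objective (higher is better), for model selection."""
        return -masked_objective(X, self.model_)


def fit_ncpd(
    t,
    n_components: int,
    max_iter: int = 500,
    tol: float = 1e-8,
    n_restarts: int = 10,
    seed: int | None = None,
) -> CPModel:
    """Functional wrapper around :class:`MaskedNCPD`; returns the CPModel."""
    est = MaskedNCPD(
        n_components=n_components,
        max_iter=max_iter,
        tol=tol,
        n_restarts=n_restarts,
        random_state=seed,
    )
    return est.fit(t).model_


def rank_scan(
    t,
    F_values: Sequence[int],
    keep_models: bool = False,
    **fit_opts,
) -> RankScan:
    """Relative masked residual from independent best-of-restarts fits at each rank.

    The rank is a user decision; this diagnostic exposes the residual
    decay so the flattening point (elbow) can be read off.
    """
    F_values = list(F_values)
    if any(b <= a for a, b in zip(F_values, F_values[1:])):
        raise ValueError("F_values must be strictly increasing")
    values, mask, _, _ = _as_values_mask(t)
    sumsq = float(np.sum(mask * values**2))
    residuals, models = [], []
    for F in F_values:
        model = fit_ncpd(t, F, **fit_opts)
        residuals.append(float(np.sqrt(masked_objective(t, model) / sumsq)))
        if keep_models:
            models.append(model)
    return RankScan(
        F_values=F_values,
        rel_residual=residuals,
        models=models if keep_models else None,
    )


def congruence(model_a: CPModel, f: int, model_b: CPModel, g: int) -> float:
    """Product of cosine similarities of the (a, b, c) columns of two components."""
    score = 1.0
    for Ma, Mb in ((model_a.A, model_b.A), (model_a.B, model_b.B), (model_a.C, model_b.C)):
        u, v = Ma[:, f], Mb[:, g]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0 or nv == 0:
            return 0.0
        score *= abs(float(u @ v) / (nu * nv))
    return score


def stability_check(t, F: int, F_plus: int, **fit_opts) -> np.ndarray:
    """Best-match congruence of each rank-F component against a rank-F_plus refit.

    A rank choice is robust when adding components leaves the leading
    systems essentially unchanged, i.e. all scores near 1.
    """
    if F_plus <= F:
        raise ValueError("F_plus must exceed F")
    m_lo = fit_ncpd(t, F, **fit_opts)
    # nested initialization: one restart of the larger fit starts from the
    # smaller fit plus small random extra components, so indistinguishable
    # (numerically tied) refits preserve rather than arbitrarily reshuffle
    # the leading structure; random restarts can still win on objective
    scale = m_lo.weights ** (1.0 / 3.0)
    est = MaskedNCPD(
        n_components=F_plus,
        init_factors=(m_lo.A * scale, m_lo.B * scale, m_lo.C * scale),
        **{k: v for k, v in fit_opts.items() if k != "seed"},
        random_state=fit_opts.get("seed"),
    )
    m_hi = est.fit(t).model_
    return match_congruences(m_lo, m_hi)


def match_congruences(m_lo: CPModel, m_hi: CPModel) -> np.ndarray:
    """For each component of ``m_lo``, the best congruence among ``m_hi``'s."""
    scores = np.zeros(m_lo.n_components)
    for f in range(m_lo.n_components):
        scores[f] = max(
            congruence(m_lo, f, m_hi, g) for g in range(m_hi.n_components)
        )
    return scores
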