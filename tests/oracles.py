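"""Independent reference implementations used to check the package.

Everything here is deliberately naive — explicit loops, exhaustive
enumeration, dense grid search — and shares no code path with the
package internals it validates.
"""

import itertools

import numpy as np


def loop_reconstruct(weights, A, B, C):
    """Triple-loop CP reconstruction sum_f w_f a_f(i) b_f(j) c_f(k)."""
    I, F = A.shape
    J = B.shape[0]
    K = C.shape[0]
    out = np.zeros((I, J, K))
    for i in range(I):
        for j in range(J):
            for k in range(K):
                for f in range(F):
                    out[i, j, k] += weights[f] * A[i, f] * B[j, f] * C[k, f]
    return out


def loop_masked_objective(values, mask, weights, A, B, C):
    """Triple-loop masked squared error."""
    recon = loop_reconstruct(weights, A, B, C)
    total = 0.0
    I, J, K = values.shape
    for i in range(I):
        for j in range(J):
            for k in range(K):
                total += mask[i, j, k] * (values[i, j, k] - recon[i, j, k]) ** 2
    return total


def loop_aggregate(values, k0, k1):
    """Triple-loop window sum with zero diagonal."""
    I = values.shape[0]
    out = np.zeros((I, I))
    for i in range(I):
        for j in range(I):
            if i == j:
                continue
            for k in range(k0, k1 + 1):
                out[i, j] += values[i, j, k]
    return out


def exhaustive_fms(S):
    """Best mean similarity over all injective matchings of a score matrix."""
    n_rows, n_cols = S.shape
    m = min(n_rows, n_cols)
    T = S if n_rows <= n_cols else S.T
    best = 0.0
    for pick in itertools.permutations(range(T.shape[1]), m):
        best = max(best, float(np.mean([T[i, g] for i, g in enumerate(pick)])))
    return best


def _unit_grid(dim, lo, hi, n):
    """Nonnegative unit vectors on an angular grid over [lo, hi] per angle."""
    axes = [np.linspace(max(0.0, l), min(np.pi / 2, h), n) for l, h in zip(lo, hi)]
    if dim == 2:
        th = axes[0]
        V = np.stack([np.cos(th), np.sin(th)], axis=1)
        P = th[:, None]
    elif dim == 3:
        th, ph = np.meshgrid(axes[0], axes[1], indexing="ij")
        th, ph = th.ravel(), ph.ravel()
        V = np.stack(
            [np.sin(ph) * np.cos(th), np.sin(ph) * np.sin(th), np.cos(ph)], axis=1
        )
        P = np.stack([th, ph], axis=1)
    else:
        raise ValueError("grid oracle supports dimensions 2 and 3 only")
    return V, P


def grid_oracle_rank1(values, mask, n=40, n_refine=6, widen=3.0):
    """Minimum masked squared error of a rank-one nonnegative model by grid search.

    Unit origin/destination vectors are enumerated on a nested angular
    grid (coarse-to-fine, window of +-``widen`` grid steps per stage);
    for each pair the optimal nonnegative temporal weights have a closed
    form, so only the spatial directions are searched.  Supports I in
    {2, 3}.
    """
    I, J, K = values.shape
    MX = mask * values
    c0 = float(np.sum(mask * values**2))
    lo_a, hi_a = np.zeros(I - 1), np.full(I - 1, np.pi / 2)
    lo_b, hi_b = np.zeros(J - 1), np.full(J - 1, np.pi / 2)
    best = None
    for _ in range(n_refine):
        A, Pa = _unit_grid(I, lo_a, hi_a, n)
        B, Pb = _unit_grid(J, lo_b, hi_b, n)
        gain = np.zeros((A.shape[0], B.shape[0]))
        for k in range(K):
            num = np.maximum(A @ MX[:, :, k] @ B.T, 0.0)
            den = (A**2) @ mask[:, :, k] @ (B.T**2)
            gain += np.where(den > 0, num**2 / np.where(den > 0, den, 1.0), 0.0)
        ia, ib = np.unravel_index(np.argmax(gain), gain.shape)
        obj = c0 - float(gain[ia, ib])
        if best is None or obj < best:
            best = obj
        step_a = widen * (hi_a - lo_a) / (n - 1)
        step_b = widen * (hi_b - lo_b) / (n - 1)
        ca, cb = Pa[ia], Pb[ib]
        lo_a, hi_a = ca - step_a, ca + step_a
        lo_b, hi_b = cb - step_b, cb + step_b
    return best
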