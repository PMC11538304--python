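# Methods

## Model

An origin–destination–period flow array `X ∈ R^{I×I×K}` is approximated
by a sum of `F` nonnegative rank-one components, `X(i,j,k) ≈ Σ_f λ_f
a_f(i) b_f(j) c_f(k)`.  Each component is read as one migration system:
`a_f ≥ 0` scores each geography's involvement as an origin, `b_f ≥ 0` as
a destination, and `c_f ≥ 0` is the system's per-period activity.  The
central assumption is that migration systems are *stable co-clusters*:
the same origin set sends to the same destination set across the whole
window, with only the intensity `c_f` varying.  Change over time is
expressed through intensity shifts (including abrupt spikes from
displacement events), not through re-wired memberships.

Diagonal cells `X(i,i,k)` record people who did not move between units
and carry no flow information, so they are excluded from the fit by a
binary weight tensor `W` with `W(i,i,k) = 0` and `W(i,j,k) = 1`
otherwise.  The fitted objective is `‖W ⊛ (X − Σ_f a_f∘b_f∘c_f)‖_F²`
subject to elementwise nonnegativity.  Cells beyond the diagonal (e.g.
censored small flows in administrative extracts) can also be declared
missing, which zeroes their weight; no imputation is ever applied to the
data itself.

## Solver

The solver is an expectation–maximization / block-coordinate scheme:

1. **Impute** every masked cell with the current reconstruction
   (`X_c = W⊛X + (1−W)⊛X̂`).
2. **Update** each factor matrix in turn by one HALS sweep on the
   completed tensor: each column is replaced by its exact nonnegative
   coordinate minimizer (a clipped least-squares step against the
   Khatri–Rao design of the other two factors).

Each HALS column update cannot increase the completed-tensor objective,
and the imputation step majorizes the masked objective, so the outer
objective trace is non-increasing — this is asserted by the test suite
on every fit, with a relative tolerance of 1e-10 for floating-point
noise.  Because the data enter only as `W⊛X`, arbitrary perturbation of
masked cells cannot change the trajectory bitwise.

Defaults: `tol = 1e-8` (relative objective decrease), `max_iter = 500`
outer iterations, `n_restarts = 10` nonnegative-uniform random
initializations.  The restart with the lowest final objective wins;
objectives that agree to within 1e-12 of the observed sum of squares are
numerically indistinguishable and are treated as ties, broken by restart
order.  A component whose companion factors collapse to zero is
re-randomized once at a tiny scale and dropped if it degenerates again.

After convergence the factor columns are normalized to unit Euclidean
norm, the absorbed scale `λ_f` (product of the raw column norms — the
only scale-invariant choice consistent with the trilinear model) ranks
the systems, and components are returned sorted by `λ`.

**Mask-null components.**  With more components than the data support, a
surplus rank-one term can migrate into the null space of the mask: if
`a_f` and `b_f` concentrate on the same single geography, the term
touches only diagonal cells and is invisible to the objective, while its
scale — set entirely by the imputation — can be arbitrarily large.  Such
components are unidentifiable artifacts of tensor completion, not
migration systems, and are dropped after fitting (threshold: observed
energy below 1e-10 of the component's total energy).

## Rank selection and stability

The rank `F` is a user decision supported by two diagnostics, never
chosen silently.  `rank_scan` fits each candidate rank independently and
reports the relative masked residual `√(masked SSE / masked Σ X²)`; the
elbow is the rank whose residual drop exceeds the following drop by the
largest ratio, flagged only when that ratio reaches 2 (a featureless,
near-linear decay yields no elbow).  `stability_check` refits at a
larger rank and reports, for each leading component, the best congruence
(product of cosine similarities of the `a`, `b`, `c` columns) against
the larger model: values near 1 mean the extra capacity did not disturb
the leading systems.  The larger fit includes one restart warm-started
from the smaller fit (padded with small random columns) alongside the
usual cold restarts.  This nested initialization matters in the
noiseless limit, where reshuffled solutions tie the structured one at
numerically-zero objective and the tie-break must not reshuffle the
leading components arbitrarily; a genuinely better cold-start solution
still wins on objective.

## From components to systems

- **Membership probabilities** are the within-component L1 normalization
  `a_f / Σ_i a_f(i)` (and analogously for destinations).  This is an
  interpretive choice — the probability reading could alternatively be
  normalized across systems per geography — but within-system
  normalization preserves the membership ranking and sums to 1 over
  geographies, matching the "probability that a county belongs to this
  system" reading.
- **Top-k lists** take the `k` largest memberships; ties break by label
  order for determinism.
- **Association matrices** are the rank-one outer products of the top-k
  origin and destination membership sub-vectors; every 2×2 minor
  vanishes by construction.
- **Shock scan** flags period `k` when `c_f(k) ≥ r × median(c_f over the
  other periods)` with default ratio `r = 3`; the score is that ratio.
  The rule is deliberately simple — a single dominant flag marks an
  abrupt displacement event; smooth trends flag nothing.
- **Classification** assigns every geography one origin and one
  destination system, either by argmax membership or by k-NN: seeds are
  geographies whose winning membership reaches 0.5× the largest
  membership in that component; the remainder are labeled by majority
  vote of the `knn_k = 5` nearest seeds in membership-row space.
  Geographies with all-zero memberships are labeled unassigned (−1).
- An `add_external_node` helper collapses all geographies outside a
  study region into a single aggregate node (flows external on both ends
  are self-loops of that node and are dropped with a logged count), and
  `aggregate_window` produces zero-diagonal pre/post-event matrices for
  comparison with static graph-clustering baselines.

## Synthetic benchmark

The generator plants the structure the model assumes.  Defaults shrink a
county-scale yearly study to desk size: `I = 30` geographies, `K = 29`
periods, `F_true = 3` systems with disjoint 5-member origin and
destination supports, membership magnitudes uniform on [0.5, 1] over the
support (sparse, nonnegative, non-orthogonal — as real systems are),
smooth sinusoidal temporal trends, and one system carrying an abrupt
spike at period 15 with 8× the baseline intensity — a hurricane-style
displacement analogue.  Count noise is Poisson with the component scales
calibrated so the mean active off-diagonal cell carries 50 movers, a
plausible county-pair flow magnitude; masked diagonal cells are filled
with junk an order of magnitude larger than any observed cell so that
mask leakage would be loud.  Generation is deterministic given the seed,
and a separate noise seed lets replicates share one planted structure.

Recovery is scored by the factor match score: the permutation-maximized
mean over components of `|cos(a,a*)|·|cos(b,b*)|·|cos(c,c*)|`, invariant
to component order and positive rescaling, computed by exhaustive
matching up to 8 components and by optimal assignment above.

What passing these benchmarks does **not** show: real flow extracts have
heavy-tailed and serially correlated noise, censored small flows,
overlapping and drifting memberships, and magnitudes spanning orders of
magnitude across pairs — none of which the generator emulates.  The
benchmarks validate the machinery (objective, solver, extraction), not
the substantive adequacy of the co-clustering model for any particular
dataset.

## Problem sizes and numerical choices

The validation pipeline uses the default 30×30×29 benchmark: one
noiseless fit (exact recovery), 20 Poisson replicates (noisy recovery
and shock detection), a rank scan over `F ∈ {1..6}`, and a stability
comparison of `F = 3` against `F = 5`.  Tiny 2×2×2 and 3×3×2 instances
are checked against a dense nested grid-search oracle that enumerates
unit-norm nonnegative spatial factors on a coarse-to-fine angular grid
(40 points per angle, six refinement stages, ±3-step windows) with the
temporal weights solved in closed form; on such instances EM-HALS
converges slowly near flat optima, so the comparison fits use
`tol = 1e-15` and up to 20 000 iterations.

## Known limitations

- Over-parameterized fits on noisy data genuinely prefer to *refine*
  the strongest system (splitting its support between two components)
  over fitting noise elsewhere, because Poisson noise concentrates
  variance in the strongest block.  Stability congruences on noisy data
  can therefore dip a few percent below 1 even when the structure is
  planted and exact; the noiseless stability check isolates the
  structural question from this effect.
- The component importance `λ` includes any energy a component places on
  masked cells; fully mask-null components are pruned, but partially
  degenerate components can carry inflated `λ`.
- No smoothness or sparsity penalties are applied to the temporal
  profiles or memberships; systems with genuinely drifting membership
  violate the model and will surface as split components or inflated
  residuals rather than being tracked.
- The shock rule compares each period to the median of the others; slow
  multi-period surges raise the median and can mask each other.
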