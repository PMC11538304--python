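# migtensor

Discovering **stable migration systems** in origin–destination flow data by
spatio-temporal tensor co-clustering.

A migration system is a set of origin geographies and destination
geographies that persistently exchange migrants with a shared temporal
activity profile — think of a sunbelt system draining midwestern counties,
or a displacement system that switches on when a hurricane makes landfall.
`migtensor` is for demographers, regional scientists, and epidemiologists
of mobility-driven spread who have long-format flow counts
(`origin, dest, period, count`) and want the systems, their members, their
relative importance, and their timing — not just a per-year graph
clustering.

## Model

Flows are arranged in a three-way array `X` of shape `I × I × K`:
`X(i, j, k)` counts movers from geography `i` to geography `j` in period
`k`.  The method seeks `F` nonnegative rank-one components

```
X  ≈  Σ_f  λ_f · a_f ∘ b_f ∘ c_f ,     A, B, C ≥ 0,
```

where `a_f` scores origins, `b_f` scores destinations, and `c_f` is the
temporal intensity of system `f`.  Diagonal cells `X(i, i, k)` record
non-movers and carry no flow information, so the fit minimizes the
squared error only over observed cells:

```
minimize  ‖ W ⊛ ( X − Σ_f a_f ∘ b_f ∘ c_f ) ‖_F²
```

with a binary weight tensor `W` that is zero on every diagonal cell (and
on any cell declared missing, e.g. censored small flows).  After
convergence the factor columns are normalized to unit Euclidean norm and
the absorbed scale `λ_f = ‖a_f‖·‖b_f‖·‖c_f‖` ranks the systems by
importance.  The solver alternates EM-style imputation of masked cells
with HALS (hierarchical alternating least squares) nonnegative updates,
which makes the objective provably non-increasing; multiple random
restarts guard against local optima.

Downstream, each component becomes an interpretable system: within-system
L1-normalized membership probabilities, top-k origin/destination lists,
the rank-one association matrix `ã_f b̃_fᵀ` over the top members, a
ratio-to-median shock scan of the temporal profile, and whole-region
classification of every geography by argmax or k-nearest-neighbour
membership vote.  A seeded synthetic generator plants known systems
(sparse memberships, smooth or spiked temporal profiles, Poisson count
noise, junk on the masked diagonal) so recovery can be scored against
ground truth.

## Worked example

Generate a 30-geography × 29-period tensor with three planted systems
(one carrying a displacement spike at period 15), fit, and read the
results:

```python
from migtensor import (PlantedSpec, generate, fit_ncpd, systems_report,
                       factor_match_score, rank_scan)

spec = PlantedSpec(seed=42)            # 30 geos, 29 periods, 3 systems, Poisson noise
tensor, truth = generate(spec)
model = fit_ncpd(tensor, 3, seed=0, n_restarts=10)

print("component weights:", [round(float(w), 1) for w in model.weights])
print("factor match score vs truth:", round(factor_match_score(model, truth), 4))

report = systems_report(model, k_top=5)
print("system 1 top origins:", report.systems[0].top_origins)
for f, flags in enumerate(report.shocks):
    if flags:
        print(f"system {f+1} shock flags:", [(p, round(r, 1)) for p, r in flags])

scan = rank_scan(tensor, [1, 2, 3, 4, 5, 6], seed=0, n_restarts=5)
print("rel residuals:", [round(r, 3) for r in scan.rel_residual])
print("elbow:", scan.elbow())
```

Output:

```
component weights: [1977.3, 1519.8, 1435.6]
factor match score vs truth: 0.9996
system 1 top origins: ['g18', 'g20', 'g19', 'g09', 'g06']
system 1 shock flags: [(15, 8.1)]
rel residuals: [0.734, 0.521, 0.11, 0.108, 0.106, 0.104]
elbow: 3
```

The fitted factors match the planted ones almost perfectly (a factor
match score of 1 is exact recovery up to component order and scale); the
shock scan flags period 15 — where the spike was planted — at 8× the
median activity of that system; and the residual-versus-rank curve
flattens after rank 3, the true number of systems.

The same workflow is available from the shell:

```
migtensor simulate --out runs/sim
migtensor fit --input runs/sim/flows.csv -F 3 --seed 0 --out runs/fit
migtensor scan --input runs/sim/flows.csv --ranks 1:6 --out runs/scan
```

Sklearn-style access is provided by `MaskedNCPD(n_components=3,
random_state=0).fit(tensor)`, with fitted attributes `origin_factors_`,
`dest_factors_`, `temporal_factors_`, `weights_`, `objective_trace_`.

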