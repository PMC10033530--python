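# regenfit

Computational analysis of liver volume recovery after 70% partial
hepatectomy (PHx). The healthy rodent liver regrows to its pre-surgery
liver-to-body-mass set point within about a week of resection, but chronic
ethanol adaptation can suppress this — in a sex-dependent way. `regenfit`
packages the modeling side of that question for systems biologists and
imaging groups who collect longitudinal liver-volume series: an ODE model
of hepatocyte state transitions, a parameter-landscape scan, per-animal
maximum-likelihood fits, a synthetic cohort generator matching the
sex-by-diet study design, and the associated cohort statistics.

## The model

Hepatocytes occupy three states — quiescent `Q`, primed `P`, replicating
`R` — as fractions of the pre-surgery cell count. A constant metabolic
load `M` expresses the body's demand for liver function; after resection
the per-cell load `M/N` (with `N = Q+P+R`) exceeds baseline by
`S = M(1/N − 1)`, which drives priming and replication through a
saturating response σ(S), and at high levels drives cell death through
δ(S) scaled by the death rate constant `Kcd`:

    dQ/dt = −k_prime σ Q + k_req (1−σ) P + 2 k_div R − Kcd α_q δ Q
    dP/dt =  k_prime σ Q − k_rep σ P − k_req (1−σ) P − Kcd δ P
    dR/dt =  k_rep σ P − k_div R − Kcd δ R

Relative liver volume is `(Q + G·(P+R) + ε)/(1+ε)`, 1.0 = pre-surgery.
Simulated recoveries at one week are classified as **healthy** (>85% of
the original volume), **suppressed** (40–85%) or **failure** (<40%).

Measured series are compared to all 10,000 simulations of a 100×100
`(M, Kcd)` grid (M linear in 5–30, Kcd logarithmic in 5e-4–0.5) by a
Gaussian log-likelihood of the residuals, `Σ log p(x_i)` with σ the
residual standard deviation, plus a variant that weights the final
residual five-fold, `log p(5x_n) + Σ_{i<n} log p(x_i)`, so the end-state
recovery dominates. Per animal, the cells at or above the 95th percentile
of the weighted log-likelihood form its credible region. See
`docs/methods.md` for the full model description and design choices.

## Worked example

```python
import numpy as np
from regenfit import (ModelParameters, GridSpec, simulate, run_sweep,
                      classify, AnimalRecord, fit_animal, recovery_curve)

params = ModelParameters()            # shipped calibrated constants
times = [0, 48, 96, 168, 336]
for M in (9.0, 20.0):
    traj = simulate(params.replace(M=M, Kcd=0.01), times)
    print(M, np.round(traj.rel_volume, 3))
```

prints

```
9.0  [0.303 0.494 0.595 0.648 0.665]
20.0 [0.303 0.391 0.623 0.88  0.965]
```

— at low metabolic load (M = 9) the liver stalls near 65% of its original
volume (suppressed regeneration, the ethanol-male phenotype), while at
M = 20 it passes 85% within the week (healthy). With `M=28, Kcd=0.3` the
death drive wins and the simulated organ collapses (failure).

Fitting the suppressed group-mean recovery curve against the full grid:

```python
sweep = run_sweep(GridSpec(), params)          # 10,000 simulations, ~2 min
modes = classify(sweep)                        # healthy/suppressed/failure
t = np.array([0., 10., 24., 48., 72., 96., 168., 336.])
animal = AnimalRecord("EM-mean", "male", "ethanol", t,
                      recovery_curve(0.6593, 72.0, t))
surface = fit_animal(animal, sweep, modes)
print(surface.best_fit_weighted, surface.best_region_modes)
```

```
(8.787878787878789, 0.0005) {'healthy': 0.0, 'suppressed': 1.0, 'failure': 0.0}
```

— the ethanol-male recovery (65.93% at one week) is best fit by M ≈ 9
and its credible region lies entirely in the suppressed mode, whereas
control-group curves (~90–97% recovery) fit at M ≈ 15–25.

The same stages are available from the shell:

```
regenfit synth --seed 1 --out cohort.csv
regenfit sweep --out sweep/
regenfit fit --animals cohort.csv --sweep sweep/ --out fits/
regenfit stats --animals cohort.csv --fits fits/cohort_summary.csv --out stats/
regenfit run --seed 1 --out run/          # everything, plus figures
```

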