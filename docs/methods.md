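# Methods

## The model

`regenfit` simulates liver volume recovery after a 70% partial hepatectomy
(PHx) with a three-state hepatocyte model. States are fractions of the
pre-surgery hepatocyte count: quiescent `Q`, primed `P` and replicating
`R`. The intact liver is the rest state `(Q, P, R) = (1, 0, 0)`; resection
is modelled as the initial condition `(1 - resection_fraction, 0, 0)` at
`t = 0` (instantaneous removal, default 70% leaving `Q = 0.30`), not as a
mid-simulation event.

The whole-body demand for hepatic function is a constant metabolic load
`M`. With `N = Q + P + R`, the per-cell load is `M / N`, and the excess
over baseline

    S = max(0, M * (1/N - 1))

is the stimulus. Two saturating Hill responses convert it into a
proliferative drive and a death drive:

    sigma(S) = S^h_s / (theta_s^h_s + S^h_s)
    delta(S) = S^h_d / (theta_d^h_d + S^h_d)

    dQ/dt = -k_prime*sigma*Q + k_req*(1-sigma)*P + 2*k_div*R - Kcd*alpha_q*delta*Q
    dP/dt =  k_prime*sigma*Q - k_rep*sigma*P - k_req*(1-sigma)*P - Kcd*delta*P
    dR/dt =  k_rep*sigma*P - k_div*R - Kcd*delta*R

Priming (`Q -> P`) and replication entry (`P -> R`) are stimulus-gated;
requiescence (`P -> Q`) takes over as the stimulus fades; division returns
two quiescent daughters per replicating cell, so the net growth rate is
`k_div * R` and the only loss pathway is death, scaled by the cell-death
rate constant `Kcd` (with `alpha_q` modulating how strongly quiescent
cells are affected). Relative liver volume is

    v = (Q + G*(P + R) + epsilon) / (1 + epsilon)

with `G > 1` for the larger size of activated hepatocytes and `epsilon`
for non-hepatocyte volume; `epsilon` is treated as an additive constant
outside the `G` weighting. This is a deliberately reduced description: it
keeps the documented state structure, the constant-load stimulus and the
death constant, but collapses the molecular signalling (cytokines, growth
factors, ECM) of richer regeneration models into the two Hill responses.
`derivatives` is exposed as a seam so a fuller equation set with the same
state structure could be substituted.

### Parameters, units, defaults

Rates are per hour; `S`, `theta_s`, `theta_d`, `M` are dimensionless.

| parameter | default | meaning / why this value |
|---|---|---|
| `M` | swept 5–30 | metabolic load; the scanned axis |
| `Kcd` | swept 5e-4–0.5 (log) | death rate constant; the scanned axis |
| `k_prime` | 0.0856 | Q→P priming rate (calibrated) |
| `k_rep` | 0.0857 | P→R replication entry (calibrated) |
| `k_div` | 0.0193 | division/return rate, ~2-day effective cycle (calibrated) |
| `k_req` | 0.934 | fast requiescence once the stimulus fades (calibrated) |
| `theta_s`, `h_s` | 9.89, 6 | stimulus half-saturation and steepness (calibrated) |
| `theta_d`, `h_d` | 45, 8 | death threshold: only high per-cell loads are lethal |
| `alpha_q` | 1.0 | quiescent cells share the load-induced death risk |
| `G` | 1.295 | volume multiplier of activated cells |
| `epsilon` | 0.005 | small non-hepatocyte volume offset |
| `resection_fraction` | 0.70 | the standard two-thirds hepatectomy |

The nuisance constants were fixed by a one-time calibration (seeded random
search, seed 20230309, followed by a Nelder–Mead polish) against the
behaviour the landscape must show, and then frozen into the shipped
default parameter file:

* C1 — healthy recovery: `v(168 h) >= 0.85` at `M = 20, Kcd = 0.01`
  (achieved: 0.880);
* C2 — suppressed recovery: `v(168 h) = 0.66 +- 0.05` at `M = 9,
  Kcd = 0.01`, tracking the ethanol-male group recovery curve at all
  observation times (achieved: 0.648);
* C3 — failure: `v(168 h) < 0.40` at `M = 28, Kcd = 0.3` (achieved:
  collapse);
* C4 — at `M = 9` the 1-week volume varies by `< 0.10` over the whole
  `Kcd` range (achieved: ~0.000; the death threshold `theta_d = 45` is far
  above the per-cell load reached at low `M`);
* C5 — at `M = 25`, increasing `Kcd` crosses healthy → failure.

The calibration deliberately places the death threshold so that `Kcd` only
matters at high load: at low `M` the stimulus never reaches lethal levels,
which is what makes low-load (suppressed) fits insensitive to `Kcd`.

### Numerics

* Integrator: LSODA (adaptive, stiff-capable), `rtol = 1e-6`,
  `atol = 1e-9`, horizon 336 h; the 1-week endpoint is exactly 168 h.
* Collapse: if `N` falls below `1e-6` the trajectory is flagged and held
  at the organ-free volume `epsilon / (1 + epsilon)` so that downstream
  likelihoods stay finite; integrator failures in sweep cells are recorded
  as collapsed rather than aborting the sweep.
* Reported states are clipped to zero at `-1e-9`-scale solver negatives.
* Halving solver tolerances moves the 1-week volume by `< 1e-4`
  (verified on random parameter draws). Monotonicity assertions in the
  tests use a `5e-4` tolerance: in the `Kcd`-insensitive region the true
  differences are ~0 and accumulated integration noise across a ladder of
  cells reaches a few `1e-4`.

## Parameter sweep and regeneration modes

The scan is 100 linearly spaced `M` values in `[5, 30]` crossed with 100
log-spaced `Kcd` values in `[5e-4, 0.5]`, endpoints included — 10,000
simulations, cached as a long CSV with a JSON sidecar carrying the grid,
evaluation times and a parameter hash (a mismatching hash invalidates the
cache). Each cell is labelled from its relative volume at 168 h: healthy
(`> 0.85`), suppressed (`0.40–0.85`), failure (`< 0.40` or collapsed).
Exact-boundary values go to suppressed so the three conditions partition
the grid.

## Likelihood fitting

For an animal with at least five post-PHx volume measurements, residuals
are simulated minus measured relative volume at the animal's observation
times. With `sigma` the sample standard deviation of the residuals (n−1
denominator, floored at `1e-6` so perfect fits stay finite) and `p` a
zero-mean Gaussian density,

    logL_unweighted = sum_i log p(x_i)
    logL_weighted   = log p(5 * x_n) + sum_{i<n} log p(x_i)

The weighting inflates the final residual inside the density — not the log
term — and `sigma` is not recomputed from the inflated value. The −24 h
point defines the normalisation (its residual is identically zero) and is
excluded. `sigma` about the residual mean is the default; a
root-mean-square-about-zero variant is available via `sigma_mode="rms0"`.

Both likelihoods are evaluated against all 10,000 cached trajectories.
Argmax ties break toward lower `M`, then lower `Kcd`. The credible region
is the set of cells at or above the 95th percentile of the animal's
weighted log-likelihoods (ties included; ~500 cells). Where best-fit
parameters are carried into downstream analyses (parameter recovery,
correlations with pre-surgery measures), the *unweighted* optima are used;
the weighted surface drives the credible regions.

Identifiability caveat: the likelihood surface has a pronounced ridge —
at high `M` many `(M, Kcd)` combinations produce near-identical recovery
curves, and at low `M` the fit is flat in `Kcd` by construction. With
0.03 observation noise at eight time points, the sampling spread of the
recovered `M` is of order one load unit, several grid steps wide. The
property suite measures this directly: noiseless on-grid recovery is
exact, while noisy recovery within ±2 grid steps (±0.5 load units)
succeeds in only ~60–70% of replicates. This mirrors the wide credible
regions the method reports and is a property of the estimator and study
design, not of the implementation.

## Synthetic cohorts

The generator emulates the study design (no per-animal tables are
deposited): 43 rats — 23 male, 20 female — across ethanol, carbohydrate
control and chow diets, measured at −24, 0, 10, 24, 48, 72, 96 h, 1 week
and 2 weeks.

Per animal, a recovery plateau is drawn from the group's printed 1-week
statistics (Normal, truncated to (0.3, 1.2)), e.g. ethanol males
0.6593 ± 0.0591, control females 0.9154 ± 0.1039. The noiseless curve is a
single exponential from the 30% remnant with group time constant `tau`
(72 h for ethanol males, 48 h otherwise, preserving the observed ordering
of group separation from 48 h onward), *anchored so the 168 h value equals
the drawn plateau exactly* — the printed group statistic is a 1-week
measurement, so it is pinned at 1 week rather than treated as a `t → inf`
asymptote — and held flat to 336 h. Observation noise is
Normal(0, 0.03) in relative-volume units (chosen well below the group
standard deviations); the −24 h reference is exactly 1 by construction.

Ancillary measures (portal and hepatic-artery flow, stiffness, oxygen
saturation, body mass) are drawn independently per time point around
anchor curves interpolated between printed group statistics (e.g. 10 h
portal flow 1.92 ± 0.44 ml/min/cm³ in ethanol males). Missingness is
Bernoulli per measure and time (30% for the hard-to-visualise hepatic
artery, 8% for volumes), with the volume mask re-drawn until the
five-measurement eligibility floor holds. Everything is driven by one
`numpy` generator, so a seed reproduces a cohort byte for byte.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: within-animal correlation between measures (an
animal's portal flow is independent of its volume trajectory, so
model-parameter/pre-surgery correlations are null by construction);
serially correlated measurement error; body-mass-driven allometry; any
group differences beyond the printed anchor statistics; chow-group
statistics (not printed; a full-recovery profile is assumed).

## Cohort statistics

Measured variables are analysed with the full three-way factorial linear
model `value ~ sex * diet * time`, time categorical, fitted by least
squares with per-term F tests ("independent measures": no within-animal
error stratum, as in the study — a debatable but faithful choice; with
per-animal random plateaus this test is anti-conservative, which the
type-I error check makes explicit by using an iid-noise null). Type II
sums of squares are the default for unbalanced data; Type III with
sum-to-zero contrasts is a switch. Pairwise group contrasts within each
time point use pooled two-sample t tests with Bonferroni adjustment over
the pairs at that time point (the family is per time point). Correlations
of best-fit parameters with pre-surgery measures are Pearson R with
two-sided p, with constant inputs reported as missing.

## Problem sizes

The shipped configuration runs the full 10,000-cell sweep (~2 minutes on
one CPU), fits animals against the cached cube in milliseconds each
(vectorised over the grid), and uses n = 100 per group for generator
fidelity checks and 200 replicates for the type-I error calibration.

## Known limitations

* The reduced model stands in for a richer published equation set that is
  not reproduced in the package; its constants are phenomenological and
  carry meaning only jointly, through the calibration targets.
* `M` is identifiable from a single noisy animal only to ~±1 load unit
  (see the identifiability caveat above); group-level conclusions rest on
  the separation between suppressed (~9) and healthy (15–25) optima,
  which is much larger than that spread.
* The factorial ANOVA ignores repeated measures; with animal-level random
  effects it over-rejects, and a mixed model would be the statistically
  preferable (but out-of-scope) alternative.
* Mode boundaries are sharp thresholds on the 1-week volume; cells near
  0.85/0.40 can flip with sub-1e-3 volume changes.
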