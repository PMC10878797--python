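# Methods

## Model

Damage accumulates on a leaf as a marked Poisson process: the number of
feeding events over the exposure period is `k ~ Poisson(lambda)` and event
`i` removes a proportion `phi_i` of leaf area, iid truncated Pareto on
`[phi_m, phi_M]` with exponent `alpha`. Cumulative damage is
`phi_T = min(sum phi_i, 1)`. The assumptions are deliberately neutral:
plants are identical and passive, events are independent, and the event-size
distribution reflects only the body-size structure of the regional herbivore
pool (power-law metabolic rate, abundance and richness), which fixes
`alpha = 1 - (b + c + 1)/a = 14/9` for the canonical exponents
`(a, b, c) = (3/4, -3/4, -2/3)`. `derive_alpha` performs this derivation in
exact rational arithmetic for any exponent triple.

The resulting distribution is mixed: `p0 = e^(-lambda)` at 0 (unattacked
leaves), an atom `p1` at 1 (leaves eaten whole), and a continuous density on
(0, 1). Plant-level damage is the mean of the plant's sampled leaves; at the
plant scale the event bounds are divided by `L`, the survey-median leaf count
per plant, because one leaf is a fraction `1/L` of the plant's leaf area.

## Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| `lambda` | expected feeding events per leaf (or plant) | fitted | the model's only free parameter |
| `phi_m` | smallest per-event damage proportion | 0.005 | smallest nonzero value a 0.5%-resolution visual survey records |
| `phi_M` | largest per-event damage proportion | 1.0 | a whole leaf |
| `alpha` | event-size exponent | 14/9 | fixed by metabolic scaling; configurable for sensitivity analyses only |
| `precision` | interval-censoring band width | 0.005 | the recording resolution |
| `grid_size` | lattice cells for the numerical density | 4096 | see below |

## Numerical distribution and likelihood

The continuous part has no closed form. It is computed on a uniform lattice
`x_i = i/N` of [0, 1] (`N = 4096` cells): the event distribution is reduced
to cell masses by exact CDF differences (mass below half a cell is lumped
into the first interior cell so that any event yields positive damage), and
the k-fold convolutions are built iteratively with FFT convolution,
truncating all mass at or above 1 into the atom after every step. Truncation
is absorbing because event sizes are positive, so the iteration is exact in
that respect; FFT round-off below the known support minimum `k * phi_m` is
zeroed. The k-summation stops either when the remaining Poisson tail is
below `1e-10` (tail assigned to `p1`: a sum of many events almost surely
exceeds 1) or when the sub-1 mass of the k-fold convolution is numerically
zero, whichever comes first. Total mass is conserved to machine precision by
construction, and the one-sample KS distance between 1e5 simulated draws and
the lattice CDF stays below 0.01 across `lambda` from 0.01 to 100 at both
leaf- and plant-scale bounds.

The convolutions do not depend on `lambda` — only the Poisson weights do —
so they are cached per (event parameters, grid size), and the per-dataset
band probabilities are precomputed once. A maximum-likelihood fit is then a
bounded Brent search on `log lambda` over `[1e-4, 1e3]` (tolerance 1e-6 in
log units) whose objective is a Poisson-weighted matrix product;  fits cost
milliseconds.

Observations are interval-censored by default: an interior value contributes
the probability of the band of width `precision` centred on it, exact 0s and
1s contribute the atom masses. Censoring is robust to the discreteness of
visual estimates, to ties, and to recorded values slightly below `phi_m`. A
pure density mode exists for continuous synthetic data; the censored
log-likelihood converges to the density version plus `n log(precision)` as
the band shrinks. Values with zero band probability (far outside the event
support) yield `-inf` with a warning rather than an exception. All-zero
datasets are degenerate — the likelihood increases monotonically as
`lambda -> 0` — and are returned at the lower search bound with a flag.

The same censoring convention is applied to the two competitor
distributions (hurdle truncated lognormal, `k = 3`; zero-one-inflated beta
with two independent boundary atoms, `k = 4`), so that AICc differences
reflect distribution shape rather than data representation. Their boundary
masses are estimated by the empirical fractions (their MLEs under the
factorized likelihood) and interior parameters by Nelder–Mead on the
censored likelihood. `delta_aicc(alt, neutral) = AICc_alt - AICc_neutral`;
positive values favour the neutral model. One caveat: for a dataset holding
only exact 0s and 1s both competitors attain the free multinomial atom
entropy, while the neutral model cannot — its atoms are functions of
`lambda` — so the three likelihoods agree only up to that constraint.

## Asymptotics

For large `lambda` with damage well below 1, `phi_T` is approximately
`Normal(lambda E[phi], lambda E[phi^2])`, so any inequality index
proportional to CV in the normal limit satisfies
`I ~= sqrt(E[phi^2]/lambda)/(c E[phi])`. The constants are pinned by the
exact normal closed forms — Gini of `N(mu, sigma)` is `sigma/(mu sqrt(pi))`
and Hoover is `sigma/(mu sqrt(2 pi))` — and the tests verify them against
simulated normal samples. The approximation is accurate to well under 2% at
`lambda = 200` with bounds `(5e-5, 1e-2)`; at small `lambda` (≈0.5) it can
be off by a large factor and the package reports, but never asserts, its
error there. Sample indices use the sample standard deviation (ddof = 1) for
CV; the probe vector instead uses central moments with denominator n, and
both conventions are deliberate and documented.

## Diagnostics

All observed-versus-predicted diagnostics are Monte Carlo with 100 predicted
replicates (simulated at the fitted rate and the observed sample size) and
are bit-for-bit reproducible given a seed.

* **KS**: two-sample tests against each replicate; the mean statistic, mean
  p and the fraction of replicate tests with p < 0.05 are reported (both
  aggregations, since either may be wanted). p-values use the asymptotic
  formula and are approximate under the heavy ties of damage data.
* **Probes**: mean, variance, skew, kurtosis (non-excess), minimum, maximum,
  quartiles (median-unbiased interpolation), Gini.
* **Constrained R²**: probe matrices are Z-scored column-wise, optionally
  residualized on a conditioning factor (survey identity), and the
  observed/predicted between-group sum of squares is divided by the total —
  the identity an RDA reduces to with a single binary constraint. Zero-
  variance columns (e.g. the minimum, constantly 0 at the leaf scale) are
  dropped with a warning. A label-permutation null (within condition groups)
  is available.
* **CV regression**: OLS r² and major-axis (model II) slope/intercept of log
  observed on log predicted CV, zero-variance pairs excluded, percentile
  bootstrap CIs (1999 resamples).
* **Shuffled null**: leaf values permuted among plants within a survey,
  preserving leaf counts; the distribution of shuffled among-plant CVs (and
  mean within-plant CVs) is an assumption-free second null.
* **KL divergence**: observed and predicted samples binned on
  `{0} ∪ (0, 0.05] ∪ ... ∪ (0.95, 1]` (the 5% damage-class convention),
  `1e-10` added per cell before renormalizing, KL(observed ‖ predicted) in
  nats averaged over 100 bootstraps of the predicted side (resampling the
  observed side too is available behind a flag; bin width, atom handling and
  epsilon are configurable since reasonable conventions differ).

## Synthetic surveys

The generator emulates the standardized survey design: 30 plants x 10
leaves, damage rounded to 0.5% (positive values floored at 0.005 so rounding
never crosses the zero boundary; rounding can be disabled). A base attack
rate of 2 events per leaf is the study default — it yields ~13% undamaged
leaves and mean damage ~12%, a regime where the zero atom, the interior and
occasional total consumption all occur. Two contaminations inject known
non-neutral structure:

* **plant_sigma**: each plant draws a mean-one lognormal multiplier on
  `lambda` (sd parameter `plant_sigma`, default study value 1.0), creating
  among-plant heterogeneity: observed among-plant CV rises above both the
  shuffled and the refitted-neutral predictions.
* **regularize**: positive leaf damages within a plant are contracted toward
  their within-plant mean by this fraction (default study value 0.8), an
  induced-defence caricature that evens damage among leaves while leaving
  the zero pattern and the damaged-leaf mean intact, so the refitted rate
  stays anchored and observed among-leaf CV falls below the neutral
  prediction. A per-event thinning mechanism was considered and rejected:
  thinning at the plant level re-Poissonizes leaf counts when events are
  split among leaves, and with heavy-tailed event sizes its among-leaf CV
  signature is of order a few percent — too weak to serve as a ground-truth
  deviation.

Both contaminations are caricatures chosen for a guaranteed sign signature,
not mechanistic models. What passing tests on these surveys shows is that
the pipeline detects deviations of the stated sign when they are present and
stays calibrated when they are absent; it says nothing about which
biological mechanism produces such deviations in real data, and the
generator omits many features of field surveys (observer error beyond
rounding, spatial structure, phylogeny, climate).

## Study conditions and calibration

The standard studies (in `neutralherb.experiments`, run by the test suite
and `scripts/acceptance.py`) use: distribution checks at
`lambda ∈ {0.01, 0.1, 1, 10, 100}` with 1e5 draws; recovery at
`lambda ∈ {0.5, 2, 10}`, 300 leaves, 20 replicates; the normal limit at
`lambda = 200`, bounds `(5e-5, 1e-2)`, 1e5 draws; model selection at n = 60
with 50 replicates; deviation signs on 30 contaminated surveys per branch;
and calibration on 200 neutral surveys. These sizes give comfortably
resolvable signals at interactive runtimes.

On calibration: the per-dataset significance rate — the fraction of the 100
replicate KS tests with p < 0.05 — averages ~5% across neutral surveys,
matching the nominal level. The stricter per-survey rule "mean p < 0.05" is
conservative (essentially never rejects on neutral data) because the rate is
estimated from the same sample it is tested against; both numbers are
reported.

## Known limitations

* The lattice density carries O(1/N) discretization bias concentrated near
  `phi_m`, visible only through the KS bound; halving checks via
  `grid_size` doubling are available but not automatic.
* The asymptotic KS p-value under ties is approximate; no tie correction is
  applied.
* `alpha = 1` is rejected rather than special-cased (the normalization
  changes form there and no analysis uses it).
* The ZOIB uses two independent boundary atoms; joint-inflation
  parameterizations exist and would change the atom likelihood factorization
  but not the censored interior.
* Presence/absence fitting ignores partial information in damage magnitudes;
  it is provided as the closed-form companion estimator, not a replacement
  for the full likelihood.
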