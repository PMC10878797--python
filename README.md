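# neutralherb

A neutral stochastic model of herbivore damage for plant–herbivore ecology.

Field surveys of herbivory record highly unequal damage: most leaves escape
nearly untouched while a few are consumed whole. `neutralherb` implements the
null hypothesis that this variability needs no heterogeneity in plant quality
or herbivore behaviour at all — it asks how much of the observed pattern is
reproduced by *identical, passive* plants attacked by herbivores sampled at
random from a regional pool. The package is aimed at ecologists who want to
fit this neutral model to damage surveys (for example HerbVar-protocol data:
~30 conspecific plants, ~10 leaves each, visually estimated damage at 0.5%
resolution), test it against phenomenological alternatives, and measure
where and how real data deviate from neutrality.

## The model

Cumulative proportion damage on a leaf is a truncated compound Poisson sum

```
phi_T = min( sum_{i=1}^{k} phi_i , 1 ),     k ~ Poisson(lambda),
```

where each feeding event removes a proportion `phi_i` of the leaf, iid with a
truncated Pareto density on `[phi_m, phi_M]`:

```
P(phi) = (1 - alpha) phi^(-alpha) / (phi_M^(1-alpha) - phi_m^(1-alpha)).
```

The exponent is not fitted: metabolic theory fixes it. With per-event
consumption scaling with herbivore body mass as `M^(3/4)`, abundance as
`M^(-3/4)` and species richness as `M^(-2/3)`, a change of variables gives
`alpha = 14/9` exactly. The only free parameter is the attack rate `lambda`,
estimated by maximum likelihood (interval-censored at the 0.5% recording
resolution; the distribution itself has no closed form and is computed by
lattice convolution). At the whole-plant scale the event bounds are divided
by `L`, the median number of leaves sampled per plant.

Two corollaries the package also implements:

* presence/absence of damage has the closed form `P(damaged) = 1 - e^(-lambda)`,
  giving a one-line attack-rate estimator;
* for large `lambda`, any unitless inequality index I of damage obeys
  `I ~= sqrt(E[phi^2]/lambda) / (c E[phi])` with `c = 1` (CV), `sqrt(pi)`
  (Gini), `sqrt(2 pi)` (Hoover) — inequality declines as `1/sqrt(lambda)`,
  so mean damage and damage variability are not independent observations.

Model adequacy is assessed against two standard competitors (a 3-parameter
hurdle truncated lognormal and a 4-parameter zero-one-inflated beta, compared
by AICc) and by Monte-Carlo diagnostics: two-sample KS tests against
simulated predicted samples, ten statistical probes summarized by a
constrained (RDA-style) variance partition, major-axis regression of log
observed on log predicted CV, a leaf-shuffle empirical null, and binned
Kullback–Leibler divergence.

## Worked example

```python
import numpy as np
from neutralherb import (EventParams, SynthConfig, generate_survey, fit_neutral,
                         plant_means, median_leaves, plant_scale_event_params,
                         compare_dataset)

event = EventParams()                    # phi_m = 0.5%, phi_M = 100%, alpha = 14/9
survey = generate_survey(SynthConfig(lam=2.0, seed=11), event)

leaf_fit = fit_neutral(survey["prop_damage"].to_numpy(), event)
print(f"leaf-scale attack rate:  lam_hat = {leaf_fit.lam_hat:.3f}")

L = int(median_leaves(survey).iloc[0])
pm = plant_means(survey)["prop_damage"].to_numpy()
report = compare_dataset(pm, plant_scale_event_params(event, L), seed=0)
```

prints/produces (values from this exact seed):

```
leaf-scale attack rate:  lam_hat = 1.977  (loglik = -1171.7, n = 300, AICc = 2345.3)
plant-scale attack rate: lam_hat = 18.78  (L = 10)
KS vs 100 predicted replicates: D = 0.222, mean p = 0.45
CV observed = 0.443, predicted = 0.545
KL divergence = 0.385 nats
dAICc (HTLN: neutral) = 0.3, (ZOIB: neutral) = 3.4
```

Reading the output: the survey was generated at a true leaf-scale rate of 2
and the MLE recovers 1.98. The plant-scale rate is roughly `L x lambda`
(independent feeding events superpose across a plant's leaves). The KS test
finds no significant departure of the observed plant means from the model's
predicted samples (mean p = 0.45), the KL divergence from prediction is
small, and both phenomenological competitors have *higher* AICc (positive
differences favour the neutral model) — as they should on neutral data,
carrying 3–4 parameters against one.

The same workflow is available from a shell:

```
neutralherb generate --out survey.csv --lam 2 --seed 11
neutralherb fit --table survey.csv --scale plant --out fits.json
neutralherb compare --table survey.csv --out-json report.json --seed 0
neutralherb sensitivity --table survey.csv --out sens.csv --bounds 0.001:1,0.005:1,0.01:1
```

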