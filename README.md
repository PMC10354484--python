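# whalepreg

Non-invasive pregnancy diagnosis for gray whales from faecal hormones
and drone photogrammetry.

Confirming pregnancy in a free-ranging baleen whale is hard: the only
definitive sign is a calf seen the following year, which misses lost
pregnancies and gives no early signal. For female Pacific Coast Feeding
Group (PCFG) gray whales, two non-invasive proxies can be collected at
sea: faecal progesterone metabolites (**fP4m**, ng of immunoreactive
hormone per g dried faeces, analysed as log fP4m) and the standardized
body width at 50% of total length from drone images (**W50** = width /
total length, unitless — pregnant females are visibly wider at
mid-body). This package implements the full analysis that turns those
measurements into per-whale pregnancy probabilities and evaluates how
well each proxy diagnoses pregnancy.

## The model

Whale-years are assigned a reproductive class from photo-identification
sighting histories — PF (pregnant: calf next year), LF (lactating), JF
(juvenile), MF (mature, unknown status). After quality control and
annual aggregation, each diagnostic variable is modelled as a
two-component normal mixture fit by expectation–maximization:

* **Model 1** — bivariate (log fP4m, W50), full covariances;
* **Model 2** — univariate log fP4m;
* **Model 3** — univariate W50.

The "pregnant" component is the one whose mean is larger in every
variable, and a record's pregnancy probability is the density ratio
`phi_H(x) / (phi_H(x) + phi_L(x))`. Uncertainty comes from a
constrained non-parametric bootstrap (10,000 replicates): the five PF
records enter every sample, replicates are kept only if the fit
converged and one component dominates, and each retained fit is
evaluated at every original record (point estimate = bootstrap mean for
Model 1, median for Models 2–3; 95% interval from the 2.5/97.5
percentiles). A record is classified pregnant at probability >= 0.75,
and performance is scored against known-status whales (PF vs LF+JF).
Photogrammetric uncertainty in the group comparison is propagated by a
Monte Carlo ANOVA (80,000 replicates) summarized with highest-density
intervals. See `docs/methods.md` for the details and design choices.

## Worked example

Run the whole pipeline on the bundled dataset:

```sh
whalepreg run-all --seed 0 --out run/
```

which prints (abridged):

```
records: 111 whale-years (76 with fP4m, 77 with W50, 42 with both)

group summaries (mean [min-max]):
  PF log_fp4m: n= 5 4.60 [2.80-5.73]
  PF      w50: n= 5 0.18 [0.17-0.19]
  ...

bootstrap retention:
  model1: 65.4% of 10000
  model2: 99.8% of 10000
  model3: 99.8% of 10000

performance                 model1    model2    model3  formula
---------------------------------------------------------------
accuracy                       71%       39%       92%  (TP + TN)/Tot
true (+) rate                  80%       80%      100%  TP/(TP + FN)
false (+) rate                 33%       70%       10%  FP/(FP + TN)

MF whale-years classified pregnant:
  model1: 6 of 25
  model2: 34 of 48
  model3: 8 of 52
```

Reading this: confirmed-pregnant females average log fP4m 4.60 and W50
0.18. Only ~65% of bivariate bootstrap replicates pass the retention
rules (the hormone axis often fails to separate), versus ~99.8% for the
univariate models. The width-only model is the clear winner — 92%
accuracy on the 25 known-status whale-years with every confirmed
pregnancy detected — while the hormone-only model misfires on 70% of
non-pregnant females, because pregnant and non-pregnant fP4m
distributions overlap heavily at the population level. Applied to
mature females of unknown status, the width model flags 8 of 52 as
pregnant with high confidence; the hormone model's 34 of 48 mostly
reflects its false-positive rate. Per-record probabilities with
quartiles and 95% intervals are written to
`run/probabilities_model*.csv`, and the Monte Carlo ANOVA
(`run/mc_anova.json`) puts the PF group mean at 0.178 (95% HPDI
0.174–0.182), well clear of the JF and LF groups near 0.15.

The library surface mirrors scikit-learn:

```python
import numpy as np
from whalepreg import BootstrapPregnancyModel, load_pcfg_females, model_matrix

df = load_pcfg_females()
X, forced, ids, sub = model_matrix(df, model=3)  # W50-only
est = BootstrapPregnancyModel(point_rule="median", dither=0.005, random_state=0)
est.fit(X, forced=forced, record_ids=ids)
print(est.retention_.retained_fraction)   # ~0.998
print(est.summaries_.head())              # point, lq, uq, ci_low, ci_high per whale-year
```

Synthetic data with the same structure (and known ground truth) comes
from `whalepreg simulate --out sim/ --seed 1` or
`whalepreg.simulate.simulate_dataset`.

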