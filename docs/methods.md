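# Methods

## The problem

Pregnancy in free-ranging baleen whales cannot be confirmed by handling;
the only hard evidence is a calf seen the following year. This package
implements a non-invasive diagnosis pipeline for female Pacific Coast
Feeding Group (PCFG) gray whales that combines two measurable proxies:

* **fP4m** — faecal progesterone metabolites, quantified by enzyme
  immunoassay in ng of immunoreactive hormone per g of dried faeces and
  analysed on the natural-log scale;
* **W50** — body width at 50% of total body length from drone
  photogrammetry, standardized by total length (unitless).

Whale-years are assigned a reproductive class from sighting histories:
PF (pregnant: calf the next year), LF (lactating: calf in the sampling
year), JF (juvenile: known age < 8, or length posterior mostly below
11.7 m when age is uncertain), MF (mature, unknown status). PF records
are the positives; LF and JF are presumed non-pregnant; MF is the
population the fitted models are ultimately applied to.

## Preprocessing

Hormone QC: duplicate assay wells with CV > 15% are flagged (the lab's
rerun loop cannot be re-executed in software, so flagged values remain
usable behind a switch, which matches the final analysed dataset);
readings below the kit's limit of detection (8.57 pg ml^-1) are replaced
by LOD/2 on the raw assay scale before unit conversion; concentration in
ng g^-1 is `pg ml^-1 x dilution x extract volume / (1000 x dry mass)`;
samples under 0.02 g dried mass are excluded (small-sample inflation);
same-day duplicates resolve to the higher-mass sample (ties break on
sample id). The annual value is the natural log of the *median*
concentration — median on the natural scale first, log second; for even
counts the order matters and this one follows from analysing the median
concentration and transforming the result.

Width QC: only measurements strictly after 26 August are kept (whales
early in the feeding season are thin after the fasting migration, so
"after the 26th" is read as excluding the 26th itself); within a
whale-year the measurement with the maximum W50 posterior mean is used
(pregnant females widen over the season), carrying that measurement's
own posterior sd; ties break toward the most recent date, the one
closest to putative late gestation.

## The mixture model

Each model treats the whale-year values as a two-component normal
mixture: Model 1 bivariate (log fP4m, W50) with full covariances,
Model 2 univariate log fP4m, Model 3 univariate W50. Fitting is
standard EM (responsibilities, then weighted moment updates), converged
when the relative log-likelihood change falls below 1e-8 within the
iteration cap. The component whose mean is strictly larger in every
modelled variable is labelled "pregnant"; when neither component
dominates the labelling is invalid (this is data, not an error — the
bootstrap uses it as a retention rule).

The pregnancy probability of a record x is the density ratio

    P(pregnant | x) = phi_H(x) / (phi_H(x) + phi_L(x)),

computed in log space so tail points never produce NaN. Two weightings
are implemented: the default `literal` mode is the bare ratio above;
`responsibility` mode additionally weights each density by its mixing
proportion (the standard posterior responsibility). The literal ratio is
the default because it reproduces the published per-record probabilities
far more closely on the bundled dataset (Model 2 mean absolute error
0.018 vs 0.047); both modes are exposed and tested.

### Numerical choices

* tol 1e-8 (relative), covariance eigenvalue floor 1e-10. A fit whose
  covariance drops through the floor has hit the unbounded-likelihood
  spike that unequal-variance Gaussian mixtures possess at tight clumps
  of data; it is restarted from random responsibilities (up to 20 times,
  the standard mixture-EM remedy) and flagged non-convergent if the
  budget is exhausted.
* Single-dataset fits (`em_fit`, `TwoComponentNormalMixture`) use a
  deterministic rank split (lower/upper half on the first variable) plus
  10 seeded random-responsibility restarts, best converged
  log-likelihood wins; `max_iter` 1000.
* Bootstrap replicate fits use the rank-split init only, with
  `max_iter` 5000: overlapping components converge slowly, and the 99th
  percentile of replicates needs ~2800 iterations at this tolerance.
  We deliberately do *not* chase the best likelihood over many inits per
  replicate: because the likelihood is unbounded, harder maximization
  drifts toward spiky clump solutions rather than the scientifically
  meaningful two-component structure; a single moderate init targets the
  well-behaved optimum. A rare consequence (order 0.5% of replicates on
  small, strongly separated data) is a replicate stuck in a spurious
  local optimum; quartile-based summaries are insensitive to it.
* The EM is implemented in batched form over replicates (arrays of
  shape `(B, n, d)` with closed-form 2x2 determinants/inverses), so the
  full 10,000-replicate, three-model pipeline runs in about two minutes
  on one CPU. The batched and single-fit code paths share the same
  update algebra and are cross-checked against each other and against
  an independent implementation (sklearn `GaussianMixture`) in tests.

## The constrained bootstrap

Confirmed pregnancies are rare (5 records), so every bootstrap sample
contains all PF records exactly once; the remaining n - 5 slots are
drawn with replacement from the non-PF pool (an alternative scheme that
also resamples PF is available behind `resample_forced`). Each of the
10,000 replicates refits the mixture; a replicate is retained only if
the fit converged *and* the component labelling is valid (one mean
dominates everywhere). Every retained fit is evaluated at every
*original* record, and per-record summaries are taken across retained
replicates: the point estimate is the bootstrap mean for the bivariate
model and the bootstrap median for the univariate models, with 25/75
quartiles and a 2.5/97.5 percentile interval (linear-interpolation
quantiles — stated because quantile conventions differ across
ecosystems).

On the bundled dataset the univariate models retain ~99.8% of
replicates and the bivariate model ~65% — the bivariate labelling often
fails to dominate in both variables because fP4m barely separates the
components.

### Smoothing for print-resolution data

The bundled study dataset carries both variables at two decimals, which
creates large atoms (26 identical W50 = 0.15 values). Exact atoms are
poison for unequal-variance mixture EM: a component can collapse onto an
atom with unbounded likelihood, which the original continuous
measurements never allowed. The pipeline therefore uses a smoothed
bootstrap on such data: every resampled value is drawn uniformly from
its rounding interval (half-width 0.005, the print resolution), while
evaluation stays at the original recorded values. This emulates
resampling from the underlying continuous data. For full-precision
inputs (e.g. the synthetic generator's output) no smoothing is applied
(`dither=None`).

A related consequence of the two-decimal data: records sharing a
printed value necessarily share a fitted probability, so per-record
agreement with probabilities computed from full-precision data is
limited by the rounding; aggregate quantities (retention, confusion
matrices, threshold counts) are insensitive to it.

## Classification and evaluation

A record is classified pregnant when its point probability is **at or
above 0.75** (the boundary is inclusive). Evaluation uses only
known-status records — PF positive, LF and JF pooled as negative; MF
excluded — and reports the six confusion-matrix rates, rounded half
away from zero to whole percents for display with unrounded values
retained. On the bundled dataset the W50-only model attains 92%
accuracy (23/25) with a 100% true-positive rate, while the fP4m-only
model suffers a 74% false-positive rate: the hormone distributions of
pregnant and non-pregnant females overlap heavily at the population
level, which is the study system's documented failure mode, not an
artifact of the implementation.

## Monte Carlo ANOVA with uncertainty propagation

Each W50 is a photogrammetric posterior (mean, sd), not an exact value.
The group comparison redraws every record's W50 from Normal(mean, sd^2)
in each of 80,000 replicates, computes per-group cell means and all
pairwise differences (cell means with explicit differencing equal
differences of ANOVA coefficients under any contrast coding), and
summarizes with means and 95% highest-posterior-density intervals. The
HPDI is the shortest contiguous window of the sorted draws containing
ceil(0.95 n) points, ties resolved to the lowest start. The bundled
dataset does not print per-measurement W50 sds, so fixture-based runs
use a configurable global default (0.005, the order implied by
two-decimal printing) and the quantitative validation of this module is
synthetic-data recovery (coverage and convergence to plug-in
differences), not the study's printed group means.

## The synthetic-data generator

`whalepreg.simulate` emits the same CSV schemas the pipeline ingests,
with ground truth attached. Defaults are the study conditions: class
counts PF 5 / LF 4 / JF 19 / MF 48 over six seasons; log-fP4m components
N(4.60, 1.15^2) pregnant vs N(4.10, 0.77^2) non-pregnant — deliberately
overlapping so the simulator reproduces the hormone variable's failure
mode rather than an idealized version; W50 components N(0.178, 0.01^2)
vs N(0.15, 0.01^2) with 0.005 measurement noise; 15% of MF truly
pregnant (their calves unobserved — the calf-loss ambiguity; a separate
`calf_loss_rate` converts would-be PF into MF to exercise the same
ambiguity from the other side, default 0 so observed class counts match
the configuration exactly). Assay rows include duplicate wells with 8%
relative noise, 5% below-LOD censoring, 5% under-mass samples, 8%
same-day duplicate jars; width rows include early-season dates (15%)
and a plausible body-width profile along the axis.

What the generator does not emulate: temporal autocorrelation within an
individual across years, assay plate effects, non-normal measurement
error, and the photogrammetric altitude-calibration process itself
(widths are drawn directly around their latent value). Passing tests on
synthetic data therefore demonstrate correctness of the statistical
machinery under the stated model, not robustness to those real-data
features.

## Known limitations

* Two-component normal mixtures only; no model selection over K.
* The maturity rule depends on sighting-history length, whose count
  convention (sampling year minus first year) is a declared convention
  of the fixture schema; "the year after sampling" is taken as calendar
  year.
* With five confirmed pregnancies, the forced-inclusion bootstrap
  understates sampling variability in the PF component; intervals for
  PF-adjacent records are accordingly optimistic.
* Aggregate reproduction of the study's results is limited by the
  two-decimal precision of the published per-record values (see the
  smoothing note above).
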