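# Methods

This note documents the models, the simulation design, the numerical
choices, and the limits of what the synthetic experiments can show.

## Observer models

The task presents, on each trial, five successive samples from a jar
containing blue and red marbles; the subject then reports the jar's
blue-marble proportion on a 0.01 grid. The observer represents the latent
proportion as a beta distribution. Because the beta prior is conjugate for
the binomial likelihood, observing a sample with B blue and R red marbles
updates Beta(α, β) to Beta(α + B, β + R); the belief mean is α/(α+β) and
its variance αβ/((α+β)²(α+β+1)) is the observer's uncertainty.

Model variants:

* **Prior width ρ ≥ 1** — the trial-initial belief is Beta(ρ, ρ). ρ = 1 is
  the flat (unbiased) prior; larger ρ both biases estimates toward 0.5 and
  caps how much uncertainty can be reduced during a trial.
* **Evidence weight δ ≥ 0** — counts enter the update as B^δ, R^δ
  (with 0^δ := 0, including δ = 0: a zero count carries no evidence);
  δ < 1 underweights large samples. δ = 1 is exact conjugate updating.
* **Response rules** — either a normal distribution centered on the
  posterior mean, truncated (renormalized, not censored) to [0, 1], with
  free noise σ; or a random draw from the final beta distribution, scored
  as the probability of the 1/100-wide response bin (beta-CDF differences;
  edge bins half-width). The binned likelihood is proper by construction.
* **Rescorla–Wagner** — a point estimate updated by
  R̂ ← R̂ − lr·(R̂ − B/(B+R)) from init 0.5, with the same truncated-normal
  response rule; it tracks no uncertainty and serves as the non-Bayesian
  comparison.

The experienced proportion θ_t used for estimation error defaults to the
pooled count ratio (total blue / total marbles); a per-sample-mean variant
is available (`TrialRecord.experienced_proportion("mean")`) since the two
differ whenever sample sizes vary within a trial.

## Fitting

Per-subject maximum likelihood by bounded L-BFGS-B from 10 uniform-random
interior starts (best of starts kept; a subject is flagged if no start
converges). Bounds: ρ ∈ [1, 50], δ ∈ [0, 5], σ ∈ [10⁻³, 1],
learning rate ∈ [0, 1] — one-sided theoretical constraints closed with
upper bounds far beyond typically fitted values. The per-family joint
likelihood is evaluated in closed vectorized form over all trials (for the
Bayesian families the final beta parameters are sums of weighted counts),
which makes multi-start fitting and thousand-fit recovery studies cheap.
BIC uses n = number of valid trials (one response per trial is the
likelihood's unit); trials with missing responses are dropped before
fitting. BIC values are negative whenever the average response density
exceeds 1 — expected for response noise σ < ~0.4 on a [0, 1] scale.

## Synthetic population

Simulated groups draw ρ as 1 plus a lognormal with median 1.45 and log-SD
1.1, giving group median ρ ≈ 2.45 with a heavy right tail (group SD ≈ 4),
and σ lognormal with median 0.10 (log-SD 0.2, clipped to [0.03, 0.3]).
These place most agents near the mildly biased regime while keeping the
prior-width axis the dominant source of between-subject accuracy
differences. Draws are quantile-stratified (Latin-hypercube style): each
agent occupies one probability stratum, randomly assigned, so that even a
30-agent group spans the population including its tail. Stratification
changes no marginal distribution; it only removes group-composition noise
between replicate datasets.

## Synthetic BOLD

Geometry is desk-scale by default: a 12×12×12 voxel grid with a 216-voxel
box mask, half of it a contiguous *effect* block (so cluster thresholding
is meaningful), 3 runs × 18 trials, TR 0.645 s. Each sample event elicits
a response of random amplitude (mean 1, arbitrary units), convolved with
the canonical HRF; white Gaussian noise (SD 0.2) is added, with optional
AR(1) and sinusoidal drift. In effect voxels the amplitude SD for trial t,
period s is

    sd(t, s) = base + gain · Var_posterior(t, s) / Var_flat_prior

with base 0.05, gain 1, and Var_flat_prior = 1/12 (the flat Beta(1,1)
prior variance). One *global* normalizer is deliberate: agents with wide
priors (ρ ≈ 1) start from maximal uncertainty and compress their amplitude
dispersion strongly across the five periods, while narrow-prior agents
start low and compress little — the individual-differences structure under
study. Normalizing per-subject by each agent's own prior variance would
invert that ordering and is not used. Null voxels get a constant amplitude
SD (0.2); estimation and gambling events are included as nuisance events
(fixed amplitude by default) so the 21-regressor run design arises
structurally.

The generator also accepts an explicit per-period amplitude-SD schedule,
which provides exact ground truth for pipeline recovery checks.

## GLM and SD_BOLD

Designs convolve unit boxcar events with the canonical double-gamma HRF
(peak ~6 s, undershoot ~16 s, ratio 1/6, via nilearn) plus its temporal
and dispersion derivatives: 7 conditions × 3 basis functions + run
constant = 22 columns per run. Convolution is done on a tr/10 grid and
sampled at scan times; the simulator uses the same machinery, so
noise-free recovery oracles are exact.

LS-S fits, per event, a GLM with the single event (3 basis columns), all
other events pooled (3 columns) and a constant; the single event's
canonical beta is kept. Events within the final 20 s of a run are
discarded (truncated HRF). The per-event normal equations are assembled
from precomputed Gram blocks, so each event costs a 7×7 solve regardless
of run length. SD_BOLD is the across-trial sample SD (n−1) of canonical
betas pooled across runs, per sample period and voxel; ΔSD_BOLD is its
least-squares slope over periods 1–5. Derivative betas are treated as
nuisance. Estimation is OLS throughout: with white-noise synthesis OLS
and ReML coincide in expectation, and prewhitening is out of scope.

**A known LS-S artifact, documented rather than hidden:** at the task's
dense timing (samples 3–7 s apart), the unmodeled amplitude variability of
*neighboring* events leaks into each single-trial beta. The leak is
period-dependent — the final sample is followed by several seconds of
silence and leaks least — so even amplitude-SD-flat voxels show a small
systematic SD_BOLD period profile (slope ≈ −0.01 in default units). The
artifact is identical for every subject, so between-subject analyses
(everything in the PLS stage) are unaffected; but a per-voxel "is this
slope zero" test at dense timing is not calibrated. The ground-truth
recovery and false-positive calibration therefore run the generator with
spaced fixations (8–16 s, the task module's configurable `iti_range_s`)
and sampling-phase-only events, where betas are identifiable and the null
false-positive rate is nominal.

Exact amplitude recovery by LS-S (and exact equivalence with per-trial
OLS) holds when the pooled-other regressor fits the other events exactly,
i.e. amplitudes equal across trials within a run; with heterogeneous
amplitudes the misfit couples through the shared constant column at the
~5·10⁻⁴ level. This is a property of LS-S itself.

## PLS and group inference

Task PLS: subject condition-mean data are centered on the subject's grand
mean, averaged over subjects, and the condition × voxel matrix is
decomposed by SVD (saliences unit-norm, singular values descending).
Behavioral PLS: the behavior × voxel cross-correlation matrix (columns
rank-transformed by default — relationships are monotone, robust to
univariate outliers) is decomposed by SVD; the first LV's brain and
behavior scores give the latent correlation. Permutation p-values use
(b+1)/(B+1) counting — a "p = 0" is reported as < 1/(B+1) — permuting
condition labels within subject (task) or behavior rows (behavioral).
Bootstrap resamples subjects with replacement; resampled saliences are
sign-aligned to the original LV by dot product; BSR = salience / bootstrap
SE, thresholded at |BSR| > 3 with 25-voxel minimum clusters under
6-neighborhood (face) connectivity. Multivariate outliers are screened by
Cook's distance > 4/n on the latent-score/behavior regression and the PLS
is refitted without them.

The pipeline can additionally run the standard-GLM comparison stage
(`analysis.parametric_glm`): a per-run design with one pooled sample-onset
regressor, its mean-centered parametric modulation by the *unbiased*
(ρ = 1) observer's posterior variance, and estimation/gambling nuisance
regressors (each × 3 basis functions, 12 regressors per run plus run
constants). The canonical modulation betas enter their own behavioral PLS
("latent uncertainty β"), and a spatially matched control variable —
the modulation betas projected onto the ΔSD_BOLD saliences — joins latent
ΔSD_BOLD in a regression on median error, testing whether the SD_BOLD
effect is spatially and statistically separable from mean-signal
uncertainty coupling. The stage is off by default; the core study path
does not require it.

Latent regressions (e.g. latent ΔSD_BOLD on fitted ρ and σ) are OLS on
rank-transformed variables; each predictor reports t, p and semi-partial
η² (its SS when entered last over total SS). Polynomial trends over the
five sample periods use the standard orthogonal contrast weights
(linear −2…2, quadratic 2 −1 −2 −1 2, cubic −1 2 0 −2 1) in a long-form
model with subject indicator covariates.

A caveat worth knowing: in-sample PLS brain scores contain the behavior
itself through the Gram diagonal (score_i includes a term ∝ V·behavior_i).
At small n this injects a trace of every behavioral component — including
response noise σ — into "latent ΔSD_BOLD", which is why the σ term of the
latent regression can reach nominal significance by leakage alone. The
meaningful contrast is the dominance of ρ's unique variance share, which
is what the validation asserts (σ's p-value is reported alongside).

## Problem sizes and what passing shows

Validation runs at desk scale: groups of 30 agents × 54 trials, a
216-voxel mask, 500 permutations and 300 bootstraps, five replicate
datasets for the end-to-end study; recovery studies use 10 datasets per
generating family. These sizes make every check sharp at the effect sizes
the generator produces while keeping the full suite fast.

Passing shows that the machinery is correct and calibrated **for data
generated by this model**: conjugate updating, likelihood code, optimizer,
LS-S algebra, SD computation, SVD/permutation/bootstrap logic, and the
end-to-end wiring of behavior to brain. The generator does not emulate
physiological noise structure (cardiac/respiratory aliasing, motion,
spatially correlated noise), ICA-style preprocessing residuals, regional
hemodynamic variability, or real response-time behavior; none of the
quantitative results transfer to real data as point estimates, only the
procedures do.

## Known limitations

* Subject effects in the bias test and polynomial contrasts are fixed
  indicator variables, not random effects; with random slopes the F tests
  would be somewhat more conservative.
* The draw-family response likelihood assumes the 0.01 response grid; for
  responses recorded off-grid it snaps to the nearest bin.
* ρ and σ recovery degrades jointly at large ρ with large σ (a nearly
  flat likelihood ridge); recovery studies report winsorized correlations
  for this reason, and both raw and winsorized values are returned.
* The missing-response path drops trials silently before fitting; no
  imputation is attempted.
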