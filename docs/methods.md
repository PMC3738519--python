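# Methods

This note documents the statistical machinery implemented in `twindow`,
the choices made where the procedures admit more than one reasonable
operationalisation, and what the synthetic-data generator does and does
not emulate.

## Data model

A study holds, per participant, 26 reaction-time (RT) conditions — catch
(no stimulus), auditory-only, visual-only, and bisensory presentations at
23 SOAs (0, ±20, ±40, ±60, ±80, ±100, ±120, ±150, ±200, ±250, ±300,
±400 ms; negative = auditory leading) — plus a temporal-order-judgment
(TOJ) table of ("visual first" count, total) per SOA. Misses are coded as
infinite latencies and retain probability mass: an RT sample's empirical
CDF counts them in `n` but they never enter finite quantiles. Latencies
are clocked from the onset of the first stimulus in the trial.

Trial-level filters (applied upstream in the published dataset, available
here for raw or simulated data): trials with stimulus/response timing
uncertainty strictly above 5 ms are excluded; TOJ responses earlier than
100 ms after first onset are false alarms and dropped (SOAs emptied by the
filter keep a zero-trial row, which contributes a factor of one to the
likelihood).

## Empirical CDFs and quantiles

The i-th of n order statistics carries plotting position (i − ½)/n (the
Hazen convention), with linear interpolation between positions; queries
below the first position clamp to the minimum latency, and queries beyond
the last *finite* position raise an error. The race analysis only needs
percentiles ≤ 25, so the error path is reached only when more than ~¾ of a
sample is missing; such SOAs are flagged *untestable* and treated as
non-significant everywhere downstream (including the contiguity rule).

The race bound B(t) = min(1, P_A(t − δ_A) + P_V(t − δ_V)) is evaluated on
the merged grid of onset-shifted sample latencies, where it is piecewise
linear, and inverted exactly by interpolation on that grid. The cap at 1
cannot affect inversion at percentiles ≤ 1. The small jump the convention
places at each sample minimum is crossed by linear interpolation; the
effect is far below the millisecond scale of the data.

## Kill-the-twin

For each catch-trial response (processed in ascending latency order, so
the outcome is deterministic), one finite latency of the target sample is
replaced by ∞:

* **conservative** (observed data): the nearest latency ≤ the catch
  latency; if none qualifies, the overall nearest;
* **progressive** (resampled null data): the overall nearest.

Ties at equal distance break toward the lower latency. "Similar latency"
is not operationally defined in the source procedures; nearest-neighbour
matching is the simplest deterministic reading, and the conservative
variant's preference for latencies at or below the guess makes it remove
(weakly) faster responses — its surviving CDF never exceeds the
progressive one (property-tested). The pipeline applies the conservative
correction to the visual-only *and* the bisensory distributions
(`kill_twin_extend_to_av`, default on). Guesses contaminate every stimulus
condition, and correcting only visual-only is visibly anticonservative:
a participant with an unlucky run of catch guesses keeps the contamination
in the tested samples while the progressive correction slows the null
resamples, and the race test then fires at every SOA.

## The race-model test

The statistic D sums the bisensory-minus-bound quantile differences at
percentiles 10, 15, 20, 25; D < 0 indicates violation. The null
distribution is simulated 1000 times per SOA: each iteration resamples
observed latencies with replacement, antithetically rank-paired — the
auditory draw at quantile u (rank ⌈u·n⌉, infinite entries sorted last)
with the visual draw at quantile 1 − u, both onset-shifted, keeping the
faster — then applies progressive kill-the-twin with the participant's
catch responses. Discrete resampling of actual latencies (not interpolated
quantiles) matches the published bootstrap and measures closer to nominal
calibration. The p-value uses the add-one convention
p = (#{D* ≤ D} + 1)/(n_iter + 1), one-sided at α = 0.05. p-values within
±0.01 of α are flagged `borderline` in reports, since their significance
can flip between seeds.

**Bound regeneration.** By default each null iteration also rebuilds the
bound from bootstrap resamples of the two unisensory samples. The observed
D carries two sources of estimation noise — the bisensory sample and the
bound — while a null statistic computed against the fixed observed bound
carries only the first; that underdispersion makes the test
anticonservative (measured rejection ≈ 0.13 at nominal 0.05 under a
race-true generator with maximal negative dependence and 60 trials per
condition). With bound regeneration the measured type-I error is ≈ 0.055
under the clean race-true null (N = 600) and 0.06–0.07 with the study's
guess/miss contamination plus twin-killing, while power against a 50 ms
coactivation gain remains ≈ 1. `regenerate_bound=False` restores the
fixed-bound variant.

The RT-defined window applies a contiguity rule to the per-SOA decisions:
the maximal run of significant SOAs containing 0, else the run nearest 0
(ties break to the positive, visual-leading side). The group-level
sign-permutation test enumerates all 2ⁿ reassignments of each
participant's D to ±, and reports the one-sided fraction of permutation
sums ≤ the observed sum (a small tolerance keeps the identity permutation
counted under floating-point reordering). Group-level outputs are labelled
illustrative; inference is per-participant.

## Bayesian psychometric model

Ψ(x) = λ_A + (1 − λ_A − λ_V) F(x; μ, σ) with F the logistic CDF. Priors:
λ_A, λ_V ~ Beta(2, 20) (mode 0.05) truncated jointly to λ_A + λ_V < 1;
μ ~ N(0, 200²) ms; σ ~ Gamma(shape 1.05, scale 1000) ms. The Gamma uses
the shape–scale parameterisation, chosen so the prior is near-flat with
mode (κ − 1)θ = 50 ms — the classic shape/rate ambiguity is resolved in
favour of the parameterisation that produces the documented mode. The
likelihood is binomial per SOA; binomial coefficients are constants and
are omitted inside the sampler.

Sampling is univariate slice sampling applied coordinate-wise
(μ, σ, λ_A, λ_V per sweep): the initial interval has the prior-SD width
placed at random around the current point, expands each end with doubling
step sizes until it exits the slice, and samples by shrinkage. Initial
values are the prior modes (μ = 0, σ = 50, λ = 0.05). The schedule is
100 burn-in sweeps then every 10th sweep until 2000 draws are retained;
runs are deterministic given the seed, and lag-1 autocorrelations of the
retained draws are reported (typically |r| < 0.05). The compute-critical
kernel is compiled with numba.

Thresholds solve Ψ(thr_A) = (λ_A + ½)/2 and Ψ(thr_V) = (½ + 1 − λ_V)/2 in
closed form via the logistic inverse (75 % correct per side when lapses
vanish; verified against a numeric root-finder to < 10⁻⁹ ms). The
TOJ-defined window takes the 5th percentile of the 2000 auditory-first
threshold draws and the 95th of the visual-first draws — deliberately the
widest plausible boundaries — using linearly interpolated order statistics.
Participants whose window escapes the tested ±400 ms range on either side
never reached threshold performance there and are excluded from group
analyses, with the failing side recorded.

The group curve averages per-participant posterior medians parameter-wise
and reads thresholds off the averaged parameters.

## Cross-task comparison

Dissociation SOAs are the significantly race-violating SOAs inside the RT
window that fall strictly outside [thr_A, thr_V]. Because the race test is
conservative by construction and the TOJ window uses its widest
boundaries, a dissociation is a robust sign of task-driven recalibration;
the reverse pattern (chance-level order judgment without RT violation) is
never counted, since absence of evidence for violation is not evidence of
absence. TOJ accuracy at a dissociation SOA is c/n for visual-leading and
(n − c)/n for auditory-leading SOAs (majority rate at SOA 0, where no
answer is correct). Group comparisons use pooled-variance t tests on
window widths and boundaries and a two-factor between-subjects ANOVA
(task × group) on widths with Type II sums of squares, appropriate for the
generally unbalanced group split; report fields record group means, SDs,
t, F and p.

## Synthetic-data generator

Defaults mirror the study design: 11 participants, 60 trials per RT
condition and per TOJ SOA, the full 23-SOA grid, a 3.94 % guess rate and a
0.7 % miss probability. Unisensory RTs are ex-Gaussian — auditory
N(230, 30²) + Exp(60) ms, visual N(280, 35²) + Exp(70) ms, standard
simple-RT magnitudes with auditory responses faster. A bisensory trial
draws a Gaussian-copula-coupled pair (correlation ρ, default 0; ρ = −1
reproduces the antithetic race exactly), onset-shifts each modality, takes
the minimum, and subtracts a coactivation gain γ (default 0 = race model
holds). γ may be a per-SOA mapping so coactivation can be confined to a
window around simultaneity — a constant gain would violate the bound at
every SOA, which no empirical window looks like. An anticipatory guessing
process races the true response in *every* stimulus condition
(min(RT, guess), guess ~ U(100, 1000) ms at the guess rate); on catch
trials the guess is the only possible response. This matters: the
progressive kill-the-twin applied to null resamples presumes the observed
distributions carry guess contamination, and a generator without it makes
the race test appear anticonservative. Misses replace latencies with ∞ at
the miss probability. TOJ counts are binomial under Ψ with per-participant
ground-truth parameters. The ex-Gaussian quantile function is tabulated
(8192-point inverse CDF, error < 0.1 ms) because per-element numerical
inversion dominates runtime otherwise.

`make_malleable_study_config` builds the canonical validation study:
5 participants with σ = 30 ms TOJ windows (thresholds ≈ ±33 ms) and
coactivation γ = 60 ms for |SOA| ≤ 80 ms, so their RT window reaches SOAs
they can still discriminate, and 6 participants with σ = 150 ms windows
(≈ ±165 ms) that cover every race-violating SOA.

What the generator does **not** emulate: sequential effects, fatigue or
practice drifts, latency-dependent miss rates, non-stationary lapsing, or
any neurally motivated coactivation dynamics (the gain is a constant shift
of the race minimum, not a diffusion-style superposition). Passing tests
therefore certify the inferential chain under a stationary, well-specified
generator — not robustness to real-data pathologies beyond the modelled
guess/miss contamination.

## Verification problem sizes

The test suite checks the sign-permutation test against exhaustive
enumeration up to n = 12; race-test calibration over 200 simulated
race-true participants (clean null: contamination processes off, since the
guess/miss machinery is validated by its own tests; 1000 resamples each)
and power over 60; parameter
recovery over 20 seeds of the 23 × 60 design, asserting the across-seed
mean and median of the posterior-median estimates within ±10 ms (μ) and
±20 % (σ) of truth — single-seed posterior spread at 60 trials/SOA is
~7 ms in μ, so a per-seed band that tight would be testing noise, not
bias; and end-to-end classification over 10 study seeds requiring the
exact 5-of-11 split in at least 9. `scripts/acceptance.py` re-runs the
pipeline plus calibration/recovery studies at (100, 40, 10) replicates.

## Known limitations

* The race test's calibration statement is empirical, under this
  generator, at these sample sizes; exactness is not claimed.
* Slice-sampling diagnostics are limited to lag-1 autocorrelation; the
  fixed burn-in/thinning schedule is trusted rather than adapted.
* The MAT reader expects the published container layout (a struct of
  per-participant substructs holding a 26×60 cell array and a 23×3 numeric
  array) and identifies fields by shape, not name.
* Group-level race and psychometric summaries are illustrative; no
  hierarchical model pools across participants.
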