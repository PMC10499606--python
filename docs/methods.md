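# Methods

`hypoconn` re-implements, as a tested pipeline, the computational
chain used to characterize an appetitive subnetwork linking the
lateral hypothalamus (LH) and the dorsolateral hippocampus (dlHPC):
intracranial EEG spectral analysis with cluster-based permutation
statistics, single-pulse evoked-potential parameterization,
streamline-probability segmentation with a connectivity index, and a
group-level connectivity battery.  Because the clinical recordings
and imaging behind such studies are not publicly deposited, the
package ships a first-class synthetic-data module that generates every
input with known ground truth, and its quality claims are
property-based: error rates are calibrated and planted effects are
recovered, at problem sizes a single CPU handles in minutes.

## Task LFP analysis

**Preprocessing.**  The conditioning chain is fixed and logged:
polyphase resampling (e.g. 1,024 → 1,000 Hz clinical rates; the
synthetic studies use 100–250 Hz), zero-phase 4th-order Butterworth
band-stop notches of ±1 Hz at 60 Hz and its 2nd–3rd harmonics (the
width is conventional for mains interference; only the targets are
method-prescribed), Laplacian rereferencing along each depth-electrode
shaft, epoching around cue onset, and amplitude-based artifact
exclusion.  The Laplacian references each interior contact to the mean
of its nearest good shaft neighbours; shaft-edge contacts fall back to
a bipolar reference, and bad channels are bridged by the next valid
neighbour.  Rereferencing refuses to stack schemes.

**Artifact rule.**  A sample is an artifact timepoint when it falls
strictly outside mean ± 4·sd, with both moments computed per channel
over all of that channel's full-length trials concatenated (spikes
included — the rule normalizes to the recorded signal itself, not a
robust estimator).  Any trial with at least one artifact timepoint on
any channel is excluded, and this exclusion is the single gate: every
downstream statistic consumes unflagged trials only, including the
normalization pools.  The rule is applied after rereferencing, on the
analysis-ready signal.  Strict inequality makes the all-zero
degenerate input flag nothing.

**Time–frequency decomposition.**  An analytic Morlet continuous
wavelet transform with centre parameter ω₀ = 6 (the classical 'morl'
parameterization), evaluated in the frequency domain:
reflect-padding, FFT, multiplication by e^{−(aω−ω₀)²/2} (zero at
negative frequencies), inverse FFT per scale.  Scales map to
frequencies through the wavelet centre frequency f = ω₀/(2πa) on a
log-spaced axis with `voices_per_octave` scales per octave (defaults
3–250 Hz, 32 voices; the simulation studies use 3–30 Hz at 9 voices,
≈ 30 frequencies).  The wavelet spectrum is unity at its centre
frequency, so a sinusoid of amplitude A yields power A²/4 at its own
frequency; absolute scale is irrelevant downstream because all
statistics are z-scored.  Samples within one Gaussian-envelope
standard deviation (a seconds) of an epoch edge carry an invalid flag
and are excluded from every pool and statistic.  The implementation is
cross-checked in the test suite against PyWavelets' independent
complex-Morlet CWT (`cmor2.0-C`, C = ω₀/2π).

**Normalization.**  Power is z-scored per channel × frequency against
the pooled prestimulus samples (the final 1 s of the 2 s pre-cue
fixation — the second closest to cue onset) of all unflagged trials of
the same condition; the alternative whole-recording mode pools every
valid sample regardless of condition.  Condition-specific baselines
equalize pre-cue power differences between conditions; the
whole-recording mode preserves them (both behaviours are tested).
Zero-variance strata are set to 0 with a warning.

**Cluster-based permutation test.**  Channels are the unit of
observation.  Given per-channel trial-averaged z-maps for two
conditions, a paired t-statistic is computed per time–frequency voxel.
The null permutes condition labels within channel, implemented as
per-channel sign flips of the difference maps — algebraically
identical for the paired t, and exactly enumerable (2^n patterns) when
the requested permutation count reaches that bound, which the engine
then does automatically.  Voxelwise two-sided p-values are rank-based
with the +1 Monte-Carlo correction (exact counts under enumeration).
Clusters are contiguous voxels with p < 0.05 under 4-connectivity
(frequency or time neighbours, not diagonal — the conservative reading
of contiguity), formed separately by sign.  Family-wise control uses
the max-statistic convention: each permutation contributes its maximum
cluster size (permuted maps are thresholded at the per-voxel 95th
percentile of null |t|, the threshold consistent with the rank
p-value), and an observed cluster is significant when its size
strictly exceeds the 95th percentile of those maxima.  Measured
family-wise error over 200 null simulations at 34 channels sits inside
the 95% binomial band around 0.05.

**Learning analysis.**  Per-trial cluster power (mean z over the
cluster band × window) is correlated with the within-condition
presentation index (Pearson, with its parametric p — recorded as an
assumption), optionally pooling observations across channels with the
index repeated per channel (the report states which was used).  The
first and last 20 trials are additionally compared with an unpaired
label-shuffling permutation test on the group-mean difference.

## Canonical response parameterization (CRP)

Single-pulse evoked trials are high-pass filtered (1 Hz, zero-phase
Butterworth), epoched −0.5…+2.0 s around the pulse, common-average
rereferenced over all channels except the stimulated pair, declared
exclusions and bad channels, and baseline-corrected by each trial's
mean over −200…−20 ms.

CRP then asks whether a reproducible response shape exists, over what
duration, and with what per-trial weight.  For each candidate duration
t (10 ms steps, 20 ms–1.5 s, bracketing typical cortico-subcortical
responses), all ordered trial pairs contribute the semi-normalized
projection x_i·x_j/‖x_j‖ over [0, t]; the response duration τ
maximizes the one-sample t-statistic of those projections (ties take
the largest duration, so noiseless rank-one input — where the profile
is flat — reports the full support).  The canonical shape is the
first singular vector of the trial matrix restricted to [0, τ],
sign-aligned to a positive mean projection and normalized so
∫s²dt = 1 (units 1/√s); weights α_k = ∫x_k·s dt therefore carry
μV·√s, their mean is the reported magnitude (a metric not biased
against longer-lasting responses, unlike RMS), and
SNR = mean_k(α_k²/∫residual_k²dt) — the explained-to-residual power
ratio, recorded as this pipeline's definition since no closed form is
standard.  The first 10 ms post-stimulus are blanked against
stimulation artifact (configurable; deflections of interest begin
tens of ms later).  Negative weights are retained — the magnitude is a
mean of signed weights with the sign convention fixed by the shape
alignment.

**Significance.**  The pooled pairwise t-test is anticonservative:
pairs share trials, and maximizing the t-profile over durations
selects on the same noise (measured false-positive rate ≈ 0.6 under a
pure-noise null).  The package therefore computes the p-value by a
split-half cross-projection test: duration and shape are re-estimated
on the even-indexed trials alone, the held-out odd-indexed trials are
projected onto that shape, and a one-sided one-sample t-test asks
whether those projections exceed zero.  The held-out projections are
independent of the selection, so the test is exactly calibrated under
the null (measured 6% at α = 0.05) while power at the default planted
response remains 100%.  The reported τ, shape, weights and SNR still
use all trials.

**Scale and unit coherence.**  Multiplying all trials by c > 0 scales
α and the magnitude by exactly c and leaves τ, the shape, and the SNR
unchanged (asserted to 1e-12).  On rank-one input the fit coincides
with a brute-force common-waveform least-squares solution.

## Tractography-derived connectivity

**Connectivity index.**  CI = log(waytotal) / log(n_samples × Vseed),
with 5,000 streamline samples per seed voxel by default; natural
logarithm (the ratio is base-invariant).  CI(1) = 0, CI at full
saturation = 1, strictly increasing in waytotal and decreasing in
Vseed.  waytotal = 0 yields a missing value with a warning.
"Normalized streamline count" is defined here as
waytotal/(n_samples × Vseed), the reaching fraction — scale-free
across seed sizes; the normalization is this pipeline's recorded
convention.

**Segmentation.**  Per-subject maps are averaged voxelwise (optionally
weighted), and the seed structure is split by 1-D k-means (k = 2,
10 restarts) on the scalar streamline probabilities — no spatial
features, so the parcellation is free of external spatial constraints.
The hotspot is the higher-mean cluster.  A between/within
variance-ratio floor (default 2) operationalizes the documented
failure mode on near-uniform maps: below it, the result reports
`converged = False` and no hotspot.  Segmentation is invariant to
affine rescalings of the probabilities.

**Cohort battery.**  Per metric: Tukey outlier removal within group
(fences at quartiles ± 1.5·IQR, type-7 linear-interpolation quartiles
— the convention is recorded in every report), Shapiro–Wilk normality
gate per group at α = 0.05, then a two-sided Student's t-test, or
Mann–Whitney U when normality is rejected in either group.  Fisher-z
rsFC values (|r| clipped at 1 − 1e−7 before atanh) enter the battery
as metrics.  Multiple-comparison correction across metrics is
deliberately not applied, mirroring per-metric clinical reporting;
this is a documented scope decision.  The multivariate logistic model
uses backward elimination: from the full candidate set, repeatedly
drop the variable whose removal most reduces the AIC until no removal
reduces it (the AIC path is non-increasing by construction).
Predictors that perfectly separate the outcome are flagged and removed
before fitting; fits use binomial-GLM IRLS, which tolerates the
near-singular Hessians transient quasi-separation produces during the
search.  VIF_j = 1/(1−R²_j) is reported for the retained set.

## Synthetic data: what it emulates, and what it does not

* **Task LFP** — 1/f^1.5 coloured Gaussian background (β and the
  20 μV scale chosen as typical of field potentials), Hann-windowed
  4–6 Hz bursts of random phase and carrier in the effect condition
  during 0–1 s post-cue, trial orders randomized and interleaved,
  40 + 40 trials by default.  `effect_z` is defined as the planted
  z-score elevation the analysis chain measures; the generator's
  amplitude constant was calibrated once against that definition
  (measured elevation 0.52/1.03/2.04 at effect_z 0.5/1/2, linear as
  intended).  The learning trend multiplies burst amplitude by
  (1 + 0.015 × trial index) — amplitude scaling is the simplest
  mechanism producing the linear power-by-trial correlation the
  analysis targets.  Injected artifacts are 50 ms biphasic transients
  at 8–12× the background sd: guaranteed to trip the ±4·sd rule,
  local in time.  Not emulated: epileptiform activity, non-stationary
  baselines, volume-conduction correlations between channels (channels
  are independent, which the paired cluster test treats as its
  exchangeability assumption anyway).
* **Evoked trials** — trials are α_k·s(t) + white noise with
  α_k ~ N(45, 5) μV·√s.  The shape is a sum of two exponentially
  decaying sinusoids (sharp ~12 Hz deflection, slow return component)
  truncated at 0.3 s with a short cosine taper.  The slow component
  (0.83 Hz, τ = 0.6 s) keeps coherent amplitude up to the endpoint:
  a response that fades smoothly into noise has no identifiable
  duration for *any* similarity-based estimator, so the generator's
  nominal duration is kept estimable by design.  noise_sd = 60 μV
  puts the explained-to-residual SNR near 2, the regime of clinically
  reported single-electrode values.  Not emulated: stimulation
  artifact waveforms, line noise, latency jitter.
* **Streamline maps** — an ellipsoidal "hippocampus" seed mask with a
  contiguous high-probability pole (p_hot = 0.8 vs p_bg = 0.1,
  optional Gaussian noise, clipped to [0, 1]); per-voxel waytotals are
  probability × 5,000 rounded.  Not emulated: spatially correlated
  tractography noise, distance effects, partial-volume boundaries.
* **Cohorts** — 17 + 17 subjects (the clinical group sizes), Gaussian
  connectivity metrics with a planted group shift on designated
  metrics in within-group-sd units, plausible covariate distributions
  (age 26 ± 5.6, binge frequency 2.7 ± 1.4/week, screening-scale
  scores), optional Tukey-detectable outlier injection.  Covariates
  are mutually independent; real behavioural covariates correlate,
  so selection behaviour on real data will differ.

Passing tests on these generators demonstrate that the statistics are
calibrated and that planted structure of realistic size is recovered;
they do not certify performance against physiological confounds the
generators exclude (epileptiform transients, correlated noise fields,
non-Gaussian metric distributions).

## Numerical choices and scaling

Simulation studies run at reduced problem sizes chosen so the full
suite executes on one CPU in minutes: 125 Hz task recordings
(effect studies use 34 channels — a realistic hippocampal electrode
count for a multi-subject iEEG pool — with 8–20 trials per
condition), 200-permutation nulls with 200 repetitions for error-rate
calibration, 30-frequency wavelet grids, 100-run learning studies at
4 channels, 50-run CRP studies at 49 trials and 500 Hz, 500 null
cohorts.  The calibration properties being tested are invariant to
these scalings.  All randomness flows from named seeds
(`numpy.random.default_rng`); generators are bit-reproducible given
(spec, seed), and the permutation engines accept explicit seeds.

Known limitations: the backward-elimination study shows that AIC-based
elimination at n = 34 with ~11 candidates retains spuriously
significant noise covariates in most runs (measured: the signal metric
is always retained, but all noise covariates are simultaneously
dropped in only ~6% of runs) — a faithful property of stepwise AIC
selection at this sample size, not a defect of the implementation;
single-subject CI values are deterministic transforms, so no
uncertainty is propagated; the EDF writer quantizes to 16 bits with
per-channel symmetric physical ranges (error ≤ max|x|/32767); and the
whole-recording normalization mode pools valid samples of epoched data
rather than literally the continuous recording.
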