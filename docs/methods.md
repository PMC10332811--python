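# Methods

## Release model and sweep rendering

The simulator is a deterministic two-variable depression–facilitation
model: a releasable-resource fraction `R` (depleted by each spike,
recovering exponentially with `tau_rec`) and a utilisation variable `u`
(resting value `U`, incremented multiplicatively at each spike, decaying
with `tau_facil`).  Spike *k* evokes a mean EPSP of `A·u_k·R_k` mV.  The
recursion in `stpkit.release` is the exact integral of the inter-spike
ODEs, which is why the validation suite can hold it to <1e-6 relative
error against independent `solve_ivp` integration.  This is the minimal
structure that reproduces both phenotypes of interest: high `U` with slow
resource recovery gives depressing trains with slow recovery from
depression; low `U` with slow facilitation decay gives facilitating
trains.  It deliberately omits calcium dynamics, multiple vesicle pools
and postsynaptic receptor saturation.

Rendering (`stpkit.sweeps`) places a fixed ~2 ms triangular-exponential
presynaptic spike template (100 mV, overshooting 0 mV) at each stimulus
time — only its peak time is consumed downstream — and adds
difference-of-exponential EPSPs (`tau_rise` < `tau_decay`, normalised so
the waveform peak equals the requested amplitude) at spike peak +
`onset_delay`.  Trial-to-trial variability has two sources: per-pulse
Bernoulli transmission failures (probability `p_fail`, trace left flat)
and white Gaussian voltage noise of standard deviation `noise_sd` added to
every postsynaptic sample.  Noise is modelled on the trace rather than on
the EPSP amplitude so that averaging over sweeps shows the 1/√n baseline
behaviour of real recordings.  Default sampling rate is 20 kHz.

Cohort defaults (`stpkit.cohorts`) encode the study conditions: 8
induction + 4 recovery pulses at 10/20/50/100 Hz, recovery delays
{62.5, 125, 250, 500, 1000, 2000, 4000} ms at 50 Hz and a fixed 250 ms
otherwise, 15 s between sweeps.  Depressing connections draw
U ∈ [0.35, 0.7], tau_rec ∈ [0.3, 0.8] s, tau_facil ∈ [5, 50] ms and
log-uniform efficacies 0.8–8 mV; facilitating connections draw
U ∈ [0.05, 0.15], tau_rec ∈ [20, 100] ms, tau_facil ∈ [0.3, 0.8] s and
0.5–3 mV — the amplitude asymmetry mirrors the larger initial EPSPs of
depressing (PVALB-targeting) connections.  Trace noise defaults to 5% of
the efficacy.

## EPSP extraction

Presynaptic QC replaces manual inspection with an automated rule: a pulse
passes when, within 5 ms of its stimulus, the presynaptic trace reaches
dV/dt ≥ 20 V/s and an absolute peak ≥ 0 mV (all three thresholds
configurable).  Postsynaptic segments (5 ms baseline to ~min(50 ms, 95% of
the inter-spike interval)) are aligned to presynaptic spike peaks,
baseline-subtracted, and averaged pointwise over QC-passing sweeps with
transmission failures *included*, so mean amplitudes reflect release
probability.

Measurement conventions: traces are smoothed with a causal 1 ms boxcar
(suppresses the positive bias of picking the maximum of a noisy window
without shifting onsets early); onset is the first crossing of baseline +
2×baseline-SD sustained for 0.5 ms; amplitude is peak minus the 5 ms
pre-pulse baseline; rise time spans the 20–80% amplitude levels
(configurable to 10–90%); decay τ is a single-exponential fit starting
where the trace first falls below 95% of peak (skipping the mixed
rise/decay region), capped at 50 ms, reported NaN and flagged when the fit
fails.  Kinetics are taken from the first pulse, whose fit window is
clean.  Polysynaptic exclusion removes connections with first-EPSP onset
delay above 4 ms (no number exists in the literature for this cutoff; it
is configurable and the removal count is logged).

Under the cohort conditions (200 connections, amplitudes 0.2–5 mV, trace
noise up to 0.3 mV, 10 sweeps, 20 Hz) the pipeline recovers first-EPSP
amplitudes with ~1% median error and decay τ with ~2–3% median error.
Peak-minus-local-baseline amplitudes of *later* pulses in fast trains
carry a systematic droop error from the preceding EPSP's decay — a few
percent at 20 Hz with τ_decay ≈ 20 ms, but substantial at 50 Hz where the
inter-spike interval matches the decay constant (measured PPR can sit
0.1–0.2 below the generative ratio).  The bias is shared by depressing and
facilitating connections and preserves their ordering around PPR = 1, so
dynamics calls are unaffected; absolute train ratios at high frequency
should be read as measurement-convention quantities, not model parameters.
No deconvolution is attempted.

## STP metrics

All ratios are oriented later/first, so facilitation ⇔ ratio > 1; a ratio
of exactly 1 is called depressing, making reported facilitation fractions
conservative.  The dynamics call uses PPR by default (the determinant
metric at 50 Hz) and can be switched to the 1:8 or 1:6–8 ratio.  The
"early recovery" scalar is the 250 ms-delay normalised 9th-pulse
amplitude.  Heatmap rows are sorted by raw first-pulse amplitude
descending with ties broken by connection id; normalised trains make every
metric scale-invariant, which the property tests assert.

## Subclass classifier

Harmonization first: for every feature, a one-way ANOVA of feature ~
recording protocol on non-missing values; eta² = SS_between/SS_total;
features with eta² strictly above 0.05 are excluded.  This is computed
once on the combined reference + query table before any fitting —
mirroring the pre-alignment order of the original workflow — and is a
known source of mild optimism in cross-validated scores.  The classifier
is robust standardisation (median/IQR; zero-IQR features dropped with a
warning) → kNN imputation (k = 5, distances in scaled retained-feature
space) → two-class LDA.  PVALB probabilities are calibrated with isotonic
regression on the full reference (a sigmoid alternative sits behind a
flag); calibration is monotone, so probability rankings are preserved.
Probabilities in [0.4, 0.6] (inclusive) are labelled *uncertain*, higher
PVALB, lower non-PVALB.  Cross-validation is stratified 5-fold with a
fixed seed, folds reduced with a warning when a class is smaller than the
fold count; PVALB is the positive class for FPR/FNR.  The model
serialises to JSON with every learned parameter explicit (scaler
center/scale, imputer training matrix, LDA coefficients, isotonic
knots) — no binary pickles.  The 2-D UMAP embedding is seeded and used
for visualisation only, never for classification.

The synthetic feature populations are per-class multivariate Gaussians
over 15 named intrinsic features, with class separation concentrated on
the fast-spiking-phenotype features (spike height, sag, upstroke
adaptation, membrane τ, f-I slope, spike width), a protocol shift added to
a named feature subset for "patch-seq" cells, and completely-at-random
missingness.  Real feature distributions are heavier-tailed and the
missingness of real recordings is not random (spike features are missing
exactly when no suprathreshold sweep exists), so passing label-recovery
tests demonstrates the pipeline's mechanics, not its field accuracy.

## Intrinsic feature extraction

From long-square sweeps: input resistance as the OLS slope of steady-state
deflection vs current over subthreshold sweeps (mV/pA → MΩ); membrane τ by
exponential fit of the step-onset charging curve; sag = (peak − steady
state)/peak deflection on the most hyperpolarising sweep; rheobase as the
smallest tested current evoking a spike; f-I slope by OLS of firing rate
(1/mean ISI when ≥2 spikes) vs current; adaptation index as the mean
normalised ISI increment; single-spike features on the first spike at
rheobase with threshold at the dV/dt = 20 V/s crossing found by walking
back from the maximum-upstroke point; adaptation ratios as spike-3 /
spike-1 feature ratios.  Chirp impedance is |FFT(V)/FFT(I)| over the
stimulus band, box-smoothed, summarised by peak frequency and
peak-to-lowest-frequency ratio.  The simulated cells behind the ground
truth are phenomenological (RC membrane with a slow sag relaxation,
rate-model spike times, stereotyped spike waveforms, resonance from a
linear slow-feedback conductance) — sufficient to validate the
measurements, not biophysical models.

## mFISH quantification

Background: per channel, the histogram of non-cellular voxels
(Freedman–Diaconis bin width, 5-bin boxcar smoothing) is read on its upper
side; HWHM is the distance from the median to the interpolated upper
half-maximum crossing of the mode; threshold = median + 3×HWHM (for
Gaussian background this is µ + 3σ√(2 ln 2), which the tests verify).
Lipofuscin: voxels above threshold in *all* HCR channels, dilated twice
with a 6-connected radius-1 structuring element in 3-D (a per-plane 2-D
variant is available; the original's choice is not recorded).
Quantification: over cell voxels outside the lipofuscin mask,
Σ max(I − threshold, 0), divided by the full cell-mask volume including
masked voxels (a flag switches to summing raw supra-threshold intensity).
Cells fully inside the mask report zero with a flag.  Depth profiles
regress per-cell mean expression on z-centroid.

## Statistics

Rank-sum: exact p (via the Mann–Whitney U distribution) when both samples
have ≤12 observations and no ties, otherwise the tie-corrected normal
approximation; two-sided by default.  FDR: Benjamini–Hochberg step-up with
cumulative-minimum monotonicity.  KS: asymptotic two-sample test.
Regression: OLS with a t-test on the slope, requiring n ≥ 3 and var(x) >
0.  The repeated-measures design (e.g. preparation × recovery delay) uses
a mixed-design ANOVA with listwise deletion of incomplete subjects and no
sphericity correction by default (Greenhouse–Geisser epsilon is reported
by the backend when wanted); each between-group needs ≥2 complete
subjects.  All are verified against enumeration or closed-form oracles in
the test suite, and the mixed ANOVA against a 400-replicate null
simulation holding the type-I rate at the nominal 5%.

## Problem sizes and determinism

Validation runs use 100 parameter draws for the ODE cross-check, 200
rendered connections for EPSP recovery, 100 connections for dynamics-call
accuracy, 400 reference cells (plus a 2000-cell permutation null) for the
classifier, 100 harmonization replicates at 300 cells per class, one
16×128×128 three-channel volume with 6 planted granules and 12 spots, and
400 ANOVA null simulations — sizes chosen so the whole harness completes
in about a minute while keeping Monte-Carlo error well inside every
acceptance margin.  Every generator and every stochastic procedure takes
an explicit seed; fixed seeds give bit-identical sweeps, volumes,
embeddings and cross-validation splits.

## Known limitations

The release model is deterministic at the level of mean amplitudes;
quantal variability beyond all-or-none failures is not modelled, and no
mechanistic model is fitted to recovery curves.  IPSPs (−55 mV holding)
and voltage-clamp screening are out of scope.  The NWB reader is a stub
pending the deposit's NWB release; sweeps travel in the package's own
HDF5/CSV layout.  Harmonization-before-CV leaks a small amount of query
information into feature selection, as noted above.  Synthetic-data
results bound implementation correctness only — transfer to real
recordings depends on how well the generators' assumptions (white noise,
stationary kinetics, Gaussian feature clouds, spherical lipofuscin) hold.
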