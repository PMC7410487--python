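# Methods

This note documents the models, parameter choices, and numerical decisions
behind `modenc`, and what the synthetic ground-truth mode does and does not
establish about real data.

## Auditory front end

**Early stage.** The cochlear filterbank is 128 zero-phase bandpass filters
with Gaussian magnitude on a log2-frequency axis, centre frequencies
log-spaced over 180–7040 Hz (~24 channels/octave).  The Gaussian width is set
so the 10 dB bandwidth satisfies Q10dB = 3: solving
`2^h − 2^−h = 1/Q10` for the half-width h in octaves and converting to the
Gaussian sigma gives σ ≈ 0.158 oct.  The hair-cell stage is a temporal first
difference (highpass) followed by a one-pole lowpass at 4 kHz; the midbrain
stage is an across-frequency first difference (sharpening frequency
selectivity), half-wave rectification, and a one-pole leaky integrator with
τ = 8 ms.  Frames are sampled every 8 ms (125 Hz frame rate), comfortably
above the Nyquist rate for the highest modulation filter (32 Hz).  All stages
before rectification are linear and rectification commutes with positive
scaling, so the spectrogram — and every modulation-energy value — scales
linearly with waveform amplitude (tested at rtol 1e-6).

One consequence of the across-frequency derivative: a pure tone's spatial
profile peaks on the rising flank of the excitation pattern, about one filter
sigma (≈4 channels, 0.16 oct) below the tone's channel.  The tone-probe test
asserts that bound rather than exact channel alignment.

**Cortical stage.** Modulation content is measured with directional 2-D
filters: the spectrogram's 2-D FFT is windowed to a single quadrant —
Gaussian magnitude in log2 of temporal frequency (centre ω, σ = 0.5 oct) times
Gaussian magnitude in log2 of spectral frequency (centre Ω, σ = 0.5 oct),
analytic in both axes — and inverse-transformed; the complex magnitude is the
phase-invariant modulation envelope.  Same-sign quadrants capture downward
sweeps, opposite-sign quadrants upward sweeps; energies are averaged over the
two directions, over time, and pooled along the tonotopic axis into bands
whose edges are geometric midpoints between the grid's centre frequencies.

The tonotopic axis spans only ~5.3 octaves over 128 channels, so the raw
spectral FFT samples modulation every ~0.19 cyc/oct — too coarse to separate
the lowest scale filters (0.3 vs 0.4 cyc/oct).  The axis is therefore
zero-padded fourfold before the 2-D FFT, which samples the identical spectral
transform at ~0.047 cyc/oct without altering the signal content.  With this
choice the filterbank recovers the generating bin of a moving ripple for
every rate×scale pair of both grids (the package's primary validation; the
filter transfer functions are approximations validated by this recovery, not
by matching any particular legacy implementation bit-for-bit).

**Grids.** Encoding: ω ∈ {1, 2, 4, 8, 16, 32} Hz, Ω ∈ {0.3, 0.4, 0.8, 1.3,
2.3, 4} cyc/oct, f ∈ {232…5746} Hz (8 bands) → 288 features.  ROI decoding:
ω ∈ {1, 2.4, 5.7, 13.5, 32}, Ω ∈ {0.25, 0.5, 1, 2, 4}, f ∈ {277…5213} → 125.
Features are linearized rate-fastest, then scale, then frequency.

**HRF.** Double gamma sampled at the TR (947 ms): response gamma with mode
4 s, undershoot gamma with mode 12 s, unit dispersions, undershoot weight
1/6, kernel normalized to unit peak and truncated at 32 s.  Convolution is
causal and per run; the tail is truncated so run lengths are preserved and
nothing bleeds across run boundaries.

## Encoding and decoding

Ridge solutions are computed in the rotated (SVD) form, which is numerically
stable and mathematically identical to both the primal and the kernel (dual)
solutions (asserted to 1e-8 in tests).  GCV uses
`N·RSS(λ) / (N − edf(λ))²` with `edf = Σ d_i²/(d_i²+λ)` (+1 when an
unpenalized intercept is present); the selected λ is the grid argmin per
voxel/feature over 25 log-spaced values 10⁻⁶…10⁶.  Degenerate designs are
handled by the λ floor of the grid.

Standardization is always column-wise; test partitions are standardized with
training-partition statistics by default (leakage-safe; standardizing the
test partition by its own statistics is available as an option).
Zero-variance columns become all-zero and are recorded in the returned
statistics.  Identification ranks use average ranks on ties (ties are
measure-zero for continuous correlations); constant rows are excluded from
identification and logged.  Best-feature argmax ties resolve to the lowest
axis value.  Group best-feature maps are voxel-wise medians; map correlations
are computed on log2-scaled axis values.

Cross-validation folds hold out consecutive disjoint run groups
({1,2},{3,4},{5,6},{7,8} for eight runs and four folds); fold assignment is a
deterministic function of the run labels.  Per-voxel coefficient profiles are
averaged across folds; decoding predictions are concatenated across folds so
each sound is predicted exactly once (asserted).

## Permutation null for reconstruction accuracies

Surrogate predictors preserve each feature's amplitude spectrum: the phase
angles of the positive-frequency FFT bins are randomly permuted among
themselves (DC and Nyquist untouched, Hermitian symmetry enforced), per run,
*before* HRF convolution.  Decoders are refit for every permutation by
default (more conservative; reusing the observed decoders and scrambling only
the comparison features is available).  The refit is cheap because the
response SVD per fold is independent of the predictors and computed once.
Per feature: empirical chance level = null mean; one-sided add-one p-value
`(b+1)/(n_perm+1)` (guaranteeing p > 0 and super-uniformity under the null);
z = (r − null mean)/null SD, flagged undefined when the null SD is zero.

## Selectivity and group inference

SI as defined above, ties to the first bin, flagged missing when
max + mean(rest) = 0.  Profile variance uses the n−1 divisor.  Group tests
are Monte-Carlo label permutations (default 10,000) of the mean difference,
two-sided by |difference| unless a directional hypothesis is configured, with
pooled-SD Cohen's d.  Regression coefficient p-values use the Freedman–Lane
scheme (permute reduced-model residuals, re-fit the full model, compare |t|),
a standard choice for covariate-adjusted permutation tests; Cook's distance
is flagged at 4/n by default (configurable).  The outlier rule used for
descriptive trimming removes values beyond grand mean ± 2 SD of the pooled
sample.

**Power.** The design power simulation draws Gaussian groups differing by d
pooled SDs and runs the permutation test per experiment (vectorized; one
shared permutation set across experiments, which leaves each experiment's
Monte-Carlo p-value valid).  For n = 27/group, d = 0.75, α = 0.05, the
two-sided simulated power is ≈ 0.77 (noncentral-t closed form 0.772); the
one-sided figure is ≈ 0.86.  A nominal "80%" for this design is consistent
with either reading depending on sidedness, which is why both are computed
and reported; the package default is two-sided.

## Synthetic ground truth

`make_cohort` plants per-voxel preferred features and Gaussian tuning:
`C_true` columns are separable Gaussian bumps in grid-index coordinates,
normalized to unit L2 norm and scaled by gain, so gain/noise_sd directly sets
per-voxel SNR.  Defaults: gain 1, noise_sd 1 (moderate, sub-unity
single-voxel SNR typical of BOLD), young bandwidth 1.0 and old bandwidth 2.0
grid units — bandwidth is the only group difference.  Responses are
`Y = S C_true + ε` with i.i.d. Gaussian ε: the generative law matches the
encoding model's assumption by construction.  This is an explicit artifact
choice — the original analysis only *fits* a linear model, it does not claim
one generated the data — and it is the simplest parameterization in which
"tuning bandwidth" maps monotonically onto SI.

Preferred features tile the grid by default (every bin is some voxel's
preference).  For selectivity-recovery studies the preferred-rate
distribution is instead concentrated on the mid-grid rate bins
(`rate_focus_weights`), emulating the cortical over-representation of
intermediate temporal rates; with uniform tiling the marginal accuracy
profile is flat and SI is driven by sampling noise, which is not the regime
the selectivity comparison addresses.

`surrogate_feature_matrix` provides AR(1) log-normal modulation energies as a
desk-scale stand-in for filterbank output when only the
encoding/decoding/statistics machinery is under study; it is labelled
synthetic and is not a model of natural-sound statistics.

**Problem sizes.** Unit tests use 4 runs × 40 snippets with 60–300 voxels;
the recovery suite uses 8 runs × 60 snippets, the 125-cell grid, and
10 subjects/group × 500 voxels; filterbank validation uses 2 s ripples.
These sizes were chosen so the full analysis logic (fourfold CV, GCV, nulls,
group tests) runs unchanged while each suite completes in seconds to a
couple of minutes.

**What passing recovery tests do and do not show.** They show the estimators
are consistent with their own generative assumptions: correct best-feature
recovery without noise, calibrated nulls for untuned voxels, SI monotone in
planted bandwidth, and a 2× bandwidth group detected at conventional
significance.  They do not show that real BOLD responses are linear in
modulation energy, that real noise is i.i.d. Gaussian (no temporal
autocorrelation, spatial correlation, motion, or physiological structure is
simulated), or that real tuning is separable or Gaussian.  Scanner physics,
preprocessing, and cortical surface geometry are out of scope; real data
enter only through `ingest_real_data` (masked 4-D NIfTI, preprocessing
assumed done upstream).

## Interfaces and reproducibility

All randomness flows from one master seed through named per-stage
substreams.  `run_study` writes tidy TSV tables (identification, selectivity,
best-feature maps, reconstruction accuracies, group tests, cohort ground
truth) plus a JSON manifest with the config, stage seeds, library versions,
and SHA-256 checksums; a config + seed reproduces every table byte-for-byte
on one platform.  The CLI exposes `simulate`, `features`, `power`, and
`run-all`; stage-wise reruns are served by the library functions themselves,
since every intermediate is cheap to regenerate from the config seed.  WAV
I/O uses float PCM via `scipy.io.wavfile`.

## Known limitations

- The cochlear/cortical filter shapes are principled approximations
  (Gaussian on log axes); absolute energy units are arbitrary, so analyses
  use only relative/standardized quantities.
- Rate filters near the snippet length (1 Hz vs 0.947 s snippets) rely on a
  single FFT bin; filterbank validation therefore uses 2 s stimuli.
- The permutation-power simulation shares one permutation set across
  simulated experiments (per-experiment validity, slight dependence across
  experiments).
- `fit_decoders` assumes voxel count below the training sample size for the
  GCV trace to be meaningful; ROI-scale analyses satisfy this by design.
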