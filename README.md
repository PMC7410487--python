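# modenc

Spectro-temporal modulation encoding and decoding analysis of auditory-cortex
fMRI responses to continuous natural-like sounds — with a fully synthetic
ground-truth mode, so that every stage of the analysis can be verified by
parameter recovery at desk scale.

## The problem

How selectively does auditory cortex represent the temporal and spectral
modulations of natural sounds, and how does that tuning change — for example,
broaden with age?  The analysis chain implemented here answers this with
linear encoding and decoding models between a biologically motivated sound
representation and voxel-wise BOLD responses:

1. **Auditory model.** Sounds are cut into TR-length snippets (947 ms) and
   passed through a two-stage model of subcortical and cortical auditory
   processing: a 128-channel constant-Q cochlear filterbank (Q10dB = 3,
   180–7040 Hz), hair-cell and midbrain stages, then a bank of directional
   2-D modulation filters jointly tuned to temporal rate ω (Hz) and spectral
   scale Ω (cyc/oct).  Time-averaged modulation energy pooled into tonotopic
   bands gives each snippet a feature vector on a (ω, Ω, f) grid — 6×6×8 = 288
   features for voxel-wise encoding, 5×5×5 = 125 for ROI decoding.  Feature
   time courses are convolved with a double-gamma HRF peaking at 4 s.

2. **Encoding (per voxel).** `Y_i = S C_i + n`, both sides z-scored (no
   intercept), solved by ridge regression; the penalty λ is selected per voxel
   by generalized cross-validation over 25 log-spaced values in 10⁻⁶…10⁶.
   Model quality is the *sound-identification score*: the predicted activity
   pattern of each held-out sound is correlated with every measured pattern and
   the rank of the match is normalized, `m_s = 1 − (rank−1)/(N_test−1)`
   (1 = correct identification, chance = 0.5).  Marginal sums of the coefficient
   grid give the voxel's tMTF/sMTF/fTF; their argmax gives best-feature maps.

3. **Decoding (per feature).** `S_j = Y C_j + b_j 1 + n`: ridge with an
   unpenalized intercept, λ per feature by GCV.  Held-out predictions from a
   fourfold run-level cross-validation (2 of 8 runs out per fold) are
   concatenated; the Pearson r between predicted and actual feature is the
   *reconstruction accuracy*, and the 288 (125) accuracies form the region's
   multi-voxel MTF.  Significance comes from phase-scrambled surrogates of the
   predictor time courses (scrambled before HRF convolution, decoders refit),
   giving per-feature chance levels, permutation p-values, and z-scores.

4. **Selectivity statistics.** For each marginal accuracy profile r_1…r_k,

       SI = (max_j r_j − mean_{j≠jmax} r_j) / (max_j r_j + mean_{j≠jmax} r_j)

   (0 = flat tuning, 1 = one-hot), plus the profile variance across bins.
   Group comparisons use label-permutation tests on the mean difference
   (10,000 permutations) with Cohen's d; regressions get Freedman–Lane
   permutation p-values and Cook's-distance outlier flags; a power simulation
   covers the two-group permutation design.

The synthetic module generates moving-ripple stimuli (the canonical probe for
modulation filters) and voxel cohorts whose ground-truth tuning is a separable
Gaussian bump on the feature grid, with two "age groups" differing only in
tuning bandwidth — so broadened tuning, and its signature of reduced SI, can be
planted and recovered.

## Worked example

Recover a planted group difference in rate tuning (old group has 2× the
tuning bandwidth of the young group):

```python
import numpy as np
from modenc import (auditory, decoding, encoding, stats, synthetic)

s_raw = synthetic.surrogate_feature_matrix(8, 60, "roi_decoding", seed=11)
s_conv = auditory.hrf_convolve(s_raw)
s_std = encoding.zscore_feature_matrix(s_conv)

w = synthetic.rate_focus_weights(5)          # preferred rates peak mid-grid
cohort = synthetic.make_cohort(10, 10, 500, bandwidth_young=1.0,
                               bandwidth_old=2.0, noise_sd=1.0,
                               rate_weights=w, seed=5)
responses = synthetic.simulate_cohort(s_std, cohort, seed=99)

si = {"young": [], "old": []}
for subj in cohort.subjects:
    grid = decoding.run_decoding_cv(s_conv, responses[subj.subject_id])
    prof = decoding.marginal_accuracy_profiles(grid)
    si[subj.group_label].append(stats.selectivity_index(prof["rate"].values))

test = stats.group_permutation_test(np.array(si["young"]), np.array(si["old"]),
                                    n_perm=10_000, seed=1)
print(f"SI difference = {test.observed:.4f}, p = {test.p_value:.4f}")
```

Output:

```
SI difference = 0.0171, p = 0.0001
```

The young group's rate selectivity index exceeds the old group's by 0.017 and
the label-permutation test rejects exchangeability at its floor p-value —
the planted broadening of tuning is detected in the expected direction.

The same study runs from the shell:

```bash
modenc run-all --seed 3 --out results/     # full synthetic study, TSV tables
modenc power                               # power of the two-group design
```

`modenc power` prints, for the default design (27 per group, d = 0.75,
α = 0.05):

```
simulated power (two-sided): 0.775
noncentral-t power (two-sided): 0.772
```

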