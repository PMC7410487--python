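"""Multivariate feature reconstruction (decoding) and permutation nulls.

A linear decoder is trained for every modulation feature: the feature's
time course is modelled as a linear combination of the multi-voxel response
pattern plus an unpenalized bias, ``S_j = Y_train @ C_j + b_j`` — ridge
regression with the penalty chosen per feature by generalized
cross-validation on the same 25-value grid as the encoding model.

Held-out predictions from all cross-validation folds are concatenated so
that every sound is predicted exactly once; the Pearson correlation between
the concatenated prediction and the actual feature is the *reconstruction
accuracy* r_j.  Arranged on the (rate, scale, frequency) grid the 288 (or
125) accuracies form the region's multi-voxel modulation transfer function;
marginal profiles are *means* over the irrelevant dimensions (contrast with
the marginal sums of the encoding MTFs).

Significance comes from a surrogate null that preserves the temporal
autocorrelation of the stimulus features: each feature column is
phase-scrambled (FFT, permute the phase angles, inverse FFT) *before* HRF
convolution, the decoding analysis is re-run, and the observed accuracy is
compared with the null accuracies (add-one permutation p; z-scored against
the null mean and SD; the null mean is the empirical chance level).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .auditory import FeatureMatrix, GridAxes, HRFSpec, hrf_convolve
from .encoding import (
    VoxelResponseMatrix,
    coef_from_svd,
    cv_folds,
    default_lambda_grid,
    gcv_select,
    ridge_gcv,
    zscore_columns,
)


@dataclass
class DecoderSet:
    coef: np.ndarray                # (V, F)
    bias: np.ndarray                # (F,)
    lambdas: np.ndarray             # (F,)
    lambda_grid: np.ndarray
    gcv_curves: np.ndarray          # (L, F)
    residual_sd: np.ndarray         # (F,)
    fold: object = None


@dataclass
class NullDistribution:
    accuracies: np.ndarray          # (n_perm, F)
    n_perm: int
    seed: int
    scramble_mode: str = "phase"


@dataclass
class ReconstructionGrid:
    """Per-feature reconstruction accuracies on the modulation grid."""

    r: np.ndarray                   # (F,) Pearson accuracies, rate-fastest order
    axes: GridAxes
    predictions: np.ndarray | None = None    # (N, F) concatenated test predictions
    actual: np.ndarray | None = None         # (N, F) concatenated actual features
    r_chance: np.ndarray | None = None       # (F,) null means
    p: np.ndarray | None = None              # (F,) add-one permutation p
    z: np.ndarray | None = None              # (F,) null-z-scored accuracies
    null: NullDistribution | None = None

    def as_grid(self) -> np.ndarray:
        return self.axes.unflatten(self.r)


# --------------------------------------------------------------------------
# Decoder estimation and reconstruction
# --------------------------------------------------------------------------

def fit_decoders(Y_train: np.ndarray, S_train: np.ndarray,
                 lambda_grid: np.ndarray | None = None) -> DecoderSet:
    """Per-feature ridge decoders with unpenalized intercept, GCV penalty."""
    coef, bias, lambdas, gcv = ridge_gcv(Y_train, S_train, lambda_grid, intercept=True)
    resid = S_train - (Y_train @ coef + bias)
    return DecoderSet(
        coef=coef,
        bias=bias,
        lambdas=lambdas,
        lambda_grid=default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid),
        gcv_curves=gcv,
        residual_sd=resid.std(axis=0),
    )


def reconstruct_features(decoders: DecoderSet, Y_test: np.ndarray) -> np.ndarray:
    Y_test = np.asarray(Y_test, dtype=float)
    if Y_test.shape[1] != decoders.coef.shape[0]:
        raise ValueError(
            f"voxel count mismatch: decoders expect {decoders.coef.shape[0]}, got {Y_test.shape[1]}"
        )
    return Y_test @ decoders.coef + decoders.bias


def _pearson_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    denom = np.linalg.norm(ac, axis=0) * np.linalg.norm(bc, axis=0)
    denom = np.where(denom == 0, np.nan, denom)
    return np.sum(ac * bc, axis=0) / denom


def reconstruction_accuracy(predictions_by_fold: list[np.ndarray],
                            actual_by_fold: list[np.ndarray],
                            test_indices: list[np.ndarray],
                            n_sounds: int,
                            axes: GridAxes) -> ReconstructionGrid:
    """Concatenate fold predictions (each sound exactly once) and correlate.

    Raises if the folds do not tile the full sound set.
    """
    coverage = np.concatenate(test_indices)
    if len(coverage) != n_sounds or len(np.unique(coverage)) != n_sounds:
        raise ValueError("cross-validation folds must cover every sound exactly once")
    n_feat = axes.n_features
    pred = np.empty((n_sounds, n_feat))
    act = np.empty((n_sounds, n_feat))
    for p, a, idx in zip(predictions_by_fold, actual_by_fold, test_indices):
        pred[idx] = p
        act[idx] = a
    r = _pearson_columns(pred, act)
    return ReconstructionGrid(r=r, axes=axes, predictions=pred, actual=act)


# --------------------------------------------------------------------------
# Decoding cross-validation (with a reusable per-fold context so the
# permutation null can re-fit decoders without recomputing the response SVD)
# --------------------------------------------------------------------------

@dataclass
class _FoldContext:
    train: np.ndarray
    test: np.ndarray
    u: np.ndarray                   # SVD of the centred z-scored training responses
    d: np.ndarray
    vt: np.ndarray
    y_mean_c: np.ndarray            # column mean of the z-scored training responses
    y_test_z: np.ndarray            # z-scored test responses (training stats)


def prepare_decoding_context(Y: VoxelResponseMatrix, n_folds: int = 4) -> list[_FoldContext]:
    folds = cv_folds(Y.run_labels, n_folds)
    out = []
    for train, test in folds:
        y_tr, y_stats = zscore_columns(Y.values[train])
        y_te, _ = zscore_columns(Y.values[test], y_stats)
        mu = y_tr.mean(axis=0)
        u, d, vt = np.linalg.svd(y_tr - mu, full_matrices=False)
        out.append(_FoldContext(train, test, u, d, vt, mu, y_te))
    return out


def _decode_folds(contexts: list[_FoldContext], S: FeatureMatrix,
                  lambda_grid: np.ndarray, test_stats: str = "train"):
    """Fit per-feature decoders in every fold and predict the held-out sounds."""
    preds, actuals, test_idx = [], [], []
    for ctx in contexts:
        s_tr, s_stats = zscore_columns(S.values[ctx.train])
        s_te, _ = zscore_columns(
            S.values[ctx.test], s_stats if test_stats == "train" else None
        )
        s_mean = s_tr.mean(axis=0)
        tc = s_tr - s_mean
        utt = ctx.u.T @ tc
        best, _ = gcv_select(ctx.d, utt, np.sum(tc**2, axis=0),
                             len(ctx.train), lambda_grid, n_params_base=1.0)
        coef = coef_from_svd(ctx.vt, ctx.d, utt, lambda_grid, best)
        bias = s_mean - ctx.y_mean_c @ coef
        preds.append(ctx.y_test_z @ coef + bias)
        actuals.append(s_te)
        test_idx.append(ctx.test)
    return preds, actuals, test_idx


def run_decoding_cv(S: FeatureMatrix, Y: VoxelResponseMatrix, n_folds: int = 4,
                    lambda_grid: np.ndarray | None = None,
                    test_stats: str = "train") -> ReconstructionGrid:
    """Fourfold run-level decoding: fit, reconstruct, concatenate, correlate."""
    if not S.hrf_convolved:
        raise ValueError("feature matrix must be HRF-convolved before decoding")
    if S.n_sounds != Y.n_sounds:
        raise ValueError("feature and response matrices disagree on sound count")
    grid = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid, dtype=float)
    contexts = prepare_decoding_context(Y, n_folds)
    preds, actuals, test_idx = _decode_folds(contexts, S, grid, test_stats)
    return reconstruction_accuracy(preds, actuals, test_idx, S.n_sounds, S.axes)


# --------------------------------------------------------------------------
# Phase-scrambled surrogates and the permutation null
# --------------------------------------------------------------------------

def phase_scramble(series: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Surrogate with the identical amplitude spectrum and permuted phases.

    The phase angles of the positive-frequency FFT bins are randomly
    permuted among themselves (DC and, for even lengths, the Nyquist bin
    stay untouched); Hermitian symmetry keeps the output real.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("series must be 1-D with length >= 3")
    spec = np.fft.rfft(x)
    n_bins = spec.size
    # movable bins: positive frequencies excluding DC and the Nyquist bin
    hi = n_bins - 1 if x.size % 2 == 0 else n_bins
    idx = np.arange(1, hi)
    phases = np.angle(spec[idx])
    spec = spec.copy()
    spec[idx] = np.abs(spec[idx]) * np.exp(1j * phases[rng.permutation(len(idx))])
    return np.fft.irfft(spec, n=x.size)


def scramble_feature_matrix(S_raw: FeatureMatrix, rng: np.random.Generator) -> FeatureMatrix:
    """Phase-scramble every feature column, independently per run."""
    from dataclasses import replace

    if S_raw.hrf_convolved:
        raise ValueError("scrambling must happen before HRF convolution")
    vals = S_raw.values.copy()
    for run in np.unique(S_raw.run_labels):
        sel = np.flatnonzero(S_raw.run_labels == run)
        for j in range(vals.shape[1]):
            vals[sel, j] = phase_scramble(vals[sel, j], rng)
    return replace(S_raw, values=vals)


def permutation_null(S_raw: FeatureMatrix, Y: VoxelResponseMatrix,
                     hrf: HRFSpec | None = None, n_folds: int = 4,
                     n_perm: int = 1000, seed: int = 0,
                     lambda_grid: np.ndarray | None = None,
                     refit: bool = True) -> ReconstructionGrid:
    """Observed reconstruction grid plus its phase-scrambled null.

    ``S_raw`` is the feature matrix *before* HRF convolution.  Each
    permutation phase-scrambles every feature column (per run), convolves
    with the HRF, and re-runs the decoding analysis — with decoders refit
    per permutation (``refit=True``, default) or with the observed decoders
    reused and only the comparison features scrambled (``refit=False``).

    Attaches, per feature: the null distribution, the empirical chance
    level r_chance (null mean), the add-one one-sided permutation p
    ``(b + 1) / (n_perm + 1)`` for accuracy >= observed, and the z-score
    of the observed accuracy relative to the null.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if S_raw.hrf_convolved:
        raise ValueError("pass the pre-convolution feature matrix")
    hrf = hrf or HRFSpec()
    grid = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid, dtype=float)

    contexts = prepare_decoding_context(Y, n_folds)
    S_obs = hrf_convolve(S_raw, hrf)
    preds, actuals, test_idx = _decode_folds(contexts, S_obs, grid)
    observed = reconstruction_accuracy(preds, actuals, test_idx, S_raw.n_sounds, S_raw.axes)

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, S_raw.axes.n_features))
    for k in range(n_perm):
        s_perm = hrf_convolve(scramble_feature_matrix(S_raw, rng), hrf)
        if refit:
            p, a, ti = _decode_folds(contexts, s_perm, grid)
            null[k] = reconstruction_accuracy(p, a, ti, S_raw.n_sounds, S_raw.axes).r
        else:
            act = np.empty_like(observed.actual)
            for ctx in contexts:
                s_tr, s_stats = zscore_columns(s_perm.values[ctx.train])
                act[ctx.test], _ = zscore_columns(s_perm.values[ctx.test], s_stats)
            null[k] = _pearson_columns(observed.predictions, act)

    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    observed.null = NullDistribution(accuracies=null, n_perm=n_perm, seed=seed)
    observed.r_chance = mean
    observed.p = (np.sum(null >= observed.r[None, :], axis=0) + 1.0) / (n_perm + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        observed.z = np.where(sd > 0, (observed.r - mean) / sd, np.nan)
    return observed


def marginal_accuracy_profiles(grid: ReconstructionGrid):
    """Marginal accuracy profiles: means over the two irrelevant dimensions."""
    from .encoding import MarginalProfile

    g = grid.as_grid()
    ax = grid.axes
    vals = {
        "rate": g.mean(axis=(1, 2)),
        "scale": g.mean(axis=(0, 2)),
        "frequency": g.mean(axis=(0, 1)),
    }
    axis = {"rate": ax.rates, "scale": ax.scales, "frequency": ax.freqs}
    return {
        d: MarginalProfile(dimension=d, axis=axis[d], values=vals[d], aggregation="mean")
        for d in vals
    }
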