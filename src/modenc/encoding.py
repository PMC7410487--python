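"""Voxel-wise linear encoding models and their evaluation.

Each voxel's response is modelled as a linear transformation of the
modulation feature matrix, ``Y_i = S_train @ C_i + n``, with both sides
column-z-scored so no intercept is needed.  The solution is ridge
regression, computed in the rotated (SVD) form which is mathematically
identical to both the primal solve ``(S'S + lam I)^-1 S' Y`` and the kernel
(dual) solve ``S' (S S' + lam I)^-1 Y``; the regularizer is chosen per
voxel by generalized cross-validation (Golub-Heath-Wahba),

    GCV(lam) = N * RSS(lam) / tr(I - H(lam))**2,

over a fixed grid of 25 log-spaced values between 1e-6 and 1e6.

Model quality is summarized by a sound-identification analysis: the
predicted activity pattern of each held-out sound is correlated with every
measured pattern, the rank of the matching sound is normalized to [0, 1]
(1 = correct identification, chance = 0.5), and scores are averaged.

Marginal modulation transfer functions (tMTF, sMTF, fTF) are marginal
*sums* of the coefficient grid over the two irrelevant dimensions; a
voxel's best feature per dimension is the argmax of its marginal profile.
Everything runs inside a fourfold run-level cross-validation (two of eight
runs held out per fold), with coefficients averaged across folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .auditory import FeatureMatrix, GridAxes

LAMBDA_GRID_EXPONENTS = np.arange(-6.0, 6.0 + 0.25, 0.5)


def default_lambda_grid() -> np.ndarray:
    """25 log-spaced ridge penalties, 1e-6 ... 1e6, grain 10**0.5."""
    return 10.0 ** LAMBDA_GRID_EXPONENTS


@dataclass
class VoxelResponseMatrix:
    """Sounds x voxels response matrix with run labels."""

    values: np.ndarray
    run_labels: np.ndarray
    z_scored: bool = False
    values_z: np.ndarray | None = None   # convenience copy, globally z-scored

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.run_labels = np.asarray(self.run_labels)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.run_labels):
            raise ValueError("response matrix must be sounds x voxels with one run label per sound")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("response matrix contains non-finite values")

    @property
    def n_sounds(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


@dataclass
class EncodingModel:
    coef: np.ndarray                # (F, V)
    lambdas: np.ndarray             # (V,) selected penalty per voxel
    lambda_grid: np.ndarray         # (L,)
    gcv_curves: np.ndarray          # (L, V)
    residual_sd: np.ndarray         # (V,) training residual SD
    axes: GridAxes | None = None
    fold: object = None             # fold provenance


@dataclass
class IdentificationResult:
    scores: np.ndarray              # (N_test,) normalized-rank scores in [0, 1]
    ranks: np.ndarray               # (N_test,) rank of the matching sound
    n_test: int
    excluded: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def accuracy(self) -> float:
        return float(np.nanmean(self.scores))


@dataclass
class MarginalProfile:
    dimension: str                  # 'rate' | 'scale' | 'frequency'
    axis: np.ndarray
    values: np.ndarray
    aggregation: str                # 'sum' (encoding) | 'mean' (decoding)


@dataclass
class BestFeatureMap:
    """Per-voxel best value of each marginal profile dimension."""

    rate: np.ndarray
    scale: np.ndarray
    frequency: np.ndarray

    def dim(self, name: str) -> np.ndarray:
        return {"rate": self.rate, "scale": self.scale, "frequency": self.frequency}[name]


# --------------------------------------------------------------------------
# Standardization
# --------------------------------------------------------------------------

def zscore_columns(matrix: np.ndarray, reference_stats: dict | None = None):
    """Column z-scoring; optionally with externally supplied statistics.

    Passing training-partition statistics standardizes a test partition
    without leakage.  Zero-variance columns map to all zeros and are
    reported in the returned stats under ``'constant_columns'``.
    """
    m = np.asarray(matrix, dtype=float)
    if reference_stats is None:
        mean = m.mean(axis=0)
        sd = m.std(axis=0, ddof=0)
        const = np.flatnonzero(sd == 0)
        if const.size:
            warnings.warn(f"{const.size} zero-variance column(s) set to 0")
        stats = {"mean": mean, "sd": sd, "constant_columns": const, "source": "self"}
    else:
        stats = reference_stats
        mean, sd, const = stats["mean"], stats["sd"], stats["constant_columns"]
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (m - mean) / safe_sd
    z[:, const] = 0.0
    return z, stats


def zscore_feature_matrix(fm: FeatureMatrix, reference_stats: dict | None = None) -> FeatureMatrix:
    from dataclasses import replace

    z, stats = zscore_columns(fm.values, reference_stats)
    return replace(fm, values=z, z_scored=True, zscore_stats=stats)


# --------------------------------------------------------------------------
# Ridge with GCV (shared by encoding and decoding)
# --------------------------------------------------------------------------

def ridge_gcv(X: np.ndarray, T: np.ndarray, lambda_grid: np.ndarray | None = None,
              intercept: bool = False):
    """Ridge regression of every column of T on X, penalty chosen by GCV.

    Returns ``(coef, bias, lambdas, gcv_curves)`` with coef of shape
    (p, n_targets).  With ``intercept=True`` both sides are centred and the
    unpenalized bias absorbs the means (one extra effective parameter in
    the GCV trace).
    """
    X = np.asarray(X, dtype=float)
    T = np.asarray(T, dtype=float)
    if X.ndim != 2 or T.ndim != 2 or X.shape[0] != T.shape[0]:
        raise ValueError("X and T must be 2-D with matching row counts")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(T))):
        raise ValueError("non-finite values in regression inputs")
    grid = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid, dtype=float)

    n = X.shape[0]
    x_mean = X.mean(axis=0) if intercept else np.zeros(X.shape[1])
    t_mean = T.mean(axis=0) if intercept else np.zeros(T.shape[1])
    Xc = X - x_mean
    Tc = T - t_mean

    u, d, vt = np.linalg.svd(Xc, full_matrices=False)
    n_params_base = 1.0 if intercept else 0.0
    best, gcv = gcv_select(d, u.T @ Tc, np.sum(Tc**2, axis=0), n, grid, n_params_base)
    lambdas = grid[best]
    coef = coef_from_svd(vt, d, u.T @ Tc, grid, best)
    bias = t_mean - x_mean @ coef if intercept else np.zeros(T.shape[1])
    return coef, bias, lambdas, gcv


def gcv_select(d: np.ndarray, utt: np.ndarray, total: np.ndarray, n: int,
               grid: np.ndarray, n_params_base: float = 0.0):
    """GCV curves and per-target argmin from a precomputed SVD projection.

    ``d``: singular values of the (centred) design; ``utt = U.T @ T``;
    ``total``: per-target sum of squares.  Returns ``(best_idx, gcv)``.
    """
    d2 = d**2
    gcv = np.empty((len(grid), utt.shape[1]))
    for i, lam in enumerate(grid):
        f = d2 / (d2 + lam)
        rss = np.maximum(total - np.sum((2.0 * f - f**2)[:, None] * utt**2, axis=0), 0.0)
        edf = n_params_base + f.sum()
        gcv[i] = n * rss / (n - edf) ** 2
    return np.argmin(gcv, axis=0), gcv


def coef_from_svd(vt: np.ndarray, d: np.ndarray, utt: np.ndarray,
                  grid: np.ndarray, best: np.ndarray) -> np.ndarray:
    """Ridge coefficients for per-target penalties, from the design SVD."""
    d2 = d**2
    coef = np.empty((vt.shape[1], utt.shape[1]))
    for i in np.unique(best):
        sel = best == i
        shrink = d / (d2 + grid[i])
        coef[:, sel] = vt.T @ (shrink[:, None] * utt[:, sel])
    return coef


def fit_encoding(S_train: np.ndarray, Y_train: np.ndarray,
                 lambda_grid: np.ndarray | None = None,
                 axes: GridAxes | None = None) -> EncodingModel:
    """Per-voxel ridge encoding fit (no intercept; inputs must be z-scored)."""
    coef, _, lambdas, gcv = ridge_gcv(S_train, Y_train, lambda_grid, intercept=False)
    resid = Y_train - S_train @ coef
    return EncodingModel(
        coef=coef,
        lambdas=lambdas,
        lambda_grid=default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid),
        gcv_curves=gcv,
        residual_sd=resid.std(axis=0),
        axes=axes,
    )


def predict_responses(model: EncodingModel, S_test: np.ndarray) -> np.ndarray:
    S_test = np.asarray(S_test, dtype=float)
    if S_test.shape[1] != model.coef.shape[0]:
        raise ValueError(
            f"feature count mismatch: model has {model.coef.shape[0]}, got {S_test.shape[1]}"
        )
    return S_test @ model.coef


# --------------------------------------------------------------------------
# Sound identification
# --------------------------------------------------------------------------

def identification_scores(Y_pred: np.ndarray, Y_test: np.ndarray) -> IdentificationResult:
    """Normalized-rank sound identification.

    For each test sound, the predicted activity pattern is Pearson-correlated
    with every measured pattern (across voxels); the rank of the matching
    pattern (1 = most similar, average ranks on ties) maps to the score
    ``m = 1 - (rank - 1) / (N_test - 1)``.
    """
    P = np.asarray(Y_pred, dtype=float)
    M = np.asarray(Y_test, dtype=float)
    if P.shape != M.shape:
        raise ValueError("prediction and measurement must have identical shape")
    n = P.shape[0]
    if n < 2:
        raise ValueError("need at least two test sounds")

    def _row_norm(A):
        Ac = A - A.mean(axis=1, keepdims=True)
        norm = np.linalg.norm(Ac, axis=1, keepdims=True)
        bad = np.flatnonzero(norm.ravel() == 0)
        norm[norm == 0] = 1.0
        return Ac / norm, bad

    Pn, bad_p = _row_norm(P)
    Mn, bad_m = _row_norm(M)
    excluded = np.union1d(bad_p, bad_m)
    if excluded.size:
        warnings.warn(f"{excluded.size} constant row(s) excluded from identification")
    R = Pn @ Mn.T                                     # (N, N) correlations
    # rank of the matching correlation within each prediction's row; rank 1
    # = largest correlation, ties get average ranks
    ranks_full = rankdata(-R, axis=1, method="average")
    ranks = ranks_full[np.arange(n), np.arange(n)]
    scores = 1.0 - (ranks - 1.0) / (n - 1.0)
    scores[excluded] = np.nan
    return IdentificationResult(scores=scores, ranks=ranks, n_test=n, excluded=excluded)


# --------------------------------------------------------------------------
# Marginal MTFs and best-feature maps
# --------------------------------------------------------------------------

_DIMS = ("rate", "scale", "frequency")


def marginal_mtf(coef_vector: np.ndarray, axes: GridAxes) -> dict[str, MarginalProfile]:
    """tMTF / sMTF / fTF as marginal sums of one voxel's coefficient grid."""
    grid = axes.unflatten(np.asarray(coef_vector, dtype=float))
    sums = {
        "rate": grid.sum(axis=(1, 2)),
        "scale": grid.sum(axis=(0, 2)),
        "frequency": grid.sum(axis=(0, 1)),
    }
    ax = {"rate": axes.rates, "scale": axes.scales, "frequency": axes.freqs}
    return {
        d: MarginalProfile(dimension=d, axis=ax[d], values=sums[d], aggregation="sum")
        for d in _DIMS
    }


def best_feature_map(coef: np.ndarray, axes: GridAxes) -> BestFeatureMap:
    """Per-voxel best feature per dimension (argmax of the marginal profile).

    Ties resolve to the lowest axis value (np.argmax takes the first index).
    """
    coef = np.asarray(coef, dtype=float)
    if coef.ndim != 2 or coef.shape[0] != axes.n_features or coef.shape[1] < 1:
        raise ValueError("coefficients must be features x voxels with >= 1 voxel")
    grids = axes.unflatten(coef.T)                    # (V, nr, ns, nf)
    return BestFeatureMap(
        rate=axes.rates[np.argmax(grids.sum(axis=(2, 3)), axis=1)],
        scale=axes.scales[np.argmax(grids.sum(axis=(1, 3)), axis=1)],
        frequency=axes.freqs[np.argmax(grids.sum(axis=(1, 2)), axis=1)],
    )


def group_map(maps: list[BestFeatureMap]) -> BestFeatureMap:
    """Voxel-wise median of subject maps (subjects share voxel order)."""
    if not maps:
        raise ValueError("empty map list")
    return BestFeatureMap(
        rate=np.median([m.rate for m in maps], axis=0),
        scale=np.median([m.scale for m in maps], axis=0),
        frequency=np.median([m.frequency for m in maps], axis=0),
    )


def map_correlation(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Pearson correlation of two best-feature maps on log-scaled axis values."""
    a = np.log2(np.asarray(map_a, dtype=float))
    b = np.log2(np.asarray(map_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("maps must have equal length")
    return float(np.corrcoef(a, b)[0, 1])


# --------------------------------------------------------------------------
# Run-level cross-validation
# --------------------------------------------------------------------------

def cv_folds(run_labels: np.ndarray, n_folds: int = 4) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic run-level folds: consecutive disjoint run groups held out.

    With eight runs and four folds this is the 2-of-8 held-out scheme
    ({1,2}, {3,4}, {5,6}, {7,8}).  Returns (train_idx, test_idx) pairs.
    """
    runs = np.unique(run_labels)
    if len(runs) % n_folds != 0:
        raise ValueError(f"{len(runs)} runs not divisible into {n_folds} folds")
    per_fold = len(runs) // n_folds
    folds = []
    for k in range(n_folds):
        test_runs = runs[k * per_fold : (k + 1) * per_fold]
        test = np.flatnonzero(np.isin(run_labels, test_runs))
        train = np.flatnonzero(~np.isin(run_labels, test_runs))
        folds.append((train, test))
    return folds


@dataclass
class EncodingCVResult:
    model: EncodingModel                    # fold-averaged coefficients
    fold_models: list[EncodingModel]
    identification: list[IdentificationResult]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([r.accuracy for r in self.identification]))


def run_encoding_cv(
    S: FeatureMatrix,
    Y: VoxelResponseMatrix,
    n_folds: int = 4,
    lambda_grid: np.ndarray | None = None,
    test_stats: str = "train",
) -> EncodingCVResult:
    """Fourfold run-level encoding CV with per-fold identification.

    ``S`` must be HRF-convolved but *not* pre-z-scored: standardization
    happens per fold from training statistics (``test_stats='train'``, the
    leakage-safe default) or from the test partition itself
    (``test_stats='self'``).
    """
    if not S.hrf_convolved:
        raise ValueError("feature matrix must be HRF-convolved before encoding")
    if S.n_sounds != Y.n_sounds:
        raise ValueError("feature and response matrices disagree on sound count")
    if test_stats not in ("train", "self"):
        raise ValueError("test_stats must be 'train' or 'self'")
    folds = cv_folds(S.run_labels, n_folds)
    fold_models, ident = [], []
    for train, test in folds:
        s_tr, s_stats = zscore_columns(S.values[train])
        y_tr, y_stats = zscore_columns(Y.values[train])
        s_te, _ = zscore_columns(S.values[test], s_stats if test_stats == "train" else None)
        y_te, _ = zscore_columns(Y.values[test], y_stats if test_stats == "train" else None)
        model = fit_encoding(s_tr, y_tr, lambda_grid, axes=S.axes)
        model.fold = (train, test)
        fold_models.append(model)
        ident.append(identification_scores(predict_responses(model, s_te), y_te))
    avg = EncodingModel(
        coef=np.mean([m.coef for m in fold_models], axis=0),
        lambdas=np.median([m.lambdas for m in fold_models], axis=0),
        lambda_grid=fold_models[0].lambda_grid,
        gcv_curves=np.mean([m.gcv_curves for m in fold_models], axis=0),
        residual_sd=np.mean([m.residual_sd for m in fold_models], axis=0),
        axes=S.axes,
    )
    return EncodingCVResult(model=avg, fold_models=fold_models, identification=ident)
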