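"""Tuning-selectivity measures and group-level permutation inference.

The selectivity index of a marginal accuracy profile r_1..r_k is

    SI = (max_j r_j - mean_{j != jmax} r_j) / (max_j r_j + mean_{j != jmax} r_j),

0 for a flat profile and 1 for one-hot tuning (on non-negative profiles).
A simpler companion measure is the sample variance of the profile across
its bins ("rate variance" for the temporal-rate profile).

Group comparisons use Monte-Carlo label-permutation tests on the mean
difference (default 10,000 permutations, add-one p so p > 0), with Cohen's
d as the effect size.  Regression coefficients get Freedman-Lane
permutation p-values (permute reduced-model residuals), with Cook's
distance flagging influential observations.  A power simulation for the
two-sample permutation design is included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps


@dataclass
class SelectivityResult:
    si: dict                 # dimension -> SI (nan when degenerate)
    variance: dict           # dimension -> profile variance
    subject_id: str = ""
    group_label: str = ""


@dataclass
class GroupTestResult:
    observed: float
    p_value: float
    n_perm: int
    seed: int
    effect_size: float       # Cohen's d (nan when pooled SD is 0)
    sides: str


# --------------------------------------------------------------------------
# Selectivity
# --------------------------------------------------------------------------

def selectivity_index(profile: np.ndarray) -> float:
    """SI of a marginal profile; ties resolve to the first (lowest) bin."""
    r = np.asarray(profile, dtype=float)
    if r.ndim != 1 or r.size < 2:
        raise ValueError("profile must be 1-D with length >= 2")
    j = int(np.argmax(r))
    rest = np.mean(np.delete(r, j))
    denom = r[j] + rest
    if denom == 0:
        warnings.warn("degenerate profile (max + mean_rest = 0): SI undefined")
        return float("nan")
    return float((r[j] - rest) / denom)


def profile_variance(profile: np.ndarray) -> float:
    """Sample variance (n-1 divisor) of the profile across its bins."""
    r = np.asarray(profile, dtype=float)
    if r.size < 2:
        raise ValueError("profile must have length >= 2")
    return float(np.var(r, ddof=1))


def selectivity_result(profiles: dict, subject_id: str = "", group_label: str = "") -> SelectivityResult:
    """SI and variance for each marginal profile dimension."""
    return SelectivityResult(
        si={d: selectivity_index(p.values) for d, p in profiles.items()},
        variance={d: profile_variance(p.values) for d, p in profiles.items()},
        subject_id=subject_id,
        group_label=group_label,
    )


# --------------------------------------------------------------------------
# Effect sizes, correlations, outliers
# --------------------------------------------------------------------------

def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    na, nb = a.size, b.size
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if pooled == 0:
        warnings.warn("zero pooled SD: Cohen's d undefined")
        return float("nan")
    return float((a.mean() - b.mean()) / pooled)


def rank_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho (average ranks) and its asymptotic p-value."""
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def trim_outliers(values: np.ndarray, k_sd: float = 2.0):
    """Drop values beyond grand mean +- k*SD of the pooled sample.

    Returns ``(kept_values, removed_indices)``.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 values")
    mu, sd = v.mean(), v.std(ddof=1)
    removed = np.flatnonzero(np.abs(v - mu) > k_sd * sd)
    return np.delete(v, removed), removed


# --------------------------------------------------------------------------
# Permutation tests
# --------------------------------------------------------------------------

def group_permutation_test(values_a: np.ndarray, values_b: np.ndarray,
                           n_perm: int = 10_000, seed: int = 0,
                           sides: str = "two") -> GroupTestResult:
    """Monte-Carlo permutation test on the mean group difference.

    ``sides='two'`` compares |difference|; ``'greater'`` tests a > b.
    Add-one rule keeps p in (0, 1].
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if n_perm < 100:
        warnings.warn("n_perm < 100: permutation p-value will be very coarse")
    if sides not in ("two", "greater"):
        raise ValueError("sides must be 'two' or 'greater'")
    obs = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    na = a.size
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(pooled)
        null[k] = perm[:na].mean() - perm[na:].mean()
    if sides == "two":
        b_count = np.sum(np.abs(null) >= abs(obs))
    else:
        b_count = np.sum(null >= obs)
    p = (b_count + 1.0) / (n_perm + 1.0)
    d = cohens_d(a, b) if (a.size >= 2 and b.size >= 2) else float("nan")
    return GroupTestResult(observed=float(obs), p_value=float(p), n_perm=n_perm,
                           seed=seed, effect_size=d, sides=sides)


# --------------------------------------------------------------------------
# Regression with permutation p-values
# --------------------------------------------------------------------------

@dataclass
class RegressionResult:
    params: np.ndarray          # including intercept (column 0)
    t_values: np.ndarray
    perm_p: np.ndarray          # Freedman-Lane permutation p per coefficient
    adj_r_squared: float
    cooks_d: np.ndarray
    cooks_flags: np.ndarray     # observations with Cook's D above threshold
    names: list[str]


def regression_with_permutation(y: np.ndarray, X: np.ndarray, n_perm: int = 1000,
                                seed: int = 0, cooks_threshold: float | None = None,
                                names: list[str] | None = None) -> RegressionResult:
    """OLS with Freedman-Lane permutation p-values per coefficient.

    For each predictor, residuals of the reduced model (that predictor
    removed) are permuted and added back to the reduced fit; the full-model
    |t| under each permutation forms the null.  An intercept is prepended;
    Cook's distance is flagged at 4/n by default.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n <= p + 2:
        raise ValueError("need n > p + 2 observations")
    Xd = sm.add_constant(X)
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise ValueError("design matrix is rank deficient")
    fit = sm.OLS(y, Xd).fit()
    cooks = fit.get_influence().cooks_distance[0]
    thr = (4.0 / n) if cooks_threshold is None else cooks_threshold

    rng = np.random.default_rng(seed)
    perm_p = np.full(Xd.shape[1], np.nan)
    for j in range(1, Xd.shape[1]):            # skip the intercept
        X_red = np.delete(Xd, j, axis=1)
        red = sm.OLS(y, X_red).fit()
        base, resid = red.fittedvalues, red.resid
        perm_idx = np.array([rng.permutation(n) for _ in range(n_perm)])
        Ystar = base[None, :] + resid[perm_idx]              # (n_perm, n)
        # vectorized full-model t for coefficient j under every permutation
        pinv = np.linalg.pinv(Xd)
        beta = Ystar @ pinv.T                                # (n_perm, p+1)
        rss = np.sum((Ystar - beta @ Xd.T) ** 2, axis=1)
        dof = n - Xd.shape[1]
        xtx_inv_jj = np.linalg.inv(Xd.T @ Xd)[j, j]
        se = np.sqrt(rss / dof * xtx_inv_jj)
        t_null = np.abs(beta[:, j] / se)
        perm_p[j] = (np.sum(t_null >= abs(fit.tvalues[j])) + 1.0) / (n_perm + 1.0)

    return RegressionResult(
        params=np.asarray(fit.params),
        t_values=np.asarray(fit.tvalues),
        perm_p=perm_p,
        adj_r_squared=float(fit.rsquared_adj),
        cooks_d=cooks,
        cooks_flags=np.flatnonzero(cooks > thr),
        names=["intercept"] + (names or [f"x{j}" for j in range(p)]),
    )


# --------------------------------------------------------------------------
# Power simulation
# --------------------------------------------------------------------------

def power_simulation(n_per_group: int = 27, effect_d: float = 0.75,
                     alpha: float = 0.05, n_experiments: int = 2000,
                     n_perm: int = 1000, seed: int = 0,
                     sides: str = "two") -> float:
    """Simulated power of the two-sample permutation test on the mean.

    Draws ``n_experiments`` pairs of Gaussian groups whose means differ by
    ``effect_d`` pooled SDs and reports the fraction rejected at ``alpha``.
    Fully vectorized: one shared set of label permutations is applied to
    every simulated experiment (each experiment's Monte-Carlo p remains
    valid conditionally on the drawn permutations).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if sides not in ("two", "greater"):
        raise ValueError("sides must be 'two' or 'greater'")
    rng = np.random.default_rng(seed)
    n = n_per_group
    data = rng.standard_normal((2 * n, n_experiments))
    data[:n] += effect_d
    obs = data[:n].mean(axis=0) - data[n:].mean(axis=0)      # (n_experiments,)

    perms = np.array([rng.permutation(2 * n) for _ in range(n_perm)])
    # mean difference under each label permutation, all experiments at once
    masks = np.zeros((n_perm, 2 * n))
    for k in range(n_perm):
        masks[k, perms[k, :n]] = 1.0
    null = (masks @ data) / n - ((1.0 - masks) @ data) / n   # (n_perm, n_experiments)

    if sides == "two":
        b = np.sum(np.abs(null) >= np.abs(obs)[None, :], axis=0)
    else:
        b = np.sum(null >= obs[None, :], axis=0)
    p = (b + 1.0) / (n_perm + 1.0)
    return float(np.mean(p < alpha))


def power_noncentral_t(n_per_group: int = 27, effect_d: float = 0.75,
                       alpha: float = 0.05, sides: str = "two") -> float:
    """Closed-form power of the two-sample t-test (noncentral t) — used as
    the analytic cross-check for the permutation simulation."""
    df = 2 * n_per_group - 2
    ncp = effect_d * np.sqrt(n_per_group / 2.0)
    if sides == "two":
        tc = sps.t.ppf(1.0 - alpha / 2.0, df)
        return float(1.0 - sps.nct.cdf(tc, df, ncp) + sps.nct.cdf(-tc, df, ncp))
    tc = sps.t.ppf(1.0 - alpha, df)
    return float(1.0 - sps.nct.cdf(tc, df, ncp))
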