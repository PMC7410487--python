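"""Synthetic stimuli and voxel cohorts with known ground truth.

The generators stand in for the human listening experiment: moving-ripple
sound streams with controlled modulation content replace the natural-sound
mixture, and simulated voxel cohorts with known Gaussian tuning over the
(rate, scale, frequency) grid replace measured BOLD responses.  Because the
ground truth is known, every downstream stage — encoding fits, best-feature
maps, feature reconstruction, selectivity statistics — can be checked for
parameter recovery.

A *moving ripple* is the canonical probe for spectro-temporal modulation
filters: a broadband tone-complex carrier whose spectrogram envelope is a
travelling sinusoid ``1 + depth * sin(2*pi*(rate*t + scale*x) + phase)``
with ``x`` the log2 frequency axis.

Voxel responses follow the same linear generative law the encoding model
assumes: ``Y = S @ C_true + noise`` with ``C_true`` columns separable
Gaussian bumps in grid-index coordinates.  Two "age groups" differ only in
tuning bandwidth, emulating a broadening of cortical tuning with age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .auditory import (
    FREQ_HI,
    FREQ_LO,
    INTEGRATION_TAU_S,
    TR_SECONDS,
    FeatureMatrix,
    GridAxes,
    grid_axes,
)

DEFAULT_SAMPLING_RATE = 16000.0
DEFAULT_N_RUNS = 8
DEFAULT_SNIPPETS_PER_RUN = 519

#: default generative conditions for cohorts: moderate single-voxel noise
#: (signal and noise of comparable scale) and a doubled bandwidth in the
#: older group relative to the young group, in grid-index units.
DEFAULT_BANDWIDTH_YOUNG = 1.0
DEFAULT_BANDWIDTH_OLD = 2.0
DEFAULT_NOISE_SD = 1.0

#: preferred-rate weights emulating the cortical bias towards intermediate
#: temporal rates (profiles peak at 4-8 Hz): mass concentrated on the
#: middle bins of a 5- or 6-bin rate axis.
def rate_focus_weights(n_rates: int) -> np.ndarray:
    centre = (n_rates - 1) / 2.0
    w = np.exp(-0.5 * ((np.arange(n_rates) - centre) / 0.75) ** 2)
    return w / w.sum()


@dataclass
class StimulusStream:
    """Concatenated-run sound stream."""

    waveform: np.ndarray
    sampling_rate: float
    run_boundaries: np.ndarray   # start sample of each run
    tr_seconds: float = TR_SECONDS

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        self.run_boundaries = np.asarray(self.run_boundaries, dtype=int)
        if not np.all(np.isfinite(self.waveform)):
            raise ValueError("waveform contains non-finite samples")
        if self.waveform.size and np.max(np.abs(self.waveform)) > 1.0 + 1e-9:
            raise ValueError("waveform must be bounded in [-1, 1]")


# --------------------------------------------------------------------------
# Ripples and streams
# --------------------------------------------------------------------------

def make_ripple(
    duration_s: float,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    rate_hz: float = 4.0,
    scale_cyc_per_oct: float = 0.8,
    depth: float = 1.0,
    direction: str = "down",
    seed: int = 0,
    n_components: int = 64,
) -> StimulusStream:
    """Moving ripple on a log-spaced tone-complex carrier.

    ``direction='down'`` means ridges drift towards lower frequencies over
    time (envelope phase ``rate*t + scale*x``); ``'up'`` flips the sign of
    the scale term.  Deterministic given ``seed``.
    """
    if duration_s <= 0 or sampling_rate <= 0:
        raise ValueError("duration and sampling rate must be positive")
    if not 0.0 <= depth <= 1.0:
        raise ValueError("depth must lie in [0, 1]")
    env_nyquist = 0.5 / INTEGRATION_TAU_S
    if rate_hz > env_nyquist:
        raise ValueError(f"rate {rate_hz} Hz above the envelope Nyquist ({env_nyquist} Hz)")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")

    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration_s * sampling_rate))) / sampling_rate
    freqs = FREQ_LO * 2.0 ** (
        np.arange(n_components) / (n_components - 1) * np.log2(FREQ_HI / FREQ_LO)
    )
    x = np.log2(freqs / freqs[0])
    phases = rng.uniform(0, 2 * np.pi, n_components)
    ripple_phase = rng.uniform(0, 2 * np.pi)
    sign = 1.0 if direction == "down" else -1.0

    wave = np.zeros_like(t)
    for fi, xi, ph in zip(freqs, x, phases):
        env = 1.0 + depth * np.sin(
            2 * np.pi * (rate_hz * t + sign * scale_cyc_per_oct * xi) + ripple_phase
        )
        wave += env * np.sin(2 * np.pi * fi * t + ph)
    wave *= 0.9 / np.max(np.abs(wave))
    return StimulusStream(wave, sampling_rate, np.array([0]))


def make_stimulus_stream(
    n_runs: int = DEFAULT_N_RUNS,
    run_duration_s: float = DEFAULT_SNIPPETS_PER_RUN * TR_SECONDS,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    component_ripples: list[dict] | None = None,
    noise_mix: bool = False,
    seed: int = 0,
) -> StimulusStream:
    """Multi-run stream: a mixture of moving ripples, or modulated noise.

    With the defaults (8 runs of 519 x 947 ms) the snippet count matches the
    original run structure: 4152 TR-length sounds.
    """
    if n_runs < 1:
        raise ValueError("need at least one run")
    if run_duration_s < TR_SECONDS:
        raise ValueError("run shorter than one TR")
    if not noise_mix and not component_ripples:
        raise ValueError("provide component ripples or select noise mode")

    rng = np.random.default_rng(seed)
    run_len = int(round(run_duration_s * sampling_rate))
    runs = []
    for _ in range(n_runs):
        if noise_mix:
            run = rng.standard_normal(run_len)
            run *= 0.5 / np.max(np.abs(run))
        else:
            run = np.zeros(run_len)
            for comp in component_ripples:
                rip = make_ripple(
                    duration_s=run_len / sampling_rate,
                    sampling_rate=sampling_rate,
                    seed=int(rng.integers(2**31)),
                    **comp,
                )
                run += rip.waveform[:run_len]
            run *= 0.9 / np.max(np.abs(run))
        runs.append(run)
    boundaries = np.arange(n_runs) * run_len
    return StimulusStream(np.concatenate(runs), sampling_rate, boundaries)


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------

@dataclass
class SubjectTruth:
    subject_id: str
    group_label: str                 # 'young' | 'old'
    pref_idx: np.ndarray             # (V, 3) int grid indices (rate, scale, freq)
    bandwidths: np.ndarray           # (3,) grid-index units, > 0
    gains: np.ndarray                # (V,) >= 0
    noise_sd: float


@dataclass
class SyntheticCohort:
    subjects: list[SubjectTruth]
    axes: GridAxes

    def to_frame(self) -> pd.DataFrame:
        """Tidy ground-truth table (one row per voxel) for TSV export."""
        rows = []
        for s in self.subjects:
            for v in range(len(s.gains)):
                rows.append(
                    {
                        "subject": s.subject_id,
                        "group": s.group_label,
                        "voxel": v,
                        "rate_idx": s.pref_idx[v, 0],
                        "scale_idx": s.pref_idx[v, 1],
                        "freq_idx": s.pref_idx[v, 2],
                        "rate_hz": self.axes.rates[s.pref_idx[v, 0]],
                        "scale_cyc_oct": self.axes.scales[s.pref_idx[v, 1]],
                        "freq_hz": self.axes.freqs[s.pref_idx[v, 2]],
                        "bw_rate": s.bandwidths[0],
                        "bw_scale": s.bandwidths[1],
                        "bw_freq": s.bandwidths[2],
                        "gain": s.gains[v],
                        "noise_sd": s.noise_sd,
                    }
                )
        return pd.DataFrame(rows)


def _as_bandwidths(bw) -> np.ndarray:
    out = np.broadcast_to(np.asarray(bw, dtype=float), (3,)).copy()
    if np.any(out <= 0):
        raise ValueError("tuning bandwidths must be positive")
    return out


def make_cohort(
    n_young: int,
    n_old: int,
    n_voxels: int,
    bandwidth_young=DEFAULT_BANDWIDTH_YOUNG,
    bandwidth_old=DEFAULT_BANDWIDTH_OLD,
    noise_sd: float = DEFAULT_NOISE_SD,
    grid_mode: str = "roi_decoding",
    rate_weights: np.ndarray | None = None,
    gain: float = 1.0,
    seed: int = 0,
) -> SyntheticCohort:
    """Draw a two-group cohort with known voxel tuning.

    Preferred features tile the grid (stratified shuffle, so every cell is
    some voxel's preference).  When ``rate_weights`` is given, the preferred
    rate index is instead drawn from that categorical distribution — used to
    emulate a cortical over-representation of intermediate temporal rates —
    while scale and frequency preferences still tile their axes.  The two
    groups differ only in tuning bandwidth.
    """
    if n_young < 1 or n_old < 1:
        raise ValueError("group sizes must be >= 1")
    if gain < 0:
        raise ValueError("gain must be non-negative")
    axes = grid_axes(grid_mode)
    if n_voxels < axes.n_features and rate_weights is None:
        warnings.warn(
            f"n_voxels={n_voxels} < {axes.n_features} feature bins: "
            "the grid cannot be fully tiled"
        )
    bw_young = _as_bandwidths(bandwidth_young)
    bw_old = _as_bandwidths(bandwidth_old)
    rng = np.random.default_rng(seed)

    def draw_prefs() -> np.ndarray:
        if rate_weights is None:
            cells = np.indices(axes.shape).reshape(3, -1).T  # (F, 3)
            reps = int(np.ceil(n_voxels / len(cells)))
            tiled = np.tile(cells, (reps, 1))[:n_voxels]
            return tiled[rng.permutation(n_voxels)]
        w = np.asarray(rate_weights, dtype=float)
        w = w / w.sum()
        r = rng.choice(len(axes.rates), size=n_voxels, p=w)
        sc_fr = np.indices(axes.shape[1:]).reshape(2, -1).T
        reps = int(np.ceil(n_voxels / len(sc_fr)))
        tiled = np.tile(sc_fr, (reps, 1))[:n_voxels]
        tiled = tiled[rng.permutation(n_voxels)]
        return np.column_stack([r, tiled])

    subjects = []
    for g, n_subj, bw in (("young", n_young, bw_young), ("old", n_old, bw_old)):
        for i in range(n_subj):
            subjects.append(
                SubjectTruth(
                    subject_id=f"{g}{i:02d}",
                    group_label=g,
                    pref_idx=draw_prefs(),
                    bandwidths=bw.copy(),
                    gains=np.full(n_voxels, float(gain)),
                    noise_sd=float(noise_sd),
                )
            )
    return SyntheticCohort(subjects=subjects, axes=axes)


def true_coefficients(subject: SubjectTruth, axes: GridAxes) -> np.ndarray:
    """Ground-truth F x V coefficient matrix of separable Gaussian bumps.

    Each voxel's tuning profile is normalized to unit L2 norm and scaled by
    its gain, so ``gain``/``noise_sd`` directly set the per-voxel SNR.
    """
    idx = np.indices(axes.shape).reshape(3, -1).T      # (F, 3) grid coords
    d = idx[None, :, :] - subject.pref_idx[:, None, :]  # (V, F, 3)
    z = d / subject.bandwidths[None, None, :]
    bumps = np.exp(-0.5 * np.sum(z * z, axis=2))        # (V, F), index order C
    # np.indices enumerates rate slowest; convert to the package's
    # rate-fastest linearization
    bumps = bumps.reshape((-1,) + axes.shape)
    flat = axes.flatten(bumps)                          # (V, F) rate-fastest
    norms = np.linalg.norm(flat, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return (flat / norms * subject.gains[:, None]).T    # (F, V)


def simulate_voxels(feature_matrix: FeatureMatrix, subject: SubjectTruth, seed: int = 0):
    """Simulate one subject's sounds x voxels response matrix.

    ``Y = S @ C_true + noise`` with i.i.d. Gaussian noise of the subject's
    ``noise_sd``.  Requires an HRF-convolved, column-z-scored feature
    matrix, matching the assumptions of the encoding model.
    """
    from .encoding import VoxelResponseMatrix, zscore_columns

    if not feature_matrix.hrf_convolved:
        raise ValueError("feature matrix must be HRF-convolved before simulation")
    if not feature_matrix.z_scored:
        raise ValueError("feature matrix must be column-z-scored before simulation")
    c_true = true_coefficients(subject, feature_matrix.axes)
    if c_true.shape[0] != feature_matrix.n_features:
        raise ValueError("cohort grid does not match the feature matrix grid")
    rng = np.random.default_rng(seed)
    y = feature_matrix.values @ c_true
    y = y + rng.normal(0.0, subject.noise_sd, size=y.shape)
    raw = VoxelResponseMatrix(values=y, run_labels=feature_matrix.run_labels.copy())
    z, _ = zscore_columns(y)
    raw.values_z = z
    return raw


def simulate_cohort(feature_matrix: FeatureMatrix, cohort: SyntheticCohort, seed: int = 0) -> dict:
    """Simulate every subject; independent noise streams per subject."""
    rng = np.random.default_rng(seed)
    return {
        s.subject_id: simulate_voxels(feature_matrix, s, seed=int(rng.integers(2**31)))
        for s in cohort.subjects
    }


# --------------------------------------------------------------------------
# Surrogate feature matrices (desk-scale stand-in for filterbank output)
# --------------------------------------------------------------------------

def surrogate_feature_matrix(
    n_runs: int,
    snippets_per_run: int,
    grid_mode: str = "roi_decoding",
    seed: int = 0,
    ar_coeff: float = 0.3,
) -> FeatureMatrix:
    """Synthetic stochastic modulation-energy matrix (not filterbank output).

    Draws positive, temporally autocorrelated (AR(1) log-normal) energies
    per feature column, per run — a desk-scale surrogate for running the
    auditory model over thousands of snippets when only the encoding /
    decoding / statistics machinery is under study.  Labelled synthetic.
    """
    axes = grid_axes(grid_mode)
    rng = np.random.default_rng(seed)
    n = n_runs * snippets_per_run
    z = np.empty((n, axes.n_features))
    innov_sd = np.sqrt(1.0 - ar_coeff**2)
    for r in range(n_runs):
        block = np.empty((snippets_per_run, axes.n_features))
        block[0] = rng.standard_normal(axes.n_features)
        eps = rng.standard_normal((snippets_per_run - 1, axes.n_features)) * innov_sd
        for t in range(1, snippets_per_run):
            block[t] = ar_coeff * block[t - 1] + eps[t - 1]
        z[r * snippets_per_run : (r + 1) * snippets_per_run] = block
    values = np.exp(0.5 * z)
    run_labels = np.repeat(np.arange(n_runs), snippets_per_run)
    return FeatureMatrix(values=values, axes=axes, run_labels=run_labels)
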