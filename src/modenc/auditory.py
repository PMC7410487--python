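"""Auditory model: waveform -> spectro-temporal modulation features.

The front end mimics the classic two-stage cortical sound-analysis model:

* an *early stage* turning the waveform into an auditory spectrogram —
  a bank of 128 overlapping constant-Q bandpass filters (Q10dB = 3) on a
  logarithmic frequency axis from 180 to 7040 Hz, followed by a hair-cell
  stage (temporal highpass then lowpass), an across-frequency first
  derivative sharpening frequency selectivity, half-wave rectification and
  leaky temporal integration with time constant 8 ms;

* a *cortical stage* decomposing the spectrogram with a bank of directional
  2-D modulation filters jointly selective for temporal modulation rate
  (omega, Hz) and spectral modulation scale (Omega, cycles/octave).  The
  magnitude of the complex (quadrature) filter output is a phase-invariant
  modulation energy; it is averaged over the upward and downward sweep
  directions, averaged over time, and pooled along the tonotopic axis into
  a small number of centre-frequency bands.

Each sound snippet therefore maps to a (rate x scale x frequency) grid of
modulation energies; snippets stack into the sounds-by-features matrix S
that the encoding and decoding models consume, after per-run convolution
with a double-gamma hemodynamic response function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.io import wavfile
from scipy.signal import lfilter
from scipy.stats import gamma as gamma_dist

# --------------------------------------------------------------------------
# Feature grids
# --------------------------------------------------------------------------

#: temporal modulation rates omega (Hz), spectral scales Omega (cyc/oct) and
#: tonotopic centre frequencies f (Hz) of the dense grid used for voxel-wise
#: encoding (6 x 6 x 8 = 288 features).
ENCODING_RATES = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0])
ENCODING_SCALES = np.array([0.3, 0.4, 0.8, 1.3, 2.3, 4.0])
ENCODING_FREQS = np.array([232.0, 367.0, 580.0, 918.0, 1452.0, 2297.0, 3633.0, 5746.0])

#: reduced grid used for region-of-interest decoding (5 x 5 x 5 = 125).
ROI_RATES = np.array([1.0, 2.4, 5.7, 13.5, 32.0])
ROI_SCALES = np.array([0.25, 0.5, 1.0, 2.0, 4.0])
ROI_FREQS = np.array([277.0, 576.0, 1201.0, 2502.0, 5213.0])

#: cochlear filterbank span
FREQ_LO = 180.0
FREQ_HI = 7040.0
N_CHANNELS = 128
Q10 = 3.0

#: hair-cell lowpass cutoff (Hz) and leaky-integrator time constant (s)
HAIRCELL_LOWPASS_HZ = 4000.0
INTEGRATION_TAU_S = 0.008

#: snippet length — the fMRI repetition time
TR_SECONDS = 0.947

GRID_MODES = ("encoding", "roi_decoding")


@dataclass(frozen=True)
class GridAxes:
    """Axes of a (rate, scale, frequency) modulation feature grid."""

    rates: np.ndarray
    scales: np.ndarray
    freqs: np.ndarray
    mode: str

    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.rates), len(self.scales), len(self.freqs))

    @property
    def n_features(self) -> int:
        r, s, f = self.shape
        return r * s * f

    def flatten(self, grid: np.ndarray) -> np.ndarray:
        """Linearize a (rate, scale, freq) array, rate index fastest."""
        if grid.shape[-3:] != self.shape:
            raise ValueError(f"grid shape {grid.shape} does not match axes {self.shape}")
        return np.reshape(grid, grid.shape[:-3] + (self.n_features,), order="F")

    def unflatten(self, flat: np.ndarray) -> np.ndarray:
        if flat.shape[-1] != self.n_features:
            raise ValueError(f"expected {self.n_features} features, got {flat.shape[-1]}")
        return np.reshape(flat, flat.shape[:-1] + self.shape, order="F")


def grid_axes(mode: str = "encoding") -> GridAxes:
    if mode == "encoding":
        return GridAxes(ENCODING_RATES, ENCODING_SCALES, ENCODING_FREQS, mode)
    if mode == "roi_decoding":
        return GridAxes(ROI_RATES, ROI_SCALES, ROI_FREQS, mode)
    raise ValueError(f"unknown grid_mode {mode!r}; expected one of {GRID_MODES}")


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------


@dataclass
class AuditorySpectrogram:
    """Time x channel auditory spectrogram (non-negative)."""

    values: np.ndarray            # (n_frames, 128)
    channel_freqs: np.ndarray     # Hz, strictly increasing, length 128
    frame_interval: float         # seconds

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != len(self.channel_freqs):
            raise ValueError("spectrogram shape does not match channel axis")
        if np.any(np.diff(self.channel_freqs) <= 0):
            raise ValueError("channel centre frequencies must be strictly increasing")


@dataclass
class FeatureMatrix:
    """Sounds x features modulation-energy matrix with provenance flags."""

    values: np.ndarray            # (n_sounds, n_features)
    axes: GridAxes
    run_labels: np.ndarray        # (n_sounds,) int
    hrf_convolved: bool = False
    z_scored: bool = False
    zscore_stats: dict | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.run_labels = np.asarray(self.run_labels)
        if self.values.shape != (len(self.run_labels), self.axes.n_features):
            raise ValueError(
                f"feature matrix shape {self.values.shape} inconsistent with "
                f"{len(self.run_labels)} sounds x {self.axes.n_features} features"
            )

    @property
    def n_sounds(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class HRFSpec:
    """Double-gamma hemodynamic response, sampled at the TR.

    ``peak_delay`` / ``undershoot_delay`` are gamma modes in seconds;
    the undershoot is subtracted with weight ``1/ratio``.
    """

    peak_delay: float = 4.0
    undershoot_delay: float = 12.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    ratio: float = 6.0
    tr_seconds: float = TR_SECONDS
    duration: float = 32.0

    def kernel(self) -> np.ndarray:
        """Unit-peak kernel sampled every TR; mode lands at 4 s +- one TR."""
        t = np.arange(0.0, self.duration, self.tr_seconds)
        a1 = self.peak_delay / self.peak_dispersion + 1.0
        a2 = self.undershoot_delay / self.undershoot_dispersion + 1.0
        h = gamma_dist.pdf(t, a1, scale=self.peak_dispersion)
        h = h - gamma_dist.pdf(t, a2, scale=self.undershoot_dispersion) / self.ratio
        if h.sum() <= 0:
            raise ValueError("HRF kernel does not integrate to a positive value")
        return h / h.max()


# --------------------------------------------------------------------------
# Early stage: auditory spectrogram
# --------------------------------------------------------------------------

def channel_centre_freqs(n_channels: int = N_CHANNELS) -> np.ndarray:
    """Log-spaced cochlear channel centres covering 180-7040 Hz inclusive."""
    return FREQ_LO * 2.0 ** (
        np.arange(n_channels) / (n_channels - 1) * np.log2(FREQ_HI / FREQ_LO)
    )


def _cochlear_sigma_oct() -> float:
    # Q10dB = f_c / BW10. Solve the half-width h (octaves) of the 10 dB band
    # on a log axis: 2**h - 2**-h = 1/Q10, then convert the Gaussian so that
    # it is 10 dB down (amplitude 10**-0.5) at +-h.
    inv_q = 1.0 / Q10
    u = (inv_q + np.sqrt(inv_q**2 + 4.0)) / 2.0
    h = np.log2(u)
    return h / np.sqrt(2.0 * np.log(10.0**0.5))


def auditory_spectrogram(waveform: np.ndarray, sampling_rate: float) -> AuditorySpectrogram:
    """Run the early auditory stage on a mono waveform.

    Stages, in order: constant-Q cochlear filterbank (zero-phase Gaussian
    magnitude on a log axis, Q10dB = 3) -> hair-cell temporal highpass
    (first difference) and lowpass (one-pole, 4 kHz) -> across-frequency
    first difference -> half-wave rectification -> leaky integration
    (tau = 8 ms) -> frame sampling every 8 ms.
    """
    w = np.asarray(waveform, dtype=float)
    if w.ndim != 1 or w.size == 0:
        raise ValueError("waveform must be a non-empty 1-D array")
    if not np.all(np.isfinite(w)):
        raise ValueError("waveform contains non-finite samples")
    if sampling_rate < 2.0 * FREQ_HI:
        raise ValueError(
            f"sampling rate {sampling_rate} Hz below Nyquist of the top channel ({FREQ_HI} Hz)"
        )

    n = w.size
    cf = channel_centre_freqs()
    spectrum = np.fft.rfft(w)
    f = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    sigma = _cochlear_sigma_oct()
    with np.errstate(divide="ignore"):
        logf = np.log2(np.where(f > 0, f, np.nan))
    x = (logf[None, :] - np.log2(cf)[:, None]) / sigma
    h = np.exp(-0.5 * np.square(x))
    h[:, f <= 0] = 0.0
    bands = np.fft.irfft(spectrum[None, :] * h, n=n, axis=1)  # (128, n)

    # hair cell: temporal highpass (first difference) then one-pole lowpass
    bands = np.diff(bands, axis=1, prepend=bands[:, :1])
    a_lp = np.exp(-2.0 * np.pi * HAIRCELL_LOWPASS_HZ / sampling_rate)
    bands = lfilter([1.0 - a_lp], [1.0, -a_lp], bands, axis=1)

    # midbrain: across-frequency first derivative, rectify, leaky integrate
    bands = np.diff(bands, axis=0, prepend=bands[:1, :])
    bands = np.maximum(bands, 0.0)
    a_int = np.exp(-1.0 / (INTEGRATION_TAU_S * sampling_rate))
    bands = lfilter([1.0 - a_int], [1.0, -a_int], bands, axis=1)

    step = max(1, int(round(INTEGRATION_TAU_S * sampling_rate)))
    frames = bands[:, step - 1 :: step].T  # (n_frames, 128)
    return AuditorySpectrogram(
        values=frames,
        channel_freqs=cf,
        frame_interval=step / sampling_rate,
    )


# --------------------------------------------------------------------------
# Cortical stage: modulation energy
# --------------------------------------------------------------------------

#: octave bandwidths (sigma of a log2 Gaussian) of the modulation filters
RATE_SIGMA_OCT = 0.5
SCALE_SIGMA_OCT = 0.5


def _log_gaussian_response(freqs: np.ndarray, centre: float, sigma_oct: float) -> np.ndarray:
    """One-sided Gaussian magnitude response on a log2 axis; zero at DC."""
    out = np.zeros_like(freqs)
    pos = freqs > 0
    out[pos] = np.exp(-0.5 * ((np.log2(freqs[pos] / centre)) / sigma_oct) ** 2)
    return out


def modulation_energy(spectrogram: AuditorySpectrogram, grid_mode: str = "encoding") -> np.ndarray:
    """Time-averaged modulation energy of one snippet on the (rate, scale, freq) grid.

    For every (rate, scale) pair the spectrogram's 2-D Fourier transform is
    windowed to a single quadrant (analytic in both axes) — one quadrant per
    sweep direction — and transformed back; the complex magnitude is the
    phase-invariant modulation envelope.  Energies are averaged over the two
    directions and over time, then pooled along the tonotopic axis into the
    grid's centre-frequency bands (band edges at geometric midpoints).

    Returns an array of shape (n_rates, n_scales, n_freqs), all values >= 0.
    """
    axes = grid_axes(grid_mode)
    spec = spectrogram.values  # (T, 128)
    if spec.ndim != 2 or spec.shape[1] != N_CHANNELS:
        raise ValueError("spectrogram must be time x 128 channels")
    if np.any(spec < 0):
        raise ValueError("spectrogram must be non-negative")
    n_t, n_c = spec.shape

    chan_spacing_oct = np.log2(FREQ_HI / FREQ_LO) / (n_c - 1)
    # zero-pad the tonotopic axis: the 128-channel span is only ~5.3 octaves,
    # so the raw FFT samples spectral modulation every ~0.19 cyc/oct — too
    # coarse to separate the lowest scale filters; padding samples the same
    # spectral transform four times finer
    n_pad = 4 * n_c
    ft = np.fft.fftfreq(n_t, d=spectrogram.frame_interval)       # Hz
    fs = np.fft.fftfreq(n_pad, d=chan_spacing_oct)               # cyc/oct
    F2 = np.fft.fft2(spec, s=(n_t, n_pad))

    t_pos = ft > 0
    s_pos = fs > 0
    s_neg = fs < 0

    out = np.zeros(axes.shape)
    for ir, rate in enumerate(axes.rates):
        hr = _log_gaussian_response(np.abs(ft), rate, RATE_SIGMA_OCT) * t_pos
        for isc, scale in enumerate(axes.scales):
            hs = np.abs(_log_gaussian_response(np.abs(fs), scale, SCALE_SIGMA_OCT))
            # downward sweep: same-sign quadrant; upward: opposite-sign
            h_down = np.outer(hr, hs * s_pos)
            h_up = np.outer(hr, hs * s_neg)
            env_down = np.abs(np.fft.ifft2(F2 * h_down))[:, :n_c]
            env_up = np.abs(np.fft.ifft2(F2 * h_up))[:, :n_c]
            per_channel = 0.5 * (env_down + env_up).mean(axis=0)  # (128,)
            out[ir, isc, :] = _pool_tonotopic(per_channel, spectrogram.channel_freqs, axes.freqs)
    return out


def _pool_tonotopic(per_channel: np.ndarray, channel_freqs: np.ndarray, centres: np.ndarray) -> np.ndarray:
    edges = np.sqrt(centres[:-1] * centres[1:])
    edges = np.concatenate(([0.0], edges, [np.inf]))
    idx = np.searchsorted(edges, channel_freqs, side="right") - 1
    out = np.zeros(len(centres))
    for b in range(len(centres)):
        sel = idx == b
        out[b] = per_channel[sel].mean() if np.any(sel) else 0.0
    return out


# --------------------------------------------------------------------------
# Snippets and the feature matrix
# --------------------------------------------------------------------------

def cut_snippets(stream, tr_seconds: float = TR_SECONDS):
    """Cut a stimulus stream into TR-length snippets, run by run.

    Returns ``(snippets, run_labels)`` where snippets is a list of 1-D
    arrays.  Each run contributes ``floor(run_samples / tr_samples)``
    snippets; the trailing partial snippet of a run is dropped.
    """
    fs = stream.sampling_rate
    tr_samples = int(np.floor(tr_seconds * fs))
    bounds = list(stream.run_boundaries) + [len(stream.waveform)]
    if len(stream.waveform) == 0:
        raise ValueError("empty stimulus stream")
    snippets: list[np.ndarray] = []
    labels: list[int] = []
    for run, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
        n_snip = (hi - lo) // tr_samples
        if n_snip < 1:
            raise ValueError(f"run {run} is shorter than one TR ({tr_seconds} s)")
        for k in range(n_snip):
            snippets.append(stream.waveform[lo + k * tr_samples : lo + (k + 1) * tr_samples])
            labels.append(run)
    return snippets, np.asarray(labels)


def build_feature_matrix(
    snippets, run_labels, sampling_rate: float, grid_mode: str = "encoding"
) -> FeatureMatrix:
    """Extract modulation energy per snippet and stack into sounds x features.

    Column order is the fixed linearization of (rate, scale, frequency) with
    the rate index fastest, then scale, then frequency.
    """
    axes = grid_axes(grid_mode)
    rows = np.empty((len(snippets), axes.n_features))
    for i, snip in enumerate(snippets):
        try:
            spec = auditory_spectrogram(snip, sampling_rate)
            rows[i] = axes.flatten(modulation_energy(spec, grid_mode))
        except Exception as exc:  # annotate which snippet broke
            raise RuntimeError(f"feature extraction failed at snippet {i}: {exc}") from exc
    return FeatureMatrix(values=rows, axes=axes, run_labels=np.asarray(run_labels))


def hrf_convolve(feature_matrix: FeatureMatrix, hrf: HRFSpec | None = None) -> FeatureMatrix:
    """Convolve every feature column with the HRF, independently per run.

    Causal convolution; output length per run equals input length (the tail
    is truncated), so nothing bleeds across run boundaries.
    """
    if feature_matrix.hrf_convolved:
        raise ValueError("feature matrix is already HRF-convolved")
    hrf = hrf or HRFSpec()
    kernel = hrf.kernel()
    vals = feature_matrix.values
    out = np.empty_like(vals)
    for run in np.unique(feature_matrix.run_labels):
        sel = feature_matrix.run_labels == run
        block = vals[sel]
        conv = np.apply_along_axis(lambda c: np.convolve(c, kernel)[: block.shape[0]], 0, block)
        out[sel] = conv
    return replace(feature_matrix, values=out, hrf_convolved=True)


# --------------------------------------------------------------------------
# WAV I/O
# --------------------------------------------------------------------------

def write_wav(path, waveform: np.ndarray, sampling_rate: float) -> None:
    wavfile.write(path, int(sampling_rate), np.asarray(waveform, dtype=np.float32))


def read_wav(path) -> tuple[np.ndarray, float]:
    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.dtype.kind == "i":
        data = data / float(np.iinfo(data.dtype).max)
    if data.ndim > 1:
        warnings.warn("multichannel WAV: averaging to mono")
        data = data.mean(axis=1)
    return data.astype(float), float(fs)
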