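"""EEG filtering, epoch-quality screening, and multitaper spectral power.

The spectrogram is computed per scoring epoch so that its time axis is the
hypnogram's epoch axis: one 30-s window per epoch, no overlap.  Within a
window the power spectral density is the average of periodograms tapered
with orthonormal discrete prolate spheroidal (Slepian) sequences —
time-bandwidth 4, 7 tapers by default, giving ≈0.27 Hz half-bandwidth over
a 30-s window.  Power is evaluated on a fixed inclusive grid of 901
frequencies from 0 to 45 Hz in 0.05 Hz steps, which spans the delta, theta,
alpha, beta and low-gamma bands plus the spindle range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import scipy.signal

from .stage_io import EpochedRecording, SignalRecord

logger = logging.getLogger("somnogram")


class SpectralError(ValueError):
    pass


@dataclass(frozen=True)
class FilterConfig:
    """Optional zero-phase frequency filters (off by default)."""

    apply: bool = False
    notch_hz: float | None = 60.0
    notch_q: float = 30.0
    bandpass_low_hz: float | None = 0.3
    bandpass_high_hz: float | None = 45.0
    # 8th order + zero-phase gives >20 dB one grid-step (5 Hz) past the edge
    bandpass_order: int = 8


@dataclass(frozen=True)
class EpochQualityConfig:
    """Epoch screening thresholds: amplitude ceiling, flatness floor,
    and annotation labels to discard outright."""

    max_amplitude_uv: float = 500.0
    flat_std_uv: float = 0.1
    excluded_annotations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.max_amplitude_uv <= 0 or self.flat_std_uv <= 0:
            raise SpectralError("quality thresholds must be positive")


@dataclass(frozen=True)
class SpectralConfig:
    freq_min_hz: float = 0.0
    freq_max_hz: float = 45.0
    freq_step_hz: float = 0.05
    time_bandwidth: float = 4.0
    n_tapers: int = 7
    db_reference: float = 1.0  # µV²/Hz
    db_floor: float = -60.0

    def __post_init__(self) -> None:
        if self.n_tapers > 2 * self.time_bandwidth - 1:
            raise SpectralError("n_tapers must not exceed 2·time_bandwidth − 1")
        if self.freq_min_hz >= self.freq_max_hz or self.freq_step_hz <= 0:
            raise SpectralError("invalid frequency grid")

    @property
    def n_freq_bins(self) -> int:
        # inclusive endpoints: 0–45 Hz at 0.05 Hz → 901 bins
        n = (self.freq_max_hz - self.freq_min_hz) / self.freq_step_hz
        n_round = round(n)
        if abs(n - n_round) > 1e-6:
            raise SpectralError("freq range must be an integer multiple of the step")
        return int(n_round) + 1

    @property
    def freqs_hz(self) -> np.ndarray:
        return self.freq_min_hz + self.freq_step_hz * np.arange(self.n_freq_bins)


@dataclass
class Spectrogram:
    """Per-epoch, per-channel multitaper power on the fixed frequency grid.

    ``power`` has shape (n_epochs, n_freq_bins, n_channels) in µV²/Hz (linear
    scale, one-sided); ``epoch_index_map[k]`` is the hypnogram epoch shown at
    spectrogram column k (the identity after joint filtering).
    """

    power: np.ndarray
    freqs_hz: np.ndarray
    channel_names: list[str]
    epoch_index_map: np.ndarray

    def __post_init__(self) -> None:
        if self.power.ndim != 3 or self.power.shape[1] != len(self.freqs_hz):
            raise SpectralError(f"power has shape {self.power.shape}")
        if np.any(np.diff(self.epoch_index_map) <= 0) and len(self.epoch_index_map) > 1:
            raise SpectralError("epoch_index_map must be strictly increasing")


# ---------------------------------------------------------------------------
# Frequency filters
# ---------------------------------------------------------------------------

def apply_frequency_filters(record: SignalRecord, config: FilterConfig) -> SignalRecord:
    """Zero-phase notch then bandpass per channel; identity when disabled."""
    if not config.apply:
        return record
    nyq = record.fs / 2.0
    data = record.samples
    if config.notch_hz is not None:
        if config.notch_hz >= nyq:
            raise SpectralError(f"notch at {config.notch_hz} Hz ≥ Nyquist {nyq} Hz")
        b, a = scipy.signal.iirnotch(config.notch_hz, config.notch_q, fs=record.fs)
        data = scipy.signal.filtfilt(b, a, data, axis=1)
    if config.bandpass_low_hz is not None and config.bandpass_high_hz is not None:
        lo, hi = config.bandpass_low_hz, config.bandpass_high_hz
        if not 0 < lo < hi < nyq:
            raise SpectralError(f"bandpass {lo}-{hi} Hz invalid for Nyquist {nyq} Hz")
        sos = scipy.signal.butter(
            config.bandpass_order, [lo, hi], btype="bandpass", fs=record.fs, output="sos"
        )
        data = scipy.signal.sosfiltfilt(sos, data, axis=1)
    logger.info("frequency filters applied (notch=%s, bandpass=%s-%s Hz)",
                config.notch_hz, config.bandpass_low_hz, config.bandpass_high_hz)
    return SignalRecord(list(record.channel_names), record.fs, data)


# ---------------------------------------------------------------------------
# Epoch quality
# ---------------------------------------------------------------------------

def flag_bad_epochs(
    epoched: EpochedRecording, config: EpochQualityConfig
) -> tuple[np.ndarray, dict[int, str]]:
    """Flag epochs with excessive amplitude, flat channels, or excluded labels.

    Returns a boolean mask (True = bad) over current epoch indices and a
    reason per flagged index.  Callers remove flagged epochs from both the
    stage and signal streams via :meth:`EpochedRecording.drop`.
    """
    n = epoched.n_epochs
    mask = np.zeros(n, dtype=bool)
    reasons: dict[int, str] = {}
    peak = np.max(np.abs(epoched.epochs), axis=(1, 2)) if n else np.empty(0)
    std = np.min(np.std(epoched.epochs, axis=2), axis=1) if n else np.empty(0)
    excluded = set(config.excluded_annotations)
    for i in range(n):
        if peak[i] > config.max_amplitude_uv:
            mask[i] = True
            reasons[i] = "amplitude"
        elif std[i] < config.flat_std_uv:
            mask[i] = True
            reasons[i] = "flat"
        elif epoched.hypnogram.stages[i] is not None and str(epoched.hypnogram.stages[i]) in excluded:
            mask[i] = True
            reasons[i] = "annotation"
    return mask, reasons


# ---------------------------------------------------------------------------
# Multitaper spectrogram
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _dpss_tapers(n_samples: int, time_bandwidth: float, n_tapers: int) -> np.ndarray:
    # scipy returns the tapers orthonormal: wᵢ·wⱼ = δᵢⱼ
    return scipy.signal.windows.dpss(n_samples, time_bandwidth, Kmax=n_tapers)


def _transform_length(n_samples: int, fs: float, step_hz: float) -> int:
    """Smallest DFT length ≥ n_samples whose native bin spacing divides step_hz."""
    base = fs / step_hz
    base_round = round(base)
    if abs(base - base_round) > 1e-6:
        raise SpectralError(
            f"sampling rate {fs} Hz is incommensurate with the {step_hz} Hz grid step"
        )
    base_round = int(base_round)
    mult = max(1, -(-n_samples // base_round))  # ceil division
    return base_round * mult


def multitaper_spectrogram(
    epoched: EpochedRecording, config: SpectralConfig | None = None
) -> Spectrogram:
    """Average-of-tapered-periodograms PSD per epoch and channel.

    One-sided density in µV²/Hz, evaluated at the exact grid frequencies
    (the transform length is padded so the native bin spacing divides the
    grid step).  Output shape is (epochs × n_freq_bins × channels).
    """
    config = config or SpectralConfig()
    fs = epoched.fs
    if fs < 2 * config.freq_max_hz:
        raise SpectralError(
            f"sampling rate {fs} Hz cannot resolve {config.freq_max_hz} Hz; "
            "lower freq_max_hz"
        )
    n_epochs, n_channels, n_samples = epoched.epochs.shape
    if n_samples < 2 * config.n_tapers:
        raise SpectralError("epochs are too short for the requested taper count")

    tapers = _dpss_tapers(n_samples, config.time_bandwidth, config.n_tapers)
    nfft = _transform_length(n_samples, fs, config.freq_step_hz)
    grid_idx = np.round(config.freqs_hz * nfft / fs).astype(int)
    assert np.allclose(grid_idx * fs / nfft, config.freqs_hz, atol=1e-9)

    # (epoch, channel, taper, sample) → rfft over samples
    x = epoched.epochs[:, :, np.newaxis, :] * tapers[np.newaxis, np.newaxis, :, :]
    spectra = np.fft.rfft(x, n=nfft, axis=-1)
    psd = (np.abs(spectra) ** 2) / fs  # per-taper two-sided density, unit-norm tapers
    psd = psd.mean(axis=2)  # average over tapers → (epoch, channel, freq)

    # one-sided: double everything except DC and Nyquist
    one_sided = 2.0 * psd
    one_sided[..., 0] = psd[..., 0]
    if nfft % 2 == 0:
        one_sided[..., -1] = psd[..., -1]

    power = one_sided[:, :, grid_idx]  # (epoch, channel, grid)
    power = np.transpose(power, (0, 2, 1))  # (epoch, grid, channel)
    return Spectrogram(
        power=power,
        freqs_hz=config.freqs_hz,
        channel_names=list(epoched.channel_names),
        epoch_index_map=np.arange(n_epochs),
    )


def to_db(power: np.ndarray, config: SpectralConfig | None = None) -> np.ndarray:
    """Linear µV²/Hz → dB re ``db_reference``, floored at ``db_floor``."""
    config = config or SpectralConfig()
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(np.maximum(power, 0.0) / config.db_reference)
    return np.maximum(db, config.db_floor)


def aggregate_display(
    spec: Spectrogram,
    method: str = "mean",
    channel: str | None = None,
    config: SpectralConfig | None = None,
) -> np.ndarray:
    """Collapse channels into one (epochs × freq) dB matrix for display."""
    db = to_db(spec.power, config)
    if method == "mean":
        return db.mean(axis=2)
    if method == "median":
        return np.median(db, axis=2)
    if method == "single-channel":
        if channel not in spec.channel_names:
            raise SpectralError(f"channel {channel!r} not in {spec.channel_names}")
        return db[:, :, spec.channel_names.index(channel)]
    raise SpectralError(f"unknown aggregation method {method!r}")


def export_spectrogram(spec: Spectrogram, path) -> None:
    """Write the power matrix and axes to a compressed ``.npz`` archive."""
    np.savez_compressed(
        path,
        power=spec.power,
        freqs_hz=spec.freqs_hz,
        channel_names=np.array(spec.channel_names),
        epoch_index_map=spec.epoch_index_map,
    )
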