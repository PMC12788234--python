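"""Signal conditioning and window-level feature extraction.

Pipeline order is fixed: trial-level 20 Hz Butterworth high-pass (zero phase)
-> per-channel 99th-percentile amplitude normalization -> overlapping
sliding-window segmentation with look-ahead (Plabel) labeling -> per-window
CWT scalogram and one-sided FFT magnitude spectrum.  Filtering and
normalization run on whole trials because per-window filtering would corrupt
window edges and per-window percentiles would break cross-window amplitude
comparability.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pywt
from scipy import signal as sps

from .config import WindowingConfig
from .synthetic import SignalTrial

#: Complex Morlet mother wavelet, bandwidth 1.5, center frequency 1.0.
CWT_WAVELET = "cmor1.5-1.0"
N_SCALES = 30
CWT_FREQ_RANGE = (20.0, 450.0)  # Hz, descending coverage


@dataclass(frozen=True)
class LabeledWindow:
    """One W-ms, 8-channel segment labeled Plabel ms past its end."""

    raw: np.ndarray  # (window_samples, 8)
    label: int
    window_start_ms: int
    label_time_ms: int
    trial_id: str
    subject_id: str


@dataclass(frozen=True)
class TimeFreqMap:
    """CWT magnitude scalogram, (n_scales, time, channels), plus the scale
    center frequencies in Hz (strictly monotone, descending)."""

    values: np.ndarray
    center_freqs: np.ndarray


@dataclass(frozen=True)
class Spectrum:
    """One-sided FFT magnitudes, (bins, channels); bin spacing fs/W."""

    values: np.ndarray


def highpass_filter(trial: SignalTrial, cutoff: float = 20.0, order: int = 4) -> SignalTrial:
    """Zero-phase Butterworth high-pass over the whole trial.

    Removes motion artifact and baseline drift below ``cutoff`` while leaving
    the myoelectric band untouched.  Forward-backward application avoids
    group-delay misalignment between samples and event labels.
    """
    if cutoff >= trial.fs / 2:
        raise ValueError("cutoff must be below Nyquist")
    if trial.samples.shape[0] <= 3 * order:
        raise ValueError(
            f"trial of {trial.samples.shape[0]} samples is shorter than the "
            f"filter warm-up ({3 * order} samples)"
        )
    sos = sps.butter(order, cutoff, btype="highpass", fs=trial.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, trial.samples, axis=0)
    return replace(trial, samples=np.ascontiguousarray(filtered))


def normalize_percentile(trial: SignalTrial, q: float = 99.0) -> SignalTrial:
    """Divide each channel by the 99th percentile of its absolute amplitude.

    Robust per-channel scaling: after the op P99(|channel|) == 1, so channels
    are amplitude-comparable while outliers do not dominate the scale.
    """
    p = np.percentile(np.abs(trial.samples), q, axis=0, method="linear")
    dead = np.flatnonzero(p == 0)
    if dead.size:
        raise ValueError(f"channel(s) {dead.tolist()} have zero P{q:g} amplitude")
    return replace(trial, samples=trial.samples / p)


def sliding_positions(duration_ms: int, cfg: WindowingConfig) -> np.ndarray:
    """Window start times (ms) before label-time pruning: 0, S, 2S, ..."""
    if duration_ms < cfg.window_ms:
        raise ValueError("trial shorter than one window")
    n = (duration_ms - cfg.window_ms) // cfg.step_ms + 1
    return np.arange(n) * cfg.step_ms


def segment_windows(
    trial: SignalTrial, cfg: WindowingConfig
) -> tuple[list[LabeledWindow], int]:
    """Segment a trial into labeled windows.

    A window starting at t is labeled by the event active at its label time
    t + W + Plabel.  Windows whose label time exceeds the trial are not
    emitted; windows whose label time falls in an event gap are dropped and
    counted (second return value).
    """
    starts = sliding_positions(trial.duration_ms, cfg)
    w_samp = cfg.window_samples
    ms_to_samp = trial.fs / 1000
    windows: list[LabeledWindow] = []
    skipped = 0
    for start in starts:
        label_time = int(start + cfg.window_ms + cfg.plabel_ms)
        if label_time > trial.duration_ms:
            continue
        label = trial.label_at(label_time)
        if label is None:
            skipped += 1
            continue
        i0 = int(start * ms_to_samp)
        windows.append(
            LabeledWindow(
                raw=trial.samples[i0 : i0 + w_samp],
                label=label,
                window_start_ms=int(start),
                label_time_ms=label_time,
                trial_id=trial.trial_id,
                subject_id=trial.subject_id,
            )
        )
    return windows, skipped


def cwt_center_freqs(n_scales: int = N_SCALES) -> np.ndarray:
    """Scale center frequencies: log-spaced, 450 Hz down to 20 Hz."""
    hi = CWT_FREQ_RANGE[1]
    lo = CWT_FREQ_RANGE[0]
    return np.geomspace(hi, lo, n_scales)


def cwt_scales(fs: int = 1000, n_scales: int = N_SCALES) -> np.ndarray:
    fc = pywt.central_frequency(CWT_WAVELET)  # cycles per sample unit
    return fc * fs / cwt_center_freqs(n_scales)


def cwt_transform(raw: np.ndarray, fs: int = 1000) -> TimeFreqMap:
    """30-scale complex-Morlet scalogram magnitude of a window.

    ``raw`` is (time, channels) or (time, ..., channels); the scale axis is
    prepended.  Linear in the input, so an all-zero window maps to an
    all-zero scalogram.
    """
    scales = cwt_scales(fs)
    coeffs, freqs = pywt.cwt(
        raw, scales, CWT_WAVELET, sampling_period=1.0 / fs, axis=0, method="fft"
    )
    return TimeFreqMap(values=np.abs(coeffs), center_freqs=freqs)


def fft_transform(raw: np.ndarray) -> Spectrum:
    """One-sided FFT magnitude of a window, W/2+1 bins at fs/W spacing.

    No taper (rectangular window), magnitudes not powers.  For a 1200-sample
    window this yields 601 bins spanning 0..500 Hz.
    """
    return Spectrum(values=np.abs(np.fft.rfft(raw, axis=0)))


def batch_features(
    windows: Sequence[LabeledWindow],
    fs: int = 1000,
    chunk: int = 64,
    dtype=np.float32,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Compute (tfmaps, spectra, labels) arrays for a list of windows.

    tfmaps: (N, 30, T, 8); spectra: (N, T/2+1, 8); labels: (N,) int.
    Windows are transformed in chunks to bound peak memory of the FFT-based
    CWT convolution.
    """
    if not windows:
        raise ValueError("no windows to featurize")
    n = len(windows)
    t_len, n_ch = windows[0].raw.shape
    tf = np.empty((n, N_SCALES, t_len, n_ch), dtype=dtype)
    sp = np.empty((n, t_len // 2 + 1, n_ch), dtype=dtype)
    labels = np.array([w.label for w in windows], dtype=np.int64)
    for i0 in range(0, n, chunk):
        block = np.stack([w.raw for w in windows[i0 : i0 + chunk]], axis=1)  # (T, B, C)
        tfm = cwt_transform(block, fs=fs)  # (30, T, B, C)
        tf[i0 : i0 + block.shape[1]] = np.transpose(tfm.values, (2, 0, 1, 3))
        spec = fft_transform(block)  # (bins, B, C)
        sp[i0 : i0 + block.shape[1]] = np.transpose(spec.values, (1, 0, 2))
    return tf, sp, labels


def preprocess_trial(trial: SignalTrial, cutoff: float = 20.0, order: int = 4) -> SignalTrial:
    """Trial-level conditioning: high-pass then percentile normalization."""
    return normalize_percentile(highpass_filter(trial, cutoff=cutoff, order=order))
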