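"""Deterministic preprocessing for pupil traces and continuous EEG.

Pupil preprocessing applies, in this fixed order: blink removal with a
buffer window, MAD-based outlier removal, linear interpolation over missing
runs, zero-phase Butterworth filtering, z-scoring of the continuous trace,
epoching, and down-sampling.  The order is part of the contract and is
exposed as ``PUPIL_STEPS``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .config import PipelineConfig
from .synth import EpochedDataset, PupilTrace
from .schedule import CELLS

logger = logging.getLogger("expectdecode")

__all__ = ["PUPIL_STEPS", "PupilEpochs", "preprocess_pupil", "epoch_eeg", "roi_mean"]

#: Canonical pupil preprocessing order (part of the pipeline contract).
PUPIL_STEPS = (
    "blink_removal",
    "outlier_removal",
    "interpolation",
    "bandpass_filter",
    "zscore",
    "epoch",
    "downsample",
)


@dataclass
class PupilEpochs:
    """Z-scored pupil epochs, (n_kept_trials, n_timepoints) at the target rate."""

    data: np.ndarray
    time_ms: np.ndarray
    trial_index: np.ndarray
    sampling_rate_hz: float
    exclusions: list = field(default_factory=list)


def _expand_mask(mask: np.ndarray, n_buffer: int) -> np.ndarray:
    """Extend every True-run of ``mask`` by ``n_buffer`` samples on each side."""
    if n_buffer <= 0 or not mask.any():
        return mask.copy()
    kernel = np.ones(2 * n_buffer + 1)
    return np.convolve(mask.astype(float), kernel, mode="same") > 0


def _interpolate_missing(x: np.ndarray, missing: np.ndarray) -> np.ndarray:
    """Linear interpolation over missing runs; edges take the nearest value."""
    out = x.copy()
    if missing.any():
        valid = np.flatnonzero(~missing)
        if valid.size == 0:
            raise ValueError("entire trace is missing; nothing to interpolate")
        out[missing] = np.interp(np.flatnonzero(missing), valid, x[valid])
    return out


def _butter_sos(highpass, lowpass, fs, order):
    """Butterworth SOS for the requested band; drops unusable cutoffs with a
    warning and returns None when no filtering remains."""
    nyq = fs / 2.0
    hp, lp = highpass, lowpass
    if lp is not None and lp >= nyq:
        warnings.warn(
            f"low-pass cutoff {lp} Hz is at/above Nyquist ({nyq} Hz); dropping it",
            RuntimeWarning, stacklevel=3,
        )
        lp = None
    if hp is not None and hp <= 0:
        hp = None
    if hp is not None and lp is not None:
        return sp_signal.butter(order, [hp, lp], btype="bandpass", fs=fs, output="sos")
    if hp is not None:
        return sp_signal.butter(order, hp, btype="highpass", fs=fs, output="sos")
    if lp is not None:
        return sp_signal.butter(order, lp, btype="lowpass", fs=fs, output="sos")
    return None


def preprocess_pupil(trace: PupilTrace, config: PipelineConfig | None = None) -> PupilEpochs:
    """Blink/outlier removal, interpolation, filtering, z-scoring, epoching,
    down-sampling — in exactly that order.

    Epochs that extend beyond the trace, or whose pre-interpolation missing
    fraction reaches ``config.max_missing_fraction``, are excluded with a
    logged reason rather than raising.
    """
    config = config or PipelineConfig()
    fs = trace.sampling_rate_hz
    x = trace.diameter.astype(float).copy()
    n = x.size

    # 1. blinks +/- buffer
    n_buffer = int(round(config.blink_buffer_ms / 1000.0 * fs))
    missing = _expand_mask(trace.missing.astype(bool), n_buffer)

    # 2. MAD outliers among currently valid samples
    valid = ~missing
    med = np.median(x[valid])
    mad = np.median(np.abs(x[valid] - med))
    if mad > 0:
        outlier = np.zeros(n, dtype=bool)
        outlier[valid] = np.abs(x[valid] - med) / mad > config.mad_threshold
        missing |= outlier

    # 3. interpolation
    x = _interpolate_missing(np.where(missing, np.nan, x), missing)

    # 4. zero-phase Butterworth
    if (config.pupil_highpass_hz, config.pupil_lowpass_hz) == (15.6, 500.0):
        warnings.warn(
            "pupil passband 15.6-500 Hz (protocol default) removes essentially "
            "all pupil dynamics (< 4 Hz); set pupil_highpass_hz/pupil_lowpass_hz "
            "to a physiologically sensible band",
            RuntimeWarning, stacklevel=2,
        )
    sos = _butter_sos(config.pupil_highpass_hz, config.pupil_lowpass_hz, fs,
                      config.pupil_filter_order)
    if sos is not None:
        x = sp_signal.sosfiltfilt(sos, x)

    # 5. z-score the continuous trace
    x = (x - x.mean()) / x.std()

    # 6. epoch around target onsets
    w0, w1 = config.pupil_epoch_window_ms
    n_epoch = int(round((w1 - w0) / 1000.0 * fs))
    epochs, kept, exclusions = [], [], []
    for _, ev in trace.events.iterrows():
        start = int(round((ev["time_ms"] + w0) / 1000.0 * fs))
        stop = start + n_epoch
        tidx = int(ev["trial_index"])
        if start < 0 or stop > n:
            exclusions.append((tidx, "epoch outside recorded trace"))
            continue
        frac_missing = float(missing[start:stop].mean())
        if frac_missing >= config.max_missing_fraction:
            exclusions.append((tidx, f"missing fraction {frac_missing:.2f}"))
            continue
        epochs.append(x[start:stop])
        kept.append(tidx)
    for tidx, reason in exclusions:
        logger.info("pupil epoch for trial %d excluded: %s", tidx, reason)

    data = np.asarray(epochs) if epochs else np.empty((0, n_epoch))

    # 7. downsample
    fs_out = config.pupil_downsample_hz
    if fs_out != fs and data.size:
        from fractions import Fraction

        frac = Fraction(fs_out / fs).limit_denominator(1000)
        data = sp_signal.resample_poly(data, frac.numerator, frac.denominator, axis=1)
    n_out = data.shape[1] if data.size else int(round((w1 - w0) / 1000.0 * fs_out))
    time_ms = w0 + np.arange(n_out) * 1000.0 / fs_out

    return PupilEpochs(
        data=data, time_ms=time_ms, trial_index=np.asarray(kept, dtype=int),
        sampling_rate_hz=fs_out, exclusions=exclusions,
    )


def epoch_eeg(continuous, sfreq_in, event_samples, schedule=None,
              config: PipelineConfig | None = None, sensor_labels=None) -> EpochedDataset:
    """Band-limit, resample to the analysis rate, and epoch continuous EEG.

    ``continuous`` is (n_sensors, n_samples); ``event_samples`` holds the
    event (target or motor-cue) onset sample indices at the input rate.
    Events whose epoch would fall outside the recording are dropped and
    logged.
    """
    config = config or PipelineConfig()
    X = np.asarray(continuous, dtype=float)
    sos = _butter_sos(config.eeg_highpass_hz, config.eeg_lowpass_hz, sfreq_in,
                      config.eeg_filter_order)
    if sos is not None:
        X = sp_signal.sosfiltfilt(sos, X, axis=1)

    fs_out = config.eeg_sampling_rate_hz
    if fs_out != sfreq_in:
        from fractions import Fraction

        frac = Fraction(fs_out / sfreq_in).limit_denominator(10_000)
        X = sp_signal.resample_poly(X, frac.numerator, frac.denominator, axis=1)
    n_samples = X.shape[1]

    w0, w1 = config.eeg_epoch_window_ms
    n_epoch = int(round((w1 - w0) / 1000.0 * fs_out))
    epochs, kept = [], []
    for j, s in enumerate(np.asarray(event_samples)):
        s_out = int(round(s * fs_out / sfreq_in))
        start = s_out + int(round(w0 / 1000.0 * fs_out))
        stop = start + n_epoch
        if start < 0 or stop > n_samples:
            logger.info("EEG epoch for event %d dropped: outside recording", j)
            continue
        epochs.append(X[:, start:stop])
        kept.append(j)
    if not epochs:
        raise ValueError("no epochs survive; all events fall outside the recording")
    data = np.stack(epochs)  # (trials, sensors, time)

    if sensor_labels is None:
        sensor_labels = [f"CH{i}" for i in range(X.shape[0])]
    if schedule is not None:
        schedule = schedule.iloc[kept].reset_index(drop=True)
    else:
        import pandas as pd

        schedule = pd.DataFrame({
            "trial_index": kept,
            "visual_expected": True, "motor_expected": True,
            "target_orientation_deg": 0.0, "cue_orientation_deg": 0.0,
            "cue_to_motor_delay_ms": 0.0, "extra_target_delay_ms": 0.0,
            "block": 1, "seed": -1,
        })
    return EpochedDataset(
        data=data, sampling_rate_hz=fs_out, epoch_window_ms=(w0, w1),
        sensor_labels=list(sensor_labels), schedule=schedule,
    )


def roi_mean(dataset: EpochedDataset, roi=None) -> dict:
    """Per-cell ERP over a sensor region of interest.

    Averages over the ROI sensors, then over trials within each 2x2 cell.
    Returns ``{cell: (n_timepoints,) array}`` plus key ``'labels'`` listing
    the ROI actually used.  Unknown sensor labels raise, naming the label.
    """
    roi = tuple(roi) if roi is not None else tuple(
        l for l in PipelineConfig().roi if l in dataset.sensor_labels
    )
    index = []
    for label in roi:
        if label not in dataset.sensor_labels:
            raise ValueError(f"unknown ROI sensor label {label!r}")
        index.append(dataset.sensor_labels.index(label))
    roi_trace = dataset.data[:, index, :].mean(axis=1)  # (trials, time)

    from .schedule import cell_labels

    labels = cell_labels(dataset.schedule)
    out = {"labels": roi}
    for cell in CELLS:
        members = labels == cell
        if members.any():
            out[cell] = roi_trace[members].mean(axis=0)
    return out
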