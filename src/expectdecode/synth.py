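"""Synthetic EEG, behavioral, and pupil data with known ground truth.

Every generator is a pure function of its arguments and a seed.  The EEG
generator runs the forward model of the decoding chain in reverse — sensor
data are a ground-truth weight matrix applied to the idealized channel
responses for each trial's orientation, gated by a temporal profile, plus
spatially correlated Gaussian noise — so the generator and the inverse
model form a closed loop: at high SNR the decoder must recover each trial's
orientation, at zero SNR accuracy must sit at chance.

The behavioral generator draws reproduction responses from the same von
Mises + uniform mixture the fitting routine assumes (on the doubled-angle
circle), and the pupil generator emits a continuous trace with per-trial
dilations, slow drift, blinks (missing samples), and outlier spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .iem import channel_responses, BasisSet
from .schedule import cell_labels, CELLS

__all__ = [
    "TuningConfig",
    "EpochedDataset",
    "BehaviorGroundTruth",
    "PupilGroundTruth",
    "PupilTrace",
    "default_forward_weights",
    "exponential_noise_covariance",
    "simulate_eeg",
    "simulate_behavior",
    "simulate_pupil",
]

#: Standard 64-channel 10-20 montage labels (10-10 extension).
SENSOR_LABELS_64 = (
    "Fp1 Fpz Fp2 AF7 AF3 AFz AF4 AF8 F7 F5 F3 F1 Fz F2 F4 F6 F8 "
    "FT7 FC5 FC3 FC1 FCz FC2 FC4 FC6 FT8 T7 C5 C3 C1 Cz C2 C4 C6 T8 "
    "TP7 CP5 CP3 CP1 CPz CP2 CP4 CP6 TP8 P7 P5 P3 P1 Pz P2 P4 P6 P8 "
    "PO7 PO3 POz PO4 PO8 O1 Oz O2 AF9 AF10 FT9"
).split()


def default_forward_weights(n_sensors: int, rng, n_channels: int = 5, smooth: int = 3) -> np.ndarray:
    """Ground-truth sensor weights: standard-normal entries smoothed across
    neighboring sensors (moving average of width ``2*smooth+1``)."""
    W = rng.standard_normal((n_sensors + 2 * smooth, n_channels))
    kernel = np.ones(2 * smooth + 1) / (2 * smooth + 1)
    W = np.apply_along_axis(lambda col: np.convolve(col, kernel, mode="valid"), 0, W)
    return W


def exponential_noise_covariance(n_sensors: int, decay: float = 3.0, variance: float = 1.0) -> np.ndarray:
    """Spatial noise covariance with exponentially decaying neighbor
    correlation, corr(i, j) = exp(-|i-j| / decay) — the high adjacent-sensor
    correlation regime that motivates covariance-aware filters."""
    idx = np.arange(n_sensors)
    return variance * np.exp(-np.abs(idx[:, None] - idx[None, :]) / decay)


@dataclass
class TuningConfig:
    """Ground truth for the EEG generator.

    ``snr`` is the ratio of signal RMS (within the nonzero part of the
    temporal profile) to noise RMS; 0 means pure noise.
    """

    n_sensors: int = 64
    true_forward_weights: np.ndarray | None = None
    signal_window_ms: tuple = (50.0, 300.0)
    noise_decay: float = 3.0
    snr: float = 1.0
    basis: BasisSet = field(default_factory=BasisSet)

    def noise_covariance(self) -> np.ndarray:
        return exponential_noise_covariance(self.n_sensors, self.noise_decay)


@dataclass
class EpochedDataset:
    """Trials x sensors x timepoints array plus its trial schedule."""

    data: np.ndarray
    sampling_rate_hz: float
    epoch_window_ms: tuple
    sensor_labels: list
    schedule: pd.DataFrame
    ground_truth: TuningConfig | None = None

    def __post_init__(self):
        n_time = int(round(
            (self.epoch_window_ms[1] - self.epoch_window_ms[0]) / 1000.0
            * self.sampling_rate_hz
        ))
        if self.data.shape[2] != n_time:
            raise ValueError(
                f"data has {self.data.shape[2]} timepoints; window/rate imply {n_time}"
            )
        if self.data.shape[0] != len(self.schedule):
            raise ValueError("trials dimension does not match schedule length")

    @property
    def times_ms(self) -> np.ndarray:
        n = self.data.shape[2]
        return self.epoch_window_ms[0] + np.arange(n) * 1000.0 / self.sampling_rate_hz


def _temporal_profile(times_ms: np.ndarray, window_ms) -> np.ndarray:
    """Unit-amplitude raised-cosine gain over the signal window, 0 outside."""
    lo, hi = window_ms
    profile = np.zeros_like(times_ms)
    inside = (times_ms >= lo) & (times_ms <= hi)
    phase = (times_ms[inside] - lo) / (hi - lo)
    profile[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
    return profile


def simulate_eeg(
    schedule: pd.DataFrame,
    tuning: TuningConfig | None = None,
    seed: int = 0,
    sampling_rate_hz: float = 256.0,
    epoch_window_ms: tuple = (-200.0, 500.0),
) -> EpochedDataset:
    """Generate orientation-tuned epochs: W_true . c(theta) . profile(t) + noise."""
    if len(schedule) == 0:
        raise ValueError("schedule is empty")
    tuning = tuning or TuningConfig()
    if tuning.snr < 0:
        raise ValueError("snr must be nonnegative")
    rng = np.random.default_rng(seed)
    n_trials = len(schedule)
    n_sensors = tuning.n_sensors
    n_time = int(round(
        (epoch_window_ms[1] - epoch_window_ms[0]) / 1000.0 * sampling_rate_hz
    ))
    times = epoch_window_ms[0] + np.arange(n_time) * 1000.0 / sampling_rate_hz

    cov = tuning.noise_covariance()
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"noise covariance is not positive definite: {err}") from err

    W = tuning.true_forward_weights
    if W is None:
        W = default_forward_weights(n_sensors, rng, tuning.basis.n_channels)
    tuning.true_forward_weights = W

    noise = rng.standard_normal((n_trials, n_sensors, n_time))
    noise = np.einsum("ps,tsn->tpn", L, noise)

    theta = schedule["target_orientation_deg"].to_numpy()
    C = channel_responses(theta, tuning.basis)           # (5, n_trials)
    profile = _temporal_profile(times, tuning.signal_window_ms)
    signal = np.einsum("pk,kt,n->tpn", W, C, profile)

    if tuning.snr > 0:
        active = profile > 0
        sig_rms = np.sqrt(np.mean(signal[:, :, active] ** 2)) if active.any() else 0.0
        noise_rms = np.sqrt(np.mean(noise**2))
        if sig_rms > 0:
            signal *= tuning.snr * noise_rms / sig_rms
        data = signal + noise
    else:
        data = noise

    labels = list(SENSOR_LABELS_64[:n_sensors])
    if len(labels) < n_sensors:
        labels += [f"EXT{i}" for i in range(n_sensors - len(labels))]
    return EpochedDataset(
        data=data,
        sampling_rate_hz=sampling_rate_hz,
        epoch_window_ms=epoch_window_ms,
        sensor_labels=labels,
        schedule=schedule.reset_index(drop=True),
        ground_truth=tuning,
    )


@dataclass
class BehaviorGroundTruth:
    """Per-cell mixture parameters for reproduction responses.

    ``kappa`` is the von Mises concentration on the doubled-angle circle;
    ``guess_rate`` is the uniform-component weight.
    """

    kappa_per_cell: dict = field(default_factory=lambda: {c: 8.0 for c in CELLS})
    guess_rate_per_cell: dict = field(default_factory=lambda: {c: 0.25 for c in CELLS})

    def __post_init__(self):
        for c in CELLS:
            if self.kappa_per_cell[c] < 0:
                raise ValueError("kappa must be nonnegative")
            if not 0.0 <= self.guess_rate_per_cell[c] <= 1.0:
                raise ValueError("guess rate must lie in [0, 1]")


def simulate_behavior(schedule: pd.DataFrame, truth: BehaviorGroundTruth | None = None,
                      seed: int = 0) -> np.ndarray:
    """Per-trial reproduction responses (deg in [0, 180)).

    With probability g the response is uniform; otherwise the doubled error
    (in radians) is von Mises(0, kappa) around the target.
    """
    truth = truth or BehaviorGroundTruth()
    rng = np.random.default_rng(seed)
    labels = cell_labels(schedule)
    target = schedule["target_orientation_deg"].to_numpy()
    n = len(schedule)
    responses = np.empty(n)
    guess = rng.uniform(0.0, 1.0, size=n)
    for cell in CELLS:
        members = np.flatnonzero(labels == cell)
        if members.size == 0:
            continue
        g = truth.guess_rate_per_cell[cell]
        kappa = truth.kappa_per_cell[cell]
        doubled = rng.vonmises(0.0, kappa, size=members.size)  # radians on 360-deg circle
        err_deg = np.rad2deg(doubled) / 2.0                    # (-90, 90]
        resp = (target[members] + err_deg) % 180.0
        is_guess = guess[members] < g
        resp[is_guess] = rng.uniform(0.0, 180.0, size=int(is_guess.sum()))
        responses[members] = resp
    return responses


@dataclass
class PupilGroundTruth:
    """Ground truth for the pupil-trace generator.

    Dilation amplitudes are in z-like units: the stochastic background
    (drift + white noise) is standardized to unit SD, and the dilation
    kernel is scaled to unit mean over the 1.5 s post-onset response window,
    so a cell's amplitude equals the expected post-onset epoch mean it adds.
    """

    dilation_amplitude_per_cell: dict = field(
        default_factory=lambda: {"VEME": 0.5, "VEMU": 0.7, "VUME": 0.5, "VUMU": 0.9}
    )
    kernel_latency_ms: float = 930.0
    kernel_shape: float = 10.1
    blink_rate_hz: float = 0.05
    blink_duration_ms: tuple = (100.0, 300.0)
    outlier_rate: float = 1e-4
    baseline_drift_sd: float = 1.0
    measurement_noise_sd: float = 0.15

    def __post_init__(self):
        if self.blink_rate_hz < 0 or self.outlier_rate < 0:
            raise ValueError("rates must be nonnegative")


@dataclass
class PupilTrace:
    """Continuous pupil-diameter recording with annotations."""

    time_ms: np.ndarray
    diameter: np.ndarray          # NaN at missing (blink) samples
    missing: np.ndarray           # bool mask, True where blink-lost
    events: pd.DataFrame          # columns: time_ms, trial_index, cell
    blinks: list                  # list of (onset_ms, offset_ms)
    sampling_rate_hz: float


def _pupil_kernel(fs: float, latency_ms: float, shape: float,
                  response_window_ms: float = 1500.0) -> np.ndarray:
    """Gamma-family dilation kernel (Hoeks-Levelt form), scaled to unit mean
    over the post-onset response window."""
    t = np.arange(1, int(4 * latency_ms / 1000.0 * fs)) / fs * 1000.0
    h = (t / latency_ms) ** shape * np.exp(shape * (1.0 - t / latency_ms))
    n_win = int(response_window_ms / 1000.0 * fs)
    h /= np.mean(h[:n_win])
    return h


def simulate_pupil(
    schedule: pd.DataFrame,
    truth: PupilGroundTruth | None = None,
    sampling_rate_hz: float = 1000.0,
    seed: int = 0,
    inter_trial_ms: float = 4000.0,
    pad_ms: float = 5000.0,
) -> PupilTrace:
    """Continuous pupil trace with per-trial event-locked dilations."""
    if sampling_rate_hz < 250.0:
        raise ValueError("sampling rate must be at least 250 Hz")
    truth = truth or PupilGroundTruth()
    rng = np.random.default_rng(seed)
    n_trials = len(schedule)
    fs = float(sampling_rate_hz)
    n_samples = int((pad_ms * 2 + n_trials * inter_trial_ms) / 1000.0 * fs)
    time_ms = np.arange(n_samples) / fs * 1000.0

    # stochastic background standardized to unit SD so dilation amplitudes
    # are in z-like units.  The slow component is a hippus-like bounded
    # oscillation (~0.1 Hz, random phase/frequency): its variance survives a
    # physiological (~4 Hz) low-pass, and being bounded (peak = sqrt(2) SD)
    # it stays inside the 2.5-MAD outlier fence downstream
    t_s = np.arange(n_samples) / fs
    f_hippus = rng.uniform(0.08, 0.15)
    drift = np.sqrt(2.0) * np.sin(2.0 * np.pi * f_hippus * t_s + rng.uniform(0, 2 * np.pi))
    drift *= truth.baseline_drift_sd
    noise = rng.standard_normal(n_samples) * truth.measurement_noise_sd
    background = drift + noise
    background /= max(np.std(background), 1e-12)

    kernel = _pupil_kernel(fs, truth.kernel_latency_ms, truth.kernel_shape)
    labels = cell_labels(schedule)
    onsets_ms = pad_ms + np.arange(n_trials) * inter_trial_ms
    diameter = background.copy()
    for j in range(n_trials):
        amp = truth.dilation_amplitude_per_cell[labels[j]]
        start = int(round(onsets_ms[j] / 1000.0 * fs))
        stop = min(start + kernel.size, n_samples)
        diameter[start:stop] += amp * kernel[: stop - start]

    # outlier spikes
    n_out = rng.binomial(n_samples, truth.outlier_rate)
    if n_out:
        pos = rng.choice(n_samples, size=n_out, replace=False)
        diameter[pos] += rng.choice([-1.0, 1.0], size=n_out) * rng.uniform(8.0, 15.0, size=n_out)

    # blinks: Poisson-count missing segments
    missing = np.zeros(n_samples, dtype=bool)
    blinks = []
    duration_s = n_samples / fs
    n_blinks = rng.poisson(truth.blink_rate_hz * duration_s)
    margin_ms = 300.0  # keep blinks disjoint so each leaves one missing segment
    for _ in range(n_blinks):
        for _attempt in range(100):
            onset = rng.uniform(0.0, time_ms[-1] - truth.blink_duration_ms[1])
            dur = rng.uniform(*truth.blink_duration_ms)
            if all(onset > b1 + margin_ms or onset + dur < b0 - margin_ms
                   for b0, b1 in blinks):
                break
        else:
            continue
        i0 = int(round(onset / 1000.0 * fs))
        i1 = min(int(round((onset + dur) / 1000.0 * fs)), n_samples)
        missing[i0:i1] = True
        blinks.append((onset, onset + dur))
    diameter[missing] = np.nan

    events = pd.DataFrame(
        {"time_ms": onsets_ms, "trial_index": schedule["trial_index"].to_numpy(),
         "cell": labels}
    )
    return PupilTrace(time_ms, diameter, missing, events, blinks, fs)
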