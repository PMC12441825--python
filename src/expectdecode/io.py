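"""File I/O: schedule/behavior/pupil CSV, epoch HDF5, EyeLink ASC subset.

All round-trips reproduce the data to declared precision (HDF5 bit-exact,
CSV to float repr).  The EyeLink reader covers the minimal monocular subset
needed here: tab-separated sample lines (time, x, y, pupil) and
SBLINK/EBLINK event lines; samples inside blinks are marked missing.
Optional BrainVision/EDF ingest delegates to MNE when it is installed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .schedule import SCHEDULE_COLUMNS
from .synth import EpochedDataset, PupilTrace

__all__ = [
    "write_schedule_csv", "read_schedule_csv",
    "write_behavior_csv", "read_behavior_csv",
    "save_epochs_h5", "load_epochs_h5",
    "write_pupil_csv", "read_pupil_csv",
    "read_eyelink_asc",
    "read_brainvision", "read_edf",
]


def write_schedule_csv(schedule: pd.DataFrame, path) -> None:
    schedule.to_csv(path, index=False, columns=list(SCHEDULE_COLUMNS))


def read_schedule_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SCHEDULE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"schedule file {path} lacks columns {sorted(missing)}")
    return df


def write_behavior_csv(schedule: pd.DataFrame, responses_deg, path,
                       subject: int = 0) -> None:
    out = pd.DataFrame({
        "subject": subject,
        "trial": schedule["trial_index"].to_numpy(),
        "visual_expected": schedule["visual_expected"].to_numpy(),
        "motor_expected": schedule["motor_expected"].to_numpy(),
        "target_deg": schedule["target_orientation_deg"].to_numpy(),
        "response_deg": np.asarray(responses_deg, dtype=float),
    })
    out.to_csv(path, index=False)


def read_behavior_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject", "trial", "visual_expected", "motor_expected",
                "target_deg", "response_deg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"behavior file {path} lacks columns {sorted(missing)}")
    return df


def save_epochs_h5(dataset: EpochedDataset, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=dataset.data)
        f.create_dataset("labels", data=np.array(dataset.sensor_labels, dtype="S16"))
        grp = f.create_group("schedule")
        for col in dataset.schedule.columns:
            vals = dataset.schedule[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype("S32")
            grp.create_dataset(col, data=vals)
        meta = f.create_group("meta")
        meta.attrs["sampling_rate_hz"] = dataset.sampling_rate_hz
        meta.attrs["epoch_window_ms"] = list(dataset.epoch_window_ms)


def load_epochs_h5(path) -> EpochedDataset:
    import h5py

    with h5py.File(path, "r") as f:
        data = f["data"][()]
        labels = [s.decode() for s in f["labels"][()]]
        sched = {}
        for col in f["schedule"]:
            vals = f["schedule"][col][()]
            if vals.dtype.kind == "S":
                vals = np.char.decode(vals)
            sched[col] = vals
        meta = f["meta"].attrs
        return EpochedDataset(
            data=data,
            sampling_rate_hz=float(meta["sampling_rate_hz"]),
            epoch_window_ms=tuple(meta["epoch_window_ms"]),
            sensor_labels=labels,
            schedule=pd.DataFrame(sched),
        )


def write_pupil_csv(trace: PupilTrace, path, events_path=None) -> None:
    pd.DataFrame({
        "time_ms": trace.time_ms,
        "diameter": trace.diameter,
        "missing": trace.missing.astype(int),
    }).to_csv(path, index=False)
    if events_path is not None:
        trace.events.to_csv(events_path, index=False)


def read_pupil_csv(path, events_path=None, sampling_rate_hz=None) -> PupilTrace:
    df = pd.read_csv(path)
    for col in ("time_ms", "diameter", "missing"):
        if col not in df.columns:
            raise ValueError(f"pupil file {path} lacks column {col!r}")
    t = df["time_ms"].to_numpy(dtype=float)
    if t.size > 1 and sampling_rate_hz is None:
        sampling_rate_hz = 1000.0 / np.median(np.diff(t))
    events = pd.read_csv(events_path) if events_path else pd.DataFrame(
        columns=["time_ms", "trial_index", "cell"]
    )
    return PupilTrace(
        time_ms=t,
        diameter=df["diameter"].to_numpy(dtype=float),
        missing=df["missing"].to_numpy() != 0,
        events=events,
        blinks=[],
        sampling_rate_hz=float(sampling_rate_hz),
    )


def read_eyelink_asc(path, sampling_rate_hz: float = 1000.0) -> PupilTrace:
    """Read the SAMPLES + SBLINK/EBLINK subset of an EyeLink ASC export."""
    times, pupil = [], []
    blinks = []
    open_blink = None
    with open(path) as f:
        for lineno, line in enumerate(f, start=1):
            parts = line.split()
            if not parts:
                continue
            tag = parts[0]
            if tag == "SBLINK":
                open_blink = float(parts[2])
            elif tag == "EBLINK":
                if len(parts) < 4:
                    raise ValueError(f"{path}:{lineno}: malformed EBLINK line")
                blinks.append((float(parts[2]), float(parts[3])))
                open_blink = None
            elif tag[0].isdigit():
                if len(parts) < 4:
                    raise ValueError(
                        f"{path}:{lineno}: sample line has {len(parts)} fields, "
                        "expected at least 4 (time, x, y, pupil)"
                    )
                times.append(float(parts[0]))
                try:
                    pupil.append(float(parts[3]))
                except ValueError:
                    pupil.append(np.nan)  # '.' placeholder during blinks
    if open_blink is not None:
        blinks.append((open_blink, times[-1] if times else open_blink))
    t = np.asarray(times)
    d = np.asarray(pupil)
    missing = ~np.isfinite(d)
    for b0, b1 in blinks:
        missing |= (t >= b0) & (t <= b1)
    d = np.where(missing, np.nan, d)
    return PupilTrace(
        time_ms=t - (t[0] if t.size else 0.0),
        diameter=d, missing=missing,
        events=pd.DataFrame(columns=["time_ms", "trial_index", "cell"]),
        blinks=blinks, sampling_rate_hz=sampling_rate_hz,
    )


def _require_mne():
    try:
        import mne
    except ImportError as err:  # pragma: no cover
        raise ImportError(
            "optional raw-EEG ingest requires MNE (pip install expectdecode[ingest])"
        ) from err
    return mne


def read_brainvision(vhdr_path):
    """Optional ingest of a BrainVision recording (returns an MNE Raw)."""
    return _require_mne().io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")


def read_edf(path):
    """Optional ingest of an EDF recording (returns an MNE Raw)."""
    return _require_mne().io.read_raw_edf(path, preload=True, verbose="error")
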