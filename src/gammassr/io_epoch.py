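"""Recording/event containers, EDF and CSV I/O, stimulus-locked epoching and rejection.

The processing chain mirrors standard telemetry-EEG practice: the continuous
signal is cut into fixed windows around stimulus triggers, each epoch is
offset-corrected by subtracting its own median, and epochs containing samples
beyond an absolute amplitude threshold are flagged as artifacts. Order is
fixed: extract -> offset-correct -> reject.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    EmptyInputError,
    IntegrityError,
    ParseError,
)

logger = logging.getLogger(__name__)

DEFAULT_EPOCH_WINDOW = (-0.500, 1.000)  # seconds around stimulus onset
DEFAULT_REJECT_UV = 300.0  # absolute single-sample threshold, µV


@dataclass
class Recording:
    """Continuous multi-channel EEG in µV.

    Parameters
    ----------
    channels
        Channel labels, e.g. ``["global_cortex", "auditory_cortex"]``.
    fs
        Sampling rate in Hz.
    data
        Array of shape ``(n_channels, n_samples)``, physical units µV.
    start_time
        Time of the first sample in seconds.
    """

    channels: list[str]
    fs: float
    data: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ConfigurationError(f"sampling rate must be positive, got {self.fs}")
        if self.data.shape[0] != len(self.channels):
            raise IntegrityError(
                f"{len(self.channels)} channel labels but data has "
                f"{self.data.shape[0]} rows"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.fs


@dataclass
class EventSeries:
    """Stimulus onset times in seconds, strictly increasing."""

    onsets: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.onsets.ndim != 1:
            raise IntegrityError("onsets must be a 1-D array")
        if self.onsets.size > 1 and not np.all(np.diff(self.onsets) > 0):
            raise IntegrityError("onsets must be strictly increasing")

    def __len__(self) -> int:
        return self.onsets.size


@dataclass
class EpochSet:
    """Fixed-length signal segments plus a rejection mask.

    ``data`` has shape ``(n_epochs, n_channels, n_samples)``. ``rejected`` is a
    boolean mask over epochs and ``reject_reason`` holds a short code per epoch
    (empty string for retained epochs). ``n_dropped_events`` counts trigger
    events whose window fell outside the recording.
    """

    window: tuple[float, float]
    fs: float
    channels: list[str]
    data: np.ndarray
    rejected: np.ndarray = field(default=None)  # type: ignore[assignment]
    reject_reason: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_dropped_events: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise IntegrityError("epoch data must be (n_epochs, n_channels, n_samples)")
        if self.rejected is None:
            self.rejected = np.zeros(self.data.shape[0], dtype=bool)
        self.rejected = np.asarray(self.rejected, dtype=bool)
        if self.reject_reason is None:
            self.reject_reason = np.array([""] * self.data.shape[0], dtype=object)
        if self.rejected.shape[0] != self.data.shape[0]:
            raise IntegrityError("rejection mask length must equal epoch count")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def n_retained(self) -> int:
        return int((~self.rejected).sum())

    @property
    def times(self) -> np.ndarray:
        """Sample times relative to the stimulus onset."""
        return self.window[0] + np.arange(self.n_samples) / self.fs

    def retained(self) -> np.ndarray:
        """Data of the retained epochs only."""
        return self.data[~self.rejected]


# ---------------------------------------------------------------------------
# EDF writing (hand-written 16-bit encoder) and reading (mne)
# ---------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(rec: Recording, path: str) -> None:
    """Minimal EDF writer: 1-s data records, 16-bit, physical units µV.

    The final record is zero-padded; callers wanting exact round trips should
    use integer-second durations.
    """
    if abs(rec.fs - round(rec.fs)) > 1e-9:
        raise ConfigurationError("EDF writing requires an integer sampling rate")
    fs = int(round(rec.fs))
    n_ch = len(rec.channels)
    n_records = int(np.ceil(rec.n_samples / fs))
    pmax = float(np.max(np.abs(rec.data))) if rec.data.size else 1.0
    if pmax == 0:
        pmax = 1.0
    dig_max, dig_min = 32767, -32768
    scale = pmax / dig_max

    header = b""
    header += _edf_field("0", 8)
    header += _edf_field("X X X X", 80)  # local patient id
    header += _edf_field("Startdate X gammassr synthetic", 80)
    header += _edf_field("01.01.00", 8)
    header += _edf_field("00.00.00", 8)
    header += _edf_field(str(256 * (1 + n_ch)), 8)
    header += _edf_field("", 44)
    header += _edf_field(str(n_records), 8)
    header += _edf_field("1", 8)  # record duration, seconds
    header += _edf_field(str(n_ch), 4)
    for lab in rec.channels:
        header += _edf_field(lab, 16)
    header += b"".join(_edf_field("", 80) for _ in range(n_ch))
    header += b"".join(_edf_field("uV", 8) for _ in range(n_ch))
    header += b"".join(_edf_field(f"{-pmax:.6g}"[:8], 8) for _ in range(n_ch))
    header += b"".join(_edf_field(f"{pmax:.6g}"[:8], 8) for _ in range(n_ch))
    header += b"".join(_edf_field(str(dig_min), 8) for _ in range(n_ch))
    header += b"".join(_edf_field(str(dig_max), 8) for _ in range(n_ch))
    header += b"".join(_edf_field("", 80) for _ in range(n_ch))
    header += b"".join(_edf_field(str(fs), 8) for _ in range(n_ch))
    header += b"".join(_edf_field("", 32) for _ in range(n_ch))

    padded = np.zeros((n_ch, n_records * fs))
    padded[:, : rec.n_samples] = rec.data
    digital = np.clip(np.round(padded / scale), dig_min, dig_max).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())


def _read_edf(path: str) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # mne loads EDF in volts
    return Recording(channels=list(raw.ch_names), fs=float(raw.info["sfreq"]), data=data_uv)


def _write_csv(rec: Recording, path: str) -> None:
    df = pd.DataFrame({"time_s": rec.times})
    for i, lab in enumerate(rec.channels):
        df[lab] = rec.data[i]
    df.to_csv(path, index=False)


def _read_csv(path: str) -> Recording:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed structure
        raise ParseError(f"could not parse columnar recording {path}: {exc}") from exc
    if "time_s" not in df.columns:
        raise ParseError(f"{path}: missing required 'time_s' column")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any() and not df[col].isna().any():
            row = int(numeric.index[numeric.isna()][0])
            raise ParseError(f"{path}: non-numeric value in column '{col}' at row {row}")
        df[col] = numeric
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ParseError(f"{path}: need at least 2 samples to infer sampling rate")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise IntegrityError(f"{path}: time column is not uniformly sampled")
    chans = [c for c in df.columns if c != "time_s"]
    return Recording(
        channels=chans,
        fs=1.0 / float(dt[0]),
        data=df[chans].to_numpy().T,
        start_time=float(t[0]),
    )


def write_recording(rec: Recording, path: str, format: str = "edf") -> None:
    """Write a recording to EDF (16-bit) or columnar CSV (time_s + one column/channel)."""
    if format == "edf":
        _write_edf(rec, path)
    elif format == "csv":
        _write_csv(rec, path)
    else:
        raise ConfigurationError(f"unknown recording format {format!r}")


def read_recording(path: str, format: str = "edf") -> Recording:
    """Read a recording from EDF (via mne) or columnar CSV."""
    if format == "edf":
        return _read_edf(path)
    if format == "csv":
        return _read_csv(path)
    raise ConfigurationError(f"unknown recording format {format!r}")


def write_events(ev: EventSeries, path: str) -> None:
    pd.DataFrame({"onset_s": ev.onsets}).to_csv(path, index=False)


def read_events(path: str) -> EventSeries:
    df = pd.read_csv(path)
    if "onset_s" not in df.columns:
        raise ParseError(f"{path}: missing required 'onset_s' column")
    vals = pd.to_numeric(df["onset_s"], errors="coerce")
    if vals.isna().any():
        row = int(vals.index[vals.isna()][0])
        raise ParseError(f"{path}: non-numeric onset at row {row}")
    return EventSeries(onsets=vals.to_numpy())


def write_epochs(es: EpochSet, path: str) -> None:
    """Single-file archive: JSON header + float32 payload (npz)."""
    np.savez(
        path,
        header=json.dumps(
            {
                "window": list(es.window),
                "fs": es.fs,
                "channels": es.channels,
                "n_dropped_events": es.n_dropped_events,
            }
        ),
        data=es.data.astype(np.float32),
        rejected=es.rejected,
        reject_reason=np.asarray(es.reject_reason, dtype=str),
    )


def read_epochs(path: str) -> EpochSet:
    with np.load(path, allow_pickle=False) as z:
        hdr = json.loads(str(z["header"]))
        return EpochSet(
            window=tuple(hdr["window"]),
            fs=hdr["fs"],
            channels=hdr["channels"],
            data=z["data"].astype(float),
            rejected=z["rejected"],
            reject_reason=z["reject_reason"].astype(object),
            n_dropped_events=hdr["n_dropped_events"],
        )


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------

def extract_epochs(
    rec: Recording,
    ev: EventSeries,
    window: tuple[float, float] = DEFAULT_EPOCH_WINDOW,
) -> EpochSet:
    """Cut stimulus-locked epochs on ``window`` seconds around each onset.

    Events whose window falls outside the recording are dropped (never
    zero-padded) and counted in ``n_dropped_events``. Raises
    :class:`EmptyInputError` if no event is extractable.
    """
    t_min, t_max = window
    if t_max <= t_min:
        raise ConfigurationError(f"empty epoch window {window}")
    n_samp = int(round((t_max - t_min) * rec.fs))
    starts = np.round((ev.onsets + t_min - rec.start_time) * rec.fs).astype(int)
    ok = (starts >= 0) & (starts + n_samp <= rec.n_samples)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("extract_epochs: dropped %d events outside the recording", n_dropped)
    if not ok.any():
        raise EmptyInputError("no stimulus window fits inside the recording")
    idx = starts[ok][:, None] + np.arange(n_samp)[None, :]
    data = rec.data[:, idx]  # (n_ch, n_ev, n_samp)
    return EpochSet(
        window=(t_min, t_max),
        fs=rec.fs,
        channels=list(rec.channels),
        data=np.transpose(data, (1, 0, 2)),
        n_dropped_events=n_dropped,
    )


def offset_correct(es: EpochSet) -> EpochSet:
    """Subtract, per epoch and channel, the median over the whole epoch."""
    if es.n_epochs == 0:
        raise EmptyInputError("no epochs to offset-correct")
    med = np.median(es.data, axis=2, keepdims=True)
    return replace(es, data=es.data - med, rejected=es.rejected.copy(),
                   reject_reason=es.reject_reason.copy())


def reject_epochs(
    es: EpochSet,
    threshold: float = DEFAULT_REJECT_UV,
    per_channel: bool = False,
) -> EpochSet:
    """Flag epochs with any sample strictly beyond ±``threshold`` µV.

    The comparison is strict ("exceeds"): samples at exactly ±threshold are
    retained. By default an epoch bad on any channel is dropped for all
    channels (conservative joint rule); ``per_channel=True`` is accepted for
    the mask computation but the stored mask stays per-epoch, taking the OR
    across channels.
    """
    if threshold <= 0:
        raise ConfigurationError("rejection threshold must be positive")
    bad_samples = np.abs(es.data) > threshold  # strict
    bad_epoch = bad_samples.any(axis=(1, 2)) if not per_channel else bad_samples.any(axis=2).any(axis=1)
    rejected = es.rejected | bad_epoch
    reasons = es.reject_reason.copy()
    newly = bad_epoch & ~es.rejected
    reasons[newly] = "amplitude"
    n_new = int(newly.sum())
    if n_new:
        logger.info("reject_epochs: rejected %d/%d epochs at ±%g µV", n_new, es.n_epochs, threshold)
    return replace(es, data=es.data, rejected=rejected, reject_reason=reasons)
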