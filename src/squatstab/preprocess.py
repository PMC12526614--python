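"""Raw stream ingest, cross-modality synchronization, and low-pass filtering.

A recording session produces two independently clocked streams: camera-derived
joint positions (mediolateral knee coordinates and vertical torso position,
nominally ~60 Hz, meters) and force-plate center-of-pressure coordinates
(mediolateral/anteroposterior, nominally 50 Hz, millimeters by force-plate
convention). The two devices start a few seconds apart, so the first step is
to linearly interpolate both onto one uniform grid covering only the interval
where both have data. All channels are then zero-phase low-pass filtered
(4th-order Butterworth, 5 Hz cutoff by default) so that segmentation timing
is not lagged by the filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .errors import IngestError, ParameterError, SynchronizationError

logger = logging.getLogger(__name__)

#: canonical channel names per modality, in CSV column order
CAMERA_CHANNELS = ("x_left_knee", "x_right_knee", "y_torso")
PLATE_CHANNELS = ("cop_x", "cop_y")

#: mapping from raw camera column names to SyncedSession channel names
_CAMERA_MAP = {"x_left_knee": "x_lk", "x_right_knee": "x_rk", "y_torso": "y_torso"}

DEFAULT_CUTOFF_HZ = 5.0
DEFAULT_FILTER_ORDER = 4
DEFAULT_GRID_RATE_HZ = 50.0


@dataclass
class SensorStream:
    """One raw time-stamped multichannel recording from a single modality.

    ``units`` records the physical unit of every channel ('m' or 'mm');
    force-plate CoP is conventionally recorded in millimeters and is
    converted to meters when the stream enters a :class:`SyncedSession`.
    """

    modality: str  # 'camera' | 'plate'
    timestamps: np.ndarray  # seconds, strictly increasing
    channels: dict[str, np.ndarray] = field(default_factory=dict)
    nominal_rate: float = 0.0
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        for name, ch in self.channels.items():
            arr = np.asarray(ch, dtype=float)
            if arr.shape != self.timestamps.shape:
                raise IngestError(
                    f"channel {name!r} length {arr.size} != {self.timestamps.size} timestamps"
                )
            self.channels[name] = arr
        if self.timestamps.size >= 2:
            dt = np.diff(self.timestamps)
            bad = np.flatnonzero(dt <= 0)
            if bad.size:
                raise IngestError(
                    f"timestamps not strictly increasing at row {int(bad[0]) + 1} "
                    f"(t={self.timestamps[bad[0] + 1]!r})"
                )

    @property
    def start(self) -> float:
        return float(self.timestamps[0])

    @property
    def end(self) -> float:
        return float(self.timestamps[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_sec": self.timestamps, **self.channels})

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9g")


@dataclass
class SyncedSession:
    """Both modalities on one uniform time grid, all channels in meters."""

    subject: int
    t: np.ndarray  # uniform grid, seconds
    dt: float
    data: dict[str, np.ndarray]  # x_lk, x_rk, y_torso, cop_x, cop_y

    CHANNELS = ("x_lk", "x_rk", "y_torso", "cop_x", "cop_y")

    @property
    def n(self) -> int:
        return self.t.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_sec": self.t, **{c: self.data[c] for c in self.CHANNELS}})

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def read_csv(cls, path, subject: int = 0) -> "SyncedSession":
        df = pd.read_csv(path)
        t = df["t_sec"].to_numpy()
        dt = float(np.median(np.diff(t)))
        return cls(subject=subject, t=t, dt=dt,
                   data={c: df[c].to_numpy() for c in cls.CHANNELS})


def read_stream(path, modality: str) -> SensorStream:
    """Read one stream CSV (``t_sec`` + channel columns) and validate it.

    Rows containing non-finite values are dropped (count logged). Non-monotone
    or duplicated timestamps raise :class:`IngestError` naming the row.
    Force-plate CoP columns are tagged as millimeters for later conversion.
    """
    if modality not in ("camera", "plate"):
        raise IngestError(f"unknown modality {modality!r}")
    df = pd.read_csv(path)
    required = ("t_sec",) + (CAMERA_CHANNELS if modality == "camera" else PLATE_CHANNELS)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise IngestError(f"{path}: missing required column(s) {missing}")
    df = df[list(required)]
    finite = np.isfinite(df.to_numpy(dtype=float)).all(axis=1)
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.warning("%s: dropped %d row(s) with non-finite values", path, n_dropped)
        df = df.loc[finite]
    t = df["t_sec"].to_numpy(dtype=float)
    if t.size >= 2:
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            raise IngestError(
                f"{path}: timestamps not strictly increasing at row {int(bad[0]) + 1}"
            )
    rate = float(1.0 / np.median(np.diff(t))) if t.size >= 2 else 0.0
    unit = "m" if modality == "camera" else "mm"
    channels = {c: df[c].to_numpy(dtype=float) for c in required[1:]}
    return SensorStream(modality=modality, timestamps=t, channels=channels,
                        nominal_rate=rate, units={c: unit for c in channels})


def _to_meters(values: np.ndarray, unit: str) -> np.ndarray:
    if unit == "m":
        return values
    if unit == "mm":
        return values * 1e-3
    raise ParameterError(f"unknown unit {unit!r}")


def synchronize(camera: SensorStream, plate: SensorStream,
                target_rate: float = DEFAULT_GRID_RATE_HZ,
                subject: int = 0, min_overlap: float = 2.0) -> SyncedSession:
    """Resample both modalities onto one uniform grid by linear interpolation.

    The grid spans only the intersection of the two recordings (no
    extrapolation) at ``target_rate``; the default 50 Hz matches the lower of
    the two nominal device rates so no information is invented.
    """
    t0 = max(camera.start, plate.start)
    t1 = min(camera.end, plate.end)
    if t1 - t0 < min_overlap:
        raise SynchronizationError(
            f"streams overlap {t1 - t0:.3f} s < {min_overlap} s "
            f"(camera [{camera.start:.3f}, {camera.end:.3f}] s, "
            f"plate [{plate.start:.3f}, {plate.end:.3f}] s)"
        )
    dt = 1.0 / target_rate
    n = int(np.floor((t1 - t0) / dt + 1e-9)) + 1
    grid = t0 + dt * np.arange(n)

    data: dict[str, np.ndarray] = {}
    for raw, canon in _CAMERA_MAP.items():
        y = _to_meters(camera.channels[raw], camera.units.get(raw, "m"))
        data[canon] = np.interp(grid, camera.timestamps, y)
    for raw in PLATE_CHANNELS:
        y = _to_meters(plate.channels[raw], plate.units.get(raw, "mm"))
        data[raw] = np.interp(grid, plate.timestamps, y)
    return SyncedSession(subject=subject, t=grid, dt=dt, data=data)


def lowpass(session: SyncedSession, cutoff: float = DEFAULT_CUTOFF_HZ,
            order: int = DEFAULT_FILTER_ORDER, zero_phase: bool = True) -> SyncedSession:
    """Butterworth low-pass every channel; zero-phase (forward-backward) by default.

    In the default mode each tone is attenuated by |H(f)|^2 = 1/(1+(f/fc)^(2n))
    (the single-pass magnitude squared), i.e. the dB attenuation doubles
    relative to a single pass; timing of events is not lagged.
    """
    nyq = 0.5 / session.dt
    if cutoff >= nyq:
        raise ParameterError(f"cutoff {cutoff} Hz >= Nyquist {nyq} Hz of the grid")
    out = {}
    if zero_phase:
        for name, y in session.data.items():
            out[name] = _butterworth_zero_phase(y, session.dt, cutoff, order)
    else:
        b, a = signal.butter(order, cutoff, btype="low", fs=1.0 / session.dt)
        for name, y in session.data.items():
            out[name] = signal.lfilter(b, a, y)
    return replace(session, data=out)


def _butterworth_zero_phase(y: np.ndarray, dt: float, cutoff: float,
                            order: int) -> np.ndarray:
    """Zero-phase Butterworth low-pass applied spectrally.

    Multiplies the spectrum by the exact two-pass magnitude
    1/(1+(f/fc)^(2n)), i.e. the squared magnitude of an order-n Butterworth,
    after reflective (even) padding at both ends. Unlike a bilinear-designed
    IIR, the attenuation matches the analytic Butterworth response at every
    frequency, with no warping toward Nyquist.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    pad = min(n - 1, max(order + 1, int(round(3.0 / (cutoff * dt)))))
    if pad > 0:
        ext = np.concatenate((y[pad:0:-1], y, y[-2:-pad - 2:-1]))
    else:
        ext = y
    freqs = np.fft.rfftfreq(ext.size, d=dt)
    gain = 1.0 / (1.0 + (freqs / cutoff) ** (2 * order))
    filtered = np.fft.irfft(np.fft.rfft(ext) * gain, n=ext.size)
    return filtered[pad:pad + n]


def hampel(y: np.ndarray, window: int = 5, n_sigmas: float = 3.0) -> np.ndarray:
    """Optional spike pre-clean (median-filter outlier replacement); off by default
    in the pipeline — low-pass filtering alone is not outlier rejection."""
    y = np.asarray(y, dtype=float).copy()
    med = signal.medfilt(y, kernel_size=2 * window + 1)
    mad = signal.medfilt(np.abs(y - med), kernel_size=2 * window + 1)
    sigma = 1.4826 * mad
    spikes = np.abs(y - med) > n_sigmas * np.maximum(sigma, 1e-12)
    y[spikes] = med[spikes]
    return y
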