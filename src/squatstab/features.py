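"""The five per-squat features and the binary instability label.

Feature ids and channel order are a fixed contract throughout the package:

1. KS, knee shakiness (m/s): sum of the two knees' mediolateral velocity
   magnitudes per time step, from backward differences. The signed sum
   Vl+Vr is exposed too, but it cancels antiphase (valgus-like) wobble, so
   the magnitude form is the default.
2. KD, knee distance (m): mediolateral separation |x_lk - x_rk|.
3. SD, squat depth (m): standing baseline minus torso height; the per-squat
   scalar is the peak depth (positive-depth convention).
4. SV, sway velocity (m/s): per-step CoP path displacement over the time step
   (standard posturography rate form by default).
5. SA, sway area (m^2): origin-anchored shoelace triangle increments of the
   CoP trajectory; the per-squat scalar is their sum.

A squat is labeled KI (1) when the per-squat knee-shakiness statistic
(default: max of |KS|) reaches 0.03 m/s, computed on PHYSICAL units before
any amplitude normalization — the threshold is dimensional.

Axis convention: x = mediolateral, y = vertical (torso) / anteroposterior
(CoP); all series in SI units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .segment import SquatCycle, minmax_normalize, resample_series

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("ks", "kd", "sd", "sv", "sa")
FEATURE_IDS = (1, 2, 3, 4, 5)
KS_THRESHOLD_M_S = 0.03


def knee_shakiness(x_lk: np.ndarray, x_rk: np.ndarray, dt: float,
                   mode: str = "magnitude") -> np.ndarray:
    """Per-step knee shakiness from backward-difference knee velocities.

    mode='magnitude' (default) returns |Vl|+|Vr|; mode='signed' returns the
    plain sum Vl+Vr, which cancels antiphase wobble. The first sample is set
    equal to the second (no t-1 available).
    """
    if dt <= 0:
        raise ParameterError(f"dt must be positive, got {dt}")
    x_lk = np.asarray(x_lk, dtype=float)
    x_rk = np.asarray(x_rk, dtype=float)
    if x_lk.shape != x_rk.shape:
        raise ParameterError("knee series length mismatch")
    if x_lk.size < 2:
        raise ParameterError("series length must be >= 2")
    vl = np.diff(x_lk) / dt
    vr = np.diff(x_rk) / dt
    if mode == "magnitude":
        ks = np.abs(vl) + np.abs(vr)
    elif mode == "signed":
        ks = vl + vr
    else:
        raise ParameterError(f"unknown mode {mode!r}")
    return np.concatenate(([ks[0]], ks))


def knee_distance(x_lk: np.ndarray, x_rk: np.ndarray) -> np.ndarray:
    """Mediolateral knee separation |x_lk - x_rk| per sample (meters)."""
    x_lk = np.asarray(x_lk, dtype=float)
    x_rk = np.asarray(x_rk, dtype=float)
    if x_lk.shape != x_rk.shape:
        raise ParameterError("knee series length mismatch")
    return np.abs(x_lk - x_rk)


def squat_depth(y_torso: np.ndarray, y_t1: float,
                as_printed_sign: bool = False) -> tuple[np.ndarray, float]:
    """Instantaneous depth series max(0, y_t1 - y(t)) and the scalar peak depth.

    Positive-depth convention by default; ``as_printed_sign`` flips the scalar
    to the raw (negative) torso-displacement difference y_min - y_t1.
    """
    y = np.asarray(y_torso, dtype=float)
    series = np.maximum(0.0, y_t1 - y)
    scalar = float(y_t1 - y.min())
    if as_printed_sign:
        scalar = -scalar
    return series, scalar


def sway_velocity(cop_x: np.ndarray, cop_y: np.ndarray, dt: float,
                  as_printed: bool = False) -> np.ndarray:
    """CoP step displacement per time step (m/s).

    The displacement delta(t) = sqrt(dCoPx^2 + dCoPy^2) uses forward
    differences; the last sample is replicated. ``as_printed`` returns
    delta*dt instead of the standard posturographic rate delta/dt.
    """
    if dt <= 0:
        raise ParameterError(f"dt must be positive, got {dt}")
    cx = np.asarray(cop_x, dtype=float)
    cy = np.asarray(cop_y, dtype=float)
    if cx.shape != cy.shape or cx.size < 2:
        raise ParameterError("CoP series must have equal length >= 2")
    delta = np.hypot(np.diff(cx), np.diff(cy))
    sv = delta * dt if as_printed else delta / dt
    return np.concatenate((sv, [sv[-1]]))


def sway_area(cop_x: np.ndarray, cop_y: np.ndarray, dt: float,
              as_printed: bool = False,
              per_second: bool = False) -> tuple[np.ndarray, float]:
    """Origin-anchored shoelace triangle increments of the CoP path and their sum.

    Increment a(t) = |x(t+1) y(t) - x(t) y(t+1)| / 2 (m^2, always >= 0); the
    scalar is the plain sum by default, or a per-second rate with
    ``per_second``. ``as_printed`` multiplies each increment by dt. The last
    increment is replicated so the series matches the input length; the
    scalar sums only the true increments.
    """
    cx = np.asarray(cop_x, dtype=float)
    cy = np.asarray(cop_y, dtype=float)
    if cx.shape != cy.shape or cx.size < 2:
        raise ParameterError("CoP series must have equal length >= 2")
    a = np.abs(cx[1:] * cy[:-1] - cx[:-1] * cy[1:]) / 2.0
    if as_printed:
        a = a * dt
    total = float(a.sum())
    if per_second:
        total /= (cx.size - 1) * dt
    return np.concatenate((a, [a[-1]])), total


def label_squat(ks: np.ndarray, threshold: float = KS_THRESHOLD_M_S,
                stat: str = "max") -> int:
    """Binary instability label: 1 (KI) iff the |KS| statistic >= threshold.

    ``ks`` must be in physical units (m/s), pre-normalization. The boundary is
    inclusive: a statistic exactly at the threshold is labeled unstable.
    """
    ks = np.asarray(ks, dtype=float)
    if ks.size == 0:
        raise ParameterError("empty KS series")
    value = ks_statistic(ks, stat)
    return int(value >= threshold)


def ks_statistic(ks: np.ndarray, stat: str = "max") -> float:
    ks = np.asarray(ks, dtype=float)
    if stat == "max":
        return float(np.abs(ks).max())
    if stat == "mean":
        return float(np.abs(ks).mean())
    raise ParameterError(f"unknown statistic {stat!r}")


@dataclass
class SquatFeatures:
    """The five feature series of one squat (physical units, cycle-native rate)
    plus the per-squat scalar aggregates and label."""

    subject: int
    index: int
    series: dict[str, np.ndarray]  # keys FEATURE_NAMES, equal lengths
    dt: float
    ks_stat: float   # m/s, |KS| aggregate used for labeling
    sd_scalar: float  # m, peak depth
    sa_total: float   # m^2
    label: int        # 0 = NKI, 1 = KI

    @property
    def summaries(self) -> dict[str, float]:
        """Per-squat scalar summary of each feature (used by the ranking)."""
        return {
            "ks": self.ks_stat,
            "kd": float(self.series["kd"].mean()),
            "sd": self.sd_scalar,
            "sv": float(self.series["sv"].mean()),
            "sa": self.sa_total,
        }


def compute_cycle_features(cycle: SquatCycle, ks_mode: str = "magnitude",
                           threshold: float = KS_THRESHOLD_M_S,
                           label_stat: str = "max") -> SquatFeatures:
    """Compute all five feature series and the label on one physical-unit
    squat window at its native sampling rate."""
    ch = cycle.channels
    ks = knee_shakiness(ch["x_lk"], ch["x_rk"], cycle.dt, mode=ks_mode)
    kd = knee_distance(ch["x_lk"], ch["x_rk"])
    sd_series, sd_scalar = squat_depth(ch["y_torso"], cycle.y_t1)
    sv = sway_velocity(ch["cop_x"], ch["cop_y"], cycle.dt)
    sa_series, sa_total = sway_area(ch["cop_x"], ch["cop_y"], cycle.dt)
    stat = ks_statistic(ks, label_stat)
    return SquatFeatures(
        subject=cycle.subject, index=cycle.index,
        series={"ks": ks, "kd": kd, "sd": sd_series, "sv": sv, "sa": sa_series},
        dt=cycle.dt, ks_stat=stat, sd_scalar=sd_scalar, sa_total=sa_total,
        label=int(stat >= threshold))


@dataclass
class LabeledDataset:
    """Tensor of squats x time steps x feature channels plus labels.

    ``X`` is min-max normalized (classifier input); ``X_phys`` keeps the
    time-normalized series in physical units (used for correlation ranking,
    which must not depend on per-subject amplitude rescaling).
    """

    X: np.ndarray        # (n, T, C) in [0, 1]
    y: np.ndarray        # (n,) int, 0 = NKI / 1 = KI
    subjects: np.ndarray  # (n,)
    feature_ids: tuple[int, ...]
    X_phys: np.ndarray | None = None
    summaries: pd.DataFrame | None = None  # per-squat scalar summaries (physical)
    truth: np.ndarray | None = None        # generator ground-truth flags, if known
    norm_record: object = None
    squat_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.X.ndim != 3:
            raise ParameterError("X must be (n_squats, n_samples, n_channels)")
        if len(self.feature_ids) != self.X.shape[2]:
            raise ParameterError("feature_ids must match the channel axis")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(FEATURE_NAMES[i - 1] for i in self.feature_ids)

    def class_counts(self) -> tuple[int, int]:
        return int((self.y == 0).sum()), int((self.y == 1).sum())


def build_dataset(features_list: list[SquatFeatures], scope: str = "per_subject",
                  n_samples: int = 20,
                  truth: np.ndarray | None = None) -> LabeledDataset:
    """Assemble the classifier dataset from per-squat features.

    Each feature series is time-normalized to ``n_samples`` points, stacked in
    the fixed channel order (KS, KD, SD, SV, SA), then min-max scaled across
    the chosen scope. Labels were computed on physical units upstream and are
    attached unchanged.
    """
    if not features_list:
        raise ParameterError("build_dataset requires at least one squat")
    mats, subjects, labels, idx = [], [], [], []
    rows = []
    for f in features_list:
        t = np.arange(next(iter(f.series.values())).size) * f.dt
        mat = np.column_stack([resample_series(t, f.series[name], n_samples)
                               for name in FEATURE_NAMES])
        mats.append(mat)
        subjects.append(f.subject)
        labels.append(f.label)
        idx.append(f.index)
        rows.append({"subject": f.subject, "squat": f.index, "label": f.label,
                     **{f"{k}_summary": v for k, v in f.summaries.items()}})
    normed, record = minmax_normalize(mats, subjects, FEATURE_NAMES, scope=scope)
    return LabeledDataset(
        X=np.stack(normed), y=np.asarray(labels, dtype=int),
        subjects=np.asarray(subjects), feature_ids=FEATURE_IDS,
        X_phys=np.stack(mats), summaries=pd.DataFrame(rows),
        truth=None if truth is None else np.asarray(truth, dtype=bool),
        norm_record=record, squat_index=np.asarray(idx))


def write_dataset(dataset: LabeledDataset, features_path, labels_path) -> None:
    """Serialize as two CSVs: long-format feature rows and per-squat labels."""
    n, T, C = dataset.X.shape
    names = dataset.feature_names
    rows = dataset.X.reshape(n * T, C)
    frame = pd.DataFrame(rows, columns=names)
    frame.insert(0, "row", np.tile(np.arange(T), n))
    frame.insert(0, "squat", np.repeat(
        dataset.squat_index if dataset.squat_index is not None else np.arange(n), T))
    frame.insert(0, "subject", np.repeat(dataset.subjects, T))
    frame.to_csv(features_path, index=False, float_format="%.9g")

    lab = pd.DataFrame({
        "subject": dataset.subjects,
        "squat": dataset.squat_index if dataset.squat_index is not None else np.arange(n),
        "label": dataset.y,
    })
    if dataset.summaries is not None:
        lab["ks_stat"] = dataset.summaries["ks_summary"].to_numpy()
    lab.to_csv(labels_path, index=False, float_format="%.9g")


def read_dataset(features_path, labels_path, n_samples: int = 20) -> LabeledDataset:
    """Load a dataset serialized by :func:`write_dataset` (normalized X only)."""
    feats = pd.read_csv(features_path)
    labels = pd.read_csv(labels_path)
    names = list(FEATURE_NAMES)
    n = len(labels)
    X = feats[names].to_numpy().reshape(n, n_samples, len(names))
    return LabeledDataset(X=X, y=labels["label"].to_numpy(dtype=int),
                          subjects=labels["subject"].to_numpy(),
                          feature_ids=FEATURE_IDS,
                          squat_index=labels["squat"].to_numpy())
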