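"""Epoch-level movement statistics from tri-axial acceleration.

The raw signal is split into a static (gravity-dominated) component,
estimated by a centred 3 s running mean per axis, and a dynamic component
(raw minus static). From the dynamic component come the dynamic body
acceleration family:

    PDBA_a = |a_dyn|                       per axis a in {x, y, z}
    ODBA   = |x_dyn| + |y_dyn| + |z_dyn|
    VeDBA  = sqrt(x_dyn^2 + y_dyn^2 + z_dyn^2)

and from the static component the posture angles (inclination, azimuth).
Traces are then summarised into fixed-length epochs (13 samples, ~0.5 s at
25 Hz) of 52 movement statistics each.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

AXES = ("x", "y", "z")

#: the 52 movement statistics, in stable column order
FEATURE_COLUMNS: tuple[str, ...] = tuple(
    [f"{ax}_{stat}" for ax in AXES
     for stat in ("mean", "median", "sd", "skew", "kurtosis", "min", "max",
                  "absmean", "invcv", "ar1")]
    + ["q_mean", "q_sd", "q_min", "q_max"]
    + ["corr_xy", "corr_yz", "corr_xz"]
    + ["incl_mean", "azim_mean"]
    + ["pdba_x_mean", "pdba_y_mean", "pdba_z_mean"]
    + ["odba_mean", "odba_sd", "odba_min", "odba_max"]
    + ["vedba_mean", "vedba_sd", "vedba_min", "vedba_max"]
    + ["odba_auc", "vedba_auc"]
)

#: metadata columns a feature table may carry alongside the statistics
META_COLUMNS = ("subject_id", "epoch_index", "epoch_start", "place", "behaviour", "category")


class NonUniformSamplingError(ValueError):
    """Raised when a trace's timestamps are not uniformly spaced."""


@dataclass
class AccelerometerTrace:
    """Uniformly sampled tri-axial acceleration for one subject-session.

    Axes follow the bio-logging convention: x = surge (anterior-posterior),
    y = sway (lateral), z = heave (dorsal-ventral). Units are g; the logger
    clips at +-8 g.
    """

    xyz: np.ndarray            # (n, 3) float array, g
    sampling_rate: float       # Hz
    place: np.ndarray | None = None   # (n,) categorical {surface, underwater, land}
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must be an (n, 3) array")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("trace contains non-finite samples")
        if np.any(np.abs(self.xyz) > 8.0 + 1e-9):
            raise ValueError("acceleration outside the +-8 g logger range")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.place is not None:
            self.place = np.asarray(self.place, dtype=object)
            if len(self.place) != len(self.xyz):
                raise ValueError("place track length mismatch")

    def __len__(self) -> int:
        return len(self.xyz)


@dataclass
class DynamicDecomposition:
    """Static/dynamic split of a trace plus derived DBA and posture series."""

    static: np.ndarray         # (n, 3)
    dynamic: np.ndarray        # (n, 3); static + dynamic == raw exactly
    pdba: np.ndarray           # (n, 3) = |dynamic|
    odba: np.ndarray           # (n,)
    vedba: np.ndarray          # (n,)
    q: np.ndarray              # (n,) raw vector magnitude
    inclination: np.ndarray    # (n,) radians in [0, pi]; NaN where static == 0
    azimuth: np.ndarray        # (n,) radians in (-pi, pi]; NaN where static == 0
    sampling_rate: float = 25.0


def _centered_running_mean(x: np.ndarray, halfwidth: int) -> np.ndarray:
    """Centred running mean with the window truncated symmetrically at the
    edges: at index i the window is [i-h_i, i+h_i] with
    h_i = min(halfwidth, i, n-1-i)."""
    n = len(x)
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    h = np.minimum(halfwidth, np.minimum(idx, n - 1 - idx))
    lo = idx - h
    hi = idx + h
    return (csum[hi + 1] - csum[lo]) / (2 * h + 1)


def decompose(trace: AccelerometerTrace, static_window_s: float = 3.0) -> DynamicDecomposition:
    """Split a trace into static and dynamic acceleration and derive the
    DBA family and posture angles.

    The static component is a centred running mean over
    ``round(static_window_s * sampling_rate)`` samples per axis (75 at
    25 Hz); the window is truncated symmetrically at the trace edges so the
    estimate stays centred. The dynamic component is raw minus static,
    elementwise.
    """
    if len(trace) < 1:
        raise ValueError("empty trace")
    if static_window_s <= 0:
        raise ValueError("static_window_s must be positive")
    window = int(round(static_window_s * trace.sampling_rate))
    halfwidth = max(window // 2, 0)

    static = np.column_stack(
        [_centered_running_mean(trace.xyz[:, k], halfwidth) for k in range(3)]
    )
    dynamic = trace.xyz - static
    pdba = np.abs(dynamic)
    odba = pdba.sum(axis=1)
    vedba = np.sqrt((dynamic ** 2).sum(axis=1))
    q = np.sqrt((trace.xyz ** 2).sum(axis=1))
    inclination, azimuth = _posture_angles(static)
    return DynamicDecomposition(
        static=static, dynamic=dynamic, pdba=pdba, odba=odba, vedba=vedba,
        q=q, inclination=inclination, azimuth=azimuth,
        sampling_rate=trace.sampling_rate,
    )


def _posture_angles(static: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mag = np.sqrt((static ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        inclination = np.arccos(np.clip(static[:, 2] / mag, -1.0, 1.0))
        azimuth = np.arctan2(static[:, 1], static[:, 0])
    # atan2 returns -pi for (y=-0, x<0); fold onto (-pi, pi]
    azimuth = np.where(azimuth == -np.pi, np.pi, azimuth)
    bad = mag == 0
    if bad.any():
        inclination = np.where(bad, np.nan, inclination)
        azimuth = np.where(bad, np.nan, azimuth)
    return inclination, azimuth


def inclination_azimuth(dec: DynamicDecomposition) -> tuple[np.ndarray, np.ndarray]:
    """Posture angles from the static component.

    inclination = arccos(static_z / |static|) in [0, pi];
    azimuth = atan2(static_y, static_x) in (-pi, pi]. Samples with zero
    static magnitude are flagged NaN and excluded from epoch means.
    """
    return dec.inclination, dec.azimuth


# ---------------------------------------------------------------------------
# epoch statistics
# ---------------------------------------------------------------------------

def _moments(w: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-epoch mean and central moments m2, m3, m4 along axis 1."""
    mean = w.mean(axis=1)
    d = w - mean[:, None]
    m2 = (d ** 2).mean(axis=1)
    m3 = (d ** 3).mean(axis=1)
    m4 = (d ** 4).mean(axis=1)
    return mean, m2, m3, m4


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    ok = den != 0
    out[ok] = num[ok] / den[ok]
    return out


def _ar1_slope(w: np.ndarray) -> np.ndarray:
    """Slope of regressing each sample on its one-sample lag, per epoch.

    Zero-variance lag series give 0 (flagged degenerate)."""
    a = w[:, :-1]
    b = w[:, 1:]
    am = a.mean(axis=1)
    bm = b.mean(axis=1)
    cov = ((a - am[:, None]) * (b - bm[:, None])).mean(axis=1)
    var = ((a - am[:, None]) ** 2).mean(axis=1)
    return _safe_div(cov, var)


def _corr(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    um = u.mean(axis=1)
    vm = v.mean(axis=1)
    du = u - um[:, None]
    dv = v - vm[:, None]
    num = (du * dv).mean(axis=1)
    den = np.sqrt((du ** 2).mean(axis=1) * (dv ** 2).mean(axis=1))
    return np.clip(_safe_div(num, den), -1.0, 1.0)


def _windows(x: np.ndarray, starts: np.ndarray, epoch_len: int) -> np.ndarray:
    idx = starts[:, None] + np.arange(epoch_len)[None, :]
    return x[idx]


def _circular_mean(w: np.ndarray) -> np.ndarray:
    """Mean direction per epoch, NaN-tolerant; NaN if no valid samples."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        s = np.nanmean(np.sin(w), axis=1)
        c = np.nanmean(np.cos(w), axis=1)
    return np.arctan2(s, c)


def epoch_features(
    dec: DynamicDecomposition,
    trace: AccelerometerTrace,
    epoch_len: int = 13,
    stride: int = 13,
) -> pd.DataFrame:
    """Summarise a decomposed trace into one row of 52 statistics per epoch.

    Epochs are windows of ``epoch_len`` samples taken every ``stride``
    samples; the default (13/13, non-overlapping) gives ~0.5 s epochs at
    25 Hz. Returns a DataFrame with the 52 ``FEATURE_COLUMNS`` plus
    ``subject_id``, ``epoch_index``, ``epoch_start`` and the modal
    ``place`` of each epoch.

    Statistic conventions: sd is the sample standard deviation (ddof=1);
    skewness and excess kurtosis are the moment estimators m3/m2^1.5 and
    m4/m2^2 - 3; the inverse coefficient of variation is mean/sd; the AR(1)
    coefficient is the OLS slope of each sample on its one-sample lag within
    the epoch; azimuth is averaged circularly. Degenerate (zero-variance)
    quantities are flagged 0.
    """
    if epoch_len < 3:
        raise ValueError("epoch_len must be >= 3 (skewness/kurtosis undefined)")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    n = len(trace)
    if epoch_len > n:
        warnings.warn(
            f"epoch_len={epoch_len} exceeds trace length {n}; returning empty table",
            stacklevel=2,
        )
        cols = list(FEATURE_COLUMNS) + ["subject_id", "epoch_index", "epoch_start", "place"]
        return pd.DataFrame(columns=cols)

    n_epochs = (n - epoch_len) // stride + 1
    starts = np.arange(n_epochs) * stride
    dt = 1.0 / dec.sampling_rate

    out: dict[str, np.ndarray] = {}
    for k, ax in enumerate(AXES):
        w = _windows(trace.xyz[:, k], starts, epoch_len)
        mean, m2, m3, m4 = _moments(w)
        sd = np.sqrt(m2 * epoch_len / (epoch_len - 1))
        out[f"{ax}_mean"] = mean
        out[f"{ax}_median"] = np.median(w, axis=1)
        out[f"{ax}_sd"] = sd
        out[f"{ax}_skew"] = _safe_div(m3, m2 ** 1.5)
        out[f"{ax}_kurtosis"] = np.where(m2 > 0, _safe_div(m4, m2 ** 2) - 3.0, 0.0)
        out[f"{ax}_min"] = w.min(axis=1)
        out[f"{ax}_max"] = w.max(axis=1)
        out[f"{ax}_absmean"] = np.abs(w).mean(axis=1)
        out[f"{ax}_invcv"] = _safe_div(mean, sd)
        out[f"{ax}_ar1"] = _ar1_slope(w)

    qw = _windows(dec.q, starts, epoch_len)
    out["q_mean"] = qw.mean(axis=1)
    out["q_sd"] = qw.std(axis=1, ddof=1)
    out["q_min"] = qw.min(axis=1)
    out["q_max"] = qw.max(axis=1)

    wx = _windows(trace.xyz[:, 0], starts, epoch_len)
    wy = _windows(trace.xyz[:, 1], starts, epoch_len)
    wz = _windows(trace.xyz[:, 2], starts, epoch_len)
    out["corr_xy"] = _corr(wx, wy)
    out["corr_yz"] = _corr(wy, wz)
    out["corr_xz"] = _corr(wx, wz)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out["incl_mean"] = np.nanmean(_windows(dec.inclination, starts, epoch_len), axis=1)
    out["azim_mean"] = _circular_mean(_windows(dec.azimuth, starts, epoch_len))

    for k, ax in enumerate(AXES):
        out[f"pdba_{ax}_mean"] = _windows(dec.pdba[:, k], starts, epoch_len).mean(axis=1)

    for name, series in (("odba", dec.odba), ("vedba", dec.vedba)):
        w = _windows(series, starts, epoch_len)
        out[f"{name}_mean"] = w.mean(axis=1)
        out[f"{name}_sd"] = w.std(axis=1, ddof=1)
        out[f"{name}_min"] = w.min(axis=1)
        out[f"{name}_max"] = w.max(axis=1)
        out[f"{name}_auc"] = np.trapezoid(w, dx=dt, axis=1)

    table = pd.DataFrame({c: out[c] for c in FEATURE_COLUMNS})
    table["subject_id"] = trace.subject_id
    table["epoch_index"] = np.arange(n_epochs)
    table["epoch_start"] = starts
    table["place"] = _modal_place(trace, starts, epoch_len)
    return table


def _modal_place(trace: AccelerometerTrace, starts: np.ndarray, epoch_len: int) -> np.ndarray:
    if trace.place is None:
        return np.full(len(starts), "surface", dtype=object)
    out = np.empty(len(starts), dtype=object)
    for i, s in enumerate(starts):
        vals, counts = np.unique(trace.place[s:s + epoch_len].astype(str), return_counts=True)
        out[i] = vals[np.argmax(counts)]
    return out


def featurize_trace(
    trace: AccelerometerTrace,
    epoch_len: int = 13,
    stride: int = 13,
    static_window_s: float = 3.0,
) -> pd.DataFrame:
    """decompose + epoch_features in one call."""
    return epoch_features(decompose(trace, static_window_s), trace, epoch_len, stride)


# ---------------------------------------------------------------------------
# session CSV I/O
# ---------------------------------------------------------------------------

def read_session_csv(path) -> tuple[AccelerometerTrace, pd.DataFrame | None]:
    """Read a session CSV (columns time/timestamp_s, x, y, z and optionally
    behaviour, category, place). Returns the trace and, when label columns
    are present, a per-sample label frame.

    The time column must be uniformly spaced; the sampling rate is inferred
    from it.
    """
    df = pd.read_csv(path)
    tcol = "timestamp_s" if "timestamp_s" in df.columns else "time"
    if tcol not in df.columns or not {"x", "y", "z"} <= set(df.columns):
        raise ValueError("session CSV needs columns time (or timestamp_s), x, y, z")
    t = df[tcol].to_numpy(dtype=float)
    if len(t) > 1:
        dts = np.diff(t)
        if np.ptp(dts) > 1e-6 * max(dts.mean(), 1e-12):
            raise NonUniformSamplingError("non-uniform sampling in session CSV")
        rate = 1.0 / dts.mean()
    else:
        rate = 25.0
    place = df["place"].to_numpy(dtype=object) if "place" in df.columns else None
    trace = AccelerometerTrace(
        xyz=df[["x", "y", "z"]].to_numpy(dtype=float),
        sampling_rate=float(rate),
        place=place,
    )
    labels = None
    if "behaviour" in df.columns:
        cols = [c for c in ("behaviour", "category") if c in df.columns]
        labels = df[cols].copy()
    return trace, labels


def write_feature_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_feature_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
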