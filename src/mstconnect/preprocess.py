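"""Motion quantification, censoring, nuisance regression and filtering.

Converts rigid-body realignment parameters and ROI time series into
censored, nuisance-regressed, band-limited data ready for spectral (ALFF)
and network (connectome) analysis.

Conventions
-----------
* Motion parameters are per-volume 6-vectors: three translations in mm
  followed by three rotations in radians (an alternate rotations-first
  dialect is available when reading files).
* Framewise displacement (FD) follows Jenkinson's RMS formulation with an
  assumed head radius (default 80 mm) and the rotation centre at the
  coordinate origin; both are configurable.
* Censored volumes are *retained* in the series after spike regression
  (their values are regressed to ~0) rather than deleted, so correlation
  estimates downstream use a common set of columns.  A deletion mode is
  available for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

__all__ = [
    "MotionTrace",
    "RoiTimeSeries",
    "NuisanceDesign",
    "compute_fd_jenkinson",
    "flag_spikes",
    "build_spike_regressors",
    "retention_decision",
    "build_design_36p",
    "regress_nuisance",
    "detrend_linear",
    "bandpass",
    "drop_dummy_volumes",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class MotionTrace:
    """Per-volume rigid-body parameters and the FD series derived from them.

    Parameters
    ----------
    params
        ``(T, 6)`` array: ``t_x, t_y, t_z`` in mm, ``r_x, r_y, r_z`` in
        radians.
    head_radius
        Assumed head radius in mm for the rotational FD contribution.
    """

    params: np.ndarray
    head_radius: float = 80.0
    fd: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("params must be a (T, 6) array")
        self.fd = compute_fd_jenkinson(self.params, self.head_radius)


@dataclass
class RoiTimeSeries:
    """One subject's ROI x volume matrix with TR, censor flags and labels."""

    values: np.ndarray
    roi_labels: list[str]
    tr_seconds: float
    censor_flags: np.ndarray | None = None
    excluded_rois: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (n_rois, n_volumes) array")
        if len(self.roi_labels) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.roi_labels)} labels for {self.values.shape[0]} rows"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.censor_flags is None:
            self.censor_flags = np.zeros(self.values.shape[1], dtype=bool)
        else:
            self.censor_flags = np.asarray(self.censor_flags, dtype=bool)
            if self.censor_flags.shape[0] != self.values.shape[1]:
                raise ValueError("censor_flags length must equal volume count")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.values.shape[1]


@dataclass
class NuisanceDesign:
    """Volume x regressor design matrix for nuisance regression.

    The base block is the 36-parameter model: Friston's 24 motion
    regressors (6 parameters, their one-volume lags, and the squares of
    both) plus 12 tissue regressors (GM/WM/CSF means, first differences,
    and the squares of both).  An intercept is always appended; a linear
    trend and per-spike indicator columns are optional.
    """

    columns: np.ndarray
    column_names: list[str]
    n_base_params: int
    includes_trend: bool
    spike_columns: int

    def __post_init__(self) -> None:
        expected = self.n_base_params + int(self.includes_trend) + self.spike_columns + 1
        if self.columns.shape[1] != expected:
            raise ValueError(
                f"design has {self.columns.shape[1]} columns, expected {expected}"
            )
        if len(self.column_names) != self.columns.shape[1]:
            raise ValueError("column_names length mismatch")

    @property
    def n_volumes(self) -> int:
        return self.columns.shape[0]


# ---------------------------------------------------------------------------
# Framewise displacement
# ---------------------------------------------------------------------------


def _rigid_transform(p: np.ndarray) -> np.ndarray:
    """4x4 homogeneous rigid transform for one parameter 6-vector.

    Rotation order R = Rz @ Ry @ Rx about the coordinate origin; the
    translation is applied after rotation.
    """
    tx, ty, tz, rx, ry, rz = p
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    T = np.eye(4)
    T[:3, :3] = Rz @ Ry @ Rx
    T[:3, 3] = (tx, ty, tz)
    return T


def compute_fd_jenkinson(params: np.ndarray, head_radius: float = 80.0) -> np.ndarray:
    """Framewise displacement (mm) per volume, Jenkinson's RMS formulation.

    For each volume ``t >= 1`` the relative transform between consecutive
    volumes, ``M = T_t @ inv(T_{t-1}) - I`` with rotational part ``A`` and
    translational part ``b``, yields

        FD_t = sqrt( (R^2 / 5) * trace(A.T @ A) + b.T @ b )

    the RMS displacement of points filling a sphere of radius ``R``
    centred at the rotation centre (here the coordinate origin).
    ``FD_0 = 0`` by convention.

    Parameters
    ----------
    params
        ``(T, 6)`` array, translations in mm then rotations in radians.
    head_radius
        Sphere radius ``R`` in mm (default 80).
    """
    params = np.asarray(params, dtype=float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError("params must be a (T, 6) array")
    if params.shape[0] < 2:
        raise ValueError("need at least 2 volumes to compute FD")
    bad = ~np.isfinite(params).all(axis=1)
    if bad.any():
        raise ValueError(f"non-finite motion parameters at volume {int(np.where(bad)[0][0])}")

    T = params.shape[0]
    fd = np.zeros(T)
    prev = _rigid_transform(params[0])
    for t in range(1, T):
        cur = _rigid_transform(params[t])
        M = cur @ np.linalg.inv(prev) - np.eye(4)
        A = M[:3, :3]
        b = M[:3, 3]
        fd[t] = np.sqrt(head_radius**2 / 5.0 * np.trace(A.T @ A) + b @ b)
        prev = cur
    return fd


# ---------------------------------------------------------------------------
# Censoring
# ---------------------------------------------------------------------------


def flag_spikes(fd: np.ndarray, threshold: float = 0.2) -> np.ndarray:
    """Flag volumes whose FD strictly exceeds ``threshold`` (mm)."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return np.asarray(fd, dtype=float) > threshold


def build_spike_regressors(flags: np.ndarray) -> np.ndarray:
    """One indicator column per flagged volume: 1 at that volume, else 0."""
    flags = np.asarray(flags, dtype=bool)
    idx = np.flatnonzero(flags)
    out = np.zeros((flags.shape[0], idx.size))
    out[idx, np.arange(idx.size)] = 1.0
    return out


def retention_decision(
    n_retained_volumes: int, tr_seconds: float, min_minutes: float = 4.0
) -> bool:
    """Keep a subject iff retained data is not strictly under ``min_minutes``.

    Returns True for keep, False for exclude.  Exclusion applies iff
    ``n_retained * tr < min_minutes * 60`` (strict inequality).
    """
    return not (n_retained_volumes * tr_seconds < min_minutes * 60.0)


def drop_dummy_volumes(values: np.ndarray, n_dummy: int = 10) -> np.ndarray:
    """Discard the first ``n_dummy`` volumes (steady-state magnetization).

    Works on 1-D series or any array whose *last* axis is time.
    """
    values = np.asarray(values)
    if n_dummy < 0 or n_dummy >= values.shape[-1]:
        raise ValueError("n_dummy must be in [0, n_volumes)")
    return values[..., n_dummy:]


# ---------------------------------------------------------------------------
# Nuisance design and regression
# ---------------------------------------------------------------------------


def _lag1(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x)
    out[1:] = x[:-1]
    return out


def _diff1(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x)
    out[1:] = np.diff(x, axis=0)
    return out


def friston24(motion_params: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Friston's 24-parameter motion block.

    6 parameters, the same 6 from the previous time point, and the 12
    corresponding squared terms.  Lagged values at volume 0 are 0.
    """
    motion_params = np.asarray(motion_params, dtype=float)
    if motion_params.ndim != 2 or motion_params.shape[1] != 6:
        raise ValueError("motion_params must be a (T, 6) array")
    lag = np.column_stack([_lag1(motion_params[:, j]) for j in range(6)])
    cols = np.column_stack([motion_params, lag, motion_params**2, lag**2])
    base = ["tx", "ty", "tz", "rx", "ry", "rz"]
    names = (
        base
        + [f"{n}_lag" for n in base]
        + [f"{n}_sq" for n in base]
        + [f"{n}_lag_sq" for n in base]
    )
    return cols, names


def build_design_36p(
    motion_params: np.ndarray,
    tissue_ts: dict[str, np.ndarray],
    include_trend: bool = False,
    spike_regressors: np.ndarray | None = None,
) -> NuisanceDesign:
    """Build the 36-parameter nuisance design plus intercept/trend/spikes.

    Parameters
    ----------
    motion_params
        ``(T, 6)`` realignment parameters.
    tissue_ts
        Mapping with keys ``"GM"``, ``"WM"``, ``"CSF"`` to length-``T``
        mean tissue time courses.
    include_trend
        Append a linear trend column.
    spike_regressors
        Optional ``(T, k)`` indicator matrix from
        :func:`build_spike_regressors`.

    Notes
    -----
    Base columns: 24 Friston motion regressors + for each tissue its mean
    course, first difference, squared course, and squared difference
    (12 columns), for 36 in total.  Differences/lags at volume 0 are 0.
    """
    motion_params = np.asarray(motion_params, dtype=float)
    T = motion_params.shape[0]
    mcols, mnames = friston24(motion_params)

    tcols, tnames = [], []
    for name in ("GM", "WM", "CSF"):
        if name not in tissue_ts:
            raise ValueError(f"missing tissue series {name!r}")
        x = np.asarray(tissue_ts[name], dtype=float)
        if x.shape[0] != T:
            raise ValueError(
                f"tissue series {name!r} has length {x.shape[0]}, expected {T}"
            )
        d = _diff1(x)
        tcols += [x, d, x**2, d**2]
        tnames += [name, f"{name}_diff", f"{name}_sq", f"{name}_diff_sq"]

    cols = [mcols] + [np.column_stack(tcols)]
    names = mnames + tnames

    if include_trend:
        cols.append(np.linspace(-0.5, 0.5, T)[:, None])
        names.append("trend")
    k = 0
    if spike_regressors is not None:
        spike_regressors = np.asarray(spike_regressors, dtype=float)
        if spike_regressors.shape[0] != T:
            raise ValueError("spike_regressors length mismatch with motion_params")
        k = spike_regressors.shape[1]
        if k:
            cols.append(spike_regressors)
            names += [f"spike_{i}" for i in range(k)]
    cols.append(np.ones((T, 1)))
    names.append("intercept")

    return NuisanceDesign(
        columns=np.column_stack([np.column_stack([c]) if c.ndim == 1 else c for c in cols]),
        column_names=names,
        n_base_params=36,
        includes_trend=include_trend,
        spike_columns=k,
    )


def regress_nuisance(y: np.ndarray, design: NuisanceDesign | np.ndarray) -> np.ndarray:
    """Least-squares residuals of ``y`` against the design.

    ``y`` may be 1-D (one series of length T) or 2-D ``(n_series, T)``.
    The solver is rank-deficient-safe (SVD pseudo-inverse); residuals are
    orthogonal to every design column.
    """
    X = design.columns if isinstance(design, NuisanceDesign) else np.asarray(design, float)
    y = np.asarray(y, dtype=float)
    one_d = y.ndim == 1
    Y = y[None, :] if one_d else y
    T = X.shape[0]
    if Y.shape[1] != T:
        raise ValueError(f"series length {Y.shape[1]} != design rows {T}")
    rank = np.linalg.matrix_rank(X)
    if rank >= T:
        raise ValueError("degenerate design: rank >= number of volumes")
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = (Y.T - X @ beta).T
    return resid[0] if one_d else resid


def detrend_linear(y: np.ndarray) -> np.ndarray:
    """Remove the best-fit intercept + slope (per row for 2-D input)."""
    y = np.asarray(y, dtype=float)
    if y.shape[-1] < 3:
        raise ValueError("need at least 3 time points")
    return _signal.detrend(y, axis=-1, type="linear")


# ---------------------------------------------------------------------------
# Band-pass filtering
# ---------------------------------------------------------------------------


def bandpass(
    y: np.ndarray,
    tr_seconds: float,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (default 0.01-0.08 Hz).

    Applied forward and backward (``filtfilt``), so the effective
    magnitude response is the squared Butterworth response and the phase
    is zero.  Works on 1-D series or 2-D ``(n_series, T)`` arrays.
    """
    nyq = 0.5 / tr_seconds
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) must satisfy 0 < low < high < Nyquist={nyq:g}"
        )
    sos = _signal.butter(order, [low_hz / nyq, high_hz / nyq], btype="band", output="sos")
    return _signal.sosfiltfilt(sos, np.asarray(y, dtype=float), axis=-1)
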