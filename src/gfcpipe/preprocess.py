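"""Temporal preprocessing of resting-state BOLD data.

Implements the stages that act on an already-realigned, already-normalized
4D series: initial-volume discard, linear detrending, temporal band-pass
filtering, nuisance regression (Friston-24 motion expansion plus white
matter and CSF compartment means; the global signal is never included),
head-motion quality control, and frame-wise displacement (FD).

The default stage order is discard -> detrend -> band-pass -> nuisance
regression.  The order is configurable at the pipeline level and is
recorded in the run manifest; changing it changes the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal


class PreprocessingError(ValueError):
    """Invalid input or configuration for a preprocessing stage."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Bold4D:
    """A subject's 4D BOLD series with voxel geometry and sampling rate.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        Voxel time series, time last.
    affine : ndarray, shape (4, 4)
        Voxel-index to world-millimetre transform.
    tr : float
        Repetition time in seconds.
    """

    data: np.ndarray
    affine: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise PreprocessingError(
                f"BOLD data must be 4D (x, y, z, t); got shape {self.data.shape}"
            )
        if self.data.shape[3] < 2:
            raise PreprocessingError("BOLD series needs at least 2 time points")
        if self.affine.shape != (4, 4):
            raise PreprocessingError("affine must be 4x4")
        if not self.tr > 0:
            raise PreprocessingError(f"TR must be positive, got {self.tr}")
        if not np.all(np.isfinite(self.data)):
            raise PreprocessingError("BOLD data contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class MotionTrace:
    """T x 6 rigid-body parameters: 3 translations (mm), 3 rotations (rad)."""

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=np.float64)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise PreprocessingError(
                f"motion parameters must be T x 6, got {self.params.shape}"
            )

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]

    def trimmed(self, n_discard: int) -> "MotionTrace":
        """Drop the first `n_discard` frames, aligning with discarded volumes."""
        if n_discard >= self.n_frames:
            raise PreprocessingError("cannot discard all motion frames")
        return MotionTrace(self.params[n_discard:])


@dataclass
class NuisanceDesign:
    """Design matrix of nuisance regressors (time points x regressors)."""

    columns: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=np.float64)
        if self.columns.ndim != 2:
            raise PreprocessingError("design must be 2D (T x K)")
        if len(self.labels) != self.columns.shape[1]:
            raise PreprocessingError("one label per design column required")


@dataclass
class MotionQCResult:
    passed: bool
    offending_frames: np.ndarray
    max_translation_mm: float
    max_rotation_deg: float


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def discard_initial(bold: Bold4D, n_discard: int = 10) -> Bold4D:
    """Drop the first `n_discard` volumes (signal-equilibration discard).

    The caller is responsible for trimming the motion trace consistently
    (see :meth:`MotionTrace.trimmed`).
    """
    if n_discard < 0:
        raise PreprocessingError("n_discard must be nonnegative")
    if n_discard >= bold.n_volumes:
        raise PreprocessingError(
            f"cannot discard {n_discard} of {bold.n_volumes} volumes"
        )
    if n_discard == 0:
        return bold
    return Bold4D(bold.data[..., n_discard:], bold.affine, bold.tr)


def motion_qc(
    motion: MotionTrace,
    trans_limit_mm: float = 2.0,
    rot_limit_deg: float = 2.0,
) -> MotionQCResult:
    """Check head motion against absolute displacement/rotation limits.

    Displacement is measured relative to the first retained frame.  A
    subject fails when any |translation| strictly exceeds `trans_limit_mm`
    or any |rotation| strictly exceeds `rot_limit_deg` (parameters are
    stored in radians and converted).
    """
    rel = motion.params - motion.params[0]
    trans = np.abs(rel[:, :3])
    rot_deg = np.degrees(np.abs(rel[:, 3:]))
    bad = (trans > trans_limit_mm).any(axis=1) | (rot_deg > rot_limit_deg).any(axis=1)
    return MotionQCResult(
        passed=not bad.any(),
        offending_frames=np.flatnonzero(bad),
        max_translation_mm=float(trans.max()),
        max_rotation_deg=float(rot_deg.max()),
    )


def compute_fd(motion: MotionTrace, head_radius_mm: float = 50.0) -> tuple[np.ndarray, float]:
    """Frame-wise displacement (Power formula).

    fd[t] = sum of |backward differences| of the three translations plus
    `head_radius_mm` times the sum of |backward differences| of the three
    rotations (arc length on a sphere).  fd[0] = 0 by convention.

    Returns
    -------
    fd : ndarray, shape (T,) — per-frame FD in mm
    mean_fd : float — arithmetic mean of fd (including the leading zero)
    """
    if motion.n_frames < 2:
        raise PreprocessingError("FD needs at least 2 frames")
    d = np.diff(motion.params, axis=0)
    fd = np.zeros(motion.n_frames)
    fd[1:] = np.abs(d[:, :3]).sum(axis=1) + head_radius_mm * np.abs(d[:, 3:]).sum(axis=1)
    return fd, float(fd.mean())


def detrend_linear(bold: Bold4D) -> Bold4D:
    """Remove the per-voxel least-squares linear trend (and mean)."""
    if bold.n_volumes < 3:
        raise PreprocessingError("linear detrend needs at least 3 time points")
    out = _signal.detrend(bold.data, axis=-1, type="linear")
    return Bold4D(out, bold.affine, bold.tr)


def _ideal_bandpass(x: np.ndarray, tr: float, low_hz: float, high_hz: float) -> np.ndarray:
    """Rectangular frequency-domain filter along the last axis.

    Series are demeaned, transformed with the real FFT, bins strictly
    outside [low_hz, high_hz] are zeroed, and the series inverted.  This
    mirrors the ideal filter used by the REST/DPABI toolbox family.
    """
    t = x.shape[-1]
    x = x - x.mean(axis=-1, keepdims=True)
    freqs = np.fft.rfftfreq(t, d=tr)
    keep = (freqs >= low_hz - 1e-12) & (freqs <= high_hz + 1e-12)
    spec = np.fft.rfft(x, axis=-1)
    spec[..., ~keep] = 0.0
    return np.fft.irfft(spec, n=t, axis=-1)


def _butter_bandpass(x: np.ndarray, tr: float, low_hz: float, high_hz: float,
                     order: int = 4) -> np.ndarray:
    nyq = 0.5 / tr
    sos = _signal.butter(order, [low_hz / nyq, high_hz / nyq], btype="band", output="sos")
    x = x - x.mean(axis=-1, keepdims=True)
    return _signal.sosfiltfilt(sos, x, axis=-1)


def bandpass(
    bold: Bold4D,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    filter_type: str = "ideal",
) -> Bold4D:
    """Temporal band-pass filter (default 0.01-0.08 Hz).

    `filter_type` is "ideal" (rectangular FFT filter, the default) or
    "butterworth" (zero-phase 4th-order).
    """
    nyquist = 0.5 / bold.tr
    if not 0 <= low_hz < high_hz:
        raise PreprocessingError(f"invalid band [{low_hz}, {high_hz}] Hz")
    if high_hz >= nyquist:
        raise PreprocessingError(
            f"high cutoff {high_hz} Hz is at or above Nyquist {nyquist} Hz"
        )
    if filter_type == "ideal":
        out = _ideal_bandpass(bold.data, bold.tr, low_hz, high_hz)
    elif filter_type == "butterworth":
        out = _butter_bandpass(bold.data, bold.tr, low_hz, high_hz)
    else:
        raise PreprocessingError(f"unknown filter_type {filter_type!r}")
    return Bold4D(out, bold.affine, bold.tr)


def friston24(motion: MotionTrace) -> NuisanceDesign:
    """Friston 24-parameter motion expansion.

    Columns (24): the six rigid-body parameters R(t); their one-frame lags
    R(t-1) with the first frame zero-padded; and the elementwise squares of
    both sets.
    """
    if motion.n_frames < 2:
        raise PreprocessingError("Friston-24 expansion needs at least 2 frames")
    r = motion.params
    r_lag = np.zeros_like(r)
    r_lag[1:] = r[:-1]
    cols = np.hstack([r, r_lag, r**2, r_lag**2])
    names = [f"mp{i+1}" for i in range(6)]
    labels = (
        names
        + [f"{n}_lag" for n in names]
        + [f"{n}_sq" for n in names]
        + [f"{n}_lag_sq" for n in names]
    )
    return NuisanceDesign(cols, labels)


def extract_compartment_mean(bold: Bold4D, compartment_mask: np.ndarray) -> np.ndarray:
    """Mean time series over a compartment (e.g. white matter or CSF) mask."""
    mask = np.asarray(compartment_mask, dtype=bool)
    if mask.shape != bold.grid_shape:
        raise PreprocessingError(
            f"mask shape {mask.shape} != image grid {bold.grid_shape}"
        )
    if not mask.any():
        raise PreprocessingError("compartment mask is empty")
    return bold.data[mask].mean(axis=0)


def build_nuisance_design(
    motion: MotionTrace,
    wm_series: np.ndarray | None = None,
    csf_series: np.ndarray | None = None,
    include_intercept: bool = True,
) -> NuisanceDesign:
    """Assemble the full nuisance design: Friston-24 (+ wm_mean, csf_mean, intercept).

    The global mean signal is deliberately never offered as a regressor.
    """
    design = friston24(motion)
    cols = [design.columns]
    labels = list(design.labels)
    t = design.columns.shape[0]
    for series, name in ((wm_series, "wm_mean"), (csf_series, "csf_mean")):
        if series is not None:
            series = np.asarray(series, dtype=np.float64)
            if series.shape != (t,):
                raise PreprocessingError(f"{name} series length != design rows")
            cols.append(series[:, None])
            labels.append(name)
    if include_intercept:
        cols.append(np.ones((t, 1)))
        labels.append("intercept")
    return NuisanceDesign(np.hstack(cols), labels)


def _collinear_columns(x: np.ndarray, labels: list[str]) -> list[str]:
    """Labels of columns linearly dependent on the columns before them."""
    bad = []
    rank = 0
    for j in range(x.shape[1]):
        new_rank = np.linalg.matrix_rank(x[:, : j + 1])
        if new_rank == rank:
            bad.append(labels[j])
        rank = new_rank
    return bad


def nuisance_regress(bold: Bold4D, design: NuisanceDesign) -> Bold4D:
    """Regress nuisance columns out of every voxel series (OLS residuals).

    Zero-variance regressor columns other than the intercept, or any linear
    dependency among columns, raise an error naming the offending columns.
    """
    x = design.columns
    if x.shape[0] != bold.n_volumes:
        raise PreprocessingError(
            f"design rows ({x.shape[0]}) != number of volumes ({bold.n_volumes})"
        )
    # Drop all-zero columns (e.g. Friston-24 of a motionless trace): they are
    # harmless no-ops, not collinearity.
    nonzero = np.abs(x).max(axis=0) > 0
    x_used = x[:, nonzero]
    labels_used = [l for l, keep in zip(design.labels, nonzero) if keep]
    if x_used.shape[1] == 0:
        return bold
    if np.linalg.matrix_rank(x_used) < x_used.shape[1]:
        bad = _collinear_columns(x_used, labels_used)
        raise PreprocessingError(f"rank-deficient nuisance design; collinear: {bad}")
    shape = bold.data.shape
    y = bold.data.reshape(-1, shape[3]).T  # T x V
    beta, *_ = np.linalg.lstsq(x_used, y, rcond=None)
    resid = y - x_used @ beta
    return Bold4D(resid.T.reshape(shape), bold.affine, bold.tr)


def preprocess_bold(
    bold: Bold4D,
    motion: MotionTrace,
    n_discard: int = 10,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    filter_type: str = "ideal",
    wm_mask: np.ndarray | None = None,
    csf_mask: np.ndarray | None = None,
) -> tuple[Bold4D, MotionTrace]:
    """Run the default chain: discard -> detrend -> band-pass -> nuisance regression.

    Returns the preprocessed image and the trimmed motion trace (frames
    aligned with the retained volumes), on which FD and motion QC should be
    computed.
    """
    bold = discard_initial(bold, n_discard)
    motion = motion.trimmed(n_discard)
    bold = detrend_linear(bold)
    bold = bandpass(bold, low_hz, high_hz, filter_type)
    wm = extract_compartment_mean(bold, wm_mask) if wm_mask is not None else None
    csf = extract_compartment_mean(bold, csf_mask) if csf_mask is not None else None
    design = build_nuisance_design(motion, wm, csf)
    bold = nuisance_regress(bold, design)
    return bold, motion
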