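"""Temporal preprocessing of template-space BOLD runs.

Covers the confound side of a resting-state pipeline: nuisance time-course
extraction, voxelwise confound regression, linear detrend + zero-phase
band-pass, framewise displacement (FD), DVARS, motion scrubbing, and the
ROI signal-to-noise ratio.  No spatial smoothing is ever applied (there is
deliberately no smoothing operation in this package: smoothing would mix
signal across the midsagittal plane and contaminate the flip-based
lateralization metric), and neither the global mean signal nor grey-matter
time courses are regressed.

All operations consume and return :class:`BoldRun` objects and are purely
temporal, i.e. they commute with any spatial permutation of voxels such as
the midsagittal flip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

FD_ROTATION_RADIUS_MM = 50.0  # rotations converted to arc length on a 50-mm sphere


@dataclass
class BoldRun:
    """One subject's 4-D template-space BOLD series plus realignment
    parameters (T x 6: three translations in mm, three rotations in
    radians)."""

    data: np.ndarray  # (x, y, z, t)
    tr_seconds: float
    voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    motion_params: np.ndarray | None = None
    subject_id: str = ""
    site_id: str = ""
    flipped: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4-D (x, y, z, t)")
        if self.data.shape[3] < 2:
            raise ValueError("a BOLD run needs at least 2 volumes")
        if not np.isfinite(self.data).all():
            raise ValueError("BOLD data contains non-finite voxels")
        vm = np.broadcast_to(np.asarray(self.voxel_mm, dtype=float), (3,))
        self.voxel_mm = tuple(float(v) for v in vm)
        if self.motion_params is not None:
            self.motion_params = np.asarray(self.motion_params, dtype=float)
            if self.motion_params.shape != (self.data.shape[3], 6):
                raise ValueError(
                    "motion_params must be T x 6 with one row per volume "
                    f"(got {self.motion_params.shape} for T={self.data.shape[3]})"
                )

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass
class NuisanceSet:
    """Nuisance regressors: CSF, white-matter and soft-tissue mean time
    courses plus the six realignment parameters."""

    csf: np.ndarray
    wm: np.ndarray
    soft_tissue: np.ndarray
    motion: np.ndarray  # T x 6

    def __post_init__(self) -> None:
        self.csf = np.asarray(self.csf, dtype=float)
        self.wm = np.asarray(self.wm, dtype=float)
        self.soft_tissue = np.asarray(self.soft_tissue, dtype=float)
        self.motion = np.asarray(self.motion, dtype=float)
        t = len(self.csf)
        if not (len(self.wm) == len(self.soft_tissue) == t and self.motion.shape == (t, 6)):
            raise ValueError("nuisance series must share one length T (motion T x 6)")
        for name, s in [("csf", self.csf), ("wm", self.wm),
                        ("soft_tissue", self.soft_tissue), ("motion", self.motion)]:
            if not np.isfinite(s).all():
                raise ValueError(f"nuisance series '{name}' contains non-finite values")

    def design_matrix(self) -> np.ndarray:
        """Intercept + 9 confound columns (csf, wm, soft tissue, 6 motion)."""
        t = len(self.csf)
        return np.column_stack([np.ones(t), self.csf, self.wm, self.soft_tissue, self.motion])

    def subset(self, keep: np.ndarray) -> "NuisanceSet":
        keep = np.asarray(keep, dtype=bool)
        return NuisanceSet(self.csf[keep], self.wm[keep], self.soft_tissue[keep], self.motion[keep])


@dataclass
class ScrubResult:
    """Bookkeeping from motion scrubbing of one run."""

    kept_mask: np.ndarray
    fd: np.ndarray
    dvars: np.ndarray
    retention_fraction: float
    mean_fd_pre: float
    mean_fd_post: float


# ---------------------------------------------------------------------------
# nuisance extraction and regression
# ---------------------------------------------------------------------------

def extract_nuisance(bold: BoldRun, masks: dict) -> NuisanceSet:
    """Mean time course over each restriction mask (csf, wm, soft_tissue)."""
    if bold.motion_params is None:
        raise ValueError("run has no realignment parameters")
    series = {}
    for name in ("csf", "wm", "soft_tissue"):
        if name not in masks:
            raise ValueError(f"missing mask '{name}'")
        mask = np.asarray(masks[name]).astype(bool)
        if mask.shape != bold.data.shape[:3]:
            raise ValueError(f"mask '{name}' not aligned to the run grid")
        if not mask.any():
            raise ValueError(f"mask '{name}' is empty")
        series[name] = bold.data[mask].mean(axis=0)
    return NuisanceSet(series["csf"], series["wm"], series["soft_tissue"], bold.motion_params)


def regress_confounds(bold: BoldRun, nuisance: NuisanceSet) -> BoldRun:
    """Replace every voxel's series by the least-squares residual of the
    model [intercept, csf, wm, soft tissue, 6 motion].

    A rank-deficient design is not fatal: the minimum-norm solution is used
    and the dependent columns are reported in a warning.
    """
    t = bold.n_volumes
    if t <= 10:
        raise ValueError(f"need more than 10 volumes to fit 10 regressors (got {t})")
    X = nuisance.design_matrix()
    if X.shape[0] != t:
        raise ValueError("nuisance length does not match the run")

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        dep = _dependent_columns(X)
        warnings.warn(
            f"confound design is rank deficient (rank {rank} of {X.shape[1]}); "
            f"dependent columns: {dep}; using the minimum-norm solution",
            RuntimeWarning,
            stacklevel=2,
        )
    flat = bold.data.reshape(-1, t).T.astype(float)  # T x V
    beta, *_ = np.linalg.lstsq(X, flat, rcond=None)
    resid = flat - X @ beta
    out = resid.T.reshape(bold.data.shape)
    return replace(bold, data=out)


def _dependent_columns(X: np.ndarray) -> list[int]:
    """Indices of design columns linearly dependent on earlier ones."""
    dep = []
    for j in range(1, X.shape[1]):
        if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
            dep.append(j)
    return dep


# ---------------------------------------------------------------------------
# detrend + band-pass
# ---------------------------------------------------------------------------

def bandpass_detrend(bold: BoldRun, low_hz: float = 0.001, high_hz: float = 0.1) -> BoldRun:
    """Per voxel: remove the best-fit line, then apply a zero-phase
    frequency-domain band-pass with the given corner frequencies."""
    if bold.tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    nyquist = 1.0 / (2.0 * bold.tr_seconds)
    if high_hz >= nyquist:
        raise ValueError(
            f"high corner {high_hz} Hz is at or above the Nyquist frequency "
            f"{nyquist} Hz for TR = {bold.tr_seconds} s"
        )
    t = bold.n_volumes
    flat = bold.data.reshape(-1, t).astype(float)
    flat = signal.detrend(flat, axis=1, type="linear")
    freqs = np.fft.rfftfreq(t, d=bold.tr_seconds)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spec = np.fft.rfft(flat, axis=1)
    spec[:, ~keep] = 0.0
    out = np.fft.irfft(spec, n=t, axis=1).reshape(bold.data.shape)
    return replace(bold, data=out)


# ---------------------------------------------------------------------------
# motion metrics and scrubbing
# ---------------------------------------------------------------------------

def framewise_displacement(motion_params: np.ndarray, mode: str = "sum_abs") -> np.ndarray:
    """Framewise displacement per volume-to-volume transition (mm).

    ``fd[0] = 0``; for t >= 1 the six differenced realignment parameters are
    combined after converting rotations to arc length on a 50-mm-radius
    sphere.  ``mode='sum_abs'`` (default) sums absolute differences, the
    usual FD; ``mode='rms'`` takes the root-mean-square of the six terms,
    the alternative reading of "root-mean-square displacement".
    """
    motion = np.asarray(motion_params, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion parameters must be T x 6")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 volumes")
    bad = ~np.isfinite(motion).all(axis=1)
    if bad.any():
        raise ValueError(f"non-finite realignment parameters at volume {int(np.argmax(bad))}")
    d = np.diff(motion, axis=0)
    d[:, 3:] *= FD_ROTATION_RADIUS_MM
    if mode == "sum_abs":
        fd = np.abs(d).sum(axis=1)
    elif mode == "rms":
        fd = np.sqrt((d**2).mean(axis=1))
    else:
        raise ValueError(f"unknown FD mode '{mode}'")
    return np.concatenate([[0.0], fd])


def dvars(bold: BoldRun, brain_mask: np.ndarray) -> np.ndarray:
    """DVARS per transition: RMS over in-mask voxels of the volume-to-volume
    signal change, expressed as percent of the run's mean in-mask intensity.

    Computed on the series as given; use the raw (unregressed) run so the
    percent scale is well defined.  ``dvars[0] = 0``.
    """
    mask = np.asarray(brain_mask).astype(bool)
    if mask.shape != bold.data.shape[:3]:
        raise ValueError("brain mask not aligned to the run grid")
    if not mask.any():
        raise ValueError("brain mask is empty")
    series = bold.data[mask].astype(float)  # V x T
    ref = series.mean()
    if ref <= 0:
        raise ValueError(f"mean in-mask intensity must be positive (got {ref})")
    rms = np.sqrt((np.diff(series, axis=1) ** 2).mean(axis=0))
    return np.concatenate([[0.0], 100.0 * rms / ref])


def scrub(
    bold: BoldRun,
    fd: np.ndarray,
    dvars_series: np.ndarray,
    threshold: float = 0.2,
) -> tuple[BoldRun, ScrubResult]:
    """Motion scrubbing: for every transition t with FD or DVARS above the
    threshold, drop the two volumes spanning it (t-1 and t) and concatenate
    the remaining volumes in order."""
    fd = np.asarray(fd, dtype=float)
    dv = np.asarray(dvars_series, dtype=float)
    t = bold.n_volumes
    if len(fd) != t or len(dv) != t:
        raise ValueError("fd and dvars must have one entry per volume")
    bad = (fd > threshold) | (dv > threshold)
    kept = np.ones(t, dtype=bool)
    idx = np.flatnonzero(bad)
    kept[idx] = False
    kept[np.clip(idx - 1, 0, None)] = False
    if not kept.any():
        raise ValueError(
            "scrubbing removed every volume; the run is unusable at "
            f"threshold {threshold}"
        )
    out = replace(
        bold,
        data=bold.data[..., kept],
        motion_params=None if bold.motion_params is None else bold.motion_params[kept],
    )
    result = ScrubResult(
        kept_mask=kept,
        fd=fd,
        dvars=dv,
        retention_fraction=float(kept.sum()) / t,
        mean_fd_pre=float(fd.mean()),
        mean_fd_post=float(fd[kept].mean()),
    )
    return out, result


def roi_snr(bold_prescrub: BoldRun, roi_mask: np.ndarray) -> float:
    """Signal-to-noise ratio of one ROI: temporal mean of the ROI-mean
    signal divided by its temporal standard deviation.

    Meant for the run *before* nuisance regression and filtering (which
    remove the mean that defines the numerator)."""
    mask = np.asarray(roi_mask).astype(bool)
    if mask.shape != bold_prescrub.data.shape[:3]:
        raise ValueError("ROI mask not aligned to the run grid")
    if not mask.any():
        raise ValueError("ROI mask is empty")
    series = bold_prescrub.data[mask].mean(axis=0)
    sd = series.std(ddof=0)
    if sd == 0:
        warnings.warn("ROI signal has zero temporal variance; SNR is infinite",
                      RuntimeWarning, stacklevel=2)
        return float("inf")
    return float(series.mean() / sd)


# ---------------------------------------------------------------------------
# one-call pipeline for a single run
# ---------------------------------------------------------------------------

def preprocess_run(
    bold: BoldRun,
    nuisance: NuisanceSet | None = None,
    masks: dict | None = None,
    brain_mask: np.ndarray | None = None,
    low_hz: float = 0.001,
    high_hz: float = 0.1,
    scrub_threshold: float = 0.2,
) -> tuple[BoldRun, ScrubResult]:
    """Confound regression -> detrend + band-pass -> FD/DVARS scrubbing.

    FD comes from the realignment parameters and DVARS from the raw run
    (percent of mean in-mask intensity), both thresholded at
    ``scrub_threshold``; the filtered volumes spanning each excursion are
    dropped.  Returns the cleaned, scrubbed run plus the scrub bookkeeping.
    """
    if nuisance is None:
        if masks is None:
            raise ValueError("provide either a NuisanceSet or restriction masks")
        nuisance = extract_nuisance(bold, masks)
    if brain_mask is None:
        brain_mask = np.ones(bold.data.shape[:3], dtype=bool)
    if bold.motion_params is None:
        raise ValueError("run has no realignment parameters")
    fd = framewise_displacement(bold.motion_params)
    dv = dvars(bold, brain_mask)
    cleaned = regress_confounds(bold, nuisance)
    cleaned = bandpass_detrend(cleaned, low_hz=low_hz, high_hz=high_hz)
    return scrub(cleaned, fd, dv, threshold=scrub_threshold)
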