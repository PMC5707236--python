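"""Resting-state ROI time-series cleanup.

Three operations, applied in the order regression -> band-pass ->
scrubbing-by-deletion:

* nuisance regression against motion parameters, global / white-matter /
  CSF signals and their first temporal derivatives;
* band-pass filtering (default 0.008-0.08 Hz) with linear detrending,
  implemented as FFT-domain masking with a cosine roll-off so the result
  is order-free and exactly reproducible;
* motion scrubbing based on framewise displacement (FD), with the
  one-back / two-forward frame augmentation and the subject-exclusion
  rule that more than one third of volumes removed disqualifies the
  subject.

Scrubbed volumes are dropped (not interpolated) before correlation; the
functions here only mark them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "CleanResult",
    "TimeSeriesError",
    "bandpass",
    "clean",
    "framewise_displacement",
    "nuisance_regress",
    "scrub",
]

MOTION_COLUMNS = ("x", "y", "z", "pitch", "roll", "yaw")


class TimeSeriesError(ValueError):
    """Invalid time-series input (shape mismatch, rank deficiency, bad band)."""


def _derivatives(x: np.ndarray) -> np.ndarray:
    """Backward differences along time; the first row is defined as 0."""
    d = np.zeros_like(x, dtype=float)
    d[1:] = np.diff(x, axis=0)
    return d


def _design_matrix(regressors: np.ndarray, include_derivatives: bool) -> tuple[np.ndarray, list[str]]:
    t = regressors.shape[0]
    cols = [np.ones((t, 1))]
    names = ["intercept"]
    cols.append(regressors)
    names += [f"reg{i}" for i in range(regressors.shape[1])]
    if include_derivatives:
        cols.append(_derivatives(regressors))
        names += [f"dreg{i}" for i in range(regressors.shape[1])]
    return np.hstack(cols), names


def _drop_duplicate_columns(design: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    keep: list[int] = []
    for j in range(design.shape[1]):
        if not any(np.array_equal(design[:, j], design[:, k]) for k in keep):
            keep.append(j)
    return design[:, keep], [names[j] for j in keep]


def nuisance_regress(
    data: np.ndarray,
    regressors: np.ndarray,
    include_derivatives: bool = True,
) -> np.ndarray:
    """Replace each ROI series by its least-squares residual.

    The design is [intercept | regressors | backward-difference
    derivatives]; exact duplicate columns are dropped first.  A design
    that is still rank deficient raises, naming the offending columns.
    """
    data = np.asarray(data, dtype=float)
    regressors = np.asarray(regressors, dtype=float)
    if regressors.ndim == 1:
        regressors = regressors[:, None]
    if data.shape[0] != regressors.shape[0]:
        raise TimeSeriesError(
            f"time dimension mismatch: data {data.shape[0]} vs regressors {regressors.shape[0]}"
        )
    design, names = _design_matrix(regressors, include_derivatives)
    design, names = _drop_duplicate_columns(design, names)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # greedy scan: a column is an offender if it does not raise the rank
        offenders = []
        kept: list[int] = []
        for j in range(design.shape[1]):
            cand = design[:, kept + [j]]
            if np.linalg.matrix_rank(cand) == len(kept) + 1:
                kept.append(j)
            else:
                offenders.append(names[j])
        raise TimeSeriesError(f"rank-deficient nuisance design; offending columns: {offenders}")
    beta, *_ = np.linalg.lstsq(design, data, rcond=None)
    return data - design @ beta


def bandpass(
    data: np.ndarray,
    tr_seconds: float,
    low_hz: float = 0.008,
    high_hz: float = 0.08,
) -> np.ndarray:
    """Linear detrend followed by FFT-domain band-pass masking.

    Implemented as the exact orthogonal projection onto the subspace of
    signals that are band-limited to [low_hz, high_hz] (binary FFT mask;
    a graded roll-off would re-attenuate transition content on every
    application) AND free of a linear trend.  Masking alone would
    reintroduce a small trend component, so the component along the
    masked trend basis is removed inside the band.  Being a projector,
    the filter is exactly idempotent, order-free and reproducible; a
    pure linear ramp maps to zero and stop-band frequencies are removed
    entirely.
    """
    nyquist = 0.5 / tr_seconds
    if not (0.0 < low_hz < high_hz < nyquist):
        raise TimeSeriesError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < Nyquist ({nyquist})"
        )
    x = np.asarray(data, dtype=float)
    t = x.shape[0]
    freqs = np.fft.rfftfreq(t, d=tr_seconds)
    gain = ((freqs >= low_hz) & (freqs <= high_hz)).astype(float)

    def mask(v: np.ndarray) -> np.ndarray:
        return np.fft.irfft(np.fft.rfft(v, axis=0) * gain[:, None], n=t, axis=0)

    z = mask(x)
    # masked image of the (centered, normalized) linear-trend direction;
    # the constant direction is already annihilated by the mask
    trend = np.arange(t, dtype=float)
    trend -= trend.mean()
    trend /= np.linalg.norm(trend)
    w = mask(trend[:, None])
    coef, *_ = np.linalg.lstsq(w, z, rcond=None)
    return z - w @ coef


def framewise_displacement(motion: np.ndarray, rotation_radius_mm: float = 50.0) -> np.ndarray:
    """Power-style framewise displacement per volume.

    Sum of absolute backward differences of the six rigid-body
    parameters, with the three rotations (radians) converted to arc
    length on a sphere of ``rotation_radius_mm``.  FD of the first
    volume is 0.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise TimeSeriesError(f"motion must be volumes x 6, got shape {motion.shape}")
    if motion.shape[0] < 2:
        raise TimeSeriesError("need at least 2 volumes to compute FD")
    diffs = np.abs(np.diff(motion, axis=0))
    fd = np.zeros(motion.shape[0])
    fd[1:] = diffs[:, :3].sum(axis=1) + rotation_radius_mm * diffs[:, 3:].sum(axis=1)
    return fd


def scrub(
    motion: np.ndarray,
    fd_threshold_mm: float = 0.5,
    n_back: int = 1,
    n_forward: int = 2,
    max_removed_fraction: float = 1.0 / 3.0,
    rotation_radius_mm: float = 50.0,
) -> tuple[np.ndarray, bool]:
    """Flag motion-contaminated volumes for removal.

    Volumes with FD above ``fd_threshold_mm`` are flagged, together with
    ``n_back`` preceding and ``n_forward`` following volumes.  Returns a
    boolean mask (True = volume removed) and the exclusion flag, which is
    True when strictly more than ``max_removed_fraction`` of volumes are
    removed.
    """
    fd = framewise_displacement(motion, rotation_radius_mm=rotation_radius_mm)
    t = fd.shape[0]
    removed = np.zeros(t, dtype=bool)
    for i in np.flatnonzero(fd > fd_threshold_mm):
        removed[max(0, i - n_back) : min(t, i + n_forward + 1)] = True
    excluded = removed.sum() > max_removed_fraction * t
    return removed, bool(excluded)


@dataclass
class CleanResult:
    """Cleaned ROI time series plus the scrubbing outcome."""

    data: np.ndarray            # volumes x ROIs, cleaned (all volumes)
    retained: np.ndarray        # boolean per volume, True = kept
    excluded: bool              # excessive-scrubbing exclusion flag
    fd: np.ndarray = field(repr=False, default=None)

    @property
    def retained_data(self) -> np.ndarray:
        return self.data[self.retained]


def clean(
    data: np.ndarray,
    regressors: np.ndarray,
    motion: np.ndarray,
    tr_seconds: float = 2.0,
    low_hz: float = 0.008,
    high_hz: float = 0.08,
    fd_threshold_mm: float = 0.5,
    include_derivatives: bool = True,
    n_back: int = 1,
    n_forward: int = 2,
    max_removed_fraction: float = 1.0 / 3.0,
) -> CleanResult:
    """Full per-subject cleanup: regression, band-pass, scrubbing.

    The motion parameters are part of the nuisance regressors supplied by
    the caller (they are not appended here); ``motion`` is used only to
    compute FD for scrubbing.
    """
    resid = nuisance_regress(data, regressors, include_derivatives=include_derivatives)
    filtered = bandpass(resid, tr_seconds, low_hz=low_hz, high_hz=high_hz)
    removed, excluded = scrub(
        motion,
        fd_threshold_mm=fd_threshold_mm,
        n_back=n_back,
        n_forward=n_forward,
        max_removed_fraction=max_removed_fraction,
    )
    if not np.all(np.isfinite(filtered)):
        raise TimeSeriesError("non-finite values after cleaning")
    fd = framewise_displacement(motion)
    return CleanResult(data=filtered, retained=~removed, excluded=excluded, fd=fd)
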