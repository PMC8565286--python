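"""Temporal cleaning of masked BOLD time series.

The stages mirror common resting-state practice: optional de-spiking,
polynomial baseline removal (which doubles as the high-pass side of an
effective band-pass), voxel-wise nuisance regression, zero-phase
low-pass filtering at 0.08 Hz, and mask-restricted Gaussian smoothing.
Temporal stage order is fixed: despike -> detrend -> nuisance ->
lowpass; the spatial smoothing stage operates on the 4D volume and is
applied before voxel extraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.polynomial import legendre
from scipy import ndimage, signal

from .io_volumes import BoldVolume, BrainMask, TimeSeriesMatrix, extract_timeseries

__all__ = [
    "NuisanceDesign",
    "read_nuisance_tsv",
    "despike",
    "detrend",
    "regress_nuisance",
    "lowpass",
    "smooth_masked",
    "preprocess_volume",
]

#: FWHM of a Gaussian = _FWHM_SIGMA * sigma
_FWHM_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class NuisanceDesign:
    """T x K nuisance regressor matrix with column labels.

    Typical use is 14 columns: six rigid-body motion parameters, the
    mean ventricle signal, and their first temporal derivatives — but
    any K >= 1 is accepted.
    """

    regressors: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.regressors = np.asarray(self.regressors, dtype=np.float64)
        if self.regressors.ndim != 2:
            raise ValueError("regressors must be a T x K matrix")
        if self.regressors.shape[1] < 1:
            raise ValueError("need at least one regressor column")
        if len(self.names) != self.regressors.shape[1]:
            raise ValueError("names must match the number of regressor columns")

    @property
    def n_frames(self) -> int:
        return self.regressors.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.regressors.shape[1]


def read_nuisance_tsv(path: str | Path) -> NuisanceDesign:
    """Read a nuisance regressor table (TSV with a header row)."""
    df = pd.read_csv(path, sep="\t")
    return NuisanceDesign(df.to_numpy(dtype=np.float64), list(df.columns))


def write_nuisance_tsv(design: NuisanceDesign, path: str | Path) -> None:
    pd.DataFrame(design.regressors, columns=design.names).to_csv(
        path, sep="\t", index=False
    )


def despike(
    ts: TimeSeriesMatrix, z_clip: float = 4.0, window: int = 5
) -> TimeSeriesMatrix:
    """Clip transient spikes toward a running-median baseline.

    Per voxel, a running median (default window 5) estimates the local
    baseline; deviations are scaled by a robust SD (1.4826 * MAD of the
    deviations) and samples beyond ``z_clip`` robust SDs are clipped to
    the ``z_clip`` boundary.  All other samples pass through unchanged.
    """
    if z_clip <= 0:
        raise ValueError(f"z_clip must be positive, got {z_clip}")
    if ts.n_frames < 5:
        raise ValueError("need at least 5 timeframes to despike")
    baseline = ndimage.median_filter(ts.values, size=(1, window), mode="nearest")
    resid = ts.values - baseline
    robust_sd = 1.4826 * np.median(np.abs(resid), axis=1, keepdims=True)
    thr = z_clip * robust_sd
    return ts.copy_with(baseline + np.clip(resid, -thr, thr))


def detrend(ts: TimeSeriesMatrix, order: int = 3) -> TimeSeriesMatrix:
    """Remove a least-squares polynomial baseline of degree 0..3.

    The fit uses a Legendre basis on time rescaled to [-1, 1] for
    numerical conditioning; order 0 is plain mean removal.  Residuals
    have zero mean per voxel.
    """
    if not 0 <= order <= 3:
        raise ValueError(f"detrend order must be in 0..3, got {order}")
    if ts.n_frames <= order + 1:
        raise ValueError(
            f"need more than {order + 1} timeframes for order-{order} detrending"
        )
    x = np.linspace(-1.0, 1.0, ts.n_frames)
    basis = legendre.legvander(x, order)  # T x (order+1)
    coef, *_ = np.linalg.lstsq(basis, ts.values.T, rcond=None)
    return ts.copy_with(ts.values - (basis @ coef).T)


def regress_nuisance(ts: TimeSeriesMatrix, design: NuisanceDesign) -> TimeSeriesMatrix:
    """Project out nuisance regressors (plus an intercept) per voxel.

    Returns the OLS residuals; these are orthogonal to every regressor
    column.  A rank-deficient design is an error that names the
    offending columns.
    """
    if design.n_frames != ts.n_frames:
        raise ValueError(
            f"design has {design.n_frames} rows but series has {ts.n_frames} frames"
        )
    X = np.column_stack([np.ones(ts.n_frames), design.regressors])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [
            (["<intercept>"] + design.names)[j]
            for j in np.flatnonzero(diag <= max(tol, 1e-10 * diag.max()))
        ]
        raise ValueError(
            f"nuisance design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {bad or 'unidentified'}"
        )
    coef, *_ = np.linalg.lstsq(X, ts.values.T, rcond=None)
    return ts.copy_with(ts.values - (X @ coef).T)


def lowpass(ts: TimeSeriesMatrix, cutoff_hz: float = 0.08, order: int = 4) -> TimeSeriesMatrix:
    """Zero-phase Butterworth low-pass filter per voxel (default 0.08 Hz)."""
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    nyquist = 1.0 / (2.0 * ts.tr_s)
    if cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz is at or above Nyquist {nyquist} Hz "
            f"(TR = {ts.tr_s} s)"
        )
    b, a = signal.butter(order, cutoff_hz / nyquist)
    return ts.copy_with(signal.filtfilt(b, a, ts.values, axis=1))


def smooth_masked(
    vol: BoldVolume, mask: BrainMask, fwhm_mm: float = 4.0
) -> BoldVolume:
    """Gaussian smoothing restricted to the brain mask.

    Each frame is smoothed with a truncated Gaussian (3 SD) whose
    weights are renormalized over in-mask neighbors, so no signal
    bleeds across the mask boundary and constants are preserved.
    Voxels outside the mask are zeroed.
    """
    if fwhm_mm <= 0:
        raise ValueError("FWHM must be positive")
    mask.check_compatible(vol.shape)
    sigma_vox = fwhm_mm / (_FWHM_SIGMA * mask.voxel_size_mm)
    m = mask.grid.astype(np.float64)
    weight = ndimage.gaussian_filter(m, sigma=sigma_vox, truncate=3.0)
    out = np.zeros_like(vol.data)
    for t in range(vol.n_frames):
        num = ndimage.gaussian_filter(
            vol.data[..., t] * m, sigma=sigma_vox, truncate=3.0
        )
        frame = np.zeros(mask.shape)
        np.divide(num, weight, out=frame, where=weight > 0)
        out[..., t] = frame * m
    return BoldVolume(out, vol.voxel_size_mm, vol.tr_s, vol.origin_mm)


def preprocess_volume(
    vol: BoldVolume,
    mask: BrainMask,
    design: NuisanceDesign | None = None,
    *,
    despike_z: float | None = 4.0,
    detrend_order: int | None = 3,
    lowpass_hz: float | None = 0.08,
    fwhm_mm: float | None = 4.0,
) -> TimeSeriesMatrix:
    """Run the full temporal pipeline and return the cleaned matrix.

    Any stage can be disabled by passing None for its parameter; stage
    order is fixed.  Smoothing, being spatial, is applied to the volume
    before extraction.
    """
    if fwhm_mm is not None:
        vol = smooth_masked(vol, mask, fwhm_mm)
    ts = extract_timeseries(vol, mask)
    if despike_z is not None:
        ts = despike(ts, despike_z)
    if detrend_order is not None:
        ts = detrend(ts, detrend_order)
    if design is not None:
        ts = regress_nuisance(ts, design)
    if lowpass_hz is not None:
        ts = lowpass(ts, lowpass_hz)
    return ts
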