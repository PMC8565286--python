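"""Threshold-free voxel-wise connectivity metrics.

For every in-mask voxel, its Pearson correlations with all other
in-mask voxels (the "correlation row", self excluded) are summarized
into two families of resting-state functional connectivity metrics:

* CSI (connectivity strength index): the mean of the row, with the
  positive and negative coefficients averaged separately (CSI_P, CSI_N)
  to avoid cancellation, plus the mixed mean over all coefficients.
* CDI (connectivity density index): the inner product of the row's
  200-bin histogram on [-1, 1] with a weighting kernel evaluated at the
  bin centers, again split into negative and positive parts.  The
  square-well (step) kernel recovers classical thresholded degree
  centrality; smooth kernels |x|^p and sin^2(pi x / 2) weight stronger
  correlations more without any threshold.

The whole-brain correlation matrix (V x V, V ~ 10^4 for 4 mm data) is
never materialized: rows are streamed in blocks and reduced on the fly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_volumes import TimeSeriesMatrix

__all__ = [
    "Kernel",
    "KERNEL_KINDS",
    "CCRow",
    "CCHistogram",
    "RFCMaps",
    "RFCResult",
    "ZMap",
    "standardize_rows",
    "cc_row",
    "cc_histogram",
    "kernel_eval",
    "csi_from_row",
    "cdi_from_histogram",
    "compute_rfc_maps",
    "zscore_map",
]

KERNEL_KINDS = (
    "abs_pow_1",
    "abs_pow_2",
    "abs_pow_3",
    "abs_pow_4",
    "sin2",
    "step",
    "sign",
)

#: kernels usable for CDI weighting (nonnegative, even)
CDI_KERNEL_KINDS = KERNEL_KINDS[:6]


@dataclass(frozen=True)
class Kernel:
    """Weighting function on [-1, 1] evaluated at histogram bin centers.

    ``abs_pow_p`` is |x|^p (p = 1..4), ``sin2`` is sin^2(pi x / 2),
    ``step`` is the square-well 1{|x| > tau} (classical degree-centrality
    thresholding, default tau = 0.3), and ``sign`` is the signum counting
    kernel (+1/-1/0), provided for completeness: weighted by it, the
    histogram yields signed counts of positive/negative correlations
    rather than a density, so it is excluded from the CDI path.
    """

    kind: str
    tau: float = 0.3

    def __post_init__(self) -> None:
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}; one of {KERNEL_KINDS}")
        if self.kind == "step" and not 0 < self.tau < 1:
            raise ValueError(f"step kernel threshold must be in (0, 1), got {self.tau}")

    @property
    def name(self) -> str:
        return self.kind

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        return kernel_eval(self, x)


def kernel_eval(k: Kernel, x: np.ndarray | float) -> np.ndarray | float:
    """Evaluate a kernel at correlation value(s) x in [-1, 1]."""
    x = np.asarray(x, dtype=np.float64)
    if np.any(np.abs(x) > 1 + 1e-12):
        raise ValueError("kernel argument outside [-1, 1]")
    if k.kind.startswith("abs_pow_"):
        p = int(k.kind.rsplit("_", 1)[1])
        out = np.abs(x) ** p
    elif k.kind == "sin2":
        out = np.sin(np.pi / 2.0 * x) ** 2
    elif k.kind == "step":
        out = (np.abs(x) > k.tau).astype(np.float64)
    elif k.kind == "sign":
        out = np.sign(x)
    else:  # pragma: no cover - guarded by Kernel.__post_init__
        raise ValueError(k.kind)
    return out if out.ndim else float(out)


@dataclass
class CCRow:
    """One voxel's correlations with every other in-mask voxel.

    ``values`` has length V-1 (self excluded); entries for degenerate
    (zero-variance) voxels are NaN and drop out of all summaries.
    """

    seed_index: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1 or finite.max() > 1):
            raise ValueError("correlation values outside [-1, 1]")


@dataclass
class CCHistogram:
    """Histogram of a correlation row over even bins on [-1, 1]."""

    edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.float64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.edges) != len(self.counts) + 1:
            raise ValueError("edges must be one longer than counts")
        if np.any(self.counts < 0):
            raise ValueError("histogram counts must be nonnegative")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class RFCMaps:
    """Per-voxel connectivity maps for one subject and one CDI kernel.

    NaN marks undefined entries (degenerate voxels, or an empty
    positive/negative part).
    """

    csi: np.ndarray
    csi_n: np.ndarray
    csi_p: np.ndarray
    cdi: np.ndarray
    cdi_n: np.ndarray
    cdi_p: np.ndarray
    kernel: Kernel


@dataclass
class RFCResult:
    """CSI maps plus CDI maps for each requested kernel."""

    csi: np.ndarray
    csi_n: np.ndarray
    csi_p: np.ndarray
    per_kernel: dict[str, RFCMaps] = field(default_factory=dict)


@dataclass
class ZMap:
    values: np.ndarray
    mu: float
    sigma: float


def standardize_rows(ts: TimeSeriesMatrix) -> TimeSeriesMatrix:
    """Center each voxel row and scale it to unit Euclidean norm.

    After standardization the dot product of two rows is their Pearson
    correlation.  Zero-variance rows cannot be standardized; they are
    zeroed and flagged in ``degenerate`` (not fatal — downstream metrics
    treat them as undefined).
    """
    if ts.n_frames < 3:
        raise ValueError("need at least 3 timeframes to correlate")
    centered = ts.values - ts.values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    scale = np.sqrt(ts.n_frames) * np.maximum(np.abs(ts.values).max(), 1.0)
    degenerate = norms <= 1e-13 * scale
    safe = np.where(degenerate, 1.0, norms)
    out = ts.copy_with(centered / safe[:, None])
    out.values[degenerate] = 0.0
    out.degenerate = degenerate
    return out


def cc_row(ts_std: TimeSeriesMatrix, seed: int) -> CCRow:
    """Correlations of one seed voxel with all others (self excluded)."""
    V = ts_std.n_voxels
    if not 0 <= seed < V:
        raise IndexError(f"seed {seed} out of range [0, {V})")
    degenerate = (
        ts_std.degenerate
        if ts_std.degenerate is not None
        else np.zeros(V, dtype=bool)
    )
    r = np.clip(ts_std.values @ ts_std.values[seed], -1.0, 1.0)
    r[degenerate] = np.nan
    if degenerate[seed]:
        r[:] = np.nan
    return CCRow(seed_index=seed, values=np.delete(r, seed))


def cc_histogram(row: CCRow | np.ndarray, n_bins: int = 200) -> CCHistogram:
    """Bin a correlation row into even bins on [-1, 1].

    Bins are left-closed/right-open with the last bin closed (so +1 lands
    in the final bin).  ``n_bins`` must be even so that 0 is a bin edge
    and the negative/positive parts split cleanly.  NaN entries
    (degenerate voxels) are ignored.
    """
    if n_bins < 2 or n_bins % 2:
        raise ValueError(f"n_bins must be even and >= 2, got {n_bins}")
    values = row.values if isinstance(row, CCRow) else np.asarray(row, dtype=float)
    values = values[np.isfinite(values)]
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    return CCHistogram(edges=edges, counts=counts)


def csi_from_row(row: CCRow | np.ndarray) -> tuple[float, float, float]:
    """Connectivity strength: (csi_p, csi_n, csi) for one row.

    csi_p averages the strictly positive coefficients, csi_n the strictly
    negative ones; csi is the mean over all (defined) coefficients.  An
    empty part yields NaN.
    """
    values = row.values if isinstance(row, CCRow) else np.asarray(row, dtype=float)
    values = values[np.isfinite(values)]
    pos = values[values > 0]
    neg = values[values < 0]
    csi_p = pos.mean() if pos.size else np.nan
    csi_n = neg.mean() if neg.size else np.nan
    csi = values.mean() if values.size else np.nan
    return float(csi_p), float(csi_n), float(csi)


def cdi_from_histogram(
    h: CCHistogram, k: Kernel, normalize: bool = True
) -> tuple[float, float, float]:
    """Connectivity density: (cdi_p, cdi_n, cdi) from a binned row.

    The kernel is evaluated at bin centers and inner-producted with the
    counts; bins with negative centers form cdi_n, positive centers
    cdi_p.  With ``normalize`` the sums are divided by the total count
    (V-1), making the metric invariant to mask size and bounded in
    [0, 1] for the six nonnegative kernels; without it the raw weighted
    counts are returned.
    """
    if k.kind not in CDI_KERNEL_KINDS:
        raise ValueError(
            f"kernel {k.kind!r} is not a density kernel; CDI supports {CDI_KERNEL_KINDS}"
        )
    centers = h.centers
    weights = kernel_eval(k, centers)
    neg = centers < 0
    pos = centers > 0
    denom = float(h.total) if normalize else 1.0
    if denom == 0:
        return np.nan, np.nan, np.nan
    cdi_n = float((h.counts[neg] * weights[neg]).sum() / denom)
    cdi_p = float((h.counts[pos] * weights[pos]).sum() / denom)
    return cdi_p, cdi_n, cdi_p + cdi_n


def compute_rfc_maps(
    ts: TimeSeriesMatrix,
    kernels: tuple[Kernel, ...] | list[Kernel] = (),
    block_size: int = 256,
    n_bins: int = 200,
    normalize: bool = True,
) -> RFCResult:
    """Whole-brain CSI and CDI maps via streamed correlation rows.

    Correlation rows are produced ``block_size`` seeds at a time, so the
    V x V matrix never exists in memory when V > block_size; results are
    independent of the block size.  Degenerate (zero-variance) voxels get
    NaN metrics and are excluded from every other voxel's row and from
    all denominators.
    """
    if ts.n_voxels < 2:
        raise ValueError("need at least 2 voxels")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    if n_bins < 2 or n_bins % 2:
        raise ValueError(f"n_bins must be even and >= 2, got {n_bins}")
    for k in kernels:
        if k.kind not in CDI_KERNEL_KINDS:
            raise ValueError(f"kernel {k.kind!r} cannot be used for CDI maps")

    ts_std = ts if ts.degenerate is not None else standardize_rows(ts)
    X = ts_std.values
    degenerate = ts_std.degenerate
    valid = ~degenerate
    Xv = X[valid]
    n_valid = int(valid.sum())
    if n_valid < 2:
        raise ValueError("fewer than 2 non-degenerate voxels")

    V = ts.n_voxels
    csi = np.full(V, np.nan)
    csi_n = np.full(V, np.nan)
    csi_p = np.full(V, np.nan)
    kvals = []
    cdi_acc = []
    centers = 0.5 * (
        np.linspace(-1, 1, n_bins + 1)[:-1] + np.linspace(-1, 1, n_bins + 1)[1:]
    )
    neg_bins = centers < 0
    pos_bins = centers > 0
    for k in kernels:
        kvals.append(kernel_eval(k, centers))
        cdi_acc.append(
            (np.full(V, np.nan), np.full(V, np.nan), np.full(V, np.nan))
        )
    bin_width = 2.0 / n_bins
    denom = float(n_valid - 1)

    valid_idx = np.flatnonzero(valid)
    for start in range(0, n_valid, block_size):
        rows_global = valid_idx[start : start + block_size]
        C = np.clip(X[rows_global] @ Xv.T, -1.0, 1.0)  # b x n_valid
        b = C.shape[0]
        brange = np.arange(b)

        pos_mask = C > 0
        neg_mask = C < 0
        pos_sum = np.where(pos_mask, C, 0.0).sum(axis=1) - 1.0  # drop self (r = 1)
        pos_cnt = pos_mask.sum(axis=1) - 1
        neg_sum = np.where(neg_mask, C, 0.0).sum(axis=1)
        neg_cnt = neg_mask.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            csi_p[rows_global] = np.where(pos_cnt > 0, pos_sum / pos_cnt, np.nan)
            csi_n[rows_global] = np.where(neg_cnt > 0, neg_sum / neg_cnt, np.nan)
        csi[rows_global] = (C.sum(axis=1) - 1.0) / denom

        if kernels:
            # per-row histograms via one flat bincount
            bins = np.minimum((C + 1.0) * (1.0 / bin_width), n_bins - 1).astype(
                np.int64
            )
            flat = bins + (np.arange(b)[:, None] * n_bins)
            counts = np.bincount(flat.ravel(), minlength=b * n_bins).reshape(
                b, n_bins
            )
            counts[brange, n_bins - 1] -= 1  # self correlation (exactly 1) out
            cdenom = denom if normalize else 1.0
            for kv, (acc_p, acc_n, acc) in zip(kvals, cdi_acc):
                wp = counts[:, pos_bins] @ kv[pos_bins] / cdenom
                wn = counts[:, neg_bins] @ kv[neg_bins] / cdenom
                acc_p[rows_global] = wp
                acc_n[rows_global] = wn
                acc[rows_global] = wp + wn

    result = RFCResult(csi=csi, csi_n=csi_n, csi_p=csi_p)
    for k, (acc_p, acc_n, acc) in zip(kernels, cdi_acc):
        result.per_kernel[k.name] = RFCMaps(
            csi=csi, csi_n=csi_n, csi_p=csi_p,
            cdi=acc, cdi_n=acc_n, cdi_p=acc_p, kernel=k,
        )
    return result


def zscore_map(values: np.ndarray) -> ZMap:
    """Standardize a map to zero mean, unit (population) SD.

    Undefined (NaN) entries are excluded from mu and sigma and propagate
    to the output.  A constant map has no z-score and is an error.
    """
    values = np.asarray(values, dtype=np.float64)
    defined = np.isfinite(values)
    if defined.sum() < 2:
        raise ValueError("need at least 2 defined values to z-score")
    mu = float(values[defined].mean())
    sigma = float(values[defined].std())
    if sigma == 0:
        raise ValueError("constant map has zero SD; z-score undefined")
    out = np.full_like(values, np.nan)
    out[defined] = (values[defined] - mu) / sigma
    return ZMap(values=out, mu=mu, sigma=sigma)
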