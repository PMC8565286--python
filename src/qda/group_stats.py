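"""Group-level inference on voxel-wise connectivity maps.

The workhorse is a two-step cluster test: (1) voxel-wise OLS of a
connectivity metric on age with gender as covariate, thresholded at an
uncorrected forming threshold (p < 0.001, i.e. |t| >= ~3.34 at df 224);
(2) family-wise error control by comparing observed cluster sizes
against the permutation null distribution of the maximum cluster
extent, obtained by permuting age across subjects and re-fitting.
Companion tools cover young-vs-elderly two-sample t-tests, logical-AND
overlap ROIs, seed-based correlation maps with Fisher-z one-sample
t-tests, mutual anti-correlation networks, and ROI-mean age trends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .io_volumes import BrainMask, TimeSeriesMatrix, map_to_grid
from .qda_core import standardize_rows

__all__ = [
    "RegressionMaps",
    "Cluster",
    "SeedMap",
    "RoiTrend",
    "read_phenotype",
    "fit_age_regression",
    "critical_t",
    "extract_clusters",
    "permutation_cluster_fwe",
    "two_sample_ttest",
    "select_subgroups",
    "overlap_rois",
    "seed_corr_map",
    "anticorr_network",
    "roi_mean_trend",
    "cluster_table",
]

#: stand-in for an infinite t-statistic (perfect fit / zero variance)
LARGE_T = 1e10

#: 6-connectivity (faces only) structuring element for 3D labeling
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class RegressionMaps:
    """Voxel-wise age-regression results.

    beta is the age coefficient (metric units per year), t its
    t-statistic, and r the partial correlation of age given gender,
    recovered from t via r = sign(t) * sqrt(t^2 / (t^2 + df)).
    """

    beta: np.ndarray
    r: np.ndarray
    t: np.ndarray
    df: int


@dataclass
class Cluster:
    """A face-connected set of supra-threshold voxels."""

    voxel_ids: np.ndarray  # indices into the mask scan order
    size: int
    com_mm: np.ndarray  # unweighted center of mass, world coordinates
    peak_t: float
    sign: int  # +1 positive-t cluster, -1 negative, 0 for plain ROIs
    mean_beta: float = np.nan
    mean_r: float = np.nan
    mass: float = np.nan  # sum of |t| over the cluster
    fwe_p: float | None = None


@dataclass
class SeedMap:
    """Seed-based correlation maps and their group one-sample t map."""

    seed_roi: np.ndarray
    subject_corr: np.ndarray  # n_subjects x V
    group_t: np.ndarray
    df: int


@dataclass
class RoiTrend:
    """ROI-mean metric per subject with its age regression."""

    roi_means: np.ndarray
    beta: float
    r: float
    t: float
    p: float
    df: int


def read_phenotype(path: str | Path) -> pd.DataFrame:
    """Read a cohort phenotype TSV (subject_id, age_years, gender 0/1)."""
    df = pd.read_csv(path, sep="\t")
    required = {"subject_id", "age_years", "gender"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject ids in phenotype table")
    if (df["age_years"] <= 0).any():
        raise ValueError("ages must be positive")
    return df


def _design(pheno: pd.DataFrame) -> np.ndarray:
    X = np.column_stack(
        [
            np.ones(len(pheno)),
            pheno["age_years"].to_numpy(dtype=float),
            pheno["gender"].to_numpy(dtype=float),
        ]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "rank-deficient design: age and gender must each vary across subjects"
        )
    return X


def _ols_t(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-column OLS of Y (n x V) on X; returns (beta_age, t_age, df)."""
    n, p = X.shape
    df = n - p
    if df < 1:
        raise ValueError(f"need more than {p} subjects, got {n}")
    xtx_inv = np.linalg.inv(X.T @ X)
    pinv = xtx_inv @ X.T
    B = pinv @ Y  # p x V
    resid = Y - X @ B
    sigma2 = (resid**2).sum(axis=0) / df
    beta = B[1]
    # numerically perfect fits: residual variance at rounding level
    scale = np.maximum((Y**2).mean(axis=0), 1e-300)
    exact = sigma2 <= 1e-24 * scale
    var_b = sigma2 * xtx_inv[1, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / np.sqrt(var_b)
    slope_zero = np.abs(beta) <= 1e-12 * np.sqrt(scale)
    t[exact & ~slope_zero] = np.sign(beta[exact & ~slope_zero]) * LARGE_T
    t[exact & slope_zero] = 0.0
    np.clip(t, -LARGE_T, LARGE_T, out=t)
    return beta, t, df


def fit_age_regression(maps: np.ndarray, pheno: pd.DataFrame) -> RegressionMaps:
    """Voxel-wise OLS of a metric on [intercept, age, gender].

    Voxels undefined (NaN) in any subject get undefined outputs.
    """
    maps = np.asarray(maps, dtype=np.float64)
    if maps.ndim != 2:
        raise ValueError("maps must be n_subjects x V")
    if maps.shape[0] != len(pheno):
        raise ValueError("number of map rows must match phenotype rows")
    if maps.shape[0] < 4:
        raise ValueError("need at least 4 subjects")
    X = _design(pheno)
    defined = np.isfinite(maps).all(axis=0)
    beta = np.full(maps.shape[1], np.nan)
    t = np.full(maps.shape[1], np.nan)
    b, tv, df = _ols_t(maps[:, defined], X)
    beta[defined] = b
    t[defined] = tv
    with np.errstate(invalid="ignore"):
        r = np.sign(t) * np.sqrt(t**2 / (t**2 + df))
    return RegressionMaps(beta=beta, r=r, t=t, df=df)


def critical_t(p_two_sided: float, df: int) -> float:
    """Two-sided Student-t critical value (e.g. p=0.001, df=224 -> ~3.34)."""
    if not 0 < p_two_sided < 1:
        raise ValueError("p must be in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.t.ppf(1.0 - p_two_sided / 2.0, df))


def _label_sign(
    t_grid: np.ndarray, t_crit: float, sign: int
) -> tuple[np.ndarray, int]:
    with np.errstate(invalid="ignore"):
        supra = t_grid >= t_crit if sign > 0 else t_grid <= -t_crit
    return ndimage.label(supra, structure=_STRUCT_6)


def _max_cluster_stat(
    t_grid: np.ndarray, t_crit: float, statistic: str
) -> tuple[float, float]:
    """Largest cluster statistic over both signs as an orderable pair.

    For ``extent`` the pair is (size, mass of that cluster): the integer
    size is the primary statistic and the continuous mass (sum of |t|)
    breaks size ties, which removes the heavy tying of a pure integer
    extent statistic and keeps the permutation p-value exact.  For
    ``mass`` the pair is (mass, 0).  (0, 0) when no cluster forms.
    """
    best = (0.0, 0.0)
    for sign in (+1, -1):
        labels, n = _label_sign(t_grid, t_crit, sign)
        if n == 0:
            continue
        masses = ndimage.sum_labels(
            np.abs(np.nan_to_num(t_grid)), labels, index=np.arange(1, n + 1)
        )
        if statistic == "extent":
            sizes = np.bincount(labels.ravel())[1:]
            i = np.lexsort((masses, sizes))[-1]
            cand = (float(sizes[i]), float(masses[i]))
        else:
            cand = (float(np.max(masses)), 0.0)
        best = max(best, cand)
    return best


def extract_clusters(
    t_map: np.ndarray,
    mask: BrainMask,
    t_crit: float,
    beta_map: np.ndarray | None = None,
    r_map: np.ndarray | None = None,
) -> list[Cluster]:
    """Face-connected supra-threshold clusters of a voxel-wise t map.

    Positive clusters come from {t >= t_crit}, negative from
    {t <= -t_crit}; connectivity is 6-neighborhood (faces only).
    """
    if t_crit <= 0:
        raise ValueError("t_crit must be positive")
    t_map = np.asarray(t_map, dtype=np.float64)
    t_grid = map_to_grid(t_map, mask, fill=np.nan)
    coords = mask.coordinates()
    index_grid = np.full(mask.shape, -1, dtype=np.intp)
    index_grid[coords[:, 0], coords[:, 1], coords[:, 2]] = np.arange(mask.n_voxels)
    world = mask.world_coordinates()

    clusters: list[Cluster] = []
    for sign in (+1, -1):
        labels, n = _label_sign(t_grid, t_crit, sign)
        for lab in range(1, n + 1):
            where = np.argwhere(labels == lab)
            ids = index_grid[where[:, 0], where[:, 1], where[:, 2]]
            ids = ids[ids >= 0]
            tvals = t_map[ids]
            clusters.append(
                Cluster(
                    voxel_ids=np.sort(ids),
                    size=len(ids),
                    com_mm=world[ids].mean(axis=0),
                    peak_t=float(tvals[np.argmax(np.abs(tvals))]),
                    sign=sign,
                    mean_beta=(
                        float(np.nanmean(beta_map[ids]))
                        if beta_map is not None
                        else np.nan
                    ),
                    mean_r=(
                        float(np.nanmean(r_map[ids])) if r_map is not None else np.nan
                    ),
                    mass=float(np.abs(tvals).sum()),
                )
            )
    clusters.sort(key=lambda c: -c.size)
    return clusters


def permutation_cluster_fwe(
    maps: np.ndarray,
    pheno: pd.DataFrame,
    mask: BrainMask,
    t_crit: float,
    n_perm: int = 1000,
    seed: int = 0,
    statistic: str = "extent",
) -> list[Cluster]:
    """Two-step cluster inference with permutation FWE correction.

    Observed clusters are formed at ``t_crit``; the null distribution of
    the maximum cluster extent (or mass) is built by permuting the age
    column across subjects — gender stays attached to each subject — and
    re-fitting.  Corrected p-values use the standard permutation form
    (1 + #{null >= observed}) / (1 + n_perm), so they are never 0 and the
    attainable floor is 1/(n_perm + 1).  With the (default) extent
    statistic, ties in the integer extent are broken by cluster mass so
    the p-value stays exact rather than conservative.  Deterministic
    given ``seed``.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    if statistic not in ("extent", "mass"):
        raise ValueError("statistic must be 'extent' or 'mass'")
    maps = np.asarray(maps, dtype=np.float64)
    reg = fit_age_regression(maps, pheno)
    clusters = extract_clusters(reg.t, mask, t_crit, reg.beta, reg.r)

    X = _design(pheno)
    defined = np.isfinite(maps).all(axis=0)
    Y = maps[:, defined]
    rng = np.random.default_rng(seed)
    null_max: list[tuple[float, float]] = []
    t_full = np.full(maps.shape[1], np.nan)
    for b in range(n_perm):
        Xp = X.copy()
        Xp[:, 1] = rng.permutation(X[:, 1])
        _, tv, _ = _ols_t(Y, Xp)
        t_full[defined] = tv
        t_grid = map_to_grid(t_full, mask, fill=np.nan)
        null_max.append(_max_cluster_stat(t_grid, t_crit, statistic))

    for c in clusters:
        obs = (float(c.size), c.mass) if statistic == "extent" else (c.mass, 0.0)
        exceed = sum(nm >= obs for nm in null_max)
        c.fwe_p = float((1 + exceed) / (1 + n_perm))
    return clusters


def two_sample_ttest(
    maps_a: np.ndarray, maps_b: np.ndarray, equal_var: bool = True
) -> tuple[np.ndarray, int]:
    """Pooled-variance two-sample t map (group A minus group B).

    Voxels with zero pooled variance yield t = 0 when the means agree and
    a large-finite +/-1e10 otherwise.  ``equal_var=False`` switches to
    Welch's statistic (df then approximated per-map via Satterthwaite at
    the map median and returned as an integer).
    """
    A = np.asarray(maps_a, dtype=np.float64)
    B = np.asarray(maps_b, dtype=np.float64)
    na, nb = A.shape[0], B.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 subjects")
    diff = A.mean(axis=0) - B.mean(axis=0)
    va = A.var(axis=0, ddof=1)
    vb = B.var(axis=0, ddof=1)
    if equal_var:
        df = na + nb - 2
        pooled = ((na - 1) * va + (nb - 1) * vb) / df
        se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    else:
        se = np.sqrt(va / na + vb / nb)
        with np.errstate(invalid="ignore", divide="ignore"):
            df_w = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
        df = int(np.nanmedian(df_w))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    zero = se == 0
    t[zero & (diff == 0)] = 0.0
    t[zero & (diff != 0)] = np.sign(diff[zero & (diff != 0)]) * LARGE_T
    np.clip(t, -LARGE_T, LARGE_T, out=t)
    return t, df


def select_subgroups(
    pheno: pd.DataFrame,
    young_range: tuple[float, float] = (18.0, 30.0),
    old_range: tuple[float, float] = (64.0, 76.0),
) -> tuple[list, list, list]:
    """Partition subjects into young/elderly subgroups by closed age
    intervals; subjects in neither interval are excluded."""
    ylo, yhi = young_range
    olo, ohi = old_range
    if ylo > yhi or olo > ohi:
        raise ValueError("age ranges must be ordered [lo, hi]")
    if max(ylo, olo) <= min(yhi, ohi):
        raise ValueError("young and elderly age ranges overlap")
    age = pheno["age_years"]
    young = pheno.loc[(age >= ylo) & (age <= yhi), "subject_id"].tolist()
    old = pheno.loc[(age >= olo) & (age <= ohi), "subject_id"].tolist()
    taken = set(young) | set(old)
    excluded = [s for s in pheno["subject_id"] if s not in taken]
    return young, old, excluded


def overlap_rois(
    clusters_a: list[Cluster], clusters_b: list[Cluster], mask: BrainMask
) -> list[Cluster]:
    """Logical-AND overlap of two cluster sets, re-split into
    face-connected components."""
    V = mask.n_voxels
    in_a = np.zeros(V, dtype=bool)
    in_b = np.zeros(V, dtype=bool)
    for c in clusters_a:
        in_a[c.voxel_ids] = True
    for c in clusters_b:
        in_b[c.voxel_ids] = True
    both = in_a & in_b
    if not both.any():
        return []
    grid = map_to_grid(both.astype(float), mask) > 0
    coords = mask.coordinates()
    index_grid = np.full(mask.shape, -1, dtype=np.intp)
    index_grid[coords[:, 0], coords[:, 1], coords[:, 2]] = np.arange(V)
    world = mask.world_coordinates()
    labels, n = ndimage.label(grid, structure=_STRUCT_6)
    out = []
    for lab in range(1, n + 1):
        where = np.argwhere(labels == lab)
        ids = np.sort(index_grid[where[:, 0], where[:, 1], where[:, 2]])
        out.append(
            Cluster(
                voxel_ids=ids,
                size=len(ids),
                com_mm=world[ids].mean(axis=0),
                peak_t=np.nan,
                sign=0,
            )
        )
    out.sort(key=lambda c: -c.size)
    return out


def seed_corr_map(
    ts_per_subject: list[TimeSeriesMatrix], roi: np.ndarray
) -> SeedMap:
    """Seed-based correlation maps for an ROI, with group inference.

    Per subject, the mean ROI time course is correlated with every
    in-mask voxel; the group map is a one-sample t-test across subjects
    on the Fisher-z-transformed correlations.  Zero-variance voxels
    across subjects get large-finite t where the mean z is nonzero.
    """
    roi = np.asarray(roi, dtype=np.intp)
    if roi.size == 0:
        raise ValueError("ROI is empty")
    n = len(ts_per_subject)
    V = ts_per_subject[0].n_voxels
    if roi.min() < 0 or roi.max() >= V:
        raise IndexError("ROI voxel indices outside the mask")
    corr = np.empty((n, V))
    for i, ts in enumerate(ts_per_subject):
        ts_std = ts if ts.degenerate is not None else standardize_rows(ts)
        seed_course = ts.values[roi].mean(axis=0)
        seed_course = seed_course - seed_course.mean()
        norm = np.linalg.norm(seed_course)
        if norm == 0:
            corr[i] = np.nan
            continue
        corr[i] = np.clip(ts_std.values @ (seed_course / norm), -1.0, 1.0)
        corr[i, ts_std.degenerate] = np.nan
    z = np.arctanh(np.clip(corr, -1 + 1e-15, 1 - 1e-15))
    mean_z = z.mean(axis=0)
    sd_z = z.std(axis=0, ddof=1) if n > 1 else np.zeros(V)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_z / (sd_z / np.sqrt(n))
    zero = sd_z == 0
    t[zero & (mean_z != 0)] = np.sign(mean_z[zero & (mean_z != 0)]) * LARGE_T
    t[zero & (mean_z == 0)] = 0.0
    np.clip(t, -LARGE_T, LARGE_T, out=t)
    return SeedMap(seed_roi=roi, subject_corr=corr, group_t=t, df=n - 1)


def anticorr_network(
    map_a: np.ndarray, map_b: np.ndarray, thr: float = -0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Mutually anti-correlated voxels of two seed correlation maps.

    Returns the indices where BOTH maps are <= ``thr`` (the conjunction
    reading of "multiply the maps and threshold negatively") together
    with the literal product map for inspection.
    """
    if thr >= 0:
        raise ValueError("threshold must be negative")
    a = np.asarray(map_a, dtype=np.float64)
    b = np.asarray(map_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("maps must have the same shape")
    with np.errstate(invalid="ignore"):
        sel = (a <= thr) & (b <= thr)
    return np.flatnonzero(sel), a * b


def roi_mean_trend(
    maps: np.ndarray, roi: np.ndarray, pheno: pd.DataFrame
) -> RoiTrend:
    """ROI-mean metric per subject regressed on age (gender covaried)."""
    roi = np.asarray(roi, dtype=np.intp)
    if roi.size == 0:
        raise ValueError("ROI is empty")
    maps = np.asarray(maps, dtype=np.float64)
    means = np.nanmean(maps[:, roi], axis=1)
    reg = fit_age_regression(means[:, None], pheno)
    t = float(reg.t[0])
    p = float(2.0 * stats.t.sf(min(abs(t), LARGE_T), reg.df))
    return RoiTrend(
        roi_means=means,
        beta=float(reg.beta[0]),
        r=float(reg.r[0]),
        t=t,
        p=p,
        df=reg.df,
    )


def cluster_table(clusters: list[Cluster]) -> pd.DataFrame:
    """Tabulate clusters (size, center of mass, beta x 10^3, r, FWE p)."""
    rows = []
    for c in clusters:
        rows.append(
            {
                "size_voxels": c.size,
                "com_x_mm": round(float(c.com_mm[0]), 3),
                "com_y_mm": round(float(c.com_mm[1]), 3),
                "com_z_mm": round(float(c.com_mm[2]), 3),
                "peak_t": round(float(c.peak_t), 4),
                "beta_e3": round(float(c.mean_beta * 1e3), 4),
                "r": round(float(c.mean_r), 4),
                "fwe_p": c.fwe_p if c.fwe_p is None else round(float(c.fwe_p), 6),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "size_voxels", "com_x_mm", "com_y_mm", "com_z_mm",
            "peak_t", "beta_e3", "r", "fwe_p",
        ],
    )
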