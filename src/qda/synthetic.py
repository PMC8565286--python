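"""Synthetic multi-subject BOLD cohorts with known ground truth.

Each subject is a 4D volume whose in-network voxels share a latent
band-limited (< 0.05 Hz by default) signal — emulating resting-state
low-frequency fluctuations — on top of AR(1) plus white noise.
Anti-correlated network pairs share one latent with opposite-sign
loadings.  The coupling amplitude can vary linearly with the subject's
age, planting a known aging effect for recovery experiments; an
optional spatial smoothing of the noise adds the local correlation that
cluster-extent inference presupposes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .io_volumes import BoldVolume, BrainMask
from .preprocess import NuisanceDesign

__all__ = [
    "NetworkSpec",
    "CohortSpec",
    "grid_mask",
    "sample_cohort",
    "simulate_subject",
    "subject_rng",
    "network_voxel_ids",
    "export_truth",
    "load_truth",
    "jaccard",
]

_FWHM_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class NetworkSpec:
    """A planted network: grid boxes sharing one latent signal.

    ``blocks`` are half-open index boxes ((x0, x1), (y0, y1), (z0, z1)).
    ``loading`` is the latent amplitude (negative for the anti-correlated
    member of a pair); ``age_slope`` changes the loading per year of age
    relative to the cohort age midpoint.  Networks with equal ``latent``
    labels share one latent signal.
    """

    name: str
    blocks: tuple
    loading: float = 1.0
    age_slope: float = 0.0
    latent: str | None = None

    @property
    def latent_id(self) -> str:
        return self.latent if self.latent is not None else self.name


@dataclass
class CohortSpec:
    """Everything needed to reproduce one synthetic cohort.

    Defaults mirror a typical adult resting-state study: ages uniform on
    18-76 years, TR 2.5 s, 150 timeframes, 4 mm voxels, AR(1) phi = 0.3,
    and a latent cut-off of 0.05 Hz.
    """

    n_subjects: int = 40
    age_range: tuple[float, float] = (18.0, 76.0)
    gender_balance: float = 0.5
    grid: tuple[int, int, int] = (12, 12, 8)
    T: int = 150
    tr_s: float = 2.5
    networks: tuple[NetworkSpec, ...] = ()
    ar1_phi: float = 0.3
    noise_sd: float = 1.0
    white_sd: float = 0.5
    latent_cutoff_hz: float = 0.05
    spatial_noise_fwhm_mm: float = 0.0
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 30:
            raise ValueError("need at least 30 timeframes")
        if not 0 <= self.ar1_phi < 1:
            raise ValueError("AR(1) coefficient must be in [0, 1)")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age range must be increasing")
        nyquist = 1.0 / (2.0 * self.tr_s)
        if self.latent_cutoff_hz > nyquist:
            raise ValueError(
                f"latent cutoff {self.latent_cutoff_hz} Hz above Nyquist {nyquist} Hz"
            )
        for net in self.networks:
            for (x0, x1), (y0, y1), (z0, z1) in net.blocks:
                if not (
                    0 <= x0 < x1 <= self.grid[0]
                    and 0 <= y0 < y1 <= self.grid[1]
                    and 0 <= z0 < z1 <= self.grid[2]
                ):
                    raise ValueError(
                        f"network {net.name!r} block outside grid {self.grid}"
                    )

    @property
    def age_mid(self) -> float:
        return 0.5 * (self.age_range[0] + self.age_range[1])

    def coupling(self, net: NetworkSpec, age: float) -> float:
        """Loading of a network at a given age (linear age modulation)."""
        coef = net.loading + net.age_slope * (age - self.age_mid)
        lo = net.loading + net.age_slope * (self.age_range[0] - self.age_mid)
        hi = net.loading + net.age_slope * (self.age_range[1] - self.age_mid)
        if net.loading != 0 and (
            np.sign(lo) != np.sign(net.loading) or np.sign(hi) != np.sign(net.loading)
        ):
            raise ValueError(
                f"network {net.name!r}: age slope flips the loading sign inside "
                "the cohort age range"
            )
        return coef


def grid_mask(spec: CohortSpec) -> BrainMask:
    """All-true brain mask covering the simulation grid."""
    return BrainMask(
        grid=np.ones(spec.grid, dtype=bool),
        voxel_size_mm=np.asarray(spec.voxel_size_mm),
    )


def sample_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw the cohort phenotype table; deterministic given the seed.

    Ages are uniform on the age range; gender is Bernoulli with
    P(gender = 1) = ``gender_balance``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    ages = rng.uniform(*spec.age_range, size=spec.n_subjects)
    genders = (rng.random(spec.n_subjects) < spec.gender_balance).astype(int)
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(spec.n_subjects)],
            "age_years": ages,
            "gender": genders,
        }
    )


def subject_rng(spec: CohortSpec, subject_index: int) -> np.random.Generator:
    """Per-subject generator: seeded with (cohort seed, subject index),
    so any subject is reproducible in isolation."""
    return np.random.default_rng([spec.rng_seed, subject_index])


def _band_limited_latent(
    rng: np.random.Generator, spec: CohortSpec
) -> np.ndarray:
    """Unit-variance low-frequency latent: low-passed white noise."""
    white = rng.standard_normal(spec.T + 60)
    nyquist = 1.0 / (2.0 * spec.tr_s)
    wn = min(spec.latent_cutoff_hz / nyquist, 0.99)
    b, a = signal.butter(4, wn)
    lat = signal.filtfilt(b, a, white)[60:]
    lat = lat - lat.mean()
    sd = lat.std()
    return lat / sd if sd > 0 else lat


def _ar1_noise(
    rng: np.random.Generator, shape: tuple, phi: float, sd: float
) -> np.ndarray:
    """AR(1) noise along the last axis with marginal SD ``sd``."""
    T = shape[-1]
    eps = rng.standard_normal(shape[:-1] + (T + 30,))
    ar = signal.lfilter([1.0], [1.0, -phi], eps, axis=-1)[..., 30:]
    return ar * (sd * np.sqrt(1.0 - phi**2))


def simulate_subject(
    spec: CohortSpec, age: float, subject_index: int
) -> tuple[BoldVolume, NuisanceDesign]:
    """Simulate one subject's 4D BOLD volume plus nuisance regressors.

    Member voxels of each network receive
    ``(loading + age_slope * (age - age_mid)) * latent(t)`` on top of
    the AR(1)-plus-white noise floor.  The emitted nuisance regressors
    are smooth random walks standing in for motion-parameter traces, so
    the cleaning pipeline can be exercised end to end.
    """
    rng = subject_rng(spec, subject_index)
    latents: dict[str, np.ndarray] = {}
    for net in spec.networks:
        if net.latent_id not in latents:
            latents[net.latent_id] = _band_limited_latent(rng, spec)

    shape = spec.grid + (spec.T,)
    noise = _ar1_noise(rng, shape, spec.ar1_phi, spec.noise_sd)
    noise += spec.white_sd * rng.standard_normal(shape)
    if spec.spatial_noise_fwhm_mm > 0:
        target_sd = noise.std()
        sigma_vox = spec.spatial_noise_fwhm_mm / (
            _FWHM_SIGMA * np.asarray(spec.voxel_size_mm)
        )
        noise = ndimage.gaussian_filter(
            noise, sigma=(*sigma_vox, 0.0), truncate=3.0
        )
        noise *= target_sd / noise.std()

    data = noise
    for net in spec.networks:
        coef = spec.coupling(net, age)
        lat = latents[net.latent_id]
        for (x0, x1), (y0, y1), (z0, z1) in net.blocks:
            data[x0:x1, y0:y1, z0:z1, :] += coef * lat

    walk = np.cumsum(0.1 * rng.standard_normal((spec.T, 6)), axis=0)
    design = NuisanceDesign(
        regressors=walk,
        names=["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"],
    )
    vol = BoldVolume(
        data=data,
        voxel_size_mm=np.asarray(spec.voxel_size_mm),
        tr_s=spec.tr_s,
    )
    return vol, design


def network_voxel_ids(spec: CohortSpec, net: NetworkSpec) -> np.ndarray:
    """Flat mask-scan-order indices of a network's member voxels."""
    mask = grid_mask(spec)
    member = np.zeros(spec.grid, dtype=bool)
    for (x0, x1), (y0, y1), (z0, z1) in net.blocks:
        member[x0:x1, y0:y1, z0:z1] = True
    coords = mask.coordinates()
    return np.flatnonzero(member[coords[:, 0], coords[:, 1], coords[:, 2]])


def export_truth(spec: CohortSpec, path: str | Path) -> None:
    """Write the machine-readable ground truth for recovery scoring."""
    truth = {
        "rng_seed": spec.rng_seed,
        "grid": list(spec.grid),
        "n_subjects": spec.n_subjects,
        "age_range": list(spec.age_range),
        "networks": [
            {
                "name": net.name,
                "loading": net.loading,
                "age_slope": net.age_slope,
                "latent": net.latent_id,
                "voxel_ids": network_voxel_ids(spec, net).tolist(),
            }
            for net in spec.networks
        ],
    }
    Path(path).write_text(json.dumps(truth, indent=1))


def load_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard overlap of two voxel-id sets."""
    sa, sb = set(np.asarray(a).tolist()), set(np.asarray(b).tolist())
    union = sa | sb
    return len(sa & sb) / len(union) if union else 0.0
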