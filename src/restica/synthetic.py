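"""Synthetic resting-state cohorts with planted group effects.

Real case/control resting-state fMRI data are access-restricted, so the rest
of the pipeline is exercised on simulated cohorts.  The generative model is
the standard linear spatiotemporal mixture

    Y(v, t) = sum_k a_k(t) * S_k(v) + eps(v, t)

with K spatially sparse, nonnegative network maps ``S_k`` (Gaussian blobs,
unit peak), band-limited unit-variance time courses ``a_k`` (power below
0.1 Hz at TR = 3 s) and spatially smoothed white noise ``eps``.  Group
effects are planted as

* an intranetwork amplitude shift ``delta`` added to a designated voxel set
  of one network's map for the listed groups (shared by both combat-exposed
  groups by default, i.e. a "Combat Increasing" region);
* an internetwork coupling effect: a shared latent band-limited signal mixed
  into both time courses of one network pair for the listed groups;
* a symptom link: inventory scores generated linearly from the per-subject
  amplitude of a designated region plus Gaussian noise, clipped to
  instrument ranges.

Everything is deterministic given (spec, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

GROUPS = ("PTSD", "CEC", "CC")

#: conversion between a Gaussian FWHM and its standard deviation
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# instrument bounds used to clip simulated inventory scores
PCL_RANGE = (17.0, 85.0)
BDI_RANGE = (0.0, 63.0)
PSSI_CLUSTER_RANGE = (0.0, 18.0)


class ConfigurationError(ValueError):
    """Raised when a ground-truth specification cannot be realized."""


@dataclass(frozen=True)
class EffectSpec:
    """Planted intranetwork effect: ``delta`` added to map values of one
    network on a fixed voxel set for the listed groups."""

    network: int
    voxels: tuple[tuple[int, int, int], ...]
    groups: tuple[str, ...]
    delta: float


@dataclass(frozen=True)
class FncSpec:
    """Planted internetwork coupling: per-group extra shared-signal variance
    fraction ``rho_extra`` mixed into both networks of ``pair``."""

    pair: tuple[int, int]
    rho_extra: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SymptomLink:
    """Linear link between a region's per-subject amplitude and scores.

    The per-subject amplitude of the region is its group shift plus a
    zero-mean Gaussian jitter with sd ``amplitude_sd`` (coherent across the
    region); scores add ``beta`` times that jitter to a group-level base and
    Gaussian noise with sd ``noise_sd``.
    """

    network: int
    voxels: tuple[tuple[int, int, int], ...]
    beta: float
    noise_sd: float
    amplitude_sd: float = 0.4


@dataclass
class GroundTruthSpec:
    grid_shape: tuple[int, int, int]
    voxel_size_mm: float
    n_networks: int
    network_maps: np.ndarray  # (K, x, y, z), nonnegative, unit peak
    brain_mask: np.ndarray  # boolean (x, y, z)
    tr_s: float
    n_timepoints: int
    effects: list[EffectSpec]
    fnc: FncSpec | None
    symptom: SymptomLink | None
    noise_sd: float
    smooth_fwhm_mm: float
    seed: int

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["network_maps"] = self.network_maps.tolist()
        d["brain_mask"] = self.brain_mask.astype(int).tolist()
        if self.fnc is not None:
            d["fnc"]["pair"] = list(self.fnc.pair)
        return json.dumps(d)


@dataclass
class SubjectScan:
    """One subject's 4-D BOLD-like volume plus phenotype."""

    subject_id: str
    data: np.ndarray  # (x, y, z, t)
    brain_mask: np.ndarray
    tr_s: float
    voxel_size_mm: float
    group: str
    age: float
    gender: int  # 0 male / 1 female
    iq: float
    pcl_total: float | None = None
    pssi_reexperiencing: float | None = None
    pssi_avoidance: float | None = None
    pssi_arousal: float | None = None
    bdi: float | None = None
    #: ground-truth bookkeeping: the symptom-region amplitude jitter drawn
    #: for this subject (None for real data)
    symptom_jitter: float | None = None

    def validate(self, n_networks: int | None = None) -> None:
        if not self.brain_mask.any():
            raise ValueError("brain mask is empty")
        inside = self.data[self.brain_mask]
        if not np.isfinite(inside).all():
            n_bad = int((~np.isfinite(inside)).sum())
            raise ValueError(f"{n_bad} non-finite values inside brain mask")
        if n_networks is not None and self.data.shape[-1] < 2 * n_networks:
            raise ValueError("time dimension shorter than 2x model order")


@dataclass
class CohortDataset:
    subjects: list[SubjectScan]
    ground_truth: GroundTruthSpec | None
    seed: int

    def by_group(self, group: str) -> list[SubjectScan]:
        return [s for s in self.subjects if s.group == group]

    @property
    def brain_mask(self) -> np.ndarray:
        return self.subjects[0].brain_mask


def gaussian_smooth(volume: np.ndarray, fwhm_mm: float, voxel_size_mm: float) -> np.ndarray:
    """Separable Gaussian smoothing of a 3-D volume.

    ``sigma`` in voxels is ``fwhm_mm / (voxel_size_mm * 2 sqrt(2 ln 2))``;
    boundary handling is reflect, which preserves total mass.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    volume = np.asarray(volume, dtype=float)
    if fwhm_mm == 0:
        return volume.copy()
    sigma = fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm
    return ndimage.gaussian_filter(volume, sigma=sigma, mode="reflect")


def _blob_centers(grid_shape: tuple[int, int, int], k: int, rng: np.random.Generator) -> np.ndarray:
    """Well-separated blob centers on an interior lattice, jittered by <=1 voxel."""
    # two complementary tetrahedra on the corners of the inner 0.3..0.7 cube
    fracs = [
        (0.30, 0.30, 0.30), (0.70, 0.70, 0.30), (0.30, 0.70, 0.70),
        (0.70, 0.30, 0.70), (0.70, 0.30, 0.30), (0.30, 0.70, 0.30),
        (0.70, 0.70, 0.70), (0.30, 0.30, 0.70),
    ]
    if k > len(fracs):
        raise ConfigurationError(f"cannot pack {k} networks; at most {len(fracs)} supported")
    shape = np.asarray(grid_shape, dtype=float)
    if (shape < 12).any():
        raise ConfigurationError("grid too small to pack separated networks (need >= 12 per axis)")
    centers = np.array(fracs[:k]) * shape
    centers = centers + rng.uniform(-1.0, 1.0, size=centers.shape)
    return centers


def make_ground_truth(
    grid_shape: tuple[int, int, int] = (24, 24, 24),
    voxel_size_mm: float = 3.0,
    n_networks: int = 6,
    tr_s: float = 3.0,
    n_timepoints: int = 150,
    blob_fwhm_vox: float = 5.0,
    noise_sd: float = 0.5,
    smooth_fwhm_mm: float = 6.0,
    effect_delta: float = 1.0,
    effect_network: int | None = None,
    effect_n_voxels: int = 30,
    effect_groups: tuple[str, ...] = ("PTSD", "CEC"),
    fnc_pair: tuple[int, int] | None = "default",
    fnc_rho_extra: dict[str, float] | None = None,
    symptom_network: int | None = None,
    symptom_n_voxels: int = 30,
    symptom_beta: float = 5.0,
    symptom_noise_sd: float = 2.0,
    symptom_amplitude_sd: float = 0.4,
    seed: int = 0,
) -> GroundTruthSpec:
    """Build the ground-truth specification for a synthetic cohort.

    Defaults plant one combat-shared intranetwork increase (``delta`` on
    ``effect_n_voxels`` voxels of one network in PTSD and CEC), one
    internetwork coupling shared by the combat groups, and a symptom link on
    a designated region of a *different* network (its per-subject amplitude
    jitter would otherwise inflate between-group variance on the planted
    contrast).  Deterministic given ``seed``.
    """
    if n_networks < 2:
        raise ConfigurationError("need at least 2 networks")
    if n_networks >= n_timepoints:
        raise ConfigurationError("need K < T")
    # resolve planted-effect placements against the network count
    if effect_network is None:
        effect_network = min(2, n_networks - 1)
    if symptom_network is None:
        symptom_network = 1 if n_networks > 1 else 0
    if fnc_pair == "default":
        fnc_pair = (n_networks - 2, n_networks - 1)
    for idx in (effect_network, symptom_network, *(fnc_pair or ())):
        if not (0 <= idx < n_networks):
            raise ConfigurationError(f"network index {idx} out of range for K={n_networks}")
    rng = np.random.default_rng(seed)
    centers = _blob_centers(grid_shape, n_networks, rng)
    sigma = blob_fwhm_vox * FWHM_TO_SIGMA
    grids = np.indices(grid_shape, dtype=float)
    maps = np.empty((n_networks,) + tuple(grid_shape))
    for k, c in enumerate(centers):
        d2 = sum((grids[i] - c[i]) ** 2 for i in range(3))
        m = np.exp(-d2 / (2.0 * sigma**2))
        m[m < 0.01] = 0.0  # sparsify far tails
        maps[k] = m / m.max()

    # ellipsoidal brain mask inscribed in the grid
    shape = np.asarray(grid_shape, dtype=float)
    half = (shape - 1) / 2.0
    d2 = sum(((grids[i] - half[i]) / (0.48 * shape[i])) ** 2 for i in range(3))
    brain_mask = d2 <= 1.0

    def _core_voxels(network: int, n: int) -> tuple:
        flat = maps[network].ravel()
        top = np.argsort(flat)[::-1][:n]
        return tuple(
            tuple(int(i) for i in np.unravel_index(ix, grid_shape)) for ix in sorted(top)
        )

    effects: list[EffectSpec] = []
    symptom: SymptomLink | None = None
    if effect_delta != 0.0 and effect_n_voxels > 0:
        effects.append(
            EffectSpec(effect_network, _core_voxels(effect_network, effect_n_voxels),
                       tuple(effect_groups), effect_delta)
        )
    if symptom_beta != 0.0 and symptom_n_voxels > 0:
        symptom = SymptomLink(
            symptom_network, _core_voxels(symptom_network, symptom_n_voxels),
            symptom_beta, symptom_noise_sd, symptom_amplitude_sd,
        )

    fnc = None
    if fnc_pair is not None:
        if fnc_rho_extra is None:
            fnc_rho_extra = {"PTSD": 0.5, "CEC": 0.5}
        fnc = FncSpec(tuple(fnc_pair), dict(fnc_rho_extra))

    gt = GroundTruthSpec(
        grid_shape=tuple(grid_shape),
        voxel_size_mm=voxel_size_mm,
        n_networks=n_networks,
        network_maps=maps,
        brain_mask=brain_mask,
        tr_s=tr_s,
        n_timepoints=n_timepoints,
        effects=effects,
        fnc=fnc,
        symptom=symptom,
        noise_sd=noise_sd,
        smooth_fwhm_mm=smooth_fwhm_mm,
        seed=seed,
    )
    _check_map_overlap(gt)
    return gt


def _check_map_overlap(gt: GroundTruthSpec, limit: float = 0.3) -> None:
    k = gt.n_networks
    flat = gt.network_maps.reshape(k, -1)
    r = np.corrcoef(flat)
    off = r[~np.eye(k, dtype=bool)]
    if np.abs(off).max() >= limit:
        raise ConfigurationError(
            f"network maps overlap too much (max |r| = {np.abs(off).max():.3f} >= {limit})"
        )


def _band_limited_timecourse(
    rng: np.random.Generator, n_t: int, tr_s: float, n_sinusoids: int = 8,
    f_max: float = 0.1, white_frac: float = 0.3,
) -> np.ndarray:
    """Unit-variance, zero-mean series with power concentrated below f_max Hz."""
    t = np.arange(n_t) * tr_s
    freqs = rng.uniform(0.005, f_max, size=n_sinusoids)
    phases = rng.uniform(0, 2 * np.pi, size=n_sinusoids)
    amps = rng.uniform(0.5, 1.0, size=n_sinusoids)
    x = (amps[:, None] * np.cos(2 * np.pi * freqs[:, None] * t + phases[:, None])).sum(axis=0)
    x = x + white_frac * np.std(x) * rng.standard_normal(n_t)
    x = x - x.mean()
    return x / x.std()


def _subject_maps(gt: GroundTruthSpec, group: str, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Per-subject effective network maps and the symptom-region jitter u."""
    maps = gt.network_maps.copy()
    for eff in gt.effects:
        if group in eff.groups:
            for v in eff.voxels:
                maps[eff.network][v] += eff.delta
    u = 0.0
    if gt.symptom is not None:
        u = float(rng.normal(0.0, gt.symptom.amplitude_sd))
        for v in gt.symptom.voxels:
            maps[gt.symptom.network][v] += u
    return maps, u


def _scores(group: str, u: float, gt: GroundTruthSpec, rng: np.random.Generator) -> dict:
    """Inventory scores: group base + planted linear link + noise, clipped."""
    beta = gt.symptom.beta if gt.symptom is not None else 0.0
    s_sd = gt.symptom.noise_sd if gt.symptom is not None else 1.0
    pcl_base = {"PTSD": 56.0, "CEC": 19.0, "CC": 19.0}[group]
    pcl_sd = {"PTSD": 6.0, "CEC": 2.5, "CC": 2.5}[group]
    out = {
        "pcl_total": float(np.clip(pcl_base + 2.0 * beta * u + rng.normal(0, pcl_sd), *PCL_RANGE)),
        "bdi": float(
            np.clip(
                {"PTSD": 28.0, "CEC": 2.0, "CC": 2.0}[group]
                + rng.normal(0, {"PTSD": 10.0, "CEC": 2.0, "CC": 2.0}[group]),
                *BDI_RANGE,
            )
        ),
    }
    if group == "PTSD":
        out["pssi_reexperiencing"] = float(np.clip(9.0 + rng.normal(0, 2.0), *PSSI_CLUSTER_RANGE))
        out["pssi_avoidance"] = float(np.clip(9.0 + beta * u + rng.normal(0, s_sd), *PSSI_CLUSTER_RANGE))
        out["pssi_arousal"] = float(np.clip(9.0 + rng.normal(0, 2.0), *PSSI_CLUSTER_RANGE))
    else:
        out["pssi_reexperiencing"] = out["pssi_avoidance"] = out["pssi_arousal"] = None
    return out


def simulate_timecourses(
    gt: GroundTruthSpec, group: str, rng: np.random.Generator
) -> np.ndarray:
    """Generating network time courses (K, T) for one subject, including the
    shared-signal internetwork coupling for groups listed in the FNC spec."""
    k, n_t = gt.n_networks, gt.n_timepoints
    tcs = np.stack([_band_limited_timecourse(rng, n_t, gt.tr_s) for _ in range(k)])
    if gt.fnc is not None:
        rho = gt.fnc.rho_extra.get(group, 0.0)
        shared = _band_limited_timecourse(rng, n_t, gt.tr_s)
        if rho > 0:
            i, j = gt.fnc.pair
            for idx in (i, j):
                mixed = np.sqrt(1.0 - rho) * tcs[idx] + np.sqrt(rho) * shared
                tcs[idx] = (mixed - mixed.mean()) / mixed.std()
    return tcs


def simulate_subject(
    gt: GroundTruthSpec, group: str, subject_seed: int, subject_id: str | None = None
) -> SubjectScan:
    """Simulate one subject's 4-D scan and phenotype from the ground truth."""
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    rng = np.random.default_rng(subject_seed)
    k = gt.n_networks

    tcs = simulate_timecourses(gt, group, rng)
    maps, u = _subject_maps(gt, group, rng)
    vol = np.einsum("kt,kxyz->xyzt", tcs, maps)

    noise = rng.standard_normal(vol.shape)
    if gt.smooth_fwhm_mm > 0:
        sigma = gt.smooth_fwhm_mm * FWHM_TO_SIGMA / gt.voxel_size_mm
        noise = ndimage.gaussian_filter(noise, sigma=(sigma, sigma, sigma, 0), mode="reflect")
        noise /= noise.std()
    vol += gt.noise_sd * noise

    scores = _scores(group, u, gt, rng)
    scan = SubjectScan(
        subject_id=subject_id or f"sub-{subject_seed:08d}",
        data=vol,
        brain_mask=gt.brain_mask.copy(),
        tr_s=gt.tr_s,
        voxel_size_mm=gt.voxel_size_mm,
        group=group,
        age=float(np.clip(rng.normal(32.5, 8.0), 19, 55)),
        gender=int(rng.random() < 0.10),
        iq=float(rng.normal(111.0 if group == "CC" else 98.0, 11.0)),
        symptom_jitter=u if gt.symptom is not None else None,
        **scores,
    )
    scan.validate(n_networks=k)
    return scan


def subject_seed_for(master_seed: int, index: int) -> int:
    """Deterministic subject seed from a master seed, independent of order."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def simulate_cohort(
    gt: GroundTruthSpec,
    n_per_group: tuple[int, int, int] = (12, 8, 8),
    seed: int = 0,
) -> CohortDataset:
    """Simulate a three-group cohort (PTSD, CEC, CC counts in ``n_per_group``)."""
    if any(n < 3 for n in n_per_group):
        raise ValueError("need at least 3 subjects per group")
    subjects = []
    idx = 0
    for group, n in zip(GROUPS, n_per_group):
        for _ in range(n):
            sid = f"sub-{idx + 1:03d}"
            subjects.append(simulate_subject(gt, group, subject_seed_for(seed, idx), sid))
            idx += 1
    return CohortDataset(subjects=subjects, ground_truth=gt, seed=seed)


def phenotype_table(cohort: CohortDataset):
    """Phenotype table (one row per subject) as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for s in cohort.subjects:
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "age": round(s.age, 2),
                "gender": s.gender,
                "iq": round(s.iq, 2),
                "pcl_total": None if s.pcl_total is None else round(s.pcl_total, 2),
                "pssi_reexperiencing": None
                if s.pssi_reexperiencing is None
                else round(s.pssi_reexperiencing, 2),
                "pssi_avoidance": None if s.pssi_avoidance is None else round(s.pssi_avoidance, 2),
                "pssi_arousal": None if s.pssi_arousal is None else round(s.pssi_arousal, 2),
                "bdi": None if s.bdi is None else round(s.bdi, 2),
            }
        )
    return pd.DataFrame(rows)
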