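"""Significant-discriminatory-region (SDR) detection.

For each non-artifact network: a right-tailed one-sample t-test over all
subjects' z-maps (Bonferroni over brain-mask voxels) defines the network
mask; two-sample voxel-wise t-tests (optionally covariate-adjusted) contrast
the three group pairs within that mask; a Monte-Carlo simulation of smooth
Gaussian noise on the same mask supplies a null distribution of maximal
cluster extents, giving the minimum significant cluster size k_min at
cluster-level alpha (and at alpha divided by the number of networks);
surviving clusters from the three contrasts are resolved into labeled SDRs
with overlap rules (overlapping same-direction PTSD-vs-CC and CEC-vs-CC
clusters merge into a single "Combat Increasing"/"Combat Decreasing" region
with the extent of the larger cluster; a single-pattern cluster overlapped
by two oppositely directed clusters yields two distinct SDRs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .synthetic import FWHM_TO_SIGMA

PAIR_LABELS = ("PTSD_vs_CC", "PTSD_vs_CEC", "CEC_vs_CC")

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class NetworkMask:
    component: int
    mask: np.ndarray
    n_voxels: int
    t_threshold: float
    alpha_voxel: float


@dataclass
class ContrastMap:
    component: int
    pair: str  # one of PAIR_LABELS, positive t means first group larger
    t_map: np.ndarray
    df: int
    covariates: list[str] = field(default_factory=list)


@dataclass
class ClusterNull:
    component: int
    n_iterations: int
    fwhm_mm: float
    max_extents: np.ndarray
    k_min: dict[float, int]

    def to_dict(self) -> dict:
        return {
            "component": self.component,
            "n_iterations": self.n_iterations,
            "fwhm_mm": self.fwhm_mm,
            "k_min": {str(a): int(k) for a, k in self.k_min.items()},
            "max_extents": self.max_extents.tolist(),
        }


@dataclass
class Cluster:
    voxels: np.ndarray  # (n, 3) int indices
    n_voxels: int
    size_mm3: float
    peak_t: float
    peak_index: tuple[int, int, int]
    peak_mm: tuple[float, float, float]
    pair: str = ""
    positive: bool = True  # first group > second group


@dataclass
class SDRecord:
    sdr_id: str
    component: int
    pattern: str
    voxels: np.ndarray
    size_mm3: float
    peak_t: float
    peak_mm: tuple[float, float, float]
    survives_bonferroni: bool


def build_network_mask(
    subject_maps: np.ndarray, brain_mask: np.ndarray, alpha: float = 0.05,
    component: int = 0,
) -> NetworkMask:
    """Right-tailed one-sample t over all subjects' z-maps, Bonferroni over
    brain-mask voxels; significant voxels form the network mask."""
    maps = np.asarray(subject_maps)
    if maps.ndim == 4:
        maps = maps[:, brain_mask]
    n = maps.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} zero-variance voxels excluded from network mask")
    n_vox = maps.shape[1]
    alpha_voxel = alpha / n_vox
    t_crit = float(stats.t.isf(alpha_voxel, df=n - 1))
    t = np.zeros(n_vox)
    ok = ~zero_var
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    keep = np.zeros_like(brain_mask)
    keep[brain_mask] = (t > t_crit) & ok
    return NetworkMask(component, keep, int(keep.sum()), t_crit, alpha_voxel)


def _glm_group_t(y: np.ndarray, group: np.ndarray, covariates: np.ndarray | None) -> tuple[np.ndarray, int]:
    """t of the group indicator in y ~ 1 + group (+ covariates), vectorized
    over columns of y.  Positive t means group==1 larger."""
    n = y.shape[0]
    cols = [np.ones(n), group.astype(float)]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        cols.extend(cov.T)
    design = np.column_stack(cols)
    p = design.shape[1]
    rank = np.linalg.matrix_rank(design)
    if rank < p:
        raise ValueError("design matrix rank-deficient (covariate collinear with group?)")
    pinv = np.linalg.pinv(design)
    beta = pinv @ y
    resid = y - design @ beta
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    xtx_inv = np.linalg.inv(design.T @ design)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 1e-300))
    return beta[1] / se, df


def pairwise_contrast(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    network_mask: np.ndarray,
    pair: str = "PTSD_vs_CC",
    covariates_a: np.ndarray | None = None,
    covariates_b: np.ndarray | None = None,
    component: int = 0,
    covariate_names: list[str] | None = None,
) -> ContrastMap:
    """Voxel-wise two-sample contrast within a network mask.

    Without covariates this is the pooled-variance two-sample t-test; with
    covariates, the t of the group coefficient in a per-voxel linear model.
    Positive t means group A > group B.
    """
    a, b = np.asarray(maps_a), np.asarray(maps_b)
    if a.ndim == 4:
        a = a[:, network_mask]
    if b.ndim == 4:
        b = b[:, network_mask]
    if a.shape[0] < 3 or b.shape[0] < 3:
        raise ValueError("need at least 3 subjects per group")
    y = np.vstack([a, b])
    group = np.concatenate([np.ones(a.shape[0]), np.zeros(b.shape[0])])
    cov = None
    if covariates_a is not None or covariates_b is not None:
        cov = np.vstack([np.atleast_2d(covariates_a.T).T, np.atleast_2d(covariates_b.T).T])
    t, df = _glm_group_t(y, group, cov)
    t_map = np.zeros(network_mask.shape)
    t_map[network_mask] = t
    return ContrastMap(component, pair, t_map, df, covariate_names or [])


def estimate_smoothness(
    residual_maps: list[np.ndarray], mask: np.ndarray, voxel_size_mm: float
) -> float:
    """Spatial smoothness (FWHM, mm) of residual maps.

    Classic first-difference estimator: for a Gaussian autocorrelation the
    lag-1 correlation rho satisfies var(dx) = 2 s^2 (1 - rho), and
    FWHM = voxel * 2 sqrt(2 ln 2) * sqrt(-1 / (4 ln rho)).  Axes with too
    few in-mask neighbor pairs are skipped; the geometric mean over axes and
    maps is returned (floor: one voxel).
    """
    if len(residual_maps) < 2:
        raise ValueError("need at least 2 residual maps")
    fwhms = []
    for m in residual_maps:
        m = np.asarray(m, dtype=float)
        vals = m[mask]
        s2 = vals.var()
        if s2 == 0:
            warnings.warn("constant residual map skipped in smoothness estimation")
            continue
        per_axis = []
        for ax in range(3):
            pair = mask & np.roll(mask, -1, axis=ax)
            idx = [slice(None)] * 3
            idx[ax] = slice(0, -1)
            pair = pair[tuple(idx)]
            if pair.sum() < 2:
                warnings.warn(f"axis {ax}: too few in-mask neighbors, skipped")
                continue
            d = np.diff(m, axis=ax)[pair]
            rho = 1.0 - d.var() / (2.0 * s2)
            if rho <= 0:
                per_axis.append(1.0)  # rougher than voxel scale
                continue
            sigma_vox = np.sqrt(-1.0 / (4.0 * np.log(rho)))
            per_axis.append(max(sigma_vox / FWHM_TO_SIGMA, 1.0))
        if per_axis:
            fwhms.append(np.exp(np.mean(np.log(per_axis))))
    if not fwhms:
        raise ValueError("smoothness estimation failed on all maps")
    return float(np.mean(fwhms) * voxel_size_mm)


def _max_cluster_extent(binary: np.ndarray, structure: np.ndarray) -> int:
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def _smooth_batch(noise: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-smooth the last three axes of a stacked noise array."""
    if sigma <= 0:
        return noise
    return ndimage.gaussian_filter(noise, sigma=(0,) * (noise.ndim - 3) + (sigma,) * 3,
                                   mode="reflect")


def monte_carlo_cluster_threshold(
    network_mask: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm: float,
    voxel_p: float = 0.001,
    n_iter: int = 1000,
    alpha_levels: tuple[float, ...] = (0.05, 0.05 / 13),
    seed: int = 0,
    connectivity: int = 26,
    component: int = 0,
    null_type: str = "z",
    group_sizes: tuple[int, int] | None = None,
) -> ClusterNull:
    """Monte-Carlo null of maximal cluster extents on a network mask.

    ``null_type='z'`` (default): each iteration smooths white Gaussian noise
    to ``fwhm_mm``, restricts to the mask, z-scores within the mask and
    thresholds two-sidedly at |z| > z_{1-p/2}.  ``null_type='t'`` instead
    simulates the two-sample pooled t-statistic on ``group_sizes`` smooth
    noise maps per iteration and thresholds at |t| > t_{1-p/2, df}; this
    matches the sampling distribution of the statistic actually thresholded
    in the contrasts (at low df a t-field crosses its higher threshold in
    smaller patches than a Gaussian field at the same marginal level).
    The maximal extent over sign-specific clusters is recorded;
    k_min(alpha) is the smallest k with empirical P(max extent >= k) <=
    alpha.
    """
    if network_mask.sum() < 10:
        raise ValueError("network mask smaller than 10 voxels; null is meaningless")
    if n_iter < 200:
        raise ValueError("need n_iter >= 200")
    if null_type not in ("z", "t"):
        raise ValueError(f"unknown null_type {null_type!r}")
    if null_type == "t" and (group_sizes is None or min(group_sizes) < 2):
        raise ValueError("t null requires group_sizes with at least 2 per group")
    rng = np.random.default_rng(seed)
    structure = _STRUCTURES[connectivity]
    sigma = fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm if fwhm_mm > 0 else 0.0

    # work on the padded bounding box of the mask
    pad = int(np.ceil(3 * sigma)) + 1
    bounds = [(max(w.min() - pad, 0), min(w.max() + pad + 1, s))
              for w, s in zip(np.where(network_mask), network_mask.shape)]
    sub = tuple(slice(lo, hi) for lo, hi in bounds)
    mask = network_mask[sub]
    shape = mask.shape
    extents = np.empty(n_iter, dtype=int)

    def record(stat_vals: np.ndarray, thr: float, i: int) -> None:
        vol = np.zeros(shape)
        vol[mask] = stat_vals
        extents[i] = max(
            _max_cluster_extent((vol > thr) & mask, structure),
            _max_cluster_extent((vol < -thr) & mask, structure),
        )

    if null_type == "z":
        z_thr = float(stats.norm.isf(voxel_p / 2.0))
        batch = 50
        for start in range(0, n_iter, batch):
            nb = min(batch, n_iter - start)
            noise = _smooth_batch(rng.standard_normal((nb,) + shape), sigma)
            vals = noise[:, mask]
            vals = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, keepdims=True)
            for j in range(nb):
                record(vals[j], z_thr, start + j)
    else:
        n_a, n_b = group_sizes
        df = n_a + n_b - 2
        t_thr = float(stats.t.isf(voxel_p / 2.0, df=df))
        n_tot = n_a + n_b
        batch = max(1, 800 // n_tot)
        for start in range(0, n_iter, batch):
            nb = min(batch, n_iter - start)
            noise = _smooth_batch(rng.standard_normal((nb, n_tot) + shape), sigma)
            vals = noise[:, :, mask]  # (nb, n_tot, V)
            a, b = vals[:, :n_a], vals[:, n_a:]
            diff = a.mean(axis=1) - b.mean(axis=1)
            sp2 = ((n_a - 1) * a.var(axis=1, ddof=1) + (n_b - 1) * b.var(axis=1, ddof=1)) / df
            t = diff / np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
            for j in range(nb):
                record(t[j], t_thr, start + j)

    # add-one Monte-Carlo exceedance estimate (Davison-Hinkley) so marginal
    # extents round toward the conservative side
    k_min = {}
    for alpha in alpha_levels:
        k = 1
        while ((extents >= k).sum() + 1) / (n_iter + 1) > alpha:
            k += 1
        k_min[alpha] = k
    return ClusterNull(component, n_iter, fwhm_mm, extents, k_min)


def extract_clusters(
    binary: np.ndarray,
    voxel_size_mm: float,
    connectivity: int = 26,
    t_map: np.ndarray | None = None,
    affine: np.ndarray | None = None,
) -> list[Cluster]:
    """Connected components of a binary map, with peak statistics.

    The peak is the voxel of maximal |t| (ties broken toward the smallest
    linear index); peak coordinates are voxel indices mapped through the
    affine (default: scaling by the voxel size).
    """
    structure = _STRUCTURES[connectivity]
    labels, n = ndimage.label(binary, structure=structure)
    out = []
    vol = voxel_size_mm**3
    for lab in range(1, n + 1):
        where = np.argwhere(labels == lab)
        if t_map is not None:
            tvals = t_map[tuple(where.T)]
            peak_pos = int(np.argmax(np.abs(tvals)))
            peak_t = float(tvals[peak_pos])
        else:
            peak_pos, peak_t = 0, 0.0
        pidx = tuple(int(i) for i in where[peak_pos])
        if affine is not None:
            mm = affine @ np.array([*pidx, 1.0])
            peak_mm = tuple(float(c) for c in mm[:3])
        else:
            peak_mm = tuple(float(i) * voxel_size_mm for i in pidx)
        out.append(
            Cluster(
                voxels=where, n_voxels=len(where), size_mm3=len(where) * vol,
                peak_t=peak_t, peak_index=pidx, peak_mm=peak_mm,
            )
        )
    return out


def significant_clusters(
    contrast: ContrastMap,
    network_mask: np.ndarray,
    null: ClusterNull,
    voxel_p: float = 0.001,
    voxel_size_mm: float = 3.0,
    connectivity: int = 26,
    affine: np.ndarray | None = None,
) -> list[tuple[Cluster, bool]]:
    """Suprathreshold clusters surviving k_min at the loosest alpha level.

    Returns (cluster, survives_bonferroni) pairs; ``survives_bonferroni``
    marks survival at the strictest alpha level of the null.
    """
    alphas = sorted(null.k_min)  # ascending: strictest first
    k_loose = null.k_min[alphas[-1]]
    k_strict = null.k_min[alphas[0]]
    t_thr = float(stats.t.isf(voxel_p / 2.0, df=contrast.df))
    out = []
    for sign in (1.0, -1.0):
        binary = (sign * contrast.t_map > t_thr) & network_mask
        for cl in extract_clusters(binary, voxel_size_mm, connectivity, contrast.t_map, affine):
            if cl.n_voxels >= k_loose:
                cl.pair = contrast.pair
                cl.positive = sign > 0
                out.append((cl, cl.n_voxels >= k_strict))
    return out


def _overlap(a: Cluster, b: Cluster) -> bool:
    sa = {tuple(v) for v in a.voxels}
    return any(tuple(v) in sa for v in b.voxels)


def resolve_sdr_patterns(
    clusters: list[tuple[Cluster, bool]], component: int
) -> list[SDRecord]:
    """Resolve one network's significant clusters into labeled SDRs.

    A PTSD-vs-CC cluster overlapping a same-direction CEC-vs-CC cluster
    merges into one SDR with the extent of the larger cluster, labeled
    Combat Increasing (both > CC) or Combat Decreasing (both < CC); ties in
    extent resolve toward the PTSD-contrast cluster.  Oppositely directed
    clusters overlapping the same single-pattern cluster stay distinct.
    Everything else becomes a single-contrast SDR.
    """
    ptsd = [(c, s) for c, s in clusters if c.pair == "PTSD_vs_CC"]
    cec = [(c, s) for c, s in clusters if c.pair == "CEC_vs_CC"]
    other = [(c, s) for c, s in clusters if c.pair == "PTSD_vs_CEC"]
    consumed_cec: set[int] = set()
    consumed_ptsd: set[int] = set()
    records: list[tuple[Cluster, bool, str]] = []

    for pi, (pc, ps) in enumerate(ptsd):
        for ci, (cc, cs) in enumerate(cec):
            if ci in consumed_cec or pc.positive != cc.positive:
                continue
            if _overlap(pc, cc):
                big, big_s = (pc, ps) if pc.n_voxels >= cc.n_voxels else (cc, cs)
                pattern = "Combat Increasing" if pc.positive else "Combat Decreasing"
                records.append((big, big_s or (ps and cs), pattern))
                consumed_cec.add(ci)
                consumed_ptsd.add(pi)
                break

    def single_pattern(c: Cluster) -> str:
        a, b = c.pair.split("_vs_")
        return f"{a}>{b}" if c.positive else f"{a}<{b}"

    for pi, (pc, ps) in enumerate(ptsd):
        if pi not in consumed_ptsd:
            records.append((pc, ps, single_pattern(pc)))
    for ci, (cc, cs) in enumerate(cec):
        if ci not in consumed_cec:
            records.append((cc, cs, single_pattern(cc)))
    for oc, os in other:
        records.append((oc, os, single_pattern(oc)))

    records.sort(key=lambda r: -r[0].n_voxels)
    out = []
    for ordinal, (cl, strict, pattern) in enumerate(records, start=1):
        out.append(
            SDRecord(
                sdr_id=f"{component}-{ordinal}",
                component=component,
                pattern=pattern,
                voxels=cl.voxels,
                size_mm3=cl.size_mm3,
                peak_t=cl.peak_t,
                peak_mm=cl.peak_mm,
                survives_bonferroni=strict,
            )
        )
    return out


def detect_sdrs(
    subject_networks: list,
    groups: list[str],
    brain_mask: np.ndarray,
    voxel_size_mm: float,
    components: list[int] | None = None,
    mask_alpha: float = 0.05,
    voxel_p: float = 0.001,
    cluster_alpha: float = 0.05,
    n_networks_bonferroni: int | None = None,
    n_iter: int = 1000,
    connectivity: int = 26,
    covariates: np.ndarray | None = None,
    seed: int = 0,
    affine: np.ndarray | None = None,
    smooth_fallback_fwhm_mm: float = 6.0,
) -> tuple[list[SDRecord], dict[int, NetworkMask], dict[int, ClusterNull]]:
    """Run the full SDR stage over all components of a cohort.

    ``subject_networks`` is one SubjectNetworks per subject, ``groups`` the
    matching group labels.  Smoothness for the Monte-Carlo null is estimated
    from within-group subject-map residuals within each network mask
    (fallback: the nominal smoothing kernel).  Cluster extents are
    calibrated against df-matched t-field nulls (one per distinct group-size
    pair per network).  Returns the SDR list plus per-component masks and
    per-(component, contrast) nulls.
    """
    k_n = subject_networks[0].maps.shape[0]
    components = list(range(k_n)) if components is None else components
    n_bonf = n_networks_bonferroni or len(components)
    alphas = (cluster_alpha, cluster_alpha / n_bonf)
    groups_arr = np.asarray(groups)
    pair_groups = {"PTSD_vs_CC": ("PTSD", "CC"), "PTSD_vs_CEC": ("PTSD", "CEC"),
                   "CEC_vs_CC": ("CEC", "CC")}
    all_records: list[SDRecord] = []
    masks: dict[int, NetworkMask] = {}
    nulls: dict[str, ClusterNull] = {}
    for comp in components:
        maps = np.stack([sn.maps[comp] for sn in subject_networks])
        nm = build_network_mask(maps, brain_mask, alpha=mask_alpha, component=comp)
        masks[comp] = nm
        if nm.n_voxels < 10:
            warnings.warn(f"component {comp}: network mask too small, skipped")
            continue
        # contrast-residual smoothness: within-group demeaned subject maps
        resid = maps.copy()
        for g in np.unique(groups_arr):
            sel = groups_arr == g
            resid[sel] -= maps[sel].mean(axis=0, keepdims=True)
        try:
            fwhm = estimate_smoothness(list(resid), nm.mask, voxel_size_mm)
        except ValueError:
            fwhm = smooth_fallback_fwhm_mm
        clusters: list[tuple[Cluster, bool]] = []
        null_by_sizes: dict[tuple[int, int], ClusterNull] = {}
        for pair, (ga, gb) in pair_groups.items():
            ia, ib = groups_arr == ga, groups_arr == gb
            sizes = (int(ia.sum()), int(ib.sum()))
            if sizes not in null_by_sizes:
                null_by_sizes[sizes] = monte_carlo_cluster_threshold(
                    nm.mask, fwhm, voxel_size_mm, voxel_p=voxel_p, n_iter=n_iter,
                    alpha_levels=alphas, seed=seed + comp, connectivity=connectivity,
                    component=comp, null_type="t", group_sizes=sizes,
                )
            null = null_by_sizes[sizes]
            nulls[f"{comp}:{pair}"] = null
            cov_a = covariates[ia] if covariates is not None else None
            cov_b = covariates[ib] if covariates is not None else None
            cm = pairwise_contrast(
                maps[ia], maps[ib], nm.mask, pair=pair, component=comp,
                covariates_a=cov_a, covariates_b=cov_b,
            )
            clusters.extend(
                significant_clusters(cm, nm.mask, null, voxel_p, voxel_size_mm,
                                     connectivity, affine)
            )
        all_records.extend(resolve_sdr_patterns(clusters, comp))
    return all_records, masks, nulls


def sdr_table(records: list[SDRecord]):
    """SDR summary table as a pandas DataFrame (one row per region)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "sdr_id": r.sdr_id,
                "component": r.component,
                "pattern": r.pattern,
                "size_mm3": r.size_mm3,
                "peak_t": round(r.peak_t, 3),
                "x_mm": r.peak_mm[0],
                "y_mm": r.peak_mm[1],
                "z_mm": r.peak_mm[2],
                "survives_bonferroni": r.survives_bonferroni,
            }
            for r in records
        ]
    )
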