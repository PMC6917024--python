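"""Group-level decomposition: two-stage PCA, Infomax ICA, ICASSO stability.

Temporal-concatenation group ICA: each subject's masked time series is
reduced to ``d1`` principal components, the reductions are stacked across
subjects and reduced/whitened to the model order ``d``, and spatial ICA is
run on the whitened voxel matrix.  Run-to-run reliability is assessed by the
ICASSO scheme: repeat ICA from random initializations, cluster the pooled
components on |spatial correlation| and report a per-cluster quality index
Iq (mean intra-cluster minus mean extra-cluster similarity); the run most
similar to the cluster centrotypes is retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .synthetic import CohortDataset, SubjectScan


class ConvergenceError(RuntimeError):
    """ICA failed to converge; carries the iteration count."""

    def __init__(self, n_iter: int):
        super().__init__(f"Infomax ICA did not converge after {n_iter} iterations")
        self.n_iter = n_iter


@dataclass
class PCAResult:
    reduced: np.ndarray  # (d1, V) orthogonal rows
    retained_variance: float


@dataclass
class ICAResult:
    sources: np.ndarray  # (d, V)
    unmixing: np.ndarray  # (d, d)
    n_iter: int
    converged: bool
    gaussian_warning: bool = False


@dataclass
class IcassoResult:
    sources: np.ndarray  # best run, (d, V)
    unmixing: np.ndarray
    stability_iq: np.ndarray  # (d,), aligned with sources rows
    best_run: int
    run_sources: list[np.ndarray] = field(default_factory=list, repr=False)


@dataclass
class ComponentLabel:
    component: int
    name: str
    matched_reference: int | None
    spatial_r: float


@dataclass
class GroupDecomposition:
    group_maps: np.ndarray  # (K_c, x, y, z) z-scored within mask
    mixing: np.ndarray  # (d, d) mixing in the reduced space
    stability_iq: np.ndarray
    artifact_flags: list[tuple[bool, list[str]]]
    brain_mask: np.ndarray
    pca_subject_dim: int
    model_order: int
    explained_variance: np.ndarray  # fraction per component, sorted descending

    @property
    def nonartifact_indices(self) -> list[int]:
        return [i for i, (f, _) in enumerate(self.artifact_flags) if not f]


def masked_timeseries(scan: SubjectScan) -> np.ndarray:
    """(T, V) matrix of in-mask time series with voxel means removed."""
    x = scan.data[scan.brain_mask].T.astype(float)  # (T, V)
    return x - x.mean(axis=0, keepdims=True)


def subject_pca(x, d1: int) -> PCAResult:
    """First-stage temporal PCA of one subject.

    ``x`` is a SubjectScan or a (T, V) matrix; voxel means over time are
    removed, then the top ``d1`` temporal principal directions are projected
    out, giving a (d1, V) matrix with orthogonal rows.
    """
    if isinstance(x, SubjectScan):
        x = masked_timeseries(x)
    x = np.asarray(x, dtype=float)
    t = x.shape[0]
    if d1 > t:
        raise ValueError(f"d1={d1} exceeds number of time points T={t}")
    x = x - x.mean(axis=0, keepdims=True)
    cov = x @ x.T / x.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    total = evals.sum()
    retained = float(evals[:d1].sum() / total) if total > 0 else 1.0
    reduced = evecs[:, :d1].T @ x
    return PCAResult(reduced=reduced, retained_variance=min(retained, 1.0))


def group_pca_concat(reduced_subjects: list[np.ndarray], d: int) -> np.ndarray:
    """Second-stage PCA on stacked subject reductions; output whitened.

    Returns a (d, V) matrix whose rows are zero-mean over voxels with
    identity covariance.
    """
    v_dims = {r.shape[1] for r in reduced_subjects}
    if len(v_dims) != 1:
        raise ValueError(f"inconsistent voxel counts across subjects: {sorted(v_dims)}")
    stacked = np.vstack(reduced_subjects)
    if d > stacked.shape[0]:
        raise ValueError(f"d={d} exceeds stacked dimension {stacked.shape[0]}")
    stacked = stacked - stacked.mean(axis=1, keepdims=True)
    cov = stacked @ stacked.T / stacked.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:d]
    evals, evecs = evals[order], evecs[:, order]
    return (evecs / np.sqrt(evals)).T @ stacked


def _fix_signs(sources: np.ndarray, unmixing: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # positive-skewness convention: the interesting tail is the positive one
    from scipy.stats import skew

    flips = np.where(skew(sources, axis=1) < 0, -1.0, 1.0)
    return sources * flips[:, None], unmixing * flips[:, None]


def infomax_ica(
    whitened: np.ndarray,
    seed: int = 0,
    lrate: float | None = None,
    max_iter: int = 2000,
    w_change_tol: float = 1e-6,
    anneal_deg: float = 60.0,
    anneal_scale: float = 0.9,
    k_freeze_iter: int = 10,
    late_decay_iter: int = 300,
) -> ICAResult:
    """Extended Infomax ICA (natural gradient, annealed learning rate).

    Operates on a whitened (d, V) matrix; block updates with a seeded random
    column permutation each pass.  The extended update switches the
    nonlinearity sign per component from the sub/super-Gaussian stability
    criterion, so both source kinds separate.  The learning rate is annealed
    when the update direction turns by more than ``anneal_deg`` degrees.
    Raises :class:`ConvergenceError` if the weight change never falls below
    ``w_change_tol``.
    """
    x = np.asarray(whitened, dtype=float)
    d, v = x.shape
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((d, d)))
    w = q
    if lrate is None:
        lrate = 0.01 / np.log(max(d, 3))
    block = int(min(max(32, np.floor(np.sqrt(v / 3.0))), v))
    eye = np.eye(d)
    sub_idx = rng.choice(v, size=min(v, 5000), replace=False)
    old_dw = None
    n_iter = 0
    converged = False
    k = np.ones(d)
    for n_iter in range(1, max_iter + 1):
        if n_iter <= k_freeze_iter:
            # sub/super-Gaussian switch: sign of E[sech^2 u]E[u^2] - E[u tanh u];
            # frozen after burn-in so the switch cannot oscillate late on
            us = w @ x[:, sub_idx]
            k = np.sign(
                (1.0 / np.cosh(us) ** 2).mean(axis=1) * (us**2).mean(axis=1)
                - (us * np.tanh(us)).mean(axis=1)
            )
            k[k == 0] = 1.0
        if n_iter > late_decay_iter:
            lrate *= 0.995  # force contraction if still wandering
        perm = rng.permutation(v)
        w_old = w.copy()
        blowup = False
        for start in range(0, v - block + 1, block):
            xb = x[:, perm[start : start + block]]
            u = w @ xb
            y = np.tanh(u)
            w = w + lrate * ((eye - (k[:, None] * y) @ u.T / block - u @ u.T / block) @ w)
            if not np.isfinite(w).all() or np.abs(w).max() > 1e8:
                blowup = True
                break
        if blowup:
            lrate *= 0.5
            q, _ = np.linalg.qr(rng.standard_normal((d, d)))
            w = q
            old_dw = None
            continue
        dw = w - w_old
        change = np.linalg.norm(dw) / max(np.linalg.norm(w), 1e-12)
        if old_dw is not None:
            denom = np.linalg.norm(dw) * np.linalg.norm(old_dw)
            if denom > 0:
                angle = np.degrees(np.arccos(np.clip((dw * old_dw).sum() / denom, -1, 1)))
                if angle > anneal_deg:
                    lrate *= anneal_scale
        old_dw = dw
        if change < w_change_tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(n_iter)

    sources = w @ x
    # order components by explained variance in the whitened space
    mixing = np.linalg.inv(w)
    var = (mixing**2).sum(axis=0) * (sources**2).mean(axis=1)
    order = np.argsort(var)[::-1]
    sources, w = sources[order], w[order]
    sources, w = _fix_signs(sources, w)

    from scipy.stats import kurtosis

    gauss = bool(np.all(np.abs(kurtosis(sources, axis=1)) < 0.1))
    if gauss:
        warnings.warn("all sources near-Gaussian: ICA solution is not identifiable")
    return ICAResult(sources=sources, unmixing=w, n_iter=n_iter, converged=True,
                     gaussian_warning=gauss)


def _abs_corr(a: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    a = a - a.mean(axis=1, keepdims=True)
    a = a / np.linalg.norm(a, axis=1, keepdims=True)
    if b is None:
        return np.abs(a @ a.T)
    b = b - b.mean(axis=1, keepdims=True)
    b = b / np.linalg.norm(b, axis=1, keepdims=True)
    return np.abs(a @ b.T)


def _negentropy_sum(sources: np.ndarray) -> float:
    from .backrecon import negentropy

    return float(sum(negentropy((s - s.mean()) / s.std()) for s in sources))


def icasso_select(
    whitened: np.ndarray, n_runs: int = 20, seed: int = 0, **ica_kwargs
) -> IcassoResult:
    """Run ICA ``n_runs`` times, cluster pooled components, pick the most
    reliable run.

    Components pooled over runs are clustered by average-linkage
    agglomerative clustering on dissimilarity 1 - |r|, cut at d clusters.
    Iq of a cluster is the mean intra-cluster |r| minus the mean |r| to all
    components outside it.  The selected run maximizes the summed |r| of its
    components to their cluster centrotypes.
    """
    if n_runs < 2:
        raise ValueError("need n_runs >= 2")
    d = whitened.shape[0]
    runs = []
    for i in range(n_runs):
        for attempt in range(3):
            run_seed = int(
                np.random.SeedSequence([int(seed), i, attempt]).generate_state(1)[0]
                & 0x7FFFFFFF
            )
            try:
                runs.append(infomax_ica(whitened, seed=run_seed, **ica_kwargs))
                break
            except ConvergenceError:
                if attempt == 2:
                    raise
                warnings.warn(f"ICA run {i} did not converge; re-seeding")
    pooled = np.vstack([r.sources for r in runs])  # (n_runs*d, V)
    sim = _abs_corr(pooled)
    np.fill_diagonal(sim, 1.0)
    dist = squareform(1.0 - sim, checks=False)
    labels = fcluster(linkage(dist, method="average"), t=d, criterion="maxclust")

    cluster_iq: dict[int, float] = {}
    centrotype: dict[int, int] = {}
    for c in np.unique(labels):
        members = np.where(labels == c)[0]
        outside = np.where(labels != c)[0]
        if len(members) == 1:
            intra = 1.0
        else:
            sub = sim[np.ix_(members, members)]
            intra = float((sub.sum() - len(members)) / (len(members) * (len(members) - 1)))
        extra = float(sim[np.ix_(members, outside)].mean()) if len(outside) else 0.0
        cluster_iq[c] = float(np.clip(intra - extra, 0.0, 1.0))
        totals = sim[np.ix_(members, members)].sum(axis=1)
        centrotype[c] = int(members[np.argmax(totals)])

    degenerate = len(np.unique(labels)) < d
    cents = np.array(sorted(centrotype.values()))
    best, best_score = 0, -np.inf
    for i in range(n_runs):
        rows = np.arange(i * d, (i + 1) * d)
        score = float(_abs_corr(pooled[rows], pooled[cents]).max(axis=1).sum())
        if score > best_score:
            best, best_score = i, score
    if degenerate:
        warnings.warn("degenerate ICASSO clustering; falling back to best run by negentropy")
        scores = [_negentropy_sum(r.sources) for r in runs]
        best = int(np.argmax(scores))

    iq = np.array([cluster_iq[labels[best * d + j]] for j in range(d)])
    return IcassoResult(
        sources=runs[best].sources,
        unmixing=runs[best].unmixing,
        stability_iq=iq,
        best_run=best,
        run_sources=[r.sources for r in runs],
    )


def zscore_map(map3d: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Z-score a 3-D map within the mask (population sd); zero outside."""
    vals = map3d[mask]
    sd = vals.std()
    if sd == 0:
        raise ValueError("constant map cannot be z-scored")
    out = np.zeros_like(map3d, dtype=float)
    out[mask] = (vals - vals.mean()) / sd
    return out


def edge_shell(mask: np.ndarray) -> np.ndarray:
    """Boundary shell of a binary mask (mask minus its erosion)."""
    return mask & ~ndimage.binary_erosion(mask)


def highfreq_power_fraction(tc: np.ndarray, tr_s: float, cutoff_hz: float = 0.10) -> float:
    """Fraction of periodogram power above ``cutoff_hz``."""
    f, p = signal.periodogram(tc - tc.mean(), fs=1.0 / tr_s)
    total = p.sum()
    return float(p[f > cutoff_hz].sum() / total) if total > 0 else 0.0


def flag_artifacts(
    maps: np.ndarray,
    brain_mask: np.ndarray,
    timecourses: np.ndarray | None = None,
    tr_s: float = 3.0,
    theta_edge: float = 0.5,
    theta_freq: float = 0.5,
    z_thresh: float = 2.0,
    manual_override: dict[int, bool] | None = None,
) -> list[tuple[bool, list[str]]]:
    """Heuristic artifact flags per component (edge-ring and high-frequency).

    A component is flagged if more than ``theta_edge`` of its supra-threshold
    voxels lie on the boundary shell of the brain mask, or if more than
    ``theta_freq`` of its time-course spectral power lies above 0.10 Hz.
    ``manual_override`` (component index -> flag) supersedes the heuristics,
    mirroring visual identification on real data.
    """
    shell = edge_shell(brain_mask)
    flags = []
    for i, m in enumerate(maps):
        reasons = []
        supra = (np.abs(m) > z_thresh) & brain_mask
        n_supra = supra.sum()
        if n_supra > 0 and (supra & shell).sum() / n_supra > theta_edge:
            reasons.append("edge_ring")
        if timecourses is not None:
            if highfreq_power_fraction(np.asarray(timecourses)[i], tr_s) > theta_freq:
                reasons.append("high_frequency")
        flagged = bool(reasons)
        if manual_override and i in manual_override:
            flagged = bool(manual_override[i])
            reasons = ["manual_override"]
        flags.append((flagged, reasons))
    return flags


def match_components(
    group_maps: np.ndarray,
    template_maps: np.ndarray,
    mask: np.ndarray | None = None,
    r_threshold: float = 0.2,
    template_names: list[str] | None = None,
) -> list[ComponentLabel]:
    """Greedy one-to-one matching of components to template networks by |r|."""
    gm = group_maps.reshape(len(group_maps), -1)
    tm = template_maps.reshape(len(template_maps), -1)
    if mask is not None:
        flat = mask.ravel()
        gm, tm = gm[:, flat], tm[:, flat]
    r = gm - gm.mean(axis=1, keepdims=True)
    t = tm - tm.mean(axis=1, keepdims=True)
    r /= np.linalg.norm(r, axis=1, keepdims=True)
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    corr = r @ t.T
    labels: dict[int, ComponentLabel] = {}
    used_c, used_t = set(), set()
    order = np.dstack(np.unravel_index(np.argsort(-np.abs(corr), axis=None), corr.shape))[0]
    for ci, ti in order:
        ci, ti = int(ci), int(ti)
        if ci in used_c or ti in used_t:
            continue
        if abs(corr[ci, ti]) < r_threshold:
            continue
        name = template_names[ti] if template_names else f"template-{ti}"
        labels[ci] = ComponentLabel(ci, name, ti, float(corr[ci, ti]))
        used_c.add(ci)
        used_t.add(ti)
    out = []
    for ci in range(len(group_maps)):
        if ci in labels:
            out.append(labels[ci])
        else:
            best = int(np.argmax(np.abs(corr[ci])))
            out.append(ComponentLabel(ci, f"component-{ci}", None, float(corr[ci, best])))
    return out


def decompose_cohort(
    cohort: CohortDataset,
    model_order: int | None = None,
    subject_pca_dim: int = 30,
    n_icasso_runs: int = 5,
    seed: int = 0,
    manual_artifacts: dict[int, bool] | None = None,
) -> GroupDecomposition:
    """Full group decomposition of a cohort.

    Model order defaults to the true network count on synthetic cohorts and
    to 20 otherwise (with a first subject-level reduction to
    ``subject_pca_dim``, default 30).
    """
    if model_order is None:
        model_order = cohort.ground_truth.n_networks if cohort.ground_truth else 20
    mask = cohort.brain_mask
    t = cohort.subjects[0].data.shape[-1]
    d1 = min(subject_pca_dim, t)
    if d1 < model_order:
        raise ValueError(f"subject PCA dim {d1} below model order {model_order}")
    reduced = [subject_pca(s, d1).reduced for s in cohort.subjects]
    whitened = group_pca_concat(reduced, model_order)
    ica = icasso_select(whitened, n_runs=n_icasso_runs, seed=seed)

    var = (ica.sources**2).mean(axis=1)
    explained = var / var.sum()

    maps = np.zeros((model_order,) + mask.shape)
    for i, src in enumerate(ica.sources):
        vol = np.zeros(mask.shape)
        vol[mask] = src
        maps[i] = zscore_map(vol, mask)

    flags = flag_artifacts(maps, mask, manual_override=manual_artifacts)
    if all(f for f, _ in flags):
        raise RuntimeError("all components flagged as artifacts")
    return GroupDecomposition(
        group_maps=maps,
        mixing=np.linalg.inv(ica.unmixing),
        stability_iq=ica.stability_iq,
        artifact_flags=flags,
        brain_mask=mask,
        pca_subject_dim=d1,
        model_order=model_order,
        explained_variance=explained,
    )
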