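"""Subject-level back-reconstruction of network maps and time courses.

Two routes are provided:

* **Reference-guided constrained ICA** (default): for each group-level
  reference map r_k, maximize over unit vectors w in the subject's whitened
  space the objective

      L(w) = J(y) + lambda * corr(y, r_k),      y = w^T X_w,

  where J is the one-unit negentropy approximation
  J(y) = (E[G(y)] - E[G(nu)])^2 with G(u) = log cosh(u) and nu standard
  normal.  The weight lambda on the spatial-similarity constraint is adapted
  upward until corr(y, r_k) >= rho_min.  This estimates subject-specific
  network maps that stay close to the group references while remaining
  maximally non-Gaussian (independent) in the subject's own data.

* **Dual regression** (oracle/baseline): spatial regression of the data on
  the group maps gives time courses; temporal regression of the data on
  those time courses gives subject maps.  Both stages are joint OLS.

Component time courses for connectivity analysis are estimated by a
per-time-point multiple regression of the volume on all subject maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .decomposition import masked_timeseries, zscore_map
from .synthetic import SubjectScan

_EG_NU: float | None = None


def _eg_nu() -> float:
    """E[log cosh(nu)] for nu ~ N(0,1), by fixed-seed Monte Carlo (cached)."""
    global _EG_NU
    if _EG_NU is None:
        rng = np.random.default_rng(20190083)
        _EG_NU = float(np.mean(np.log(np.cosh(rng.standard_normal(1_000_000)))))
    return _EG_NU


def negentropy(y: np.ndarray) -> float:
    """Negentropy approximation J(y) = (E[G(y)] - E[G(nu)])^2, G = log cosh."""
    return float((np.mean(np.log(np.cosh(y))) - _eg_nu()) ** 2)


@dataclass
class SubjectNetworks:
    subject_id: str
    maps: np.ndarray  # (K_n, x, y, z) z-scored within mask
    timecourses: np.ndarray  # (K_n, T), rows zero mean
    reference_corr: np.ndarray  # (K_n,)
    method: str  # 'guided' or 'dual_regression'
    brain_mask: np.ndarray = field(repr=False, default=None)
    fallback: list[int] = field(default_factory=list)


def _whiten_subject(x: np.ndarray, d_s: int) -> np.ndarray:
    """Whiten a (T, V) matrix to (d_s, V): zero-mean rows, identity covariance."""
    x = x - x.mean(axis=0, keepdims=True)
    x = x - x.mean(axis=1, keepdims=True)
    cov = x @ x.T / x.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:d_s]
    evals, evecs = np.maximum(evals[order], 1e-12), evecs[:, order]
    return (evecs / np.sqrt(evals)).T @ x


def _flatten_refs(references: np.ndarray, mask: np.ndarray) -> np.ndarray:
    refs = np.asarray(references)
    if refs.ndim == 4:
        refs = refs[:, mask]
    r = refs - refs.mean(axis=1, keepdims=True)
    return r / r.std(axis=1, keepdims=True)


def guided_component(
    x_w: np.ndarray,
    ref: np.ndarray,
    rho_min: float = 0.2,
    lam0: float = 1.0,
    lam_max: float = 64.0,
    step: float = 0.1,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> tuple[np.ndarray, float, bool]:
    """Constrained negentropy ascent for a single reference.

    Returns (map values over voxels, correlation with reference, success).
    ``x_w`` is the whitened (d_s, V) subject matrix; ``ref`` the z-scored
    reference over the same voxels.
    """
    v = x_w.shape[1]
    ref = (ref - ref.mean()) / ref.std()
    w = x_w @ ref / v  # projection of the reference into the whitened space
    nw = np.linalg.norm(w)
    if nw < 1e-12:
        return np.zeros(v), 0.0, False
    w = w / nw
    lam = lam0
    eg = _eg_nu()

    def objective(y):
        c = np.mean(np.log(np.cosh(y))) - eg
        return c * c + lam * float(y @ ref) / v

    success = False
    while True:
        cur_step = step
        y = w @ x_w
        obj = objective(y)
        for _ in range(max_iter):
            c = np.mean(np.log(np.cosh(y))) - eg
            grad = 2.0 * c * (x_w @ np.tanh(y)) / v + lam * (x_w @ ref) / v
            w_new = w + cur_step * grad
            w_new /= np.linalg.norm(w_new)
            y_new = w_new @ x_w
            obj_new = objective(y_new)
            if obj_new < obj:
                cur_step *= 0.5
                if cur_step < 1e-8:
                    break
                continue
            delta = np.linalg.norm(w_new - w)
            w, y, obj = w_new, y_new, obj_new
            if delta < tol:
                break
        corr = float(y @ ref) / (v * y.std())
        if corr >= rho_min:
            success = True
            break
        if lam >= lam_max:
            break
        lam *= 2.0
    y = w @ x_w
    corr = float(y @ ref) / (v * y.std())
    return y, corr, success


def guided_subject_maps(
    scan: SubjectScan,
    references: np.ndarray,
    rho_min: float = 0.2,
    extra_dims: int = 5,
    **opt_kwargs,
) -> SubjectNetworks:
    """Reference-guided subject maps for all (non-artifact) references.

    Each component is optimized independently in the subject's whitened
    space (dimension = number of references + ``extra_dims``).  Components
    whose similarity constraint cannot be met fall back to their dual
    regression map (recorded in ``fallback``).
    """
    mask = scan.brain_mask
    refs = _flatten_refs(references, mask)
    k_n = refs.shape[0]
    x = masked_timeseries(scan)
    d_s = min(k_n + extra_dims, x.shape[0])
    x_w = _whiten_subject(x, d_s)

    maps = np.zeros((k_n,) + mask.shape)
    corrs = np.zeros(k_n)
    fallback: list[int] = []
    dr = None
    for k in range(k_n):
        y, corr, ok = guided_component(x_w, refs[k], rho_min=rho_min, **opt_kwargs)
        if not ok:
            warnings.warn(f"component {k}: similarity constraint unattainable; "
                          "falling back to dual regression")
            if dr is None:
                dr = dual_regression(scan, references)
            maps[k] = dr.maps[k]
            corrs[k] = dr.reference_corr[k]
            fallback.append(k)
            continue
        vol = np.zeros(mask.shape)
        vol[mask] = y
        maps[k] = zscore_map(vol, mask)
        corrs[k] = corr
    tcs = estimate_timecourses(scan, maps)
    return SubjectNetworks(
        subject_id=scan.subject_id, maps=maps, timecourses=tcs,
        reference_corr=corrs, method="guided", brain_mask=mask, fallback=fallback,
    )


def dual_regression(scan: SubjectScan, references: np.ndarray) -> SubjectNetworks:
    """Two-stage (spatial then temporal) joint OLS back-projection."""
    mask = scan.brain_mask
    refs = _flatten_refs(references, mask)  # (K, V)
    x = masked_timeseries(scan)  # (T, V)
    design = refs.T  # (V, K)
    rank = np.linalg.matrix_rank(design)
    if rank < refs.shape[0]:
        raise ValueError(f"group maps rank-deficient over mask (rank {rank} < {refs.shape[0]})")
    # stage 1: time courses
    tcs, *_ = np.linalg.lstsq(design, x.T, rcond=None)  # (K, T)
    tcs = tcs - tcs.mean(axis=1, keepdims=True)
    # stage 2: subject maps
    beta, *_ = np.linalg.lstsq(tcs.T, x, rcond=None)  # (K, V)
    maps = np.zeros((refs.shape[0],) + mask.shape)
    corrs = np.zeros(refs.shape[0])
    for k in range(refs.shape[0]):
        b = beta[k]
        c = float(np.corrcoef(b, refs[k])[0, 1])
        if c < 0:
            b, c = -b, -c
            tcs[k] = -tcs[k]
        vol = np.zeros(mask.shape)
        vol[mask] = b
        maps[k] = zscore_map(vol, mask)
        corrs[k] = c
    return SubjectNetworks(
        subject_id=scan.subject_id, maps=maps, timecourses=tcs,
        reference_corr=corrs, method="dual_regression", brain_mask=mask,
    )


def estimate_timecourses(scan: SubjectScan, subject_maps: np.ndarray) -> np.ndarray:
    """Multiple regression of each volume on all subject maps jointly.

    Returns a (K, T) array with zero-mean rows.
    """
    mask = scan.brain_mask
    maps = np.asarray(subject_maps)
    if maps.ndim == 4:
        maps = maps[:, mask]
    design = maps.T  # (V, K)
    rank = np.linalg.matrix_rank(design)
    if rank < maps.shape[0]:
        raise ValueError(f"subject maps rank-deficient (rank {rank} < {maps.shape[0]})")
    x = masked_timeseries(scan)  # (T, V)
    tcs, *_ = np.linalg.lstsq(design, x.T, rcond=None)
    return tcs - tcs.mean(axis=1, keepdims=True)


def backreconstruct_cohort(
    cohort, references: np.ndarray, method: str = "guided", **kwargs
) -> list[SubjectNetworks]:
    """Back-reconstruct every subject in a cohort against shared references."""
    fn = {"guided": guided_subject_maps, "dual_regression": dual_regression}[method]
    return [fn(s, references, **kwargs) for s in cohort.subjects]
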