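"""Symptom-correlation statistics and summary-table tests.

Connectivity measures (mean z within a discriminatory region, or a
network-pair Fisher z) are correlated with symptom inventories.  The
correlation method is chosen by a bimodality rule: samples with strongly
platykurtic distributions (excess kurtosis below a threshold, default -1.0;
a balanced two-component mixture of well-separated normals approaches -2)
use Spearman's rank correlation, everything else Pearson's r.  Partial
correlations residualize both variables on the covariates first.  Group
comparisons recomputable from printed summary statistics (pooled two-sample
t, one-way ANOVA from group means/sds/ns, Pearson chi-square) are provided
for phenotype-table reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats


@dataclass
class SummaryGroup:
    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


@dataclass
class CorrelationResult:
    target: str
    inventory: str
    method: str
    coefficient: float
    p: float
    n: int
    partial_covariates: list[str] | None = None
    coefficient_partial: float | None = None
    p_partial: float | None = None


def mean_sdr_connectivity(subject_map: np.ndarray, voxels: np.ndarray) -> float:
    """Mean z-score of a subject's map over an SDR's voxel set."""
    voxels = np.asarray(voxels)
    if len(voxels) == 0:
        raise ValueError("empty voxel set")
    return float(subject_map[tuple(voxels.T)].mean())


def excess_kurtosis(x) -> float:
    """Moment estimator m4/m2^2 - 3 (population moments, no bias correction)."""
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    m = x - x.mean()
    m2 = np.mean(m**2)
    if m2 == 0:
        raise ValueError("zero variance")
    return float(np.mean(m**4) / m2**2 - 3.0)


def choose_method(x, kurtosis_threshold: float = -1.0) -> str:
    """'spearman' for clearly bimodal (platykurtic) samples, else 'pearson'."""
    return "spearman" if excess_kurtosis(x) < kurtosis_threshold else "pearson"


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _t_pvalue(r: float, df: int) -> float:
    if df <= 0:
        return np.nan
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df))


def _spearman_exact_p(rho: float, n: int) -> float:
    """Two-sided exact permutation p for Spearman's rho at small n (batched
    enumeration of all n! rank permutations)."""
    base = np.arange(1, n + 1, dtype=float)
    base = base - base.mean()
    denom = (base**2).sum()
    count = 0
    total = 0
    batch = []
    target = abs(rho) - 1e-12
    for perm in permutations(range(n)):
        batch.append(perm)
        if len(batch) == 100_000:
            rhos = (base[np.array(batch)] * base).sum(axis=1) / denom
            count += int((np.abs(rhos) >= target).sum())
            total += len(batch)
            batch = []
    if batch:
        rhos = (base[np.array(batch)] * base).sum(axis=1) / denom
        count += int((np.abs(rhos) >= target).sum())
        total += len(batch)
    return count / total


def correlate(x, y, method: str = "pearson") -> tuple[float, float, int]:
    """Correlation coefficient, two-sided p and n.

    Pearson: product-moment r with the t-based p.  Spearman: Pearson on
    average ranks; exact permutation p for n <= 10, t approximation above.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input")
    if method == "spearman":
        rx, ry = _rank(x), _rank(y)
        rho = float(np.corrcoef(rx, ry)[0, 1])
        p = _spearman_exact_p(rho, n) if n <= 10 else _t_pvalue(rho, n - 2)
        return rho, p, n
    if method == "pearson":
        r = float(np.corrcoef(x, y)[0, 1])
        return r, _t_pvalue(r, n - 2), n
    raise ValueError(f"unknown method {method!r}")


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_correlate(x, y, covariates, method: str = "pearson") -> tuple[float, float, int]:
    """Correlation of x and y after removing covariates by least squares.

    The Spearman variant rank-transforms all variables first.  p uses the t
    approximation with df = n - 2 - (number of covariates).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != x.size:
        cov = cov.T
    n, k = cov.shape
    if x.size != n or y.size != n:
        raise ValueError("length mismatch between variables and covariates")
    if n <= k + 3:
        raise ValueError("need n > number of covariates + 3")
    if method == "spearman":
        x, y = _rank(x), _rank(y)
        cov = np.column_stack([_rank(c) for c in cov.T])
    design = np.column_stack([np.ones(n), cov])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        sub_ranks = [np.linalg.matrix_rank(np.delete(design, i + 1, axis=1))
                     for i in range(k)]
        bad = [i for i, r in enumerate(sub_ranks) if r == rank]
        raise ValueError(f"covariate matrix rank-deficient (collinear column(s) {bad})")
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    if rx.std() <= 1e-10 * x.std() or ry.std() <= 1e-10 * y.std():
        raise ValueError("residual has zero variance after removing covariates")
    r = float(np.corrcoef(rx, ry)[0, 1])
    return r, _t_pvalue(r, n - 2 - k), n


def two_sample_t_from_summary(a: SummaryGroup, b: SummaryGroup) -> tuple[float, int]:
    """Pooled-variance two-sample t from printed group summaries."""
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    if sp2 == 0:
        return (0.0, df) if a.mean == b.mean else (np.inf, df)
    t = (a.mean - b.mean) / np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    return float(t), df


def oneway_anova_from_summary(groups: list[SummaryGroup]) -> tuple[float, int, int]:
    """One-way fixed-effects ANOVA F from group means, sds and ns."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups])
    sds = np.array([g.sd for g in groups])
    grand = (ns * means).sum() / ns.sum()
    ssb = (ns * (means - grand) ** 2).sum()
    ssw = ((ns - 1) * sds**2).sum()
    df1 = len(groups) - 1
    df2 = int(ns.sum()) - len(groups)
    if ssw == 0:
        return (0.0, df1, df2) if ssb == 0 else (np.inf, df1, df2)
    return float((ssb / df1) / (ssw / df2)), df1, df2


def chi_square_independence(counts: np.ndarray) -> tuple[float, int]:
    """Pearson chi-square for an R x C table, no continuity correction."""
    obs = np.asarray(counts, dtype=float)
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero marginal in contingency table")
    expected = np.outer(row, col) / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return chi2, df


def fisher_r_to_z(r: float) -> float:
    """Fisher's variance-stabilizing transform z = atanh(r)."""
    r = float(r)
    if abs(r) >= 1.0:
        raise ValueError(f"|r| must be < 1, got {r}")
    return float(np.arctanh(r))


def correlate_sdrs_with_symptoms(
    subject_networks: list,
    groups: list[str],
    sdr_records: list,
    phenotype,
    inventory: str = "pcl_total",
    pooled_groups: tuple[str, ...] = ("PTSD", "CEC"),
    kurtosis_threshold: float = -1.0,
    covariate_names: tuple[str, ...] = ("age", "gender", "iq"),
) -> list[CorrelationResult]:
    """Correlate each SDR's mean connectivity with an inventory score.

    Subjects come from ``pooled_groups``; the correlation method follows the
    bimodality rule on the pooled inventory sample; partial correlations
    control for the listed phenotype covariates.
    """
    idx = [i for i, g in enumerate(groups) if g in pooled_groups]
    scores = np.array([phenotype.iloc[i][inventory] for i in idx], dtype=float)
    keep = np.isfinite(scores)
    idx = [i for i, k in zip(idx, keep) if k]
    scores = scores[keep]
    if len(idx) < 4:
        raise ValueError("too few subjects with scores")
    method = choose_method(scores, kurtosis_threshold)
    cov = np.column_stack(
        [np.array([phenotype.iloc[i][c] for i in idx], dtype=float) for c in covariate_names]
    )
    out = []
    for rec in sdr_records:
        conn = np.array(
            [mean_sdr_connectivity(subject_networks[i].maps[rec.component], rec.voxels)
             for i in idx]
        )
        coef, p, n = correlate(conn, scores, method)
        try:
            cp, pp, _ = partial_correlate(conn, scores, cov, method)
        except ValueError:
            cp, pp = None, None
        out.append(
            CorrelationResult(
                target=rec.sdr_id, inventory=inventory, method=method,
                coefficient=coef, p=p, n=n,
                partial_covariates=list(covariate_names),
                coefficient_partial=cp, p_partial=pp,
            )
        )
    return out
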