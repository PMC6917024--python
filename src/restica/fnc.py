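"""Functional network connectivity (FNC): internetwork coupling statistics.

Component time courses are detrended, despiked (running-median/MAD rule)
and low-pass filtered (fifth-order Butterworth, 0.15 Hz cutoff, zero-phase);
pairwise Pearson correlations are Fisher r-to-z transformed; group
differences per network pair are tested by one-way ANOVA with Bonferroni
correction over tested pairs, followed by pairwise post hoc t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import signal, stats


@dataclass
class FNCMatrix:
    subject_id: str
    z_matrix: np.ndarray  # (K, K) symmetric, diagonal NaN
    cutoff_hz: float
    order: int
    tr_s: float
    degenerate_pairs: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class FNCTestResult:
    pair: tuple[int, int]
    f_stat: float
    df: tuple[int, int]
    p_uncorrected: float
    p_bonferroni: float
    posthoc: dict[str, float]  # contrast label -> corrected p
    group_means: dict[str, float]


def despike(tc: np.ndarray, window: int = 5, n_mad: float = 4.0) -> np.ndarray:
    """Replace points deviating from the running median (given window) by
    more than ``n_mad`` times the MAD of those deviations."""
    med = signal.medfilt(tc, kernel_size=window)
    dev = tc - med
    mad = np.median(np.abs(dev - np.median(dev)))
    if mad == 0:
        mad = np.mean(np.abs(dev)) or 1e-12
    out = tc.copy()
    bad = np.abs(dev) > n_mad * mad
    out[bad] = med[bad]
    return out


def postprocess_timecourse(
    tc: np.ndarray, tr_s: float, cutoff_hz: float = 0.15, order: int = 5
) -> np.ndarray:
    """Detrend, despike and zero-phase Butterworth low-pass a time course.

    The linear trend is removed by least squares; spikes are replaced by the
    running median; the filter is applied forward-backward (``filtfilt``),
    which squares the magnitude response (-6 dB at the cutoff).
    """
    tc = np.asarray(tc, dtype=float)
    if tc.size < 30:
        raise ValueError("need at least 30 time points")
    nyquist = 0.5 / tr_s
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyquist} Hz")
    x = signal.detrend(tc, type="linear")
    x = despike(x)
    b, a = signal.butter(order, cutoff_hz / nyquist)
    return signal.filtfilt(b, a, x)


def butterworth_gain_db(freq_hz: float, cutoff_hz: float, order: int = 5,
                        zero_phase: bool = False) -> float:
    """Analytic Butterworth magnitude response in dB at ``freq_hz``."""
    g = -10.0 * np.log10(1.0 + (freq_hz / cutoff_hz) ** (2 * order))
    return 2.0 * g if zero_phase else g


def fnc_matrix(
    timecourses: np.ndarray, tr_s: float, subject_id: str = "",
    cutoff_hz: float = 0.15, order: int = 5, postprocess: bool = True,
) -> FNCMatrix:
    """Fisher-z connectivity matrix from component time courses."""
    tcs = np.asarray(timecourses, dtype=float)
    if postprocess:
        tcs = np.stack([postprocess_timecourse(t, tr_s, cutoff_hz, order) for t in tcs])
    k = tcs.shape[0]
    z = np.full((k, k), np.nan)
    degenerate = []
    sds = tcs.std(axis=1)
    for i, j in combinations(range(k), 2):
        if sds[i] == 0 or sds[j] == 0:
            degenerate.append((i, j))
            continue
        r = float(np.corrcoef(tcs[i], tcs[j])[0, 1])
        clipped = np.clip(r, -1 + 1e-12, 1 - 1e-12)
        if clipped != r:
            degenerate.append((i, j))
        z[i, j] = z[j, i] = np.arctanh(clipped)
    return FNCMatrix(subject_id, z, cutoff_hz, order, tr_s, degenerate)


def fnc_group_tests(
    z_by_group: dict[str, list[FNCMatrix]],
    pairs_to_test: list[tuple[int, int]],
) -> list[FNCTestResult]:
    """One-way ANOVA on Fisher-z per network pair, Bonferroni over pairs,
    with pairwise post hoc t-tests (each p multiplied by 3, capped at 1)."""
    m = len(pairs_to_test)
    group_names = list(z_by_group)
    results = []
    for pair in pairs_to_test:
        i, j = pair
        samples = {}
        skip = False
        for g in group_names:
            vals = np.array([fm.z_matrix[i, j] for fm in z_by_group[g]])
            vals = vals[np.isfinite(vals)]
            if len(vals) < 3:
                warnings.warn(f"pair {pair}: group {g} has <3 usable subjects, skipped")
                skip = True
                break
            samples[g] = vals
        if skip:
            continue
        f, p = stats.f_oneway(*samples.values())
        n_total = sum(len(v) for v in samples.values())
        df = (len(samples) - 1, n_total - len(samples))
        posthoc = {}
        for ga, gb in combinations(group_names, 2):
            _, tp = stats.ttest_ind(samples[ga], samples[gb])
            posthoc[f"{ga}_vs_{gb}"] = min(1.0, float(tp) * 3)
        results.append(
            FNCTestResult(
                pair=pair, f_stat=float(f), df=df, p_uncorrected=float(p),
                p_bonferroni=min(1.0, float(p) * m), posthoc=posthoc,
                group_means={g: float(v.mean()) for g, v in samples.items()},
            )
        )
    return results


def fnc_for_cohort(
    subject_networks: list, groups: list[str], tr_s: float,
    pairs_to_test: list[tuple[int, int]] | None = None,
    cutoff_hz: float = 0.15, order: int = 5,
) -> tuple[dict[str, list[FNCMatrix]], list[FNCTestResult]]:
    """Connectivity matrices and group tests for a back-reconstructed cohort."""
    k = subject_networks[0].timecourses.shape[0]
    if pairs_to_test is None:
        pairs_to_test = list(combinations(range(k), 2))
    z_by_group: dict[str, list[FNCMatrix]] = {}
    for sn, g in zip(subject_networks, groups):
        fm = fnc_matrix(sn.timecourses, tr_s, sn.subject_id, cutoff_hz, order)
        z_by_group.setdefault(g, []).append(fm)
    return z_by_group, fnc_group_tests(z_by_group, pairs_to_test)
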