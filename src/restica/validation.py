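"""Reproducibility experiments: the package's own end-to-end checks.

Each function runs one self-contained experiment on synthetic cohorts (or on
printed summary statistics) and returns plain numbers.  They are used by the
test suite and by ``scripts/acceptance.py``; problem sizes are chosen for
desk-scale runs and are documented in the methods note.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage, stats

from . import backrecon, decomposition, fnc, sdr, symptoms
from .decomposition import decompose_cohort, match_components, zscore_map
from .synthetic import (
    FWHM_TO_SIGMA,
    make_ground_truth,
    simulate_cohort,
    simulate_subject,
    subject_seed_for,
)


def _derive(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence([int(seed), stream]).generate_state(1)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------- Table 1

def table1_statistics() -> dict:
    """Group comparisons recomputed from the printed cohort summaries:
    combat-exposure totals, lifetime trauma checklist, gender balance."""
    drri_t, drri_df = symptoms.two_sample_t_from_summary(
        symptoms.SummaryGroup("PTSD", 53.4, 16.2, 50),
        symptoms.SummaryGroup("CEC", 42.6, 14.5, 28),
    )
    lec_t, lec_df = symptoms.two_sample_t_from_summary(
        symptoms.SummaryGroup("PTSD", 5.8, 2.5, 49),
        symptoms.SummaryGroup("CEC", 4.0, 1.7, 28),
    )
    # gender counts from the printed percentages (92/93/88% male of 50/28/25)
    chi2, chi2_df = symptoms.chi_square_independence([[46, 26, 22], [4, 2, 3]])
    return {
        "drri_t": drri_t, "drri_df": drri_df,
        "lec_t": lec_t, "lec_df": lec_df,
        "gender_chi2": chi2, "gender_chi2_df": chi2_df,
    }


# ------------------------------------------------- decomposition recovery

def decomposition_recovery(seed: int = 0, cohort=None, decomp=None) -> dict:
    """Group decomposition of the default cohort (24^3 grid, T=150, 12/8/8):
    minimum |r| between matched group maps and the planted networks."""
    if cohort is None:
        gt = make_ground_truth(seed=seed)
        cohort = simulate_cohort(gt, (12, 8, 8), seed=seed)
    gt = cohort.ground_truth
    if decomp is None:
        decomp = decompose_cohort(cohort, seed=seed)
    labels = match_components(decomp.group_maps, gt.network_maps, mask=gt.brain_mask)
    rs = [abs(l.spatial_r) for l in labels if l.matched_reference is not None]
    return {
        "min_abs_r": float(min(rs)) if len(rs) == gt.n_networks else 0.0,
        "n_matched": len(rs),
        "n_subjects": len(cohort.subjects),
    }


# --------------------------------------------- back-reconstruction check

def backrecon_noninferiority(seed: int = 0, n_subjects: int = 20) -> dict:
    """Guided maps vs dual regression on truth-correlation, one simulated
    subject per replicate; also the minimal similarity to the references."""
    gt = make_ground_truth(seed=seed)
    mask = gt.brain_mask
    refs = np.stack([zscore_map(m, mask) for m in gt.network_maps])
    truth = gt.network_maps.copy()
    eff = gt.effects[0]
    for v in eff.voxels:
        truth[eff.network][v] += eff.delta
    truth = np.stack([zscore_map(m, mask) for m in truth])
    guided_rs, dual_rs, ref_corrs = [], [], []
    for i in range(n_subjects):
        scan = simulate_subject(gt, "PTSD", subject_seed_for(_derive(seed, 1), i))
        g = backrecon.guided_subject_maps(scan, refs)
        d = backrecon.dual_regression(scan, refs)
        k = gt.n_networks
        guided_rs.append(
            np.mean([np.corrcoef(g.maps[j][mask], truth[j][mask])[0, 1] for j in range(k)])
        )
        dual_rs.append(
            np.mean([np.corrcoef(d.maps[j][mask], truth[j][mask])[0, 1] for j in range(k)])
        )
        ok = [j for j in range(k) if j not in g.fallback]
        ref_corrs.append(g.reference_corr[ok].min())
    return {
        "guided_mean_truth_r": float(np.mean(guided_rs)),
        "dual_mean_truth_r": float(np.mean(dual_rs)),
        "difference": float(np.mean(guided_rs) - np.mean(dual_rs)),
        "min_reference_corr": float(min(ref_corrs)),
        "n_subjects": n_subjects,
    }


# --------------------------------------------------- cluster-null checks

def cluster_null_calibration(
    seed: int = 0, n_iter: int = 1000, n_fresh: int = 500,
    grid: tuple[int, int, int] = (24, 24, 24), fwhm_mm: float = 6.0,
    voxel_size_mm: float = 3.0, voxel_p: float = 0.001,
) -> dict:
    """Apply k_min(0.05) from the z-field null to fresh null maps and
    measure the familywise positive rate."""
    mask = np.ones(grid, dtype=bool)
    null = sdr.monte_carlo_cluster_threshold(
        mask, fwhm_mm, voxel_size_mm, voxel_p=voxel_p, n_iter=n_iter, seed=seed
    )
    k05 = null.k_min[0.05]
    k_bonf = null.k_min[0.05 / 13]
    rng = np.random.default_rng(_derive(seed, 2))
    sigma = fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm
    z_thr = float(stats.norm.isf(voxel_p / 2.0))
    struct = ndimage.generate_binary_structure(3, 3)
    hits = 0
    for _ in range(n_fresh):
        noise = ndimage.gaussian_filter(rng.standard_normal(grid), sigma, mode="reflect")
        vals = noise[mask]
        z = (vals - vals.mean()) / vals.std()
        vol = np.zeros(grid)
        vol[mask] = z
        ext = max(
            sdr._max_cluster_extent(vol > z_thr, struct),
            sdr._max_cluster_extent(vol < -z_thr, struct),
        )
        hits += ext >= k05
    return {
        "fwer": hits / n_fresh,
        "k_min_05": k05,
        "k_min_bonf13": k_bonf,
        "n_fresh": n_fresh,
    }


# ------------------------------------------------------------- SDR stage

def _mini_pipeline(seed: int, grid=(16, 16, 16), n_t=100, n_per_group=(8, 6, 6),
                   n_iter=500, with_sdr=True):
    gt = make_ground_truth(grid_shape=grid, n_timepoints=n_t, seed=seed)
    cohort = simulate_cohort(gt, n_per_group, seed=seed)
    decomp = decompose_cohort(cohort, seed=seed)
    nets = backrecon.backreconstruct_cohort(cohort, decomp.group_maps, method="guided")
    records = None
    if with_sdr:
        groups = [s.group for s in cohort.subjects]
        records, _, _ = sdr.detect_sdrs(
            nets, groups, cohort.brain_mask, gt.voxel_size_mm, n_iter=n_iter, seed=seed
        )
    return gt, cohort, decomp, nets, records


def sdr_planted_recovery(seed: int = 0, cohort=None, decomp=None) -> dict:
    """Default cohort: fraction of the planted combat-shared region covered
    by a Combat Increasing SDR on the matching component."""
    if cohort is None:
        gt = make_ground_truth(seed=seed)
        cohort = simulate_cohort(gt, (12, 8, 8), seed=seed)
    gt = cohort.ground_truth
    if decomp is None:
        decomp = decompose_cohort(cohort, seed=seed)
    nets = backrecon.backreconstruct_cohort(cohort, decomp.group_maps, method="guided")
    groups = [s.group for s in cohort.subjects]
    records, _, _ = sdr.detect_sdrs(
        nets, groups, cohort.brain_mask, gt.voxel_size_mm, n_iter=1000, seed=seed
    )
    labels = match_components(decomp.group_maps, gt.network_maps, mask=gt.brain_mask)
    eff = gt.effects[0]
    comp = next(l.component for l in labels if l.matched_reference == eff.network)
    planted = set(eff.voxels)
    overlap = 0.0
    for r in records:
        if r.component == comp and r.pattern == "Combat Increasing":
            overlap = max(overlap, len(planted & {tuple(v) for v in r.voxels}) / len(planted))
    return {"overlap": overlap, "n_planted_voxels": len(planted), "n_sdrs": len(records)}


def sdr_null_specificity(seed: int = 0, n_seeds: int = 20) -> dict:
    """Scaled cohorts with no PTSD-vs-CEC effect planted: count seeds whose
    familywise-corrected SDR table contains a PTSD-vs-CEC pattern."""
    clean = 0
    for i in range(n_seeds):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            *_, records = _mini_pipeline(_derive(seed, 100 + i))
        false_pos = [
            r for r in records
            if r.pattern in ("PTSD>CEC", "PTSD<CEC") and r.survives_bonferroni
        ]
        clean += not false_pos
    return {"clean_seeds": clean, "n_seeds": n_seeds, "clean_fraction": clean / n_seeds}


# ------------------------------------------------------------- FNC stage

def fnc_planted_coupling(seed: int = 0, n_seeds: int = 20) -> dict:
    """Scaled cohorts with the shared PTSD+CEC coupling: how often the
    planted pair is top-F with the expected post hoc pattern."""
    top_hits = pattern_hits = 0
    for i in range(n_seeds):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gt, cohort, decomp, nets, _ = _mini_pipeline(
                _derive(seed, 200 + i), with_sdr=False
            )
            groups = [s.group for s in cohort.subjects]
            _, results = fnc.fnc_for_cohort(nets, groups, gt.tr_s)
        top = max(results, key=lambda r: r.f_stat)
        labels = match_components(decomp.group_maps, gt.network_maps, mask=gt.brain_mask)
        comp_of_net = {l.matched_reference: l.component for l in labels}
        planted = tuple(sorted((comp_of_net[gt.fnc.pair[0]], comp_of_net[gt.fnc.pair[1]])))
        if tuple(sorted(top.pair)) == planted:
            top_hits += 1
            ph = top.posthoc
            if (ph["PTSD_vs_CC"] < 0.05 and ph["CEC_vs_CC"] < 0.05
                    and ph["PTSD_vs_CEC"] >= 0.05):
                pattern_hits += 1
    return {
        "top_f_hits": top_hits, "pattern_hits": pattern_hits, "n_seeds": n_seeds,
        "top_f_fraction": top_hits / n_seeds, "pattern_fraction": pattern_hits / n_seeds,
    }


def butterworth_gains(tr_s: float = 1.0, cutoff_hz: float = 0.15, order: int = 5) -> dict:
    """Single-pass gain measured on a sinusoid at the cutoff, plus the
    analytic stopband value at twice the cutoff."""
    from scipy import signal

    t = np.arange(4000) * tr_s
    x = np.sin(2 * np.pi * cutoff_hz * t)
    b, a = signal.butter(order, cutoff_hz / (0.5 / tr_s))
    single = signal.lfilter(b, a, x)[1000:-1000]
    measured_db = float(20 * np.log10(np.abs(single).max()))
    return {
        "gain_cutoff_db_measured": measured_db,
        "gain_cutoff_db_analytic": fnc.butterworth_gain_db(cutoff_hz, cutoff_hz, order),
        "gain_2x_cutoff_db_analytic": fnc.butterworth_gain_db(2 * cutoff_hz, cutoff_hz, order),
    }


# --------------------------------------------------------- symptom stage

def symptom_link_detection(seed: int = 0, n_seeds: int = 20, n_subjects: int = 50) -> dict:
    """PTSD-only cohorts of n=50: fraction of seeds where the avoidance
    score correlates with mean region connectivity at p < 0.01."""
    detections = 0
    for i in range(n_seeds):
        gt = make_ground_truth(grid_shape=(16, 16, 16), n_timepoints=60,
                               seed=_derive(seed, 300 + i))
        refs = np.stack([zscore_map(m, gt.brain_mask) for m in gt.network_maps])
        vox = np.array(gt.symptom.voxels)
        conns, scores = [], []
        for j in range(n_subjects):
            scan = simulate_subject(gt, "PTSD", subject_seed_for(_derive(seed, 300 + i), j))
            d = backrecon.dual_regression(scan, refs)
            conns.append(symptoms.mean_sdr_connectivity(d.maps[gt.symptom.network], vox))
            scores.append(scan.pssi_avoidance)
        _, p, _ = symptoms.correlate(conns, scores, "pearson")
        detections += p < 0.01
    return {
        "detections": detections, "n_seeds": n_seeds,
        "detection_fraction": detections / n_seeds, "n_subjects": n_subjects,
    }


def closed_form_checks() -> dict:
    """Exact values computable by hand: two-point kurtosis and the
    constructed partial-correlation case."""
    kurt = symptoms.excess_kurtosis(np.tile([-1.0, 1.0], 50))
    n = 12
    rng = np.random.default_rng(4)
    q, _ = np.linalg.qr(rng.standard_normal((n, 4)))
    e = np.column_stack([c - c.mean() for c in q[:, 1:].T])
    q2, _ = np.linalg.qr(e)
    e1, e2, e3 = q2[:, 0], q2[:, 1], q2[:, 2]
    x = e1
    z = 0.5 * e1 + np.sqrt(0.75) * e2
    a = 0.25 / np.sqrt(0.75)
    y = 0.5 * e1 + a * e2 + np.sqrt(1 - 0.25 - a**2) * e3
    partial, _, _ = symptoms.partial_correlate(x, y, z[:, None], "pearson")
    return {"two_point_excess_kurtosis": float(kurt), "partial_correlation": float(partial)}
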