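# restica

A group independent component analysis (ICA) comparison pipeline for
resting-state fMRI case/control cohorts, built around the three-group design
used in combat-related PTSD research: patients (PTSD), combat-exposed
controls (CEC) and civilian controls (CC).

The package covers the full analysis chain:

1. **Synthetic cohorts** — a generator for multi-subject 4-D BOLD-like data
   following the linear mixture `Y(v,t) = Σ_k a_k(t) S_k(v) + ε(v,t)` with
   K sparse nonnegative network maps, band-limited time courses (power below
   0.1 Hz at TR = 3 s) and spatially smoothed noise. Group effects are
   planted as intranetwork amplitude shifts, internetwork couplings and
   linear symptom links, so every downstream stage is testable without
   access-restricted clinical data.
2. **Group decomposition** — two-stage PCA (subject reduction to d₁, group
   reduction/whitening to model order d) followed by extended Infomax ICA,
   with ICASSO stability analysis (cluster quality index Iq over repeated
   runs) and heuristic artifact flagging (edge-ring and high-frequency
   features).
3. **Subject back-reconstruction** — reference-guided constrained ICA: for
   each group reference r_k, maximize `J(y) + λ·corr(y, r_k)` over the
   subject's whitened space, where `J(y) = (E[G(y)] − E[G(ν)])²` with
   `G = log cosh` is the negentropy approximation. Dual regression is
   provided as the baseline/oracle route.
4. **Discriminatory regions (SDRs)** — per-network one-sample masks
   (Bonferroni over brain voxels), voxel-wise two-sample t contrasts
   (p < 0.001, optionally covariate-adjusted), Monte-Carlo cluster-extent
   correction per network mask (cluster-level p < 0.05 and p < 0.05/K), and
   overlap rules that merge concordant PTSD-vs-CC and CEC-vs-CC clusters
   into "Combat Increasing"/"Combat Decreasing" regions.
5. **Functional network connectivity (FNC)** — detrend/despike, fifth-order
   Butterworth low-pass (0.15 Hz), pairwise Fisher r-to-z, one-way ANOVA per
   network pair with Bonferroni correction and post hoc t-tests.
6. **Symptom statistics** — mean SDR connectivity vs inventory scores
   (PCL, PSS-I clusters, BDI), with Pearson/Spearman chosen by a bimodality
   rule (excess kurtosis), partial correlations controlling for age, gender
   and IQ, and group-comparison tests recomputable from printed summary
   statistics (pooled t, one-way ANOVA, Pearson χ²).

## Worked example

```python
from restica import (make_ground_truth, simulate_cohort, decompose_cohort,
                     detect_sdrs, sdr_table)
from restica.backrecon import backreconstruct_cohort

gt = make_ground_truth(seed=7)                  # 24^3 grid, K=6, TR 3 s
cohort = simulate_cohort(gt, (12, 8, 8), seed=7)
decomp = decompose_cohort(cohort, seed=7)
nets = backreconstruct_cohort(cohort, decomp.group_maps)
records, masks, nulls = detect_sdrs(
    nets, [s.group for s in cohort.subjects], cohort.brain_mask,
    voxel_size_mm=3.0, seed=7,
)
print(sdr_table(records)[["sdr_id", "pattern", "size_mm3", "peak_t",
                          "survives_bonferroni"]])
```

```
  sdr_id            pattern  size_mm3  peak_t  survives_bonferroni
0    0-1  Combat Increasing     270.0   6.982                 True
1    2-1  Combat Increasing     216.0   6.287                 True
2    5-1  Combat Decreasing    5373.0 -24.013                 True
3    5-2  Combat Increasing     810.0  47.184                 True
```

The 810 mm³ Combat Increasing region on component 5 is exactly the planted
30-voxel combat-shared amplitude increase (30 × 27 mm³); the large Combat
Decreasing region is its complement inside the same network mask (z-scored
subject maps renormalize, so a focal increase depresses the rest of the
network), and the two small clusters sit on the internetwork-coupling pair,
where the shared signal leaks a little of each map into the other for the
combat groups. A full synthetic run is also available from the shell:

```bash
restica run-all --seed 7 --output out/
restica report out/
```

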