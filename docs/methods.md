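# Methods

## Generative model for synthetic cohorts

Real three-group resting-state cohorts of this kind are access-restricted,
so the pipeline ships with a generator whose output mimics the data regime
the analysis is designed for: 3 mm isotropic voxels, TR = 3 s, ~150 time
points, 6 mm FWHM spatial smoothing. Each subject's 4-D volume is

    Y(v, t) = Σ_k a_k(t) · S_k(v) + σ · ε(v, t)

* **Network maps `S_k`** — K Gaussian blobs (FWHM ≈ 5 voxels, unit peak,
  tails below 0.01 truncated) centered on two complementary tetrahedra of
  the inner 0.3–0.7 cube of the grid, jittered ≤ 1 voxel per seed. Pairwise
  spatial correlation is validated to stay below 0.3 (default placement
  gives ≈ 0.03). The brain mask is the inscribed ellipsoid.
* **Time courses `a_k`** — sums of 8 random-phase sinusoids with
  frequencies drawn from 0.005–0.1 Hz plus 30% white noise, standardized to
  zero mean, unit variance. No task structure, motion or physiological
  regressors are modeled; the published generative process of real data is
  unknown, so these are explicit stand-ins.
* **Noise `ε`** — white Gaussian noise smoothed with the 6 mm kernel and
  rescaled to unit variance, so `σ` (default 0.5) is the effective
  per-voxel noise sd relative to the unit-variance network signal.

Planted group structure (the defaults define the study conditions):

* **Intranetwork effect** — δ = 1.0 added to the 30 strongest-support
  voxels of network 2 for PTSD and CEC subjects ("combat-shared" increase).
* **Internetwork coupling** — a shared latent band-limited signal mixed
  into both time courses of the pair (K−2, K−1) with variance fraction
  ρ = 0.5 for PTSD and CEC only.
* **Symptom link** — the 30 core voxels of network 1 receive a per-subject
  coherent amplitude jitter u ~ N(0, 0.4); the avoidance score is
  9 + 5·u + N(0, 2) (clipped to the instrument range) and the total
  symptom checklist adds 10·u to group-level bases (56 for PTSD, 19 for
  controls), giving the strongly bimodal pooled distribution the
  bimodality rule is designed for. The symptom region is deliberately a
  *different* network than the group-effect region: a coherent amplitude
  jitter on the contrast region would inflate between-group variance there
  and couple two otherwise independent experiments.
* **Phenotypes** — age ~ N(32.5, 8) (clipped 19–55), gender ~ Bernoulli(0.1)
  for the female code (matching the ~90/10 split of such cohorts), IQ
  ~ N(98, 11) for the combat groups and N(111, 11) for civilian controls.

Subject seeds derive from the master seed by integer hashing
(`SeedSequence([seed, index])`), so cohorts are bit-reproducible and
independent of iteration order.

What passing tests on this generator do **not** show: robustness to motion,
registration error, physiological confounds, non-stationary noise, or
inter-subject spatial variability of network topography — none of which are
simulated.

## Group decomposition

Subject data are masked, voxel-mean-removed over time and reduced to d₁
(default 30) temporal principal components; the stacked reductions are
reduced to the model order d and whitened over voxels. On synthetic cohorts
d defaults to the true network count; for real-data scale the defaults d=20,
d₁=30 are kept in the configuration.

ICA is extended Infomax: natural-gradient block updates
`W ← W + η [I − K tanh(u)uᵀ/B − uuᵀ/B] W` with the per-component
sub/super-Gaussian switch K estimated from the stability criterion
`sign(E[sech²u]E[u²] − E[u tanh u])` and frozen after a 10-pass burn-in
(late switching can oscillate); learning rate annealed ×0.9 whenever the
update direction turns by more than 60°, with an additional ×0.995 decay per
pass after pass 300 to force contraction; random orthogonal initialization
and a seeded column permutation per pass make runs reproducible.
Non-convergence after 2000 passes raises an error carrying the iteration
count. Component signs follow the positive-skewness convention, and
components are ordered by explained variance.

ICASSO: ICA repeated n_runs times (default 5 at desk scale, 20 at study
scale) from different seeded initializations; pooled components are
clustered by average-linkage agglomeration on 1 − |r|, cut at d clusters;
Iq = mean intra-cluster |r| − mean extra-cluster |r|, clipped to [0, 1]; the
retained run maximizes summed |r| to the cluster centrotypes. A run that
fails to converge is replaced by a re-seeded one (that is what the stability
scheme is for); degenerate clusterings fall back to the run with maximal
summed negentropy, with a warning.

Artifact flagging is heuristic (edge-ring fraction of supra-threshold
voxels > 0.5, or > 0.5 of time-course power above 0.10 Hz); on real data the
original identification was visual, so a manual override mapping is
authoritative when provided.

## Reference-guided back-reconstruction

For each z-scored group reference r_k the subject map is
y = wᵀX_w, with X_w the subject's data whitened to K_n + 5 dimensions, and w
the unit vector maximizing

    L(w) = J(y) + λ · corr(y, r_k),     J(y) = (E[G(y)] − E[G(ν)])²,

G = log cosh, E[G(ν)] ≈ 0.37457 computed once by a fixed-seed 10⁶-sample
Monte Carlo and cached. Optimization is projected gradient ascent
(step 0.1, halved on objective decrease, tolerance ‖Δw‖ < 1e-6, ≤ 500
steps), initialized at the projection of r_k onto the whitened space — which
is also the corr-maximizing start, so the negentropy of the solution can
only improve on its initialization. λ starts at 1 and doubles (≤ 64) until
corr(y, r_k) ≥ ρ_min = 0.2; if the constraint remains unattainable the
component falls back to its dual-regression map, with a warning. Components
are optimized independently (no joint orthogonality across subject maps).
Dual regression (two joint OLS stages) is retained both as a baseline and as
the oracle in tests; FNC time courses come from a per-time-point multiple
regression of the volume on all subject maps, the default route.

## SDR detection

* **Network mask** — right-tailed one-sample t over all subjects' z-maps,
  threshold α/(number of brain-mask voxels) (Bonferroni), df = n−1. Only
  positive-mean network voxels are analyzed.
* **Contrasts** — pooled-variance two-sample t per voxel within the mask
  (p < 0.001, two-tailed) for PTSD-vs-CC, PTSD-vs-CEC, CEC-vs-CC; with
  covariates, the t of the group coefficient in a per-voxel linear model
  (df = n₁+n₂−2−c).
* **Smoothness** — estimated from within-group demeaned subject maps by the
  first-difference estimator (lag-1 correlation of a Gaussian ACF), geometric
  mean over axes, floor one voxel; fallback is the nominal 6 mm kernel.
* **Cluster null** — Monte-Carlo simulation per network mask. The public
  operation simulates a smooth Gaussian z-field (z-scored within the mask,
  |z| > z₁₋p/₂). The pipeline uses the df-matched variant: each iteration
  draws n₁+n₂ smooth noise maps and computes the actual pooled two-sample
  t-field, thresholded at t₁₋p/₂,df — at df 10–20 a t-field crosses its
  (higher) threshold in smaller patches than a Gaussian field at the same
  marginal level, and matching the statistic being thresholded is the
  defensible calibration. Max extents are recorded per sign;
  k_min(α) uses the add-one Monte-Carlo exceedance estimate so marginal
  extents round conservatively. Defaults: 1000 iterations (500 in the
  20-seed replication experiments), 26-connectivity (6/18 configurable —
  extents change with the dialect), cluster α = 0.05 with an additional
  Bonferroni factor for the number of analyzed networks.
* **Overlap rules** — same-direction PTSD-vs-CC and CEC-vs-CC clusters that
  share ≥ 1 voxel merge into one SDR with the extent of the larger cluster
  (ties toward the PTSD contrast), labeled Combat Increasing/Decreasing;
  a single-pattern cluster overlapped by two oppositely directed clusters
  yields two distinct SDRs; everything else is a single-contrast SDR. Peaks
  are the voxels of maximal |t| (ties to the smallest linear index),
  reported in mm through the NIfTI affine.

Because each network is tested at cluster-level α = 0.05, a calibrated
pipeline necessarily produces occasional uncorrected false-positive
clusters in any given contrast (expected rate 1 − (1−α)^K per cohort); the
familywise claim of the pipeline is the across-network Bonferroni level, and
the null-specificity replication experiment counts PTSD-vs-CEC patterns at
that level.

## FNC and symptom statistics

Time courses are linearly detrended, despiked by a running-median rule
(window 5; points beyond 4×MAD replaced by the median — a stand-in for the
unstated toolbox method) and low-pass filtered with a fifth-order
Butterworth at 0.15 Hz applied forward-backward; zero-phase filtering
doubles the attenuation (−6.02 dB at the cutoff instead of −3.01 dB).
Pearson correlations are clipped to ±(1−1e-12) before Fisher r-to-z
(degenerate pairs flagged). Group tests: one-way ANOVA per tested pair
(all pairs among components owning ≥ 1 SDR), Bonferroni over the number of
tested pairs; post hoc two-sample t-tests corrected ×3, capped at 1.

Correlation method selection operationalizes the bimodality rule as excess
kurtosis (population-moment estimator m₄/m₂² − 3) below −1.0 → Spearman,
else Pearson; a balanced two-point mixture, the extreme bimodal case, has
kurtosis −2, and the threshold sits between that regime and the Gaussian 0.
Spearman p-values use exhaustive permutation enumeration for n ≤ 10 and the
t approximation above. Partial correlations residualize both variables (and
rank-transform first in the Spearman variant) on the covariates plus
intercept; df = n − 2 − c. The 41-correlation family is deliberately not
corrected for multiple comparisons by default (a Bonferroni/FDR switch
exists), mirroring the exploratory role of this stage.

Summary-statistic tests (pooled two-sample t, one-way ANOVA from
means/sds/ns, Pearson χ² without continuity correction) allow cohort tables
to be reproduced from printed summaries alone.

## Problem sizes of the validation experiments

Chosen as desk-scale defaults: decomposition recovery and planted-SDR
recovery run on the default cohort (24³ grid, T=150, 12/8/8 subjects);
the back-reconstruction comparison uses 20 single-subject replicates at
default scale; null-specificity and FNC replications run 20 cohorts at
16³/T=100/(8,6,6) with 500-iteration nulls; symptom-link detection runs 20
cohorts of 50 PTSD subjects at 16³/T=60. The cluster-null calibration uses
1000 null iterations and 500 fresh maps on a full 24³ mask.

## Known limitations

* The constrained-ICA objective is this package's concrete formulation of
  reference-guided back-reconstruction; published variants differ in the
  constraint form and joint orthogonality.
* Cluster inference assumes stationary smoothness within each network mask;
  non-stationary fields (and z-scored-map renormalization, which turns a
  focal increase into a diffuse apparent decrease elsewhere in the mask)
  are real effects a user must interpret, not artifacts of the code.
* Model-order estimation (MDL/AIC), spatial normalization, permutation
  cluster inference, TFCE, dynamic FNC and anatomical labeling are out of
  scope.
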