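# Methods

## Scope and model

The package analyses parcellated resting-state signals as binary
undirected graphs. A subject's network is built from the Pearson
correlation matrix of their region time series; nodes are the 90 cerebral
regions of an AAL-style parcellation (any region count is supported);
edges are defined by sparsity thresholding. All inference is
non-parametric (label permutation), matching the common practice for
small imaging cohorts where parametric assumptions on derived graph
metrics are hard to defend.

## Synthetic data generator

The generator exists so that thresholding, metrics and inference can be
validated against known structure. It emulates the second-order
statistics of conditioned BOLD parcel signals and nothing more.

**Substrate.** A Watts–Strogatz graph (default n = 90, ring neighbourhood
k = 8, rewiring p = 0.1), redrawn until connected. This gives simulated
control networks the small-world signature (γ > 1, λ ≈ 1) after
thresholding.

**Covariance.** Control covariance is I + w·A with A the substrate
adjacency and w the target edge correlation (default 0.3), repaired to
the nearest valid correlation matrix by eigenvalue clipping (floor 1e−6)
and diagonal rescaling. The repair is necessary because I + 0.3·A is
indefinite at degree 8; it introduces weak indirect correlations between
nodes sharing neighbours, as real functional connectivity does. The
realised edge correlation stays within ~0.01 of the target and leakage
onto non-edges is below 0.02 in magnitude.

**Lesion.** The patient group's covariance subtracts `effect_size` from
each *affected* edge before repair. Affected edges are grown from a random
seed edge, preferring edges internal to the already-covered node set, so
the lesion is a compact connected subnetwork (13 edges typically span
7–9 nodes, each losing several connections) rather than a sprawling tree.
The realised patient-minus-control correlation difference on lesion edges
equals the nominal effect to within ~0.01.

**Signals.** Multivariate Gaussian samples (time × region) from the group
covariance, then zero-phase band-pass 0.01–0.08 Hz at TR 2 s — the same
filter the preprocessing stage applies, so correlations are preserved in
expectation while the signals carry realistic autocorrelation. Defaults
mirror the emulated acquisition: 12 patients, 24 controls, 229 retained
volumes. A consequence worth knowing: the pass-band occupies ~28% of the
Nyquist range, so 229 volumes carry roughly 64 effective samples and the
per-subject standard deviation of a Fisher-z edge value is ≈ 0.125, not
the 1/√226 ≈ 0.067 of white data. All power statements below follow from
this.

**What is not modelled.** Hemodynamics, physiological noise, motion,
scanner drift, spatial smoothness, inter-subject anatomical variability.
Passing tests therefore show the *analysis machinery* is correct and
calibrated, not that it would behave identically on acquired data;
effects of the unmodelled noise sources on power are not represented.

**Covariates.** Age ~ N(67, 5) years, education ~ N(12, 5) years, sex
binary at a 1:2 male:female ratio, MMSE ~ N(28, 2) clipped to [0, 30],
AVLT subscores with trial-wise increasing means — loose calibration to an
elderly cohort, not a claim of realism. Optionally MMSE is generated as a
linear function of a chosen metric plus confounder terms and noise, with
the generating coefficients recorded, so the regression stage has a
recoverable ground truth; `link_beta_for_r2` converts a target population
R² into the slope.

## Conventions and defaults

- **Pipeline order** is fixed: discard (default 10 volumes) → linear
  detrend (with intercept) → band-pass (zero-phase forward–backward
  Butterworth, order 4, reflection padding — transients matter at ~230
  samples) → nuisance regression of externally supplied columns.
  Whole-brain/WM/CSF signals cannot be derived from parcel averages, so
  they are accepted as optional regressor files rather than recomputed.
- **Edge ranking** is over raw signed correlation (strongest positive
  first), the common toolbox default for binary sparsity networks; an
  absolute-value option exists. Edge counts use round-half-away-from-zero
  of S·n(n−1)/2; ties break lexicographically by (i, j) with a stable
  sort, so thresholding is deterministic across platforms. One shared
  ranking per subject guarantees nested edge sets along the sweep.
- **Disconnected graphs** (possible at the sparse end of the sweep): L_p
  averages over reachable pairs only and the unreachable fraction is
  reported; a harmonic alternative (L_p = 1/E_glob) is available via
  `convention="harmonic"`. Nodes with degree < 2 contribute 0 to C_p and
  E_loc and stay in the mean, keeping AUCs comparable across subjects.
- **Random ensemble**: 100 members, 10 accepted double-edge swaps per
  edge, degree sequence preserved exactly; connectedness is not enforced
  (enforcing it biases the null). γ and λ normalise by the ensemble mean.
- **Betweenness** is normalised by (n−1)(n−2)/2.
- **AUC** is the trapezoidal integral over the sparsity grid (width 0.24
  for the default grid, so a constant curve c integrates to 0.24·c).
- **Permutation tests** are one-tailed with the 95th-percentile critical
  value and Phipson–Smyth +1 correction (p can never be 0; sampled mode),
  with an exhaustive-enumeration mode (exact p, no correction) for small
  samples. The `auto` direction follows the observed sign and is flagged
  in the result; note that under the null this selective direction
  doubles the nominal one-sided level, so calibration claims use a fixed
  direction.
- **NBS**: edge statistics are pooled-variance two-sample t on Fisher-z
  correlations (raw-r option retained); the primary threshold applies to
  |t| by default with a signed one-sided option; component size is its
  edge count; component p = (#{null max ≥ size}+1)/(n_perm+1). An
  optional node mask restricts the analysis to a region subset — the
  mechanism used when NBS follows a nodal screening stage.
- **Distance classification**: Euclidean distance between MNI centroids;
  long-range iff strictly greater than the 75 mm cutoff.
- **Regression**: OLS of score on [metric, age, sex, education] with
  intercept; reports the metric coefficient and p, R² and adjusted
  R² = 1−(1−R²)(n−1)/(n−p−1); warns when residual df < 8, where such
  fits are fragile.
- **Region indexing** is 1-based AAL numbering in every file format and
  0-based internally; conversion is confined to the I/O layer.

## Operating characteristics and power

The experiments module measures the pipeline's statistical behaviour by
simulation; the test suite asserts these properties at reduced problem
sizes chosen to keep the default run in the minutes range (200 null
replicates at 999 permutations for type-I error; 20 replicates for the
small-world rate; 100 null replicates at 199 permutations for the NBS
family-wise rate; 5 replicates at 499 permutations for lesion recovery).

- **Type-I error.** On null data (both groups identical, 12 vs 24
  subjects) the one-tailed AUC permutation test rejects at the
  95th-percentile criterion at the nominal 0.05 rate.
- **Small-world emulation.** Simulated control networks thresholded at
  sparsity 0.15 show γ > 1 with λ in [0.8, 1.2] in ≥ 90% of replicates.
- **NBS family-wise error.** Under the global null the rate of any
  significant component is the nominal 0.05 — this holds at any threshold
  because observed and permuted statistics share one distribution.
- **NBS recovery — a power analysis.** Whether a compact 13-edge lesion
  can be *detected* at the study scale is a different matter, and the
  honest answer is rarely:
  - *Whole-network NBS at T = 2.441.* With df = 34, |t| ≥ 2.441 admits
    ≈ 2% of the 4005 edges; ~80 random edges on 90 nodes are supercritical
    for percolation, so the null's largest component has median ≈ 76
    edges and a 13-edge lesion merged into the giant component shifts its
    size by too little (measured p ≈ 0.1–0.3). The one-sided variant
    (≈ 1%) sits at the percolation threshold and remains marginal.
    Raising the effect size does not help: once every lesion edge is
    suprathreshold the component-size statistic has saturated.
  - *Two-stage (screen, then masked NBS).* Restricting NBS to regions
    significant in ≥ 1 of the 3 nodal AUC tests (p < 0.05) collapses the
    null component sizes and is how a 13-edge component can reach
    p < 0.05 at this threshold. The binding constraint becomes screening
    power: the between-subject variance of sparsity-thresholded nodal
    AUCs is dominated by noise-edge churn near the rank cutoff, giving
    per-node t ≈ 2–3 at 12 vs 24 subjects even for implanted correlation
    differences of 0.4–0.55 — enough to select most, but rarely all,
    lesioned regions. Recovery of ≥ 90% of lesion edges therefore
    succeeds in well under half of replicates at this design.
  - *Machinery check.* When the mask covers the lesioned regions, NBS
    recovers the implanted subnetwork essentially always (see the
    masked-recovery test and `examples/04_group_inference_nbs.py`), so
    the limitation is the design's statistical power, not the
    implementation.

## Known limitations

- Global/WM/CSF nuisance signals must be supplied externally; the package
  never guesses them from parcel data.
- Weighted, directed, partial-correlation and wavelet connectivity are
  out of scope; the networks are binary and undirected throughout.
- The NBS node-subset rule following nodal screening is exposed as an
  explicit mask argument rather than a hard-coded selection, because more
  than one reading of that selection step is defensible.
- T = 2.441 is accepted as the primary threshold as given; it equals the
  one-sided p = 0.01 t-quantile at df = 34.
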