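# Methods

This note documents the models, parameter choices and numerical
conventions behind `docnet`, in the spirit of a package methods
appendix: what is computed, under which assumptions, and where a design
was genuinely open.

## Preprocessing and connectivity

Nodal series (nodes × T) are processed in a fixed order: linear
detrending per node, zero-phase band-pass filtering, nuisance
regression, Pearson correlation with Fisher's z transform.

- **Filter.** Chebyshev type I, order 4, 0.5 dB passband ripple,
  band 0.01–0.08 Hz at TR = 2 s, applied forward–backward
  (`sosfiltfilt`) so the net response is zero-phase.  Order and ripple
  are conventional choices for BOLD band-passing; only the family and
  band are fixed by the analysis design.
- **Nuisance regression.** One joint OLS fit per node against an
  intercept, all confound channels (global, white matter, CSF, six
  motion parameters) and the backward-difference derivatives of the
  first three channels (first element 0).  A joint fit is
  order-invariant, unlike sequential regressions, and its residuals are
  exactly orthogonal to every design column.  Confound channels are
  regressed unfiltered from the already-filtered data; filtering the
  channels first changes residuals only marginally inside the passband.
- **Fisher z.** |r| is clamped at 1 − 10⁻¹⁵ before `atanh`, so
  duplicated series map to z ≈ 17.6 instead of infinity.

## Graph construction

Edges are selected by *proportional density*: at density d, the
round(d·K(K−1)/2) largest |z| values (round half away from zero) keep
|z| as weight.  Ties are broken by ascending (i, j) order, which makes
edge sets nested across densities — the property the AUC summaries rely
on.  The default grid is 2.5–32.5 % in 2 % steps (16 densities), the
range over which the original clinical analysis found all subjects
admissible; `select_density_range` re-derives admissibility from the
two criteria (< 10 % unconnected nodes, σ > 1.5) per subject, and the
pipeline intersects subject ranges when asked (`admissibility =
"criteria"`).  Whether the published range was derived per subject or
jointly is not documented; the intersection is our interpretation.

## Topological metrics

- Strength sᵢ = Σⱼ wᵢⱼ, degree = nonzero count, betweenness on edge
  lengths 1/w (the standard mapping for correlation weights), normalized
  by 2/((K−1)(K−2)).
- Clustering uses the geometric-mean triangle form on weights scaled by
  the maximum weight; nodes of degree < 2 contribute 0.
- Characteristic path length is the mean *finite* shortest-path length;
  disconnected pairs are excluded (the < 10 % unconnected criterion
  makes occasional isolates possible, and a harmonic-mean efficiency
  variant would be a different statistic).
- Null models: Maslov–Sneppen double-edge swaps on the binary topology
  (10 swap attempts per edge), then the original weight multiset is
  shuffled onto the rewired edges.  Degree sequence, edge count and
  weight multiset are preserved exactly.  Metrics are normalized by the
  null-ensemble mean; σ = (C/C_null)/(L/L_null).
- **Degree is never null-normalized**: because the nulls preserve every
  node's degree exactly, normalized degree is identically 1.  Degree
  therefore enters all downstream analyses raw.  (It is intrinsically
  comparable across subjects anyway — the total degree at a fixed
  density is constant.)  Betweenness is scale-invariant under global
  weight scaling, so its normalization can be switched off
  (`normalize_metrics`) when the null ensembles are the runtime
  bottleneck; strength, the only metric carrying a per-subject global
  scale, is always normalized in the default configuration.
- AUC summaries integrate metric-vs-density profiles with the trapezoid
  rule over the admissible densities; non-finite normalization
  sentinels are dropped pointwise.

## Distance profiles

Euclidean distances between node centres are binned into 18 half-open
10 mm intervals [0,10) … [170,180]; 75 mm is the conventional
short/long-range cut.  For a target network, every ordered pair (i in
network, j anywhere, j ≠ i) contributes the thresholded edge weight
(zero if cut) to its bin; empty bins are flagged missing, never
zero-filled.  Per-subject profiles are computed at each admissible
density and AUC-summarized before the per-bin group ANOVA.  Binning raw
|z| instead of thresholded weights is a documented alternative (pass an
unthresholded weight matrix).

## Classification

Features concatenate the three AUC-summarized nodal metrics (order:
network, node id, strength/betweenness/degree).  Training folds z-score
features with their own statistics; test subjects are transformed with
the training statistics.  One linear SVM (C = 1) per class one-vs-rest;
for two classes the second classifier is the exact mirror of the first,
so a single fit suffices.  Decoding takes the argmax of decision
scores, ties to the lowest class index.  LOOCV significance comes from
permuting all labels once per iteration and re-running the full LOOCV;
p is the literal proportion of null accuracies ≥ the actual one (no +1
correction), so p = 0 is reportable and, under ties, p is conservative
(stochastically ≥ uniform).  Nodal weight maps default to
|Σ weights| per node across the three metrics and three classifiers; the
Σ|w| reading is available as a switch.  Sensitivity is the correct
fraction of the more-impaired class (VS/UWS ≻ MCS ≻ control),
specificity that of the other class.

## Group statistics

The state × network ANOVA is a fixed-effects crossed design with
interaction (no subject random effect): with 29 subjects and 10
networks the error df is 290 − 30 = 260 and the effect dfs are 2, 9
and 18, the accounting the design implies.  Degenerate all-equal tables
short-circuit to F = 0.  Tukey HSD handles pairwise contrasts.
Network-pair correlations across patients subtract the control-group
mean from each patient value first and Bonferroni-multiply p by 3 (one
comparison per metric).  The nodal permutation test averages the
one-way ANOVA F over the three metrics per node, rebuilds the null by
resampling subjects into groups of the original sizes (10,000 default),
and applies Benjamini–Hochberg FDR across the tested nodes.

## Synthetic cohort generator

The generator exists so the full pipeline can be exercised and
validated without clinical data.  It emulates the *statistical*
structure of the study, not fMRI physics.

**Geometry.**  Each of the 10 networks is a set of mirrored Gaussian
sub-clusters (σ = 13 mm) at a lateral offset of ±45–60 mm, with network
centres scattered in the coronal plane (σ = 22 mm); all coordinates are
rescaled down to a maximal span of 170 mm when they exceed it.  Most
networks get one locus per hemisphere; the FPN gets four loci
(bilateral anterior DLPFC-like and posterior PPC-like), so roughly
half to three quarters of its within-network pairs are long-range.  A
single compact cluster per network was rejected because it cannot
produce both short (< 40 mm) and long (> 75 mm) within-network pairs.
The locus layout also controls how much the positive-definiteness
repair erodes the planted effects: a two-locus FPN makes the long-pair
perturbation a near-complete-bipartite graph whose spectrum forces
heavy eigenvalue flooring (nominal +0.15 realized as ≈ +0.11), while
the four-locus layout realizes ≈ +0.13 to +0.14.  Only the FPN (25)
and DMN (58) node counts are pinned; the eight remaining networks
absorb the other 181 nodes in round numbers.
`power264_parcellation()` instead loads the published 264 coordinates
(via nilearn) with reconstructed block labels of the published sizes.

**Signal model.**  Subjects draw T = 235 samples from a zero-mean
Gaussian whose correlation matrix is modular — 0.30 within networks,
0.05 between, unit variances — plus the planted group effects:
+0.15 · m on within-FPN pairs farther than 75 mm and −0.15 · m on
within-DMN pairs closer than 40 mm, where the group multiplier m is 1
for VS/UWS, 0.08/0.15 ≈ 0.53 for MCS and 0 for controls (so the
VS/UWS > MCS > control ordering holds by construction).  The perturbed
matrix is repaired to positive definiteness by flooring eigenvalues at
10⁻⁶.  Per patient, the FPN and DMN effects are scaled by severity
factors max(0, 1 + 0.20·N(0,1)) whose latent normals correlate at 0.5:
the two networks' disruptions track overall impairment but are
expressed partly independently.  That partial independence is what
makes *combined* FPN+DMN features classify better than either network
alone — with a single shared factor the two feature sets would be
redundant.

**Nuisance and noise.**  A shared global fluctuation (loading 0.15),
white-matter and CSF channels (0.10 each), six motion channels (leak
0.02) and white noise (SD 0.15) are mixed in, and everything is
band-limited with the same filter the analysis uses, so ≥ 90 % of
spectral mass lies in 0.01–0.08 Hz and the correlation structure is
preserved (all nodes pass through an identical linear filter).  The
confound matrix records the injected nuisance series themselves — what
an ideal global/WM/CSF/motion extraction would recover — so nuisance
regression removes exactly the planted nuisance.  Deriving the global
channel from the empirical node mean instead would re-introduce the
classical global-signal-regression artifact (the brain mean contains
the network signals and regression attenuates within-network coupling
by roughly half); the generator deliberately sidesteps that confound so
that pipeline validation is about the planted effects, not about GSR
pathology.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: hemodynamics and scanner physics, head
motion spikes, spatial autocorrelation within regions, non-Gaussian and
non-stationary BOLD fluctuations, anatomical asymmetry, and the true
empirical global signal with its GSR side effects.  Effect magnitudes
in correlation units are not reported by clinical studies; the planted
±0.15/±0.08 values are calibrated to reproduce effect *directions and
orderings* robustly at the study's sample sizes, not any particular
accuracy or F value.

## Determinism and problem sizes

All randomness flows from explicit integer seeds; sub-streams are
derived by SHA-256 hashing of (seed, stage, index) and kept below 2³¹.
Reports are byte-identical for identical configs and seeds.

Validation suites run at deliberately reduced sizes chosen as the
smallest that keep the checks statistically meaningful: the
planted-effect and combined-superiority batteries use 20 cohorts of the
full study geometry (29 subjects, 264 nodes, T = 235) with 20 rewired
nulls per graph and strength-only normalization; classifier calibration
uses 100 toy null cohorts (10 subjects, 8 features) with 49-permutation
LOOCV nulls; the acceptance script runs one study-sized cohort with 20
nulls, 200 label permutations and 2000 nodal permutations.  Library
defaults remain at the full 100/1000/10,000 counts.

## Known limitations

- Betweenness on graphs with exactly tied path lengths depends on the
  shortest-path enumeration of the backend; with continuous weights
  ties have measure zero, and the brute-force oracle uses a 10⁻⁹
  tolerance.
- The admissibility intersection rule and the half-open bin convention
  are interpretations where the original analysis is silent; both are
  switchable at the API level.
- `nodal_weight_map` sums signed weights before the absolute value by
  default; for binary (two-classifier) runs the mirrored weights cancel
  exactly, so weight maps are only meaningful for ≥ 3 classes.
- The two-way ANOVA treats network as a crossed fixed effect, implying
  the df accounting above; a repeated-measures variant would need a
  different error model and is out of scope.
- On simulated cohorts, concatenating FPN and DMN features improves on
  the better single network only in a majority — not the vast majority
  — of cohorts: whichever network's disruption happens to be expressed
  more strongly in a given 29-subject draw can classify better alone,
  and adding the other network's larger feature block then costs a few
  held-out subjects.  A single-cohort combined-beats-single observation
  should therefore be read as draw-dependent.
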