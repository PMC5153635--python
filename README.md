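# docnet

Graph-theoretical analysis of resting-state functional brain networks in
disorders of consciousness (DOC), built as a reusable, fully tested
Python pipeline.  It targets the question: how do the fronto-parietal
network (FPN) and default-mode network (DMN) reorganize in patients in a
vegetative state / unresponsive wakefulness syndrome (VS/UWS) or a
minimally conscious state (MCS), and can their topology classify
conscious state?

The package is aimed at researchers who have nodal BOLD time series
(region × timepoint matrices from any parcellation) and want the full
chain from time series to statistics — plus a synthetic cohort generator
that makes every stage testable without access to clinical data.

## The analysis

1. **Connectivity.** Each nodal series is detrended, band-pass filtered
   (Chebyshev type I, 0.01–0.08 Hz at TR = 2 s, zero phase) and
   residualized against nuisance channels (global, white-matter and CSF
   signals, their first derivatives, six motion channels).  Pairwise
   Pearson correlations are Fisher-z transformed into a symmetric matrix
   *z*.
2. **Graphs.** At each connection density *d* of the grid 2.5–32.5 %
   (step 2 %), the top ⌈*d·K(K−1)/2*⌋ entries of |*z*| become edge
   weights.  A density is admissible when < 10 % of nodes are
   unconnected and small-worldness σ > 1.5.
3. **Topology.**  Nodal connectivity strength *s*ᵢ = Σⱼ *w*ᵢⱼ, degree,
   and weighted betweenness (edge lengths 1/*w*); network-level values
   are means over each network's *K*ⱼ nodes.  Metrics are normalized
   against 100 degree-matched Maslov–Sneppen null graphs and summarized
   across densities by the area under the curve (AUC).  Small-worldness
   σ = γ/λ with γ = C/C_null and λ = L/L_null.
4. **Distance profiles.** Connectivity strength from each network's
   nodes to all brain nodes, binned by Euclidean distance (18 × 10 mm
   bins, 0–180 mm; 75 mm separates short from long range), compared
   across groups per bin by one-way ANOVA with Tukey HSD.
5. **Classification.** Feature vectors concatenate the three nodal
   metrics over the chosen networks; three linear one-vs-rest SVMs with
   loss-based (argmax) decoding, leave-one-out cross-validation, and a
   1000-permutation null for significance.  Nodal SVM-weight maps rank
   each region's contribution.
6. **Group statistics.** Two-way ANOVA (state × network) with Tukey
   post-hoc, control-referenced Pearson correlations between FPN and DMN
   metrics across patients (Bonferroni-corrected), and a
   10,000-permutation test on nodal average F values with
   Benjamini–Hochberg FDR.

The synthetic cohort generator plants the study's statistical structure:
29 subjects (11 VS/UWS, 7 MCS, 11 controls), 264 nodes in 10 networks
(FPN = 25, DMN = 58), T = 235 timepoints, band-limited signals, and
group-scaled covariance perturbations that *strengthen long-range
(> 75 mm) within-FPN* coupling and *weaken short-range (< 40 mm)
within-DMN* coupling, with VS/UWS > MCS > control ordering.

## Worked example

```python
from docnet.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(
    out_dir="demo-out",
    network_sizes={"FPN": 12, "DMN": 20, "VIS": 10, "SMN": 10, "SAL": 8},
    n_topology_nulls=10, n_mvpa_perm=99, n_nodal_perm=200,
    seed=7,
)
report = run_pipeline(config)
cls = report["classification"]["FPN+DMN"]
print(f"FPN+DMN three-way accuracy: {cls['accuracy_pct']:.1f}%"
      f" (chance {cls['chance_pct']:.1f}%, p = {cls['permutation_p']:.3f})")
r = report["network_stats"]["strength"]["fpn_dmn_correlation"]["r"]
print(f"FPN-DMN strength correlation across patients: r = {r:.2f}")
```

simulates the default 29-subject cohort on a compact 60-node partition
(about a minute) and prints

```
FPN+DMN three-way accuracy: 72.4% (chance 33.3%, p = 0.000)
FPN-DMN strength correlation across patients: r = -0.17
```

— the planted cohort is classified far above the 33.3 % chance level
(none of 99 label permutations matched it) and the two networks'
strength deviations are anti-correlated across patients, the
qualitative signature the pipeline is designed to detect.  The full
report also carries per-metric ANOVAs (state effect F, Tukey
contrasts), per-bin distance statistics, binary contrasts with
sensitivity/specificity, and the nodal weight map.

The same stages are available as a CLI:

```sh
docnet simulate --n-vs 11 --n-mcs 7 --n-ctrl 11 --t 235 --seed 1 --out cohort/
docnet connectivity --manifest cohort/cohort.json --out z/
docnet run-all --seed 1 --out full-run/
```

## Layout

- `src/docnet/synthetic.py` — parcellation + cohort generator
- `src/docnet/connectivity.py` — preprocessing and Fisher-z matrices
- `src/docnet/graphs.py` — density thresholding, admissibility
- `src/docnet/topology.py` — nodal/global metrics, nulls, AUC
- `src/docnet/distance.py` — distance-binned profiles
- `src/docnet/mvpa.py` — SVM classification, permutation tests
- `src/docnet/stats.py` — ANOVA, Tukey, correlations, nodal permutation
- `src/docnet/pipeline.py`, `cli.py`, `io.py` — orchestration, CLI, TSV/JSON
- `docs/methods.md` — modeling assumptions and design choices
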