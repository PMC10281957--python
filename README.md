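# cytoverbs

Composable, tidy "verbs" for analyzing high-dimensional cytometry data
(mass cytometry / CyTOF, spectral flow) in Python.

Cytometry experiments measure dozens of protein markers on millions of
single cells, and the biology lives at three levels of observation: the
cell (marker expression profiles), the cell subpopulation (clusters), and
the whole sample (patient outcome, stimulation condition). `cytoverbs`
represents all three with one tidy structure — a `CytoTable`, a
`pandas.DataFrame` with one row per cell, one column per channel or
annotation, and the acquisition panel attached as metadata — and a small
vocabulary of verbs that each take a tidy table and return a tidy table,
so analyses chain into readable pipelines:

- **I/O** — `read_fcs` / `write_fcs` (FCS 3.0/3.1 binary), `read_csv_cells`
  / `write_csv_cells`; `bind_samples`, `join_sample_metadata`
- **preprocess** — `undo_randomization` (strip acquisition noise from ion
  counts), `transform_arcsinh` (x → asinh(x/c), cofactor c = 5 by
  convention), `transform_inverse`, `scale_channels`
- **downsample** — per-group constant-count, proportional, or SPADE-style
  density-dependent downsampling (keep probability TD/dᵢ, where dᵢ is the
  fixed-radius neighbor count and TD the target-percentile density)
- **cluster** — FlowSOM-style self-organizing map + average-linkage
  metaclustering, or k-means, behind one verb (`cluster_cells`)
- **reduce** — internal PCA, plus delegated Barnes-Hut tSNE and UMAP
- **extract** — sample-level features: cluster abundances, per-cluster
  marker central tendencies, percent-positive fractions, and earth mover's
  distance / Jensen-Shannon divergence between stimulation conditions
- **analyze** — differential abundance (logit-proportion Welch/paired
  t-tests) and differential expression, with Benjamini-Hochberg FDR control
- **synthetic** — a seeded cohort generator (Gaussian mixtures on the
  arcsinh scale, Dirichlet per-sample composition, optional planted
  effects) so every verb is testable with known ground truth

## Worked example

Simulate a two-arm cohort in which cluster 2's abundance is raised by
0.12 in arm B, then recover that effect end to end:

```python
import cytoverbs as cv

spec = cv.CohortSpec(
    n_samples_per_arm=8, n_clusters=4, n_markers=6, cells_per_sample=500,
    effect=cv.Effect(target_cluster=2, proportion_delta=0.12), seed=7,
)
tables, metadata, truth = cv.simulate_cohort(spec)
cells = cv.join_sample_metadata(
    cv.bind_samples(tables, metadata["sample_id"].tolist()), metadata
)
cells = cv.preprocess(cells)                     # de-randomize + arcsinh
cells = cv.cluster_cells(cells, method="som", k=4, seed=7)
features = cv.extract_features(cells, ["abundance"])
results = cv.analyze_abundance(features, outcome_col="arm")
print(results.sort_values("q_value").to_string(index=False))
```

```
unit    effect  statistic  p_value  q_value  n_group_a  n_group_b
   1  0.589015   2.794124 0.014602 0.045556          8          8
   4 -0.446605  -2.561596 0.022778 0.045556          8          8
   2 -0.222430  -1.440032 0.171845 0.229127          8          8
   3  0.002663   0.010911 0.991474 0.991474          8          8
```

Each row is one cluster: `effect` is the difference in mean
logit-proportion (arm B − arm A), `statistic` the Welch t-statistic, and
`q_value` the BH-adjusted p-value. The SOM relabels clusters by size, and
its label "1" is exactly the planted true cluster 2 (cross-tabulating
`.cluster` against the generator's hidden `.true_cluster` shows a
one-to-one match); it is correctly the top-ranked, significant unit
(q ≈ 0.046), with the compensatory dilution of the other clusters showing
up as negative effects.

The same pipeline runs from the shell:

```sh
cytoverbs simulate --out-dir cohort --seed 7
cytoverbs pipeline --config pipeline.yaml --seed 7 --out-dir run
```

where `pipeline.yaml` lists ordered stages (`read`/`simulate`, then
`preprocess`, `downsample`, `cluster`, `reduce`, `extract`, `analyze`).
Every stage writes its output as CSV plus a panel sidecar, and
`manifest.json` records parameters, row counts, seeds, and content hashes.

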