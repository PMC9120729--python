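# connethresh

Thresholding and scan–rescan consistency analysis for weighted structural
brain networks.

Diffusion-MRI connectomes contain unstable low-weight (likely
false-positive) connections. This package implements the two standard
weight-based cleanups — **MST-anchored fixed-density thresholding** (keep
the maximum spanning tree of the streamline-count graph, then add edges
strongest-first until a target density) and **absolute thresholding**
(drop edges below a streamline cutoff) — and the analyses used to choose
a threshold in longitudinal patient studies:

* **Consistency**: dice overlap of edges detected at scan and rescan,
  one-way ICC of edge weights over common edges, and ICCs of hub scores
  (degree, betweenness centrality), swept over the full threshold grids
  (densities .02–.40 in steps of .01; cutoffs 1–40 streamlines).
* **Sensitivity**: baseline-standardized z-scores of global efficiency
  and FA/MD-weighted node strength, cross-threshold correlation
  matrices, and a 2×2 mixed ANOVA (time within, WMH-median-split group
  between) with Cohen's d per effect, evaluated at every threshold
  level.
* **Synthetic cohorts**: a generator producing paired baseline/follow-up
  connectomes with a shared true backbone, session-independent low-weight
  false positives, weight-dependent dropout, subject/session noise, and
  injected group/time effects — with full ground truth for recovery and
  calibration tests.

Everything operates on plain delimited-text matrices (N×N per weight
channel NOS/FA/MD, plus a labels sidecar) and a CSV cohort manifest.

## CLI

```sh
# generate a synthetic scan-rescan cohort (matrices + manifest + ground truth)
connethresh synth --seed 1 --out cohort/

# threshold a single connectome, or sweep a grid
connethresh threshold --nos nos.csv --fa fa.csv --labels labels.txt \
    --method fixed-density --level 0.15 --out thr/

# per-subject consistency statistics and per-level summary
connethresh consistency --manifest cohort/manifest.csv \
    --method fixed-density --out consistency/

# per-level mixed-ANOVA table for one metric
connethresh sensitivity --manifest cohort/manifest.csv \
    --metric global_efficiency --out anova.csv

# the full report bundle (consistency + sensitivity + metadata)
connethresh run --manifest cohort/manifest.csv --out report/
```

`connethresh run` accepts a YAML config (`--config`) controlling the
methods, grids, efficiency convention, and test family; every output
table carries a hash of that config, and `run_metadata.yaml` records all
convention choices. The report includes a recommended fixed-density band:
levels whose mean dice is within one SD of the maximum while every node
stays connected.

## Package layout

| module | contents |
| --- | --- |
| `connethresh.core` | data model, validation, delimited-text I/O, cohort manifests |
| `connethresh.threshold` | maximum spanning tree, fixed-density and absolute thresholding, sweeps |
| `connethresh.metrics` | degree, betweenness, global efficiency, FA/MD node strength |
| `connethresh.consistency` | dice, one-way ICC, per-subject consistency sweeps |
| `connethresh.sweep_analysis` | z-scoring, cross-threshold correlations, median split, mixed ANOVA |
| `connethresh.synth` | synthetic cohort generator with ground truth |
| `connethresh.pipeline` / `cli` | orchestration, report bundle, command-line interface |
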