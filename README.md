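# mstraj

Single-cell pseudotime trajectory reconstruction from expression matrices:

1. **simulate** — synthetic differentiation-trajectory count generator
   (metastable plateaus, modular gene programs, a biphasic regulator,
   off-trajectory contaminants, negative-binomial counts with dropout) with
   full planted ground truth;
2. **filter** — cell QC, library normalization, and a correlated-gene filter
   (keep genes with Spearman ρ > 0.4 to at least 2 other genes);
3. **modules / states** — gene-module detection by average-linkage
   hierarchical clustering of 1 − Spearman distances with an automated
   cut-height scan, offline hypergeometric term enrichment (or marker rule)
   for module selection, and hierarchical cell-state assignment;
4. **graph** — a cell-state graph built as the consensus of many randomized
   minimum spanning trees (gene resampling or distance jitter), edges
   annotated with occurrence frequency;
5. **pseudotime** — Yen's K-shortest-paths ensemble (default K = 9,000)
   between start and end cells, each path resampled to a fixed grid
   (default L = 41), averaged into per-gene expression profiles with
   dispersion, cell-state occupancy and edge usage;
6. **phases** — a global gene-variation curve (mean |derivative| of the
   min–max-normalized most-dispersed profiles) segmented into metastable
   states (second derivative ≥ 0) and transition phases (second
   derivative < 0);
7. **bootstrap** — robustness of the profiles from resampled-cell replicate
   datasets (default 1,000), scored as per-gene mean pairwise Spearman
   correlation across replicates.

## CLI

Each stage is a subcommand of `mstraj`; `mstraj run` drives the whole
pipeline from one YAML file:

```bash
mstraj simulate --config cfg.yaml --out-matrix counts.mtx --out-truth truth.tsv --seed 17
mstraj filter --in counts.mtx --qc qc.yaml --r-min 0.4 --min-partners 2 \
    --out filtered.tsv --report qc_report.tsv
mstraj modules --in filtered.tsv --annotation go.tsv --out modules.json
mstraj states --in filtered.tsv --modules modules.json --out states.tsv
mstraj graph --in filtered.tsv --modules modules.json --n-trees 1000 \
    --mode gene_resample --seed 17 --out graph.edgelist
mstraj pseudotime --graph graph.edgelist --matrix filtered.tsv \
    --start CELL_A --end CELL_B -K 9000 -L 41 --out profiles.tsv \
    --edge-usage usage.tsv
mstraj phases --profiles profiles.tsv --out phases.tsv
mstraj bootstrap --matrix filtered.tsv --modules modules.json \
    --start-markers gA,gB --end-markers gX,gY --n-boot 1000 --boot-k 450 \
    --seed 17 --out robustness.tsv
mstraj run --config run.yaml
```

Matrices are Matrix Market (`.mtx` with `<stem>.genes.txt` /
`<stem>.cells.txt` sidecars) or delimited text (genes in rows, header row
of cell ids). Annotation files are two-column TSV (`gene<TAB>term`), read
offline — no network access anywhere.

## Python API

```python
from mstraj import (TrajectoryConfig, simulate_trajectory, qc_filter_cells,
                    normalize, correlation_filter_genes, detect_modules,
                    select_modules, cluster_cells, cell_distance,
                    consensus_mst, k_shortest_paths, ensemble_profiles,
                    global_variation, segment_phases, bootstrap_profiles,
                    profile_robustness)

matrix, truth = simulate_trajectory(TrajectoryConfig(seed=1))
```

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (grid-length,
ensemble-size and bootstrap-count contracts, metastable-state recovery,
bootstrap robustness, and the property suites with independent brute-force
oracles).

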