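# radscreen

Analysis of genome-wide, high-content RNAi foci screens — the kind of
experiment in which every gene is knocked down in a well of a 384-well
plate, cells are irradiated, and the number of DNA-repair foci (e.g.
RAD51) per nucleus is the phenotype. The package takes per-cell feature
tables (DNA-stain intensity and foci count per segmented cell) and turns
them into a ranked, annotated candidate gene list:

1. **Cell-cycle gating.** Homologous-recombination foci form only in
   S/G2. Cells are pooled, binned into equal-count quantile bins by DNA
   content, and the G1-to-S cut-off is placed at the intensity where the
   mean foci count per bin reaches 2; G1 cells are discarded.
2. **3D B-score normalization.** Per-well readouts of one run are stacked
   into a row × column × plate cube and decomposed additively,
   `y[r,c,p] = μ + α_r + β_c + γ_p + ε[r,c,p]`, by a three-way median
   polish. Residuals are scaled by 1.4826 × MAD (the robust,
   normal-consistent SD estimate), so a score of −2 is two robust SDs
   below the screen-wide level.
3. **Replicate merging and hit calling.** Duplicate runs are merged by
   rank summation; the candidate-list size is chosen by scanning sizes
   from 50 in steps of 25 and keeping the size with the best
   between-replicate score correlation; hits are genes scoring strictly
   below −2. A composite HRR score (product of two screens' scores)
   cross-references an orthogonal recombination-activity screen.
4. **Network and pathway filtering.** Candidates are projected onto a
   confidence-weighted functional gene network (edges ≥ 0.5), the induced
   subnetwork is clustered by shared-neighbourhood similarity, and genes
   and clusters are annotated by hypergeometric over-representation with
   Benjamini–Hochberg adjustment.
5. **Synthetic screens.** A fully specified generator emulates the whole
   experiment — G1/S/G2 DNA-content mixture, rising foci-rate curve,
   negative-binomial counts, row/column/plate artifacts, control wells,
   planted hits, networks and gene sets — with recorded ground truth, so
   every step is testable end to end.

## Worked example

```python
from radscreen import (SimulationConfig, simulate_screen, estimate_g1_cutoff,
                       summarize_wells, normalize_screen, call_hits)

sim = simulate_screen(SimulationConfig(seed=42).compact())
cells = sim.cells["rep1"]
curve = estimate_g1_cutoff(cells)                  # G1/S cut-off at mean foci = 2
summaries = summarize_wells(cells, sim.layouts, min_cells=5, cutoff=curve.cutoff)
result = normalize_screen(summaries, sim.layouts)  # 3D B-scores
hits = call_hits(result.gene_scores, threshold=-2.0)
```

Running `python examples/02_normalize_3db.py` (which does exactly this)
prints:

```
median polish: 9 iterations, converged=True
overall level: 3.92 foci; row effects span [-0.50, 0.40], plate effects span [-0.44, 0.72]
robust scale (1.4826 x MAD of residuals): 0.614 foci
2016 gene scores; range [-5.14, 4.89]
genes with 3D B-score < -2: 69 (40 of the 40 true hits among them)
fraction of non-hit genes below -2: 0.015 (normal tail expectation 0.023)
```

The polish found an average of ~3.9 foci per well with row and plate
biases up to ±0.7 foci; after removing them, all 40 planted suppressor
genes score below −2 while the false-call rate among null genes stays at
the normal-tail level. The other scripts in `examples/` walk through
gating/QC, replicate merging and candidate sizing, and network
clustering/enrichment, each printing the numbers it computes.

A thin CLI mirrors the library (`radscreen simulate | gate | normalize |
call-hits | network | enrich | run-all`); every subcommand reads and
writes plain delimited text.

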