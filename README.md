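# gipool

Condition-dependent genetic-interaction mapping from pooled double-mutant
fused-barcode sequencing.

## The problem

In pooled yeast double-mutant screens, every strain carries a chimeric
"fused" barcode — the concatenation of a donor and a recipient strain
barcode — so one paired-end amplicon read identifies one double mutant.
Sequencing the pool before and after competitive growth in a condition
turns read counts into per-strain fitness, and fitness into genetic
interactions: a double mutant whose fitness deviates from the product of
its single-mutant fitnesses reveals a functional relationship between the
two genes. Re-growing aliquots of the same pool under different drugs maps
how those relationships rewire with the environment.

`gipool` implements the complete computational path: a forward simulator of
such screens (so every stage is testable against ground truth),
demultiplexing and mismatch-tolerant barcode counting from FASTQ,
strain/pair quality control, interaction scoring with propagated errors and
an empirical null, gene-level FDR-controlled calls, and differential
(condition-dependent) interaction networks with condition clustering.

## The model

For strain pair *xy* with pseudocounted frequency *f* in a sample and
*f₀* in the heterozygous-diploid reference ("time zero") pool:

    g_xy·t = log2(f / f₀) + gen_pool          (realised doublings)
    g_wt·t = mean(g_ij·t | ij neutral–neutral)
    w_xy   = g_xy / g_wt                      (relative fitness)
    w_x    = mean(w_xj | j neutral)           (single-mutant fitness)

    GIS_xy = max(w_xy, 0) − max(w_x, 0) · max(w_y, 0)

where `gen_pool` is the number of generations of pool growth and "neutral"
genes are deletions with no fitness effect. Uncertainty combines a global
per-condition technical-replicate term σ̂(w_xy) with the spreads of the
marginal means via the delta method applied to
GIS = w_xy − g_x·g_y / g_wt²; Z = GIS/σ̂ is referenced against a normal
fitted to neutral-pair Z (the empirical null) for a two-tailed p.
Barcode replicates of a gene pair are combined by inverse-variance
weighting, p-values by signed weighted Stouffer, FDR by Storey q-values,
and a pair is called interacting at q < 0.01 and |GIS| > 0.075
(differentials between conditions: ΔZ = ΔGIS/√(σ̂a²+σ̂b²), q < 0.01,
|ΔGIS| > 0.1).

Quality control mirrors pooled-screen practice: pairs under-represented in
the het-diploid reference (C_xy < 30) are unscorable; loci < 75 kbp apart
co-segregate at meiosis and are flagged `linked`; barcode replicates whose
interaction profile correlates at r < 0.5 with their same-gene siblings
(the signature of acquired aneuploidy) are excluded, and everything is
rescored after each exclusion.

## Worked example

The numbered drivers under `analysis/` run a full synthetic study — a
26-repair × 14-neutral gene pool in six conditions forming three drug
families, 5% aneuploid replicates injected:

```
$ python analysis/01_simulate_screen.py
simulated 6400 barcode pairs x 13 samples
9 aneuploid barcode replicates injected: ['NEU02_r2', 'NEU05_d1', ...]

$ python analysis/03_quality_control.py
pairs: 6400 total, 6044 well-measured (C_xy >= 30), 16 linked, 5311 retained
caught 9/9 aneuploids; 1 honest replicates excluded

$ python analysis/04_score_interactions.py
GIS vs planted epsilon: r = 0.996, RMSE = 0.023
calls per class: {'neutral': 3574, 'negative': 571, 'positive': 523}
same-gene control mean GIS: -0.721

$ python analysis/05_differential_network.py
  DMSO    vs NoDrug :    0 significant,    0 type-changing
  BLMC    vs ZEOC   :    0 significant,    0 type-changing
  MMS     vs NQO4   :    0 significant,    0 type-changing
  MMS     vs ZEOC   :  157 significant,  119 type-changing
  ...
condition dendrogram: ((BLMC,ZEOC),((MMS,NQO4),(DMSO,NoDrug)));
```

Reading the output: the QC stage removes exactly the injected artifact
replicates; gene-level GIS tracks the planted interaction strengths to
±0.02; same-gene controls (which cannot survive haploid double selection)
score as strong synthetic lethals; and conditions within a simulated drug
family show no differential interactions and merge first in the
complete-linkage/Chebyshev dendrogram, while cross-family comparisons show
~140 significant differences each.

The same stages are available as a CLI (`gipool simulate | count | qc |
score | diff | all`) for running on real count tables or FASTQ.

## Layout

- `src/gipool/` — library: `simulate`, `counting`, `qc`, `scoring`,
  `genecalls`, `differential`, `design`, `pipeline`, `cli`
- `analysis/` — numbered narrative drivers writing `results/`
- `tests/` — unit, property and end-to-end statistical tests
- `docs/methods.md` — model, assumptions, parameter choices, limitations
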