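# Methods

## Growth model and interaction score

The pool is modelled as strains in joint exponential growth. A strain
pair's frequency trajectory between the heterozygous-diploid reference
sample ("time zero", before meiosis and selection) and a post-selection
haploid sample reflects its doublings relative to the pool:

    g_xy·t = log2(f_t / f_0) + gen_pool

`gen_pool`, the total number of generations of pool growth, converts the
frequency log-ratio (which is relative to the pool's mean growth) into
absolute doublings. The time unit is arbitrary: every downstream quantity
is a ratio of doublings, so rescaling g·t and gen_pool together changes
nothing. A pseudocount of 0.5 on every raw count keeps frequencies and
log-ratios finite at zero observed reads.

Wild-type doublings are the mean over retained, unlinked neutral–neutral
pairs; relative fitness is `w_xy = g_xy/g_wt`; a strain's single-mutant
fitness is the mean of its fitness across retained, unlinked neutral
partners. The interaction score is the multiplicative-model residual

    GIS_xy = max(w_xy, 0) − max(w_x, 0)·max(w_y, 0),

negative fitness estimates being measurement artifacts clipped to zero.
The multiplicative expectation is the field's standard neutral model for
fitness epistasis; no alternative (log-ratio, minimum) definitions are
provided.

## Error model and significance

Four uncertainty terms are estimated per condition:

- σ̂(w_xy): one global scalar, the median absolute difference of w_xy
  between the two technical replicates over all strains. With more than
  two replicates the median pools all replicate pairs. The absolute value
  is taken before the median (a signed median would sit near zero and
  carry no scale information).
- σ̂(g_x), σ̂(g_y): the sample SD (ddof = 1 throughout, as the neutral sets
  are small) of the doublings averaged into each marginal mean; a barcode
  with a single neutral partner gets 0 (no spread estimate) and a barcode
  with none has its pairs skipped with a warning.
- σ̂(g_wt): the sample SD over the neutral–neutral pairs.

They combine by the delta method applied to the marginal-term form
`GIS = w_xy − g_x·g_y/g_wt²` (the unique reading consistent with
GIS ≡ w_xy − w_x·w_y, since w_x = g_x/g_wt):

    σ̂_GIS² = σ̂_wxy² + (g_y/g_wt²)²σ̂_gx² + (g_x/g_wt²)²σ̂_gy²
            + (2 g_x g_y/g_wt³)² σ̂_gwt²

Covariances between terms are ignored, as is the dependence of w_xy on
g_wt (σ̂_wxy is treated as a directly estimated global term). Against
brute-force Monte Carlo in the small-uncertainty regime the propagated
σ̂ is accurate to a few percent.

Z = GIS/σ̂_GIS is calibrated empirically: a normal is fitted (sample
moments) to Z over "neutral pairs" — retained, unlinked, distinct-gene
pairs containing at least one neutral gene, where no interactions are
expected — and the two-tailed p is `min(P(null ≥ Z), P(null ≤ Z))·2`,
capped at 1 and floored at the smallest positive float. At least 20
neutral pairs with finite Z are required.

## Gene-level aggregation and calls

Barcode pairs measuring the same gene pair are combined by
inverse-variance weights ω = 1/σ̂² (ω, to avoid colliding with fitness w):
weighted-mean GIS, σ̂_gene = 1/√(Σω), Z accordingly; a σ̂ = 0 record
dominates by construction and triggers an unweighted fallback with a
warning. Two-tailed p-values combine by signed weighted Stouffer
(z_b = sign(GIS_b)·Φ⁻¹(1 − p_b/2), Z = Σωz/√(Σω²)), so conflicting
replicates cancel rather than average into spurious significance.

FDR is Storey's q-value with the smoother π₀ estimate (π₀(λ) on
λ = 0.05…0.95, cubic polynomial read off at λ = 0.95, clamped to (0,1]),
computed within each condition over unlinked distinct-gene pairs; with
π₀ = 1 it reduces exactly to Benjamini–Hochberg, which is also the
fallback below 20 p-values. Calls use q < 0.01 plus an effect-size floor
|GIS| > 0.075: high-confidence but tiny effects are reported neutral.
Same-gene and linked pairs are scored and reported with flags but never
called and never enter normalisation or null sets.

## Differential interactions and condition clustering

For each unordered condition pair, ΔGIS = GIS_a − GIS_b and
ΔZ = ΔGIS/√(σ̂_a² + σ̂_b²) per gene pair. The ΔZ null is again an
empirical normal over neutral pairs; repair–repair pairs get two-tailed
p, within-condition-pair q-values, and a differential call at q < 0.01
and |ΔGIS| > 0.1. Each record carries both per-condition calls and the
type change (+/−/n), and summaries count both all significant
differentials and the type-changing subset, since a magnitude shift that
leaves the interaction class unchanged is usually less interpretable. If
two conditions are statistically identical the neutral ΔZ distribution
degenerates (SD = 0); then only ΔZ equal to the null point is
unsurprising, and no differential is called because |ΔGIS| = 0.

Conditions are clustered on gene-level GIS profiles with the Chebyshev
(maximum) distance and complete linkage; gene pairs missing in either
condition are dropped pairwise, never imputed, and conditions enter in
lexicographic order so equal-height merges are deterministic. The tree is
exported as Newick.

## Quality control

Filter order is fixed — het-diploid coverage, then linkage, then
replicate-profile correlation — each followed by one rescoring pass,
because coverage conditions every later estimate and the profile filter
needs scored profiles. All filters are masks over the immutable raw count
table and are idempotent.

- **Coverage**: pairs with reference-sample count C_xy < 30 are dropped
  from all denominators and neutral means. A pair absent from the
  het-diploid pool cannot report depletion.
- **Linkage**: loci < 75 kbp apart on one chromosome (midpoint
  coordinates) are flagged; their haploid depletion reflects reduced
  independent segregation, not epistasis, so they are excluded from g_wt,
  marginal means and nulls but still reported.
- **Replicate profiles**: each barcode replicate's GIS profile (mean GIS
  per partner gene × condition, both sides of the cross pooled per gene)
  is correlated against the mean profile of its same-gene siblings;
  r < 0.5 excludes it. Profiles deliberately include same-gene and linked
  partner entries: those strongly negative, replicate-consistent controls
  anchor honest replicates — a neutral gene's interaction profile is
  otherwise flat and would correlate at r ≈ 0 — while a globally corrupted
  replicate still decorrelates. A single-replicate gene is kept
  (correlation undefined); a two-replicate disagreement flags both and
  excludes neither, since the data cannot say which is wrong; if every
  replicate of a gene fails, the best-covered one is kept with a warning.

## Synthetic screens

The generator implements the forward model the scorer inverts, with the
statistical structure of a real pooled screen:

- Starting abundances are Gamma(shape = `hetdip_dispersion`, mean 1);
  the default shape 2.0 produces the dispersed representation and
  low-count tail that the coverage filter exists to catch.
- The het-diploid reference sample's expected shares are the starting
  abundances; each haploid sample's are `N₀·d·2^(w_xy·gen_pool)` with
  d = 0.05 for linked pairs (reduced meiotic segregation; applied to
  haploid samples only, since the depletion happens at sporulation, after
  the reference is drawn). Default gen_pool = 6 generations and 10⁶ reads
  per sample; neither is dictated by the assay, both are typical of such
  experiments.
- True pairwise fitness is `max(w_x·w_y + ε, 0)`; ε is configurable per
  gene pair per condition, optionally with dense background epistasis
  among repair genes (`background_epsilon_sd`). Neutral genes have
  fitness 1; repair genes default to U(0.7, 1).
- Same-gene pairs get w_xy = 0: a haploid spore carries one locus, hence
  one of the two resistance markers, and dies under double selection —
  the built-in synthetic-lethal control.
- Aneuploid artifacts: each barcode replicate is, with some probability,
  given an independently redrawn fitness profile (new marginal fitness
  plus independent pairwise terms, SD 0.2). Such replicates also escape
  same-gene lethality, as a duplication spanning the deleted locus
  restores a wild-type copy; this is what makes the artifact's profile
  decorrelate from its siblings rather than merely wobble.
- Two technical replicates per condition are independent multinomial
  draws at fixed depth; reads (25-nt mates: 20-nt barcode + 5-nt constant
  flank, 6-nt index read) carry i.i.d. per-base substitution errors on
  the barcode mates. Barcode sequences are sampled with pairwise Hamming
  distance ≥ 5, making the ≤ 3-mismatch matcher unambiguous on error-free
  reads; sample indices keep distance ≥ 3 and are matched exactly.
- `linked_fraction` places that fraction of genes into disjoint co-located
  couples (< 75 kbp); all other genes sit ≥ 200 kbp apart.

What the simulator does not emulate: mating/sporulation kinetics,
recombination failure, chromosome-level copy-number mechanics,
culture-batch effects, or PCR amplification bias. Passing tests therefore
demonstrate correctness of the inference given multinomial counting noise
and the stated growth model, not robustness to every real-data artifact.

## Numerical choices

- Sample SD (ddof = 1) wherever a standard deviation is estimated.
- Median ties (even counts) use the midpoint.
- p-values are floored at the smallest positive double before q-value
  conversion; p = 0 inputs to Stouffer are clamped with a warning.
- Pair orientation is (donor, recipient) at barcode level and
  alphabetical at gene level; genomic coordinates are 1-based.
- Frequencies are computed over retained pairs only, so each QC exclusion
  changes denominators and everything is rescored.

## Known limitations

- Per-pair counting noise scales with a pair's starting abundance, but
  the error model carries one global σ̂(w) per condition. Neutral-pair Z
  is therefore a scale mixture — near-normal within coverage strata but
  mildly heavy-tailed pooled (~2% of neutral pairs below p = 0.01 on
  fully-null screens instead of the nominal 1%). The empirical null
  absorbs the scale, not the shape. In practice gene-level aggregation
  and the double cutoff leave null screens with essentially zero calls,
  but single-barcode p-values near the tail should be read as
  approximate.
- The profile-correlation filter needs either control anchors or real
  interaction structure to separate honest replicates from artifacts; on
  a screen with few genes (anchors dominating) its power to catch
  artifacts drops.
- Storey's π₀ smoother uses a cubic polynomial rather than the original
  smoothing spline; on uniform p-values the two agree to within a few
  percent, and π₀ is clamped to (0, 1].
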