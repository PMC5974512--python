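"""Forward simulation of a pooled double-mutant fitness screen.

The generator emulates the statistical structure the scoring model inverts:

* a many-by-many haploid double-mutant pool built from barcoded donor and
  recipient single mutants (several barcode replicates per gene per side);
* per-strain exponential growth, where a double mutant's doublings over the
  experiment are ``w_xy * gen_pool`` (relative fitness times generations of
  pool growth) and ``w_xy = max(w_x * w_y + epsilon, 0)`` under the
  multiplicative interaction model;
* a heterozygous-diploid reference ("time zero") sample whose counts are
  proportional to the gamma-dispersed starting abundances;
* same-gene barcode pairs that cannot survive haploid double selection
  (``w_xy = 0``, i.e. synthetic-lethal controls);
* genetically linked pairs (< 75 kbp apart on one chromosome) depleted at
  meiosis by a fixed segregation factor;
* two technical replicates per growth condition, each an independent
  multinomial read sample at fixed depth;
* occasional "aneuploid" barcode replicates whose whole fitness profile is
  redrawn, reproducing the decorrelated replicate profiles that the
  replicate-correlation QC filter has to catch.

Read-level output (:func:`simulate_reads`) emits 25-nt paired reads
(20-nt barcode + 5-nt constant flank) plus a 6-nt sample-index read, with
optional per-base substitution errors on the barcode mates.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gipool.core import BarcodeLibrary, FusedCountTable, pair_annotations

#: constant flank appended after the 20-nt barcode to fill the 25-nt read
FLANK = "ACGTA"

#: bp cutoff below which two same-chromosome loci are treated as linked
LINKAGE_CUTOFF_BP = 75_000

@dataclass
class SimulationConfig:
    """Parameters of a synthetic pooled screen.

    Attributes
    ----------
    n_repair_genes, n_neutral_genes
        Sizes of the two gene classes. Neutral loci (fitness-neutral
        deletions) anchor single-mutant fitness estimation and the null.
    replicates_per_gene
        Barcode replicates per gene on each side of the cross.
    true_single_fitness
        gene -> relative single-mutant fitness in [0, 1.5]. Genes absent
        from the map default to 1.0 (neutral) or a uniform draw on
        [0.7, 1.0] (repair).
    true_epsilon
        (gene_i, gene_j, condition) -> interaction term added to
        ``w_i * w_j``; unlisted triples are 0. Symmetric in the gene pair.
    background_epsilon_sd
        If > 0, every repair-repair gene pair without an explicit
        ``true_epsilon`` entry receives an i.i.d. N(0, sd) interaction per
        condition, emulating the dense epistasis structure of a real
        repair-gene network.
    conditions
        All sample conditions, including ``reference_condition`` (the
        heterozygous-diploid stage).
    gen_pool
        Generations of pool growth, either one number for every haploid
        sample or a per-condition map.
    reads_per_sample
        Multinomial sequencing depth per sample.
    linked_fraction
        Fraction of genes placed in linked couples (< 75 kbp apart on a
        shared chromosome); all other genes are placed far apart.
    linked_depletion
        Factor applied to a linked pair's haploid starting abundance,
        modelling reduced independent segregation at meiosis.
    samegene_included
        Whether same-gene barcode pairs appear in the pool.
    aneuploid_replicate_rate
        Probability that a barcode replicate has its whole fitness profile
        independently redrawn (aneuploidy-like artifact).
    hetdip_dispersion
        Gamma shape of starting abundances; 1 = exponential spread,
        larger = tighter around equal representation.
    """

    n_repair_genes: int = 10
    n_neutral_genes: int = 6
    replicates_per_gene: int = 2
    true_single_fitness: dict[str, float] = field(default_factory=dict)
    true_epsilon: dict[tuple[str, str, str], float] = field(default_factory=dict)
    background_epsilon_sd: float = 0.0
    conditions: tuple[str, ...] = ("hetdip", "NoDrug", "MMS")
    reference_condition: str = "hetdip"
    gen_pool: float | dict[str, float] = 6.0
    reads_per_sample: int = 1_000_000
    linked_fraction: float = 0.1
    linked_depletion: float = 0.05
    samegene_included: bool = True
    aneuploid_replicate_rate: float = 0.0
    aneuploid_profile_sd: float = 0.2
    hetdip_dispersion: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_repair_genes < 1 or self.n_neutral_genes < 1:
            raise ValueError("need at least one gene of each class")
        if self.replicates_per_gene < 1:
            raise ValueError("replicates_per_gene must be >= 1")
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be positive")
        if not self.conditions:
            raise ValueError("conditions must be non-empty")
        if self.reference_condition not in self.conditions:
            raise ValueError(
                f"reference condition {self.reference_condition!r} not in conditions"
            )
        if not 0.0 <= self.linked_fraction <= 1.0:
            raise ValueError("linked_fraction must be in [0, 1]")
        if self.hetdip_dispersion < 1.0:
            raise ValueError("hetdip_dispersion must be >= 1")
        for g, w in self.true_single_fitness.items():
            if not 0.0 <= w <= 1.5:
                raise ValueError(f"single fitness for {g} outside [0, 1.5]: {w}")
        genes = set(self.gene_names())
        for gi, gj, cond in self.true_epsilon:
            if gi not in genes or gj not in genes:
                raise ValueError(f"epsilon entry for unknown gene pair ({gi}, {gj})")
            if cond not in self.conditions:
                raise ValueError(f"epsilon entry for unknown condition {cond!r}")
        for cond in self.growth_conditions():
            if self.gen_pool_for(cond) <= 0:
                raise ValueError(f"gen_pool must be > 0 (condition {cond!r})")

    def gene_names(self) -> list[str]:
        repair = [f"RPR{i + 1:02d}" for i in range(self.n_repair_genes)]
        neutral = [f"NEU{i + 1:02d}" for i in range(self.n_neutral_genes)]
        return repair + neutral

    def gene_classes(self) -> dict[str, str]:
        return {
            g: ("repair" if g.startswith("RPR") else "neutral")
            for g in self.gene_names()
        }

    def growth_conditions(self) -> list[str]:
        return [c for c in self.conditions if c != self.reference_condition]

    def gen_pool_for(self, condition: str) -> float:
        if isinstance(self.gen_pool, dict):
            return float(self.gen_pool[condition])
        return float(self.gen_pool)


@dataclass
class SimulationTruth:
    """Ground truth of a simulated screen.

    ``strains`` is the barcode library table plus an ``aneuploid`` flag;
    ``w_true`` holds the true double-mutant fitness per barcode pair per
    condition; ``epsilon_true`` the planted gene-level interaction terms;
    ``interaction_class`` the sign class ({positive, negative, neutral}) of
    each unlinked non-same-gene gene pair per condition.
    """

    strains: pd.DataFrame
    w_true: pd.DataFrame
    epsilon_true: pd.DataFrame
    interaction_class: pd.DataFrame


def random_barcodes(n: int, rng: np.random.Generator, min_dist: int = 5) -> list[str]:
    """Draw ``n`` 20-mers with pairwise Hamming distance >= ``min_dist``.

    Rejection sampling; the distance floor guarantees the 85%-identity
    matcher (<= 3 mismatches) is unambiguous on error-free reads.
    """
    chosen: list[np.ndarray] = []
    guard = 0
    while len(chosen) < n:
        cand = rng.integers(0, 4, size=20)
        if all(int(np.sum(cand != c)) >= min_dist for c in chosen):
            chosen.append(cand)
        guard += 1
        if guard > 200 * n + 1000:
            raise RuntimeError("barcode sampling failed to satisfy distance floor")
    return ["".join("ACGT"[b] for b in arr) for arr in chosen]


def _place_genes(
    genes: list[str], linked_fraction: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Assign chromosome/position: linked couples < 75 kbp, the rest far apart."""
    n_linked_genes = int(len(genes) * linked_fraction) // 2 * 2
    order = list(rng.permutation(genes))
    couples = [
        (order[i], order[i + 1]) for i in range(0, n_linked_genes, 2)
    ]
    singles = order[n_linked_genes:]
    rows = {}
    slot = 0
    n_chrom = 16
    for a, b in couples:
        chrom = f"chr{slot % n_chrom + 1:02d}"
        base = 100_000 + 400_000 * (slot // n_chrom)
        offset = int(rng.integers(5_000, 70_000))
        rows[a] = (chrom, base)
        rows[b] = (chrom, base + offset)
        slot += 1
    for g in singles:
        chrom = f"chr{slot % n_chrom + 1:02d}"
        base = 100_000 + 400_000 * (slot // n_chrom)
        rows[g] = (chrom, base)
        slot += 1
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["chromosome", "position_bp"])
    return out.loc[genes]


def build_library(config: SimulationConfig, rng: np.random.Generator) -> BarcodeLibrary:
    """Barcoded donor/recipient strain collections for the configured genes."""
    genes = config.gene_names()
    classes = config.gene_classes()
    coords = _place_genes(genes, config.linked_fraction, rng)
    n_bc = 2 * config.replicates_per_gene * len(genes)
    seqs = random_barcodes(n_bc, rng)
    rows = []
    k = 0
    for side, tag in (("donor", "d"), ("recipient", "r")):
        for gene in genes:
            for rep in range(1, config.replicates_per_gene + 1):
                bc_id = f"{gene}_{tag}{rep}"
                rows.append(
                    {
                        "barcode_id": bc_id,
                        "sequence": seqs[k],
                        "side": side,
                        "strain_id": bc_id,
                        "gene": gene,
                        "gene_class": classes[gene],
                        "chromosome": coords.loc[gene, "chromosome"],
                        "position_bp": int(coords.loc[gene, "position_bp"]),
                    }
                )
                k += 1
    return BarcodeLibrary(pd.DataFrame(rows))


def _epsilon_lookup(config: SimulationConfig) -> dict[tuple[str, str, str], float]:
    eps: dict[tuple[str, str, str], float] = {}
    for (gi, gj, cond), e in config.true_epsilon.items():
        eps[(gi, gj, cond)] = e
        eps[(gj, gi, cond)] = e
    return eps


def simulate_pool(
    config: SimulationConfig,
) -> tuple[SimulationTruth, FusedCountTable, BarcodeLibrary]:
    """Simulate one full screen: truth, fused count table and library.

    The forward model draws per-pair starting abundances
    ``N0 ~ Gamma(shape=hetdip_dispersion, mean=1)``, sets the
    heterozygous-diploid reference sample's expected share proportional to
    ``N0``, and each haploid sample's expected share proportional to
    ``N0 * depletion * 2^(w_xy * gen_pool)`` (depletion < 1 only for linked
    pairs), then draws ``reads_per_sample`` reads per sample from a
    multinomial, independently for two technical replicates per condition.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    library = build_library(config, rng)
    ann = pair_annotations(library)
    if not config.samegene_included:
        ann = ann[~ann["same_gene"]]

    genes = config.gene_names()
    classes = config.gene_classes()
    fitness = dict(config.true_single_fitness)
    for g in genes:
        if g not in fitness:
            fitness[g] = 1.0 if classes[g] == "neutral" else float(
                rng.uniform(0.7, 1.0)
            )

    # per-barcode fitness; aneuploid replicates get an independent redraw
    strains = library.table.copy()
    aneuploid = rng.random(len(strains)) < config.aneuploid_replicate_rate
    strains["aneuploid"] = aneuploid
    w_barcode = {}
    for _, row in strains.iterrows():
        if row["aneuploid"]:
            w_barcode[row["barcode_id"]] = float(rng.uniform(0.4, 1.2))
        else:
            w_barcode[row["barcode_id"]] = fitness[row["gene"]]

    eps = _epsilon_lookup(config)
    growth_conditions = config.growth_conditions()
    if config.background_epsilon_sd > 0:
        repair = [g for g in genes if classes[g] == "repair"]
        for i, gi in enumerate(repair):
            for gj in repair[i + 1 :]:
                for cond in growth_conditions:
                    if (gi, gj, cond) not in eps:
                        e = float(rng.normal(0.0, config.background_epsilon_sd))
                        eps[(gi, gj, cond)] = e
                        eps[(gj, gi, cond)] = e
    aneu_ids = set(strains.loc[strains["aneuploid"], "barcode_id"])

    donors = ann.index.get_level_values(0)
    recips = ann.index.get_level_values(1)
    w_d = np.array([w_barcode[b] for b in donors])
    w_r = np.array([w_barcode[b] for b in recips])
    same_gene = ann["same_gene"].to_numpy()
    aneu_pair = np.array([d in aneu_ids or r in aneu_ids for d, r in zip(donors, recips)])

    w_true = pd.DataFrame(index=ann.index, columns=growth_conditions, dtype=float)
    for cond in growth_conditions:
        e = np.array(
            [eps.get((gd, gr, cond), 0.0) for gd, gr in zip(ann["gene_d"], ann["gene_r"])]
        )
        w = w_d * w_r + e
        if aneu_pair.any():
            # decorrelate the artifact replicate's profile with pairwise noise
            noise = rng.normal(0.0, config.aneuploid_profile_sd, size=len(w))
            w = np.where(aneu_pair, w_d * w_r + noise, w)
        w = np.clip(w, 0.0, None)
        # haploid same-gene selection kills the pair -- unless one side is
        # aneuploid: a duplication spanning the locus restores a wild-type
        # copy and lets the double marker survive, which is exactly how the
        # artifact corrupts a replicate's profile
        w[same_gene & ~aneu_pair] = 0.0
        w_true[cond] = w

    linked = (ann["distance_bp"] < LINKAGE_CUTOFF_BP).fillna(False).to_numpy() & ~same_gene
    n0 = rng.gamma(shape=config.hetdip_dispersion, scale=1.0 / config.hetdip_dispersion,
                   size=len(ann))

    sample_rows = []
    count_cols = {}
    het_id = f"{config.reference_condition}_T0"
    p0 = n0 / n0.sum()
    count_cols[het_id] = rng.multinomial(config.reads_per_sample, p0)
    sample_rows.append(
        {"sample_id": het_id, "condition": config.reference_condition,
         "tech_replicate": 0, "stage": "hetdip", "gen_pool": 0.0}
    )
    for cond in growth_conditions:
        gp = config.gen_pool_for(cond)
        share = n0 * np.where(linked, config.linked_depletion, 1.0)
        share = share * np.exp2(w_true[cond].to_numpy() * gp)
        p = share / share.sum()
        for rep in (1, 2):
            sid = f"{cond}_R{rep}"
            count_cols[sid] = rng.multinomial(config.reads_per_sample, p)
            sample_rows.append(
                {"sample_id": sid, "condition": cond, "tech_replicate": rep,
                 "stage": "haploid", "gen_pool": gp}
            )

    counts = pd.DataFrame(count_cols, index=ann.index).sort_index()
    table = FusedCountTable(counts, pd.DataFrame(sample_rows))

    # gene-level planted epsilon and its sign class, for recovery checks
    gp_rows = []
    for i, gi in enumerate(genes):
        for gj in genes[i:]:
            for cond in growth_conditions:
                e = eps.get((gi, gj, cond), 0.0)
                gp_rows.append(
                    {"gene1": min(gi, gj), "gene2": max(gi, gj), "condition": cond,
                     "epsilon": e,
                     "class": "positive" if e > 0 else "negative" if e < 0 else "neutral"}
                )
    epsilon_true = pd.DataFrame(gp_rows)
    interaction_class = epsilon_true[["gene1", "gene2", "condition", "class"]]

    truth = SimulationTruth(
        strains=strains,
        w_true=w_true,
        epsilon_true=epsilon_true,
        interaction_class=interaction_class,
    )
    return truth, table, library


def _open_text(path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def _apply_errors(
    seqs: np.ndarray, error_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-base substitutions on a (n_reads, read_len) uint8 base-index array."""
    if error_rate == 0.0 or seqs.size == 0:
        return seqs
    mask = rng.random(seqs.shape) < error_rate
    shift = rng.integers(1, 4, size=seqs.shape)
    return np.where(mask, (seqs + shift) % 4, seqs)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy()


_BASE_TO_IDX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_IDX[_b] = _i


def sample_indices(sample_ids: list[str], rng: np.random.Generator) -> dict[str, str]:
    """Assign a distinct 6-nt index to each sample (pairwise distance >= 3)."""
    chosen: list[np.ndarray] = []
    out = {}
    guard = 0
    for sid in sample_ids:
        while True:
            cand = rng.integers(0, 4, size=6)
            if all(int(np.sum(cand != c)) >= 3 for c in chosen):
                chosen.append(cand)
                out[sid] = "".join("ACGT"[b] for b in cand)
                break
            guard += 1
            if guard > 100_000:
                raise RuntimeError("index sampling failed")
    return out


def simulate_reads(
    table: FusedCountTable,
    library: BarcodeLibrary,
    error_rate: float,
    r1_path,
    r2_path,
    index_path,
    seed: int = 0,
) -> pd.DataFrame:
    """Emit paired 25-nt barcode reads plus a 6-nt sample-index read.

    Each count in ``table`` becomes exactly that many read triples before
    errors; per-base substitution errors at ``error_rate`` are applied to
    the two barcode mates (the index read is emitted verbatim, matching the
    exact-match demultiplexing downstream). Returns the sample sheet with
    an ``index_seq`` column.
    """
    if not 0.0 <= error_rate <= 0.25:
        raise ValueError(f"error_rate outside [0, 0.25]: {error_rate}")
    rng = np.random.default_rng(seed)
    donor_seq = library.donors["sequence"].to_dict()
    recip_seq = library.recipients["sequence"].to_dict()
    for d, r in table.counts.index:
        if d not in donor_seq or r not in recip_seq:
            raise ValueError(f"pair ({d}, {r}) has no barcode sequences in library")

    sample_ids = list(table.counts.columns)
    idx_map = sample_indices(sample_ids, rng)

    pair_r1 = np.array(
        [_BASE_TO_IDX[_encode(donor_seq[d] + FLANK)] for d, _ in table.counts.index]
    ).reshape(len(table.counts.index), 25) if len(table.counts.index) else np.zeros((0, 25), np.uint8)
    pair_r2 = np.array(
        [_BASE_TO_IDX[_encode(recip_seq[r] + FLANK)] for _, r in table.counts.index]
    ).reshape(len(table.counts.index), 25) if len(table.counts.index) else np.zeros((0, 25), np.uint8)

    decode = np.frombuffer(b"ACGT", dtype=np.uint8)
    qual25 = "I" * 25
    qual6 = "I" * 6
    with _open_text(r1_path, "w") as f1, _open_text(r2_path, "w") as f2, _open_text(
        index_path, "w"
    ) as fi:
        for sid in sample_ids:
            col = table.counts[sid].to_numpy()
            reps = np.repeat(np.arange(len(col)), col)
            r1 = _apply_errors(pair_r1[reps], error_rate, rng)
            r2 = _apply_errors(pair_r2[reps], error_rate, rng)
            r1s = decode[r1].tobytes().decode()
            r2s = decode[r2].tobytes().decode()
            idx_seq = idx_map[sid]
            for i in range(len(reps)):
                rid = f"read_{sid}_{i}"
                f1.write(f"@{rid}\n{r1s[25 * i:25 * i + 25]}\n+\n{qual25}\n")
                f2.write(f"@{rid}\n{r2s[25 * i:25 * i + 25]}\n+\n{qual25}\n")
                fi.write(f"@{rid}\n{idx_seq}\n+\n{qual6}\n")

    sheet = table.samples.copy()
    sheet["index_seq"] = sheet["sample_id"].map(idx_map)
    return sheet
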