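"""Central data containers: the barcode library and the fused-count table.

Everything downstream operates on two tables:

* a :class:`BarcodeLibrary` mapping each 20-nt strain barcode to its gene,
  gene class (``repair``/``neutral``), side of the cross
  (``donor``/``recipient``) and genomic coordinate, and
* a :class:`FusedCountTable` of integer read counts per
  (donor barcode x recipient barcode) per sequencing sample, together with
  the sample metadata (condition, technical replicate, pool stage and the
  number of generations of pool growth).

Both round-trip through plain TSV so every pipeline stage can be re-run
from intermediates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LIBRARY_COLUMNS = [
    "barcode_id",
    "sequence",
    "side",
    "strain_id",
    "gene",
    "gene_class",
    "chromosome",
    "position_bp",
]

SAMPLE_COLUMNS = ["sample_id", "condition", "tech_replicate", "stage", "gen_pool"]

VALID_SIDES = ("donor", "recipient")
VALID_CLASSES = ("repair", "neutral")
VALID_STAGES = ("hetdip", "haploid")


@dataclass
class BarcodeLibrary:
    """Barcode-to-strain annotation table.

    Parameters
    ----------
    table
        One row per barcode with the columns in :data:`LIBRARY_COLUMNS`.
        Sequences are 20-nt uppercase ACGT strings, unique within each side;
        ``position_bp`` is 1-based.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in LIBRARY_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"barcode library missing columns: {missing}")
        t = self.table.reset_index(drop=True).copy()
        t["position_bp"] = t["position_bp"].astype(int)
        bad_side = set(t["side"]) - set(VALID_SIDES)
        if bad_side:
            raise ValueError(f"invalid side values: {sorted(bad_side)}")
        bad_class = set(t["gene_class"]) - set(VALID_CLASSES)
        if bad_class:
            raise ValueError(f"invalid gene_class values: {sorted(bad_class)}")
        for seq in t["sequence"]:
            if len(seq) != 20 or set(seq) - set("ACGT"):
                raise ValueError(f"barcode sequence not 20 nt over ACGT: {seq!r}")
        for side in VALID_SIDES:
            seqs = t.loc[t["side"] == side, "sequence"]
            if seqs.duplicated().any():
                raise ValueError(f"duplicate barcode sequences on {side} side")
            ids = t.loc[t["side"] == side, "barcode_id"]
            if ids.duplicated().any():
                raise ValueError(f"duplicate barcode ids on {side} side")
        if (t["position_bp"] < 1).any():
            raise ValueError("position_bp must be >= 1 (1-based)")
        self.table = t

    def side(self, side: str) -> pd.DataFrame:
        """Rows for one side, indexed by barcode_id."""
        return self.table[self.table["side"] == side].set_index("barcode_id")

    @property
    def donors(self) -> pd.DataFrame:
        return self.side("donor")

    @property
    def recipients(self) -> pd.DataFrame:
        return self.side("recipient")

    def genes(self) -> pd.DataFrame:
        """Per-gene annotation (class, chromosome, position) across sides."""
        g = self.table.groupby("gene").agg(
            gene_class=("gene_class", "first"),
            chromosome=("chromosome", "first"),
            position_bp=("position_bp", "first"),
        )
        return g

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "BarcodeLibrary":
        return cls(pd.read_csv(path, sep="\t", dtype={"barcode_id": str, "gene": str}))


@dataclass
class FusedCountTable:
    """Integer counts per fused barcode pair per sample.

    ``counts`` is a wide matrix indexed by a (donor_barcode, recipient_barcode)
    MultiIndex with one column per sample_id; ``samples`` holds the metadata
    row for each column. Exactly one sample must be the heterozygous-diploid
    reference ("time zero") whose frequencies anchor growth estimation.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        s = self.samples.reset_index(drop=True).copy()
        missing = [c for c in SAMPLE_COLUMNS if c not in s.columns]
        if missing:
            raise ValueError(f"sample metadata missing columns: {missing}")
        bad_stage = set(s["stage"]) - set(VALID_STAGES)
        if bad_stage:
            raise ValueError(f"invalid stage values: {sorted(bad_stage)}")
        if s["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids")
        if sorted(s["sample_id"]) != sorted(self.counts.columns):
            raise ValueError("sample metadata does not match count columns")
        n_ref = (s["stage"] == "hetdip").sum()
        if n_ref != 1:
            raise ValueError(f"need exactly one hetdip reference sample, got {n_ref}")
        c = self.counts.copy()
        if (c.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        c = c.astype(np.int64)
        c.index = c.index.set_names(["donor_barcode", "recipient_barcode"])
        c = c[list(s["sample_id"])]  # canonical column order: the sample sheet's
        self.counts = c
        self.samples = s

    @property
    def hetdip_sample(self) -> str:
        return self.samples.loc[self.samples["stage"] == "hetdip", "sample_id"].iloc[0]

    @property
    def conditions(self) -> list[str]:
        hap = self.samples[self.samples["stage"] == "haploid"]
        return sorted(hap["condition"].unique())

    def condition_samples(self, condition: str) -> list[str]:
        sel = (self.samples["condition"] == condition) & (
            self.samples["stage"] == "haploid"
        )
        sub = self.samples[sel].sort_values("tech_replicate")
        return list(sub["sample_id"])

    def gen_pool(self, sample_id: str) -> float:
        row = self.samples.set_index("sample_id").loc[sample_id]
        return float(row["gen_pool"])

    def to_long(self) -> pd.DataFrame:
        long = self.counts.stack().rename("count").reset_index()
        long.columns = ["donor_barcode", "recipient_barcode", "sample_id", "count"]
        return long

    @classmethod
    def from_long(cls, long: pd.DataFrame, samples: pd.DataFrame) -> "FusedCountTable":
        wide = (
            long.pivot_table(
                index=["donor_barcode", "recipient_barcode"],
                columns="sample_id",
                values="count",
                fill_value=0,
                aggfunc="sum",
            )
            .sort_index()
        )
        wide.columns.name = None
        return cls(wide, samples)

    def write_tsv(self, counts_path, samples_path) -> None:
        self.to_long().to_csv(counts_path, sep="\t", index=False)
        self.samples.to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, counts_path, samples_path) -> "FusedCountTable":
        long = pd.read_csv(counts_path, sep="\t")
        samples = pd.read_csv(samples_path, sep="\t")
        return cls.from_long(long, samples)


def pair_annotations(library: BarcodeLibrary) -> pd.DataFrame:
    """Annotation for every donor x recipient barcode pair.

    Returns a frame indexed by (donor_barcode, recipient_barcode) with the
    genes and gene classes on both sides, the ``same_gene`` flag and, for
    same-chromosome pairs, the distance between the two loci in bp
    (NaN for different chromosomes).
    """
    d = library.donors
    r = library.recipients
    idx = pd.MultiIndex.from_product(
        [d.index, r.index], names=["donor_barcode", "recipient_barcode"]
    )
    ann = pd.DataFrame(index=idx)
    ann["gene_d"] = d["gene"].reindex(idx.get_level_values(0)).to_numpy()
    ann["gene_r"] = r["gene"].reindex(idx.get_level_values(1)).to_numpy()
    ann["class_d"] = d["gene_class"].reindex(idx.get_level_values(0)).to_numpy()
    ann["class_r"] = r["gene_class"].reindex(idx.get_level_values(1)).to_numpy()
    ann["same_gene"] = (ann["gene_d"] == ann["gene_r"]).to_numpy()
    chrom_d = d["chromosome"].reindex(idx.get_level_values(0)).to_numpy()
    chrom_r = r["chromosome"].reindex(idx.get_level_values(1)).to_numpy()
    pos_d = d["position_bp"].reindex(idx.get_level_values(0)).to_numpy(float)
    pos_r = r["position_bp"].reindex(idx.get_level_values(1)).to_numpy(float)
    same_chrom = chrom_d == chrom_r
    dist = np.where(same_chrom, np.abs(pos_d - pos_r), np.nan)
    ann["distance_bp"] = dist
    ann["neutral_neutral"] = (ann["class_d"] == "neutral") & (
        ann["class_r"] == "neutral"
    )
    ann["any_neutral"] = (ann["class_d"] == "neutral") | (ann["class_r"] == "neutral")
    return ann.sort_index()


def canonical_gene_pair(gene_a: str, gene_b: str) -> tuple[str, str]:
    """Alphabetical orientation used for gene-level records."""
    return (gene_a, gene_b) if gene_a <= gene_b else (gene_b, gene_a)
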