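"""Strain/pair quality control preceding interaction scoring.

Three filters are applied in a fixed order, each followed by one scoring
recomputation pass, since each exclusion changes frequency denominators and
neutral means:

1. **Heterozygous-diploid coverage** -- a pair whose count in the reference
   sample (``C_xy``) is below 30 was never well represented in the pool, so
   its apparent depletion carries no fitness information; such pairs are
   dropped from all downstream denominators and neutral means.
2. **Genetic linkage** -- two loci < 75 kbp apart on the same chromosome
   segregate together at meiosis, so their double mutants are depleted for
   reasons unrelated to epistasis. Linked pairs stay scored and reported,
   flagged, but are excluded from wild-type growth estimation, marginal
   fitness means and the neutral null.
3. **Replicate profile correlation** -- a barcode replicate whose
   interaction-score profile (over partner genes x conditions) correlates
   at Pearson r < 0.5 with the mean profile of its same-gene siblings is
   behaving like a different strain (in practice: aneuploidy acquired
   during strain construction) and is excluded.

All filters operate as masks over the immutable raw count table and are
idempotent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gipool.core import BarcodeLibrary, FusedCountTable, pair_annotations
from gipool.scoring import score_barcode_pairs

CXY_THRESHOLD = 30
LINKAGE_CUTOFF_BP = 75_000
REPLICATE_R_CUTOFF = 0.5


@dataclass
class PairClassification:
    """Pair-level QC state.

    ``frame`` is indexed like the count table and carries the pair
    annotation plus ``C_xy``, ``well_measured``, ``linked`` and the overall
    ``retained`` mask. ``excluded_barcodes`` lists barcode replicates
    removed by the profile filter; ``flagged_barcodes`` lists two-replicate
    disagreements that cannot be resolved without external evidence;
    ``replicate_report`` records every replicate's profile correlation.
    """

    frame: pd.DataFrame
    excluded_barcodes: list[str] = field(default_factory=list)
    flagged_barcodes: list[str] = field(default_factory=list)
    replicate_report: pd.DataFrame | None = None

    def write_tsv(self, path) -> None:
        out = self.frame.reset_index()[
            [
                "donor_barcode",
                "recipient_barcode",
                "gene_d",
                "gene_r",
                "C_xy",
                "same_gene",
                "linked",
                "well_measured",
                "retained",
            ]
        ]
        out.to_csv(path, sep="\t", index=False)


def build_classification(table: FusedCountTable, library: BarcodeLibrary) -> PairClassification:
    """Initial classification: annotation joined with hetdip coverage."""
    ann = pair_annotations(library)
    ann = ann.reindex(table.counts.index)
    if ann["gene_d"].isna().any():
        raise ValueError("count table contains pairs absent from the library")
    frame = ann.copy()
    frame["C_xy"] = table.counts[table.hetdip_sample]
    frame["well_measured"] = True
    frame["linked"] = False
    frame["retained"] = True
    return PairClassification(frame=frame)


def filter_hetdip_coverage(
    classification: PairClassification, threshold: int = CXY_THRESHOLD
) -> PairClassification:
    """Flag pairs with reference-sample coverage C_xy < threshold."""
    f = classification.frame
    f["well_measured"] = f["C_xy"] >= threshold
    _refresh_retained(classification)
    return classification


def classify_linkage(
    classification: PairClassification, cutoff_bp: int = LINKAGE_CUTOFF_BP
) -> PairClassification:
    """Mark same-chromosome pairs closer than ``cutoff_bp`` as linked.

    Same-gene pairs are handled by their own flag and are not marked linked.
    """
    f = classification.frame
    f["linked"] = (f["distance_bp"] < cutoff_bp).fillna(False) & ~f["same_gene"]
    _refresh_retained(classification)
    return classification


def _refresh_retained(classification: PairClassification) -> None:
    f = classification.frame
    excluded = set(classification.excluded_barcodes)
    bad_bc = f.index.get_level_values(0).isin(excluded) | f.index.get_level_values(
        1
    ).isin(excluded)
    f["retained"] = f["well_measured"] & ~bad_bc


def _barcode_profiles(records: pd.DataFrame, library: BarcodeLibrary) -> dict[str, pd.Series]:
    """GIS profile per barcode replicate, over (partner gene, condition).

    All partner entries are kept, including the same-gene and linked ones:
    their strongly negative, replicate-consistent scores anchor the
    correlation between honest replicates (whose interaction profile may
    otherwise be flat, e.g. for neutral genes), while a globally redrawn
    profile still decorrelates on the remaining entries.
    """
    informative = records
    profiles: dict[str, pd.Series] = {}
    by_donor = informative.groupby(["donor_barcode", "gene_r", "condition"])["GIS"].mean()
    for bc in by_donor.index.get_level_values(0).unique():
        profiles[bc] = by_donor.loc[bc]
    by_recip = informative.groupby(["recipient_barcode", "gene_d", "condition"])["GIS"].mean()
    for bc in by_recip.index.get_level_values(0).unique():
        profiles[bc] = by_recip.loc[bc]
    return profiles


def _pearson(a: pd.Series, b: pd.Series) -> float:
    joined = pd.concat([a, b], axis=1, join="inner").dropna()
    if len(joined) < 3:
        return float("nan")
    x, y = joined.iloc[:, 0], joined.iloc[:, 1]
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(x.corr(y))


def filter_replicates_by_profile(
    records: pd.DataFrame,
    library: BarcodeLibrary,
    classification: PairClassification,
    r_cutoff: float = REPLICATE_R_CUTOFF,
) -> PairClassification:
    """Exclude barcode replicates whose GIS profile disagrees with siblings.

    For each barcode replicate of a gene (both sides pooled), the Pearson
    correlation of its profile against the mean profile of the gene's other
    replicates is computed. Replicates with r < ``r_cutoff`` are excluded,
    except: a gene with a single replicate is kept (correlation undefined);
    a gene with exactly two disagreeing replicates has both flagged but
    neither excluded (the conflict is unresolvable from the data); if every
    replicate of a gene fails, the one with the highest hetdip coverage is
    kept with a warning.
    """
    profiles = _barcode_profiles(records, library)
    lib = library.table.set_index("barcode_id")
    coverage = classification.frame.groupby(level=0)["C_xy"].sum().add(
        classification.frame.groupby(level=1)["C_xy"].sum(), fill_value=0
    )

    excluded: list[str] = []
    flagged: list[str] = []
    rep_rows = []
    for gene, group in lib.groupby("gene"):
        bcs = [b for b in group.index if b in profiles]
        if len(bcs) <= 1:
            for b in bcs:
                rep_rows.append({"barcode_id": b, "gene": gene, "profile_r": np.nan,
                                 "excluded": False, "flagged": False})
            continue
        rs = {}
        for b in bcs:
            others = [profiles[o] for o in bcs if o != b]
            mean_other = pd.concat(others, axis=1).mean(axis=1)
            rs[b] = _pearson(profiles[b], mean_other)
        if len(bcs) == 2:
            fail = any(np.isfinite(r) and r < r_cutoff for r in rs.values())
            for b in bcs:
                rep_rows.append({"barcode_id": b, "gene": gene, "profile_r": rs[b],
                                 "excluded": False, "flagged": fail})
                if fail:
                    flagged.append(b)
            continue
        failing = [b for b in bcs if np.isfinite(rs[b]) and rs[b] < r_cutoff]
        if len(failing) == len(bcs):
            keep = max(failing, key=lambda b: coverage.get(b, 0))
            warnings.warn(
                f"all replicates of {gene} fail the profile filter; retaining "
                f"{keep} (highest hetdip coverage)"
            )
            failing = [b for b in failing if b != keep]
        for b in bcs:
            rep_rows.append({"barcode_id": b, "gene": gene, "profile_r": rs[b],
                             "excluded": b in failing, "flagged": False})
        excluded.extend(failing)

    classification.excluded_barcodes = sorted(set(classification.excluded_barcodes) | set(excluded))
    classification.flagged_barcodes = sorted(set(classification.flagged_barcodes) | set(flagged))
    classification.replicate_report = pd.DataFrame(
        rep_rows, columns=["barcode_id", "gene", "profile_r", "excluded", "flagged"]
    )
    _refresh_retained(classification)
    return classification


def run_qc(
    table: FusedCountTable,
    library: BarcodeLibrary,
    cxy_threshold: int = CXY_THRESHOLD,
    linkage_cutoff_bp: int = LINKAGE_CUTOFF_BP,
    replicate_r_cutoff: float = REPLICATE_R_CUTOFF,
) -> PairClassification:
    """Full QC pass: coverage -> linkage -> replicate-profile correlation.

    The profile filter needs a first scoring pass, which is run here on the
    coverage- and linkage-filtered data; callers rescore afterwards on the
    final masks.
    """
    classification = build_classification(table, library)
    filter_hetdip_coverage(classification, cxy_threshold)
    classify_linkage(classification, linkage_cutoff_bp)
    first_pass, _ = score_barcode_pairs(table, classification.frame)
    filter_replicates_by_profile(first_pass, library, classification, replicate_r_cutoff)
    return classification
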