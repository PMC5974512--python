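"""Coverage, linkage and replicate-profile filters."""

import numpy as np
import pandas as pd
import pytest

from gipool.qc import (
    build_classification,
    classify_linkage,
    filter_hetdip_coverage,
    filter_replicates_by_profile,
    run_qc,
)
from gipool.simulate import SimulationConfig, simulate_pool


@pytest.fixture(scope="module")
def classified(small_screen_module):
    table, library = small_screen_module
    cl = build_classification(table, library)
    filter_hetdip_coverage(cl)
    classify_linkage(cl)
    return table, library, cl


@pytest.fixture(scope="module")
def small_screen_module():
    cfg = SimulationConfig(
        n_repair_genes=5, n_neutral_genes=4, replicates_per_gene=2,
        reads_per_sample=100_000, linked_fraction=0.25, seed=21,
    )
    _, table, library = simulate_pool(cfg)
    return table, library


def test_coverage_threshold_boundary(classified):
    """C_xy = 29 is excluded, C_xy = 30 retained (threshold is >=)."""
    table, library, _ = classified
    cl = build_classification(table, library)
    cl.frame.loc[cl.frame.index[0], "C_xy"] = 29
    cl.frame.loc[cl.frame.index[1], "C_xy"] = 30
    filter_hetdip_coverage(cl, threshold=30)
    assert not cl.frame.iloc[0]["well_measured"]
    assert cl.frame.iloc[1]["well_measured"]
    assert not cl.frame.iloc[0]["retained"]


def test_coverage_no_change_when_all_pass(classified):
    table, library, _ = classified
    cl = build_classification(table, library)
    cl.frame["C_xy"] = 100
    filter_hetdip_coverage(cl)
    assert cl.frame["well_measured"].all()


def test_linkage_classification_boundary(classified):
    """Same chromosome < 75 kbp -> linked; >= 75 kbp or trans -> unlinked."""
    _, _, cl = classified
    f = cl.frame
    within = f["distance_bp"] < 75_000
    assert (f.loc[within & ~f["same_gene"], "linked"]).all()
    assert not f.loc[f["distance_bp"] >= 75_000, "linked"].any()
    assert not f.loc[f["distance_bp"].isna(), "linked"].any()


def test_filters_idempotent(classified):
    table, library, _ = classified
    cl = build_classification(table, library)
    filter_hetdip_coverage(cl)
    classify_linkage(cl)
    before = cl.frame.copy()
    filter_hetdip_coverage(cl)
    classify_linkage(cl)
    pd.testing.assert_frame_equal(before, cl.frame)


def test_filters_do_not_mutate_counts(classified):
    table, library, _ = classified
    raw = table.counts.copy()
    run_qc(table, library)
    pd.testing.assert_frame_equal(raw, table.counts)


def _fake_records(profiles: dict[str, dict]) -> pd.DataFrame:
    """Barcode-level GIS records from {donor_barcode: {partner_gene: gis}}."""
    rows = []
    for donor, partners in profiles.items():
        for (gene_r, cond), gis in partners.items():
            rows.append(
                {
                    "donor_barcode": donor,
                    "recipient_barcode": f"{gene_r}_r1",
                    "gene_d": donor.split("_")[0],
                    "gene_r": gene_r,
                    "condition": cond,
                    "GIS": gis,
                    "same_gene": donor.split("_")[0] == gene_r,
                    "linked": False,
                }
            )
    return pd.DataFrame(rows)


def _library_for(genes_d, genes_r):
    from gipool.core import BarcodeLibrary
    from gipool.simulate import random_barcodes

    rng = np.random.default_rng(1)
    n = sum(len(v) for v in genes_d.values()) + len(genes_r)
    seqs = iter(random_barcodes(n, rng))
    rows = []
    for gene, reps in genes_d.items():
        for rep in reps:
            rows.append(dict(barcode_id=f"{gene}_{rep}", sequence=next(seqs), side="donor",
                             strain_id=f"{gene}_{rep}", gene=gene, gene_class="repair",
                             chromosome="chr01", position_bp=1))
    for i, gene in enumerate(genes_r):
        rows.append(dict(barcode_id=f"{gene}_r1", sequence=next(seqs), side="recipient",
                         strain_id=f"{gene}_r1", gene=gene, gene_class="neutral",
                         chromosome="chr02", position_bp=1 + 200_000 * i))
    return BarcodeLibrary(pd.DataFrame(rows))


def test_profile_filter_keeps_identical_replicates():
    partners = [("P1", "c1"), ("P2", "c1"), ("P3", "c1"), ("P1", "c2"), ("P2", "c2"), ("P3", "c2")]
    base = {p: g for p, g in zip(partners, [-0.5, 0.2, 0.0, -0.4, 0.3, 0.1])}
    recs = _fake_records({"GA_d1": base, "GA_d2": base, "GA_d3": base})
    lib = _library_for({"GA": ["d1", "d2", "d3"]}, ["P1", "P2", "P3"])
    cl = build_classification_from_records(recs, lib)
    filter_replicates_by_profile(recs, lib, cl)
    assert cl.excluded_barcodes == []
    rep = cl.replicate_report.set_index("barcode_id")
    assert np.allclose(rep.loc[["GA_d1", "GA_d2", "GA_d3"], "profile_r"], 1.0)


def test_profile_filter_excludes_decorrelated_replicate():
    rng = np.random.default_rng(5)
    partners = [(f"P{i}", c) for i in range(1, 9) for c in ("c1", "c2", "c3")]
    base = {p: g for p, g in zip(partners, rng.normal(0, 0.3, len(partners)))}
    flipped = {p: -g for p, g in base.items()}  # anti-correlated profile
    recs = _fake_records({"GA_d1": base, "GA_d2": base, "GA_d3": flipped})
    lib = _library_for({"GA": ["d1", "d2", "d3"]}, [f"P{i}" for i in range(1, 9)])
    cl = build_classification_from_records(recs, lib)
    filter_replicates_by_profile(recs, lib, cl)
    assert cl.excluded_barcodes == ["GA_d3"]
    assert not cl.frame.loc["GA_d3"]["retained"].any()


def test_profile_filter_two_replicates_flagged_not_excluded():
    rng = np.random.default_rng(6)
    partners = [(f"P{i}", "c1") for i in range(1, 9)]
    base = {p: g for p, g in zip(partners, rng.normal(0, 0.3, len(partners)))}
    flipped = {p: -g for p, g in base.items()}
    recs = _fake_records({"GA_d1": base, "GA_d2": flipped})
    lib = _library_for({"GA": ["d1", "d2"]}, [f"P{i}" for i in range(1, 9)])
    cl = build_classification_from_records(recs, lib)
    filter_replicates_by_profile(recs, lib, cl)
    assert cl.excluded_barcodes == []
    assert set(cl.flagged_barcodes) == {"GA_d1", "GA_d2"}


def test_profile_filter_single_replicate_retained():
    partners = [(f"P{i}", "c1") for i in range(1, 5)]
    base = {p: 0.1 for p in partners}
    recs = _fake_records({"GA_d1": base})
    lib = _library_for({"GA": ["d1"]}, [f"P{i}" for i in range(1, 5)])
    cl = build_classification_from_records(recs, lib)
    filter_replicates_by_profile(recs, lib, cl)
    assert cl.excluded_barcodes == []


def build_classification_from_records(recs, lib):
    """Classification whose count table covers the records' pairs."""
    from gipool.core import FusedCountTable

    pairs = pd.MultiIndex.from_frame(
        recs[["donor_barcode", "recipient_barcode"]].drop_duplicates()
    )
    full = pd.MultiIndex.from_product(
        [lib.donors.index, lib.recipients.index],
        names=["donor_barcode", "recipient_barcode"],
    )
    counts = pd.DataFrame(
        {"hd": 100, "c1_R1": 100, "c1_R2": 100}, index=full
    )
    samples = pd.DataFrame(
        {
            "sample_id": ["hd", "c1_R1", "c1_R2"],
            "condition": ["hetdip", "c1", "c1"],
            "tech_replicate": [0, 1, 2],
            "stage": ["hetdip", "haploid", "haploid"],
            "gen_pool": [0.0, 6.0, 6.0],
        }
    )
    table = FusedCountTable(counts, samples)
    cl = build_classification(table, lib)
    filter_hetdip_coverage(cl)
    classify_linkage(cl)
    return cl


def test_aneuploid_replicate_is_excluded_end_to_end():
    """An injected replicate with a redrawn fitness profile decorrelates
    from its siblings and is removed by the r < 0.5 rule."""
    conds = ("hetdip", "C1", "C2", "C3", "C4", "C5", "C6")
    cfg = SimulationConfig(
        n_repair_genes=26, n_neutral_genes=14, replicates_per_gene=2,
        conditions=conds, reads_per_sample=1_000_000, seed=2,
        background_epsilon_sd=0.15, aneuploid_replicate_rate=0.05,
    )
    truth, table, library = simulate_pool(cfg)
    aneu = set(truth.strains.loc[truth.strains.aneuploid, "barcode_id"])
    assert aneu  # seed chosen so at least one artifact is present
    cl = run_qc(table, library)
    assert aneu <= set(cl.excluded_barcodes)
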