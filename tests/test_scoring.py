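"""Frequency/doubling/fitness arithmetic, error propagation, empirical null."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gipool.scoring import (
    doublings,
    fit_neutral_null,
    p_neutral,
    replicate_sigma,
    sigma_gis,
    strain_frequencies,
    wildtype_doublings,
)


class TestStrainFrequencies:
    def test_pseudocount_arithmetic(self):
        f = strain_frequencies(pd.Series({"A": 10, "B": 0}))
        assert np.isclose(f["A"], 10.5 / 11)
        assert np.isclose(f["B"], 0.5 / 11)

    def test_equal_counts_give_equal_frequencies(self):
        f = strain_frequencies(pd.Series([7, 7, 7, 7]))
        assert np.allclose(f, 0.25)

    def test_zero_counts_share_pseudocount_floor(self):
        f = strain_frequencies(pd.Series({"A": 99, "B": 0, "C": 0}))
        assert np.isclose(f["B"], 0.5 / 100.5)
        assert f["B"] == f["C"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="retained"):
            strain_frequencies(pd.Series(dtype=float))

    @given(st.lists(st.integers(min_value=0, max_value=10**6), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_frequencies_sum_to_one(self, counts):
        f = strain_frequencies(pd.Series(counts))
        assert np.isclose(f.sum(), 1.0)
        assert (f > 0).all()


class TestDoublings:
    @pytest.mark.parametrize(
        "ft,f0,gen,expected",
        [(0.1, 0.1, 5.0, 5.0), (0.2, 0.1, 5.0, 6.0), (0.1 / 32, 0.1, 5.0, 0.0)],
    )
    def test_log_ratio_plus_generations(self, ft, f0, gen, expected):
        g = doublings(pd.Series([ft]), pd.Series([f0]), gen)
        assert np.isclose(g.iloc[0], expected)


class TestWildtypeDoublings:
    def test_mean_and_sample_sd(self):
        g = pd.Series([4.0, 5.0, 6.0])
        mask = pd.Series([True, True, True])
        mean, sd = wildtype_doublings(g, mask)
        assert mean == 5.0 and sd == 1.0

    def test_degenerate_neutral_set(self):
        g = pd.Series([5.0, 5.0, 5.0])
        mean, sd = wildtype_doublings(g, pd.Series([True] * 3))
        assert mean == 5.0 and sd == 0.0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            wildtype_doublings(pd.Series([5.0]), pd.Series([True]))


class TestReplicateSigma:
    def test_identical_replicates(self):
        w = pd.DataFrame({"R1": [1.0, 0.5], "R2": [1.0, 0.5]})
        assert replicate_sigma(w) == 0.0

    def test_median_of_absolute_differences(self):
        w = pd.DataFrame({"R1": [0.0, 0.0, 0.0], "R2": [0.1, -0.2, 0.3]})
        assert np.isclose(replicate_sigma(w), 0.2)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            replicate_sigma(pd.DataFrame({"R1": [1.0]}))


class TestSigmaGis:
    def test_only_wxy_term_survives(self):
        s = sigma_gis(0.07, np.array([5.0]), np.array([5.0]), 5.0,
                      np.array([0.0]), np.array([0.0]), 0.0)
        assert np.isclose(s[0], 0.07)

    def test_gwt_partial_forced_value(self):
        # (2 g_x g_y / g_wt^3) * sigma_gwt = 2*25/125 * 1 = 0.4
        s = sigma_gis(0.0, np.array([5.0]), np.array([5.0]), 5.0,
                      np.array([0.0]), np.array([0.0]), 1.0)
        assert np.isclose(s[0], 0.4)

    def test_zero_gwt_rejected(self):
        with pytest.raises(ValueError, match="g_wt"):
            sigma_gis(0.1, np.array([1.0]), np.array([1.0]), 0.0,
                      np.array([0.1]), np.array([0.1]), 0.1)

    def test_matches_monte_carlo_sd(self):
        """Delta-method sigma within 25% of brute-force Monte-Carlo SD in the
        small-uncertainty regime."""
        rng = np.random.default_rng(11)
        for _ in range(5):
            gx, gy, gwt = rng.uniform(3, 7, size=3)
            s_w = rng.uniform(0.005, 0.05)
            s_gx, s_gy, s_gwt = rng.uniform(0.02, 0.2, size=3)
            n = 200_000
            w_draw = s_w * rng.standard_normal(n)
            gx_d = gx + s_gx * rng.standard_normal(n)
            gy_d = gy + s_gy * rng.standard_normal(n)
            gwt_d = gwt + s_gwt * rng.standard_normal(n)
            mc_sd = np.std(w_draw - gx_d * gy_d / gwt_d**2, ddof=1)
            delta = sigma_gis(s_w, np.array([gx]), np.array([gy]), gwt,
                              np.array([s_gx]), np.array([s_gy]), s_gwt)[0]
            assert abs(delta - mc_sd) / mc_sd < 0.25


class TestNeutralNull:
    def test_simple_moments(self):
        mu, sd = fit_neutral_null(np.array([-1.0, 0.0, 1.0]), min_pairs=3)
        assert mu == 0.0 and sd == 1.0

    def test_standard_normal_recovered(self):
        rng = np.random.default_rng(0)
        mu, sd = fit_neutral_null(rng.standard_normal(10_000))
        assert abs(mu) < 0.05 and abs(sd - 1) < 0.05

    def test_degenerate_null_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_neutral_null(np.full(30, 2.0))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="neutral pairs"):
            fit_neutral_null(np.zeros(5))

    @pytest.mark.parametrize(
        "z,expected",
        [(0.0, 1.0), (1.959964, 0.05), (-1.959964, 0.05)],
    )
    def test_two_tailed_p(self, z, expected):
        assert np.isclose(p_neutral(z, 0.0, 1.0), expected, atol=1e-4)

    def test_p_symmetric_about_null_mean(self):
        assert np.isclose(p_neutral(2.5, 1.0, 0.5), p_neutral(-0.5, 1.0, 0.5))


class TestPipelineInvariances:
    def test_time_unit_invariance(self):
        """Rescaling every g*t (and hence g_wt*t) by a common factor leaves
        the fitness ratios w unchanged: the time unit is arbitrary."""
        rng = np.random.default_rng(2)
        g = pd.Series(rng.uniform(3, 7, 30))
        mask = pd.Series([True] * 30)
        for c in (0.5, 2.0, 10.0):
            gwt, _ = wildtype_doublings(g, mask)
            gwt_c, _ = wildtype_doublings(g * c, mask)
            assert np.allclose(g / gwt, (g * c) / gwt_c)

    def test_depth_invariance(self, small_screen):
        """Multiplying all counts in a sample by a constant leaves the
        frequencies unchanged up to the pseudocount."""
        _, _, table, _ = small_screen
        col = table.counts[table.hetdip_sample]
        f1 = strain_frequencies(col)
        f10 = strain_frequencies(col * 10)
        # the pseudocount floor dominates only for near-zero counts
        assert np.allclose(f1, f10, rtol=5e-3, atol=1e-5)


def test_scoring_oracle_on_toy_pool(small_screen):
    """Brute-force recomputation of GIS for a 3x3 pool matches the engine
    to 1e-12 (independent arithmetic, shared inputs only)."""
    from gipool.core import BarcodeLibrary, FusedCountTable
    from gipool.qc import build_classification, classify_linkage, filter_hetdip_coverage
    from gipool.scoring import score_barcode_pairs
    from gipool.simulate import random_barcodes

    rng = np.random.default_rng(8)
    seqs = iter(random_barcodes(6, rng))
    rows = []
    for side, genes in (("donor", ["RX", "NA1", "NA2"]), ("recipient", ["RY", "NB1", "NB2"])):
        for i, g in enumerate(genes):
            rows.append(dict(
                barcode_id=f"{g}_{side[0]}", sequence=next(seqs), side=side,
                strain_id=f"{g}_{side[0]}", gene=g,
                gene_class="repair" if g.startswith("R") else "neutral",
                chromosome=f"chr{i + (0 if side == 'donor' else 3):02d}",
                position_bp=100_000,
            ))
    lib = BarcodeLibrary(pd.DataFrame(rows))
    idx = pd.MultiIndex.from_product(
        [[f"{g}_d" for g in ["RX", "NA1", "NA2"]], [f"{g}_r" for g in ["RY", "NB1", "NB2"]]],
        names=["donor_barcode", "recipient_barcode"],
    )
    counts = pd.DataFrame(
        {
            "hd": [100, 120, 90, 110, 95, 105, 80, 130, 100],
            "c_R1": [40, 200, 180, 190, 210, 200, 170, 260, 190],
            "c_R2": [45, 190, 175, 200, 205, 195, 160, 250, 210],
        },
        index=idx,
    )
    samples = pd.DataFrame({
        "sample_id": ["hd", "c_R1", "c_R2"],
        "condition": ["hetdip", "c", "c"],
        "tech_replicate": [0, 1, 2],
        "stage": ["hetdip", "haploid", "haploid"],
        "gen_pool": [0.0, 6.0, 6.0],
    })
    table = FusedCountTable(counts, samples)
    cl = build_classification(table, lib)
    filter_hetdip_coverage(cl)
    classify_linkage(cl)
    records, _ = score_barcode_pairs(table, cl.frame, min_neutral_null=3)

    # --- brute force, straight from the formulas ---
    ps = 0.5
    f0 = (counts["hd"] + ps) / (counts["hd"] + ps).sum()
    g_reps = []
    for s in ("c_R1", "c_R2"):
        f = (counts[s] + ps) / (counts[s] + ps).sum()
        g_reps.append(np.log2(f / f0) + 6.0)
    g = (g_reps[0] + g_reps[1]) / 2
    nn = [(f"{a}_d", f"{b}_r") for a in ("NA1", "NA2") for b in ("NB1", "NB2")]
    gwt = np.mean([g.loc[p] for p in nn])
    target = ("RX_d", "RY_r")
    gx = np.mean([g.loc[(target[0], f"{b}_r")] for b in ("NB1", "NB2")])
    gy = np.mean([g.loc[(f"{a}_d", target[1])] for a in ("NA1", "NA2")])
    w_xy = g.loc[target] / gwt
    expected_gis = max(w_xy, 0) - max(gx / gwt, 0) * max(gy / gwt, 0)

    got = records.set_index(["donor_barcode", "recipient_barcode"]).loc[target]
    assert abs(got["GIS"] - expected_gis) < 1e-12
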