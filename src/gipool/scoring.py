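"""Barcode-pair-level genetic-interaction scoring.

The model inverts pooled exponential growth. For strain pair *xy* in one
sample, with count-derived frequency ``f`` (pseudocount 0.5) and ``f0``
from the heterozygous-diploid reference sample:

    g_xy*t = log2(f / f0) + gen_pool

where ``gen_pool`` is the total number of generations of pool growth, so
``g_xy*t`` is the strain's realised number of doublings. Wild-type doublings
``g_wt*t`` are the mean over retained, unlinked neutral-neutral pairs, and
relative fitness is ``w_xy = g_xy / g_wt``. Single-mutant fitness ``w_x``
is the mean of ``w_xj`` over the strain's retained, unlinked neutral
partners. The genetic interaction score under the multiplicative model is

    GIS_xy = max(w_xy, 0) - max(w_x, 0) * max(w_y, 0)

(negative fitness estimates are artifacts of measurement noise and are
clipped to 0 before entering the score).

Uncertainty: sigma(w_xy) is a single per-condition scalar, the median
absolute difference of w_xy between the two technical replicates across all
strains; sigma(g_x), sigma(g_y) and sigma(g_wt) are the sample SDs of the
doublings averaged into each mean. The delta method applied to
``GIS = w_xy - g_x*g_y / g_wt**2`` (the marginal terms re-expressed in
doublings) combines them:

    sigma_GIS^2 = sigma_wxy^2
                + (g_y / g_wt^2)^2 * sigma_gx^2
                + (g_x / g_wt^2)^2 * sigma_gy^2
                + (2 g_x g_y / g_wt^3)^2 * sigma_gwt^2

covariances between terms being ignored. Z = GIS / sigma_GIS is then
referenced against an empirical null: a normal fitted to Z over "neutral
pairs" (retained, unlinked, non-same-gene pairs containing at least one
neutral gene), giving a two-tailed p = 2 * min(P(Z_null >= Z), P(Z_null <= Z)).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from gipool.core import FusedCountTable

PSEUDOCOUNT = 0.5

#: minimum neutral pairs required to fit the empirical null
MIN_NEUTRAL_NULL = 20


def strain_frequencies(counts: pd.Series, pseudocount: float = PSEUDOCOUNT) -> pd.Series:
    """Pseudocounted strain frequencies within one sample.

    ``counts`` must already be restricted to the retained pairs: exclusions
    are removed from the denominator, not zeroed.
    """
    if len(counts) == 0:
        raise ValueError("no retained pairs: cannot compute frequencies")
    x = counts.astype(float) + pseudocount
    return x / x.sum()


def doublings(f_t: pd.Series, f_0: pd.Series, gen_pool: float) -> pd.Series:
    """Realised doublings g*t = log2(f_t / f_0) + gen_pool."""
    return np.log2(f_t / f_0) + gen_pool


def wildtype_doublings(gt: pd.Series, neutral_neutral_mask: pd.Series) -> tuple[float, float]:
    """Mean and sample SD of g*t over retained unlinked neutral-neutral pairs."""
    vals = gt[neutral_neutral_mask.reindex(gt.index, fill_value=False)]
    if len(vals) < 3:
        raise ValueError(
            f"need >= 3 neutral-neutral pairs to estimate wild-type growth, got {len(vals)}"
        )
    return float(vals.mean()), float(vals.std(ddof=1))


def replicate_sigma(w_by_rep: pd.DataFrame) -> float:
    """Global per-condition fitness uncertainty.

    Median over strains of |w_xy(R1) - w_xy(R2)|; with more than two
    technical replicates, the median pools all replicate pairs.
    """
    reps = list(w_by_rep.columns)
    if len(reps) < 2:
        raise ValueError("need >= 2 technical replicates to estimate sigma_wxy")
    diffs = [
        (w_by_rep[a] - w_by_rep[b]).abs().to_numpy()
        for a, b in itertools.combinations(reps, 2)
    ]
    return float(np.nanmedian(np.concatenate(diffs)))


def sigma_gis(
    sigma_wxy: float,
    g_x: np.ndarray,
    g_y: np.ndarray,
    g_wt: float,
    sigma_gx: np.ndarray,
    sigma_gy: np.ndarray,
    sigma_gwt: float,
) -> np.ndarray:
    """Delta-method propagation of the four error terms into sigma_GIS."""
    if g_wt == 0:
        raise ValueError("g_wt is zero: delta-method propagation undefined")
    var = (
        sigma_wxy**2
        + (g_y / g_wt**2) ** 2 * sigma_gx**2
        + (g_x / g_wt**2) ** 2 * sigma_gy**2
        + (2.0 * g_x * g_y / g_wt**3) ** 2 * sigma_gwt**2
    )
    return np.sqrt(var)


def fit_neutral_null(z: np.ndarray, min_pairs: int = MIN_NEUTRAL_NULL) -> tuple[float, float]:
    """Normal (mu, sigma) fitted to neutral-pair Z scores (sample moments)."""
    z = np.asarray(z, dtype=float)
    z = z[np.isfinite(z)]
    if len(z) < min_pairs:
        raise ValueError(f"need >= {min_pairs} neutral pairs with finite Z, got {len(z)}")
    mu = float(np.mean(z))
    sigma = float(np.std(z, ddof=1))
    if sigma == 0:
        raise ValueError("neutral-pair Z scores are degenerate (sigma = 0)")
    return mu, sigma


def p_neutral(z, mu: float, sigma: float):
    """Two-tailed empirical-null p: 2 * min(P(null >= z), P(null <= z)).

    Capped at 1; floored at the smallest positive float so extreme scores
    (same-gene synthetic-lethal controls) stay representable.
    """
    p_pos = stats.norm.sf(z, loc=mu, scale=sigma)
    p_neg = stats.norm.cdf(z, loc=mu, scale=sigma)
    p = np.minimum(np.minimum(p_pos, p_neg) * 2.0, 1.0)
    return np.maximum(p, np.finfo(float).tiny)


@dataclass
class ErrorModel:
    """Per-condition global error terms and the fitted neutral null."""

    frame: pd.DataFrame  # condition, g_wt, sigma_wxy, sigma_gwt, null_mu, null_sigma


def _marginal_doublings(
    g_cond: pd.Series, partner_mask: pd.Series, level: str
) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Mean/SD/count of g*t over each barcode's retained neutral partners."""
    sub = g_cond[partner_mask.reindex(g_cond.index, fill_value=False)]
    grp = sub.groupby(level=level)
    return grp.mean(), grp.std(ddof=1), grp.size()


def score_barcode_pairs(
    table: FusedCountTable,
    qc_frame: pd.DataFrame,
    min_neutral_null: int = MIN_NEUTRAL_NULL,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every retained barcode pair in every condition.

    Parameters
    ----------
    table
        Fused counts with one hetdip reference sample and two technical
        replicates per growth condition.
    qc_frame
        Pair classification aligned to ``table.counts.index`` with boolean
        columns ``retained``, ``linked``, ``same_gene``, ``neutral_neutral``,
        ``any_neutral`` (see :mod:`gipool.qc`).

    Returns
    -------
    records : long DataFrame
        One row per retained pair per condition: marginal fitnesses, w_xy,
        GIS, sigma_GIS, Z_GIS and the neutral-null p-value, plus the QC
        flags needed downstream.
    error_model : DataFrame
        Per-condition g_wt, sigma_wxy, sigma_gwt and fitted null (mu, sigma).
    """
    counts = table.counts
    qc = qc_frame.reindex(counts.index)
    if qc["retained"].isna().any():
        raise ValueError("qc_frame does not cover the count table's pairs")
    ret_idx = qc.index[qc["retained"].astype(bool)]
    sub_qc = qc.loc[ret_idx]

    usable = ~sub_qc["linked"] & ~sub_qc["same_gene"]
    nn_mask = sub_qc["neutral_neutral"] & usable
    neutral_pair_mask = sub_qc["any_neutral"] & usable

    # neutral-partner masks for marginal fitness, per side
    donor_partner = usable & (sub_qc["class_r"] == "neutral")
    recip_partner = usable & (sub_qc["class_d"] == "neutral")

    f0 = strain_frequencies(counts.loc[ret_idx, table.hetdip_sample])

    rec_frames = []
    err_rows = []
    for cond in table.conditions:
        sids = table.condition_samples(cond)
        g_reps = {}
        w_reps = {}
        for s in sids:
            f = strain_frequencies(counts.loc[ret_idx, s])
            g = doublings(f, f0, table.gen_pool(s))
            gwt_rep, _ = wildtype_doublings(g, nn_mask)
            g_reps[s] = g
            w_reps[s] = g / gwt_rep
        g_cond = pd.concat(g_reps, axis=1).mean(axis=1)
        g_wt, s_gwt = wildtype_doublings(g_cond, nn_mask)
        w_cond = g_cond / g_wt
        s_wxy = replicate_sigma(pd.concat(w_reps, axis=1))

        gx_mean, gx_sd, gx_n = _marginal_doublings(g_cond, donor_partner, "donor_barcode")
        gy_mean, gy_sd, gy_n = _marginal_doublings(
            g_cond, recip_partner, "recipient_barcode"
        )
        # a single neutral partner gives no spread estimate; carry 0, not NaN
        gx_sd = gx_sd.where(gx_n > 1, 0.0)
        gy_sd = gy_sd.where(gy_n > 1, 0.0)

        donors = ret_idx.get_level_values("donor_barcode")
        recips = ret_idx.get_level_values("recipient_barcode")
        g_x = gx_mean.reindex(donors).to_numpy()
        g_y = gy_mean.reindex(recips).to_numpy()
        s_gx = gx_sd.reindex(donors).to_numpy()
        s_gy = gy_sd.reindex(recips).to_numpy()

        no_partner = np.isnan(g_x) | np.isnan(g_y)
        if no_partner.any():
            warnings.warn(
                f"{int(no_partner.sum())} pairs skipped in {cond}: a side has no "
                "retained neutral partner"
            )

        w_x = g_x / g_wt
        w_y = g_y / g_wt
        gis = np.clip(w_cond.to_numpy(), 0.0, None) - np.clip(w_x, 0.0, None) * np.clip(
            w_y, 0.0, None
        )
        s_gis = sigma_gis(s_wxy, g_x, g_y, g_wt, s_gx, s_gy, s_gwt)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(s_gis > 0, gis / s_gis, np.nan)

        rec = pd.DataFrame(
            {
                "condition": cond,
                "gene_d": sub_qc["gene_d"].to_numpy(),
                "gene_r": sub_qc["gene_r"].to_numpy(),
                "class_d": sub_qc["class_d"].to_numpy(),
                "class_r": sub_qc["class_r"].to_numpy(),
                "same_gene": sub_qc["same_gene"].to_numpy(),
                "linked": sub_qc["linked"].to_numpy(),
                "neutral_pair": neutral_pair_mask.to_numpy(),
                "g_xy": g_cond.to_numpy(),
                "w_x": w_x,
                "w_y": w_y,
                "w_xy": w_cond.to_numpy(),
                "GIS": gis,
                "sigma_GIS": s_gis,
            },
            index=ret_idx,
        )
        rec = rec[~no_partner]
        rec["Z_GIS"] = np.where(
            rec["sigma_GIS"] > 0, rec["GIS"] / rec["sigma_GIS"], np.nan
        )
        mu, null_sd = fit_neutral_null(
            rec.loc[rec["neutral_pair"], "Z_GIS"].to_numpy(), min_neutral_null
        )
        rec["p_neutral"] = p_neutral(rec["Z_GIS"].to_numpy(), mu, null_sd)
        rec_frames.append(rec)
        err_rows.append(
            {
                "condition": cond,
                "g_wt": g_wt,
                "sigma_wxy": s_wxy,
                "sigma_gwt": s_gwt,
                "null_mu": mu,
                "null_sigma": null_sd,
            }
        )

    records = pd.concat(rec_frames).reset_index()
    error_model = pd.DataFrame(err_rows)
    return records, error_model
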