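"""Gene-pair-level aggregation, FDR control and interaction calls.

Several barcode pairs measure the same gene pair (barcode replicates on
both sides). Their scores are consolidated by inverse-variance weighting
(weight omega_b = 1 / sigma_b^2, written omega to avoid colliding with
fitness w):

    GIS_gene   = sum(omega * GIS) / sum(omega)
    sigma_gene = sqrt(sum(omega^2 * sigma^2)) / sum(omega)  = 1 / sqrt(sum(omega))
    Z_gene     = GIS_gene / sigma_gene

Barcode-level two-tailed p-values are combined with a signed, weighted
Stouffer test (each record's z carries the sign of its GIS so conflicting
replicates cancel), and gene-level p-values are converted to q-values with
Storey's method (smoother pi0 estimate) within each condition. A gene pair
is called positive (negative) when q < 0.01 and GIS > 0.075 (< -0.075);
otherwise neutral.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from gipool.core import canonical_gene_pair

Q_CUTOFF = 0.01
EFFECT_CUTOFF = 0.075

_TINY_P = np.finfo(float).tiny


def combine_barcode_records(
    gis: np.ndarray, sigma: np.ndarray
) -> tuple[float, float, float, np.ndarray]:
    """Inverse-variance-weighted gene-level (GIS, sigma, Z) and the weights.

    A record with sigma = 0 carries infinite weight and dominates: the
    combination then falls back to the unweighted mean of the zero-sigma
    records with sigma_gene = 0 (flagged upstream).
    """
    gis = np.asarray(gis, float)
    sigma = np.asarray(sigma, float)
    if np.any(sigma == 0):
        zero = sigma == 0
        w = zero.astype(float)
        return float(gis[zero].mean()), 0.0, float("nan"), w
    omega = 1.0 / sigma**2
    gis_gene = float(np.sum(omega * gis) / np.sum(omega))
    sigma_gene = float(1.0 / np.sqrt(np.sum(omega)))
    z_gene = gis_gene / sigma_gene
    return gis_gene, sigma_gene, z_gene, omega


def stouffer_combine(p: np.ndarray, gis_signs: np.ndarray, omega: np.ndarray) -> float:
    """Weighted Stouffer combination of two-tailed p-values with direction.

    z_b = sign(GIS_b) * Phi^-1(1 - p_b / 2); Z = sum(omega z) / sqrt(sum(omega^2));
    returns 2 * (1 - Phi(|Z|)).
    """
    p = np.asarray(p, float)
    if np.any(p <= 0):
        warnings.warn("p-values of 0 clamped to the smallest positive float")
        p = np.maximum(p, _TINY_P)
    if np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    signs = np.where(np.asarray(gis_signs, float) < 0, -1.0, 1.0)
    z = signs * stats.norm.isf(p / 2.0)
    omega = np.asarray(omega, float)
    if not np.all(np.isfinite(omega)):
        omega = np.isinf(omega).astype(float)
    z_comb = np.sum(omega * z) / np.sqrt(np.sum(omega**2))
    return float(max(2.0 * stats.norm.sf(abs(z_comb)), _TINY_P))


def storey_qvalue(p: np.ndarray, lambdas: np.ndarray | None = None) -> np.ndarray:
    """Storey q-values with the smoother pi0 estimate.

    pi0(lambda) = #{p > lambda} / (n (1 - lambda)) is evaluated on
    lambda = 0.05, 0.10, ..., 0.95, smoothed with a cubic polynomial and
    read off at the largest lambda; pi0 is clamped to (0, 1]. q-values are
    pi0 * n * p_(i) / i made monotone by a cumulative minimum from the
    largest p down. With pi0 = 1 this is exactly Benjamini-Hochberg, which
    is also the fallback (with a warning) for n < 20, where the smoother
    is unstable.
    """
    p = np.asarray(p, float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    n = len(p)
    if n == 0:
        return np.array([])
    if n < 20:
        warnings.warn("fewer than 20 p-values: using pi0 = 1 (Benjamini-Hochberg)")
        pi0 = 1.0
    else:
        lambdas = np.arange(0.05, 0.96, 0.05) if lambdas is None else lambdas
        pi0_l = np.array([np.mean(p > lam) / (1 - lam) for lam in lambdas])
        coef = np.polyfit(lambdas, pi0_l, 3)
        pi0 = float(np.polyval(coef, lambdas.max()))
        pi0 = min(max(pi0, 1e-8), 1.0)
    order = np.argsort(p)
    ranked = p[order]
    q_ranked = pi0 * n * ranked / np.arange(1, n + 1)
    q_ranked = np.minimum.accumulate(q_ranked[::-1])[::-1]
    q_ranked = np.minimum(q_ranked, 1.0)
    q = np.empty(n)
    q[order] = q_ranked
    return q


def call_interaction(
    gis: float, q: float, q_cutoff: float = Q_CUTOFF, effect_cutoff: float = EFFECT_CUTOFF
) -> str:
    """{positive, negative, neutral} from FDR and effect-size cutoffs."""
    if np.isfinite(q) and q < q_cutoff:
        if gis > effect_cutoff:
            return "positive"
        if gis < -effect_cutoff:
            return "negative"
    return "neutral"


def combine_to_gene_level(
    records: pd.DataFrame,
    q_cutoff: float = Q_CUTOFF,
    effect_cutoff: float = EFFECT_CUTOFF,
) -> pd.DataFrame:
    """Aggregate barcode-pair records into one row per gene pair per condition.

    ``records`` is the output of :func:`gipool.scoring.score_barcode_pairs`.
    Gene pairs are canonicalised alphabetically. FDR (q) is computed within
    each condition over unlinked, distinct-gene pairs; same-gene and linked
    pairs are reported with their flags but carry q = NaN and no call.
    """
    rec = records.copy()
    pairs = [canonical_gene_pair(a, b) for a, b in zip(rec["gene_d"], rec["gene_r"])]
    rec["gene1"] = [p[0] for p in pairs]
    rec["gene2"] = [p[1] for p in pairs]

    gene_class = dict(zip(rec["gene_d"], rec["class_d"]))
    gene_class.update(zip(rec["gene_r"], rec["class_r"]))

    rows = []
    grouped = rec.groupby(["gene1", "gene2", "condition"], sort=True)
    for (g1, g2, cond), sub in grouped:
        gis_gene, sigma_gene, z_gene, omega = combine_barcode_records(
            sub["GIS"].to_numpy(), sub["sigma_GIS"].to_numpy()
        )
        if sigma_gene == 0.0:
            warnings.warn(
                f"all barcode records for ({g1}, {g2}, {cond}) have sigma = 0; "
                "unweighted mean used"
            )
            z_gene = float("nan")
        p_gene = stouffer_combine(
            sub["p_neutral"].to_numpy(), sub["GIS"].to_numpy(), omega
        )
        agg = {}
        for col in ("w_x", "w_y", "w_xy"):
            v = sub[col].to_numpy()
            w = omega if np.all(np.isfinite(omega)) else np.ones_like(v)
            agg[col] = float(np.sum(w * v) / np.sum(w))
        rows.append(
            {
                "gene1": g1,
                "gene2": g2,
                "condition": cond,
                "class1": gene_class[g1],
                "class2": gene_class[g2],
                "same_gene": bool(sub["same_gene"].iloc[0]),
                "linked": bool(sub["linked"].any()),
                "neutral_pair": bool(sub["neutral_pair"].any()),
                "n_barcode_pairs": len(sub),
                **agg,
                "GIS": gis_gene,
                "sigma_GIS": sigma_gene,
                "Z_GIS": z_gene,
                "p_neutral": p_gene,
            }
        )
    gene_table = pd.DataFrame(rows)

    gene_table["q_neutral"] = np.nan
    callable_mask = ~gene_table["same_gene"] & ~gene_table["linked"]
    for cond, sub in gene_table[callable_mask].groupby("condition"):
        gene_table.loc[sub.index, "q_neutral"] = storey_qvalue(
            sub["p_neutral"].to_numpy()
        )
    gene_table["call"] = [
        call_interaction(g, q, q_cutoff, effect_cutoff) if ok else pd.NA
        for g, q, ok in zip(
            gene_table["GIS"], gene_table["q_neutral"], callable_mask
        )
    ]
    return gene_table
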