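"""Condition-dependent (differential) genetic interactions.

For every unordered pair of conditions (a, b) and every gene pair,

    deltaGIS = GIS_a - GIS_b
    deltaZ   = deltaGIS / sqrt(sigma_a^2 + sigma_b^2)

The null for deltaZ is empirical, fitted (normal, sample moments) on the
unlinked neutral pairs (gene pairs containing at least one neutral locus),
where interactions -- hence interaction *changes* -- are not expected.
Two-tailed p-values for the repair-repair pairs are converted to q-values
within each condition pair, and a differential interaction is called when
q < 0.01 and |deltaGIS| > 0.1. Each record carries the per-condition calls
and the interaction-type change (e.g. "-" -> "n"), since a score shift that
does not change interaction type is often less interesting than one that
does.

Conditions are also hierarchically clustered on their gene-level GIS
profiles using the maximum (Chebyshev) distance and complete linkage,
with gene pairs missing in either condition dropped pairwise.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import complete
from scipy.spatial.distance import squareform
from skbio.tree import TreeNode

from gipool.genecalls import storey_qvalue
from gipool.scoring import fit_neutral_null, p_neutral

DELTA_Q_CUTOFF = 0.01
DELTA_EFFECT_CUTOFF = 0.1

_CALL_SYMBOL = {"positive": "+", "negative": "-", "neutral": "n"}


def delta_gis_z(
    gene_records: pd.DataFrame, cond_a: str, cond_b: str
) -> pd.DataFrame:
    """deltaGIS and deltaZ for every gene pair scored in both conditions."""
    cols = ["gene1", "gene2", "GIS", "sigma_GIS", "call", "class1", "class2",
            "same_gene", "linked", "neutral_pair"]
    a = gene_records[gene_records["condition"] == cond_a][cols].set_index(["gene1", "gene2"])
    b = gene_records[gene_records["condition"] == cond_b][cols].set_index(["gene1", "gene2"])
    joined = a.join(b, lsuffix="_a", rsuffix="_b", how="inner")
    if joined.empty:
        raise ValueError(f"conditions {cond_a!r}, {cond_b!r} share no scored gene pairs")
    denom = np.sqrt(joined["sigma_GIS_a"] ** 2 + joined["sigma_GIS_b"] ** 2)
    if (denom == 0).any():
        raise ValueError("both conditions report sigma = 0 for some gene pair")
    out = pd.DataFrame(index=joined.index)
    out["delta_GIS"] = joined["GIS_a"] - joined["GIS_b"]
    out["delta_Z"] = out["delta_GIS"] / denom
    out["call_a"] = joined["call_a"]
    out["call_b"] = joined["call_b"]
    for c in ("class1", "class2", "same_gene", "linked", "neutral_pair"):
        out[c] = joined[f"{c}_a"]
    return out


def call_differentials(
    gene_records: pd.DataFrame,
    q_cutoff: float = DELTA_Q_CUTOFF,
    effect_cutoff: float = DELTA_EFFECT_CUTOFF,
    min_neutral: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Differential records for all condition pairs, plus per-pair summary.

    Records are emitted for repair-repair gene pairs (the pairs of
    interest); the neutral pairs define the deltaZ null. Condition pairs
    are canonicalised lexicographically (cond_a < cond_b); the record for
    the reversed orientation is the negation.

    Returns
    -------
    differentials : DataFrame
        gene1, gene2, cond_a, cond_b, delta_GIS, delta_Z, p_delta, q_delta,
        significant, call_a, call_b, type_change, type_changing.
    summary : DataFrame
        Per condition pair: number of significant differentials and the
        subset that changes interaction type.
    """
    conds = sorted(gene_records["condition"].unique())
    frames = []
    summary_rows = []
    for cond_a, cond_b in itertools.combinations(conds, 2):
        d = delta_gis_z(gene_records, cond_a, cond_b)
        usable = ~d["same_gene"] & ~d["linked"]
        neutral = d[usable & d["neutral_pair"]]
        if len(neutral) < min_neutral:
            raise ValueError(
                f"only {len(neutral)} neutral pairs for ({cond_a}, {cond_b}); "
                f"need >= {min_neutral} for the deltaZ null"
            )
        rr = d[usable & (d["class1"] == "repair") & (d["class2"] == "repair")].copy()
        dz_neutral = neutral["delta_Z"].to_numpy()
        if np.std(dz_neutral, ddof=1) == 0:
            # degenerate null (e.g. two identical conditions): only scores
            # equal to the null point are unsurprising
            mu = float(np.mean(dz_neutral))
            rr["p_delta"] = np.where(
                rr["delta_Z"] == mu, 1.0, np.finfo(float).tiny
            )
        else:
            mu, sd = fit_neutral_null(dz_neutral, min_neutral)
            rr["p_delta"] = p_neutral(rr["delta_Z"].to_numpy(), mu, sd)
        rr["q_delta"] = storey_qvalue(rr["p_delta"].to_numpy())
        rr["significant"] = (rr["q_delta"] < q_cutoff) & (
            rr["delta_GIS"].abs() > effect_cutoff
        )
        rr["type_change"] = [
            f"{_CALL_SYMBOL.get(a, '?')}->{_CALL_SYMBOL.get(b, '?')}"
            for a, b in zip(rr["call_a"], rr["call_b"])
        ]
        rr["type_changing"] = rr["significant"] & (rr["call_a"] != rr["call_b"])
        rr["cond_a"] = cond_a
        rr["cond_b"] = cond_b
        frames.append(rr.reset_index())
        summary_rows.append(
            {
                "cond_a": cond_a,
                "cond_b": cond_b,
                "n_gene_pairs": len(rr),
                "n_significant": int(rr["significant"].sum()),
                "n_type_changing": int(rr["type_changing"].sum()),
            }
        )
    differentials = pd.concat(frames, ignore_index=True)[
        ["gene1", "gene2", "cond_a", "cond_b", "delta_GIS", "delta_Z",
         "p_delta", "q_delta", "significant", "call_a", "call_b",
         "type_change", "type_changing"]
    ]
    return differentials, pd.DataFrame(summary_rows)


def _nan_chebyshev(profiles: pd.DataFrame) -> np.ndarray:
    """Condensed max-distance matrix with pairwise-complete columns."""
    conds = profiles.index
    n = len(conds)
    dmat = np.zeros((n, n))
    vals = profiles.to_numpy(float)
    for i in range(n):
        for j in range(i + 1, n):
            both = np.isfinite(vals[i]) & np.isfinite(vals[j])
            if not both.any():
                raise ValueError(
                    f"conditions {conds[i]!r} and {conds[j]!r} share no scored pairs"
                )
            dmat[i, j] = dmat[j, i] = np.max(np.abs(vals[i, both] - vals[j, both]))
    return squareform(dmat, checks=False)


def cluster_conditions(
    gene_records: pd.DataFrame, value: str = "GIS"
) -> tuple[np.ndarray, list[str], str]:
    """Complete-linkage clustering of conditions on GIS profiles.

    Profiles run over unlinked, distinct-gene gene pairs; the distance is
    the maximum absolute difference (Chebyshev) over pairs scored in both
    conditions. Conditions enter in lexicographic order, which makes equal-
    distance merges deterministic.

    Returns the scipy linkage matrix, the condition order, and the tree in
    Newick form.
    """
    usable = gene_records[~gene_records["same_gene"] & ~gene_records["linked"]]
    profiles = usable.pivot_table(
        index="condition", columns=["gene1", "gene2"], values=value
    )
    if len(profiles) < 2:
        raise ValueError("need >= 2 conditions to cluster")
    if profiles.isna().all(axis=1).any():
        bad = profiles.index[profiles.isna().all(axis=1)]
        raise ValueError(f"conditions with all-missing profiles: {list(bad)}")
    profiles = profiles.sort_index()
    condensed = _nan_chebyshev(profiles)
    linkage = complete(condensed)
    tree = TreeNode.from_linkage_matrix(linkage, list(profiles.index))
    newick = str(tree).strip()
    return linkage, list(profiles.index), newick
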