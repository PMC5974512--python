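"""Simulate the reference synthetic screen used by the downstream analyses.

A 26-repair x 14-neutral gene pool (two barcode replicates per gene per
side), grown in six conditions arranged in three "drug families" with
correlated interaction structure (solvent controls, alkylating agents,
double-strand-break inducers), sequenced at 1e6 reads per sample with two
technical replicates, with 5% of barcode replicates carrying an
aneuploidy-like redrawn profile. Writes counts, library, sample metadata
and ground truth under results/screen/.
"""

from pathlib import Path

import numpy as np

from gipool.simulate import SimulationConfig, simulate_pool

OUT = Path(__file__).resolve().parent.parent / "results" / "screen"

FAMILIES = {
    "ctrl": ("NoDrug", "DMSO"),
    "alkyl": ("MMS", "NQO4"),
    "dsb": ("ZEOC", "BLMC"),
}
SEED = 1


def build_epsilons(rng: np.random.Generator) -> dict[tuple[str, str, str], float]:
    """Repair-pair interactions shared within drug families.

    Each repair pair gets a baseline epistasis plus a family-specific shift
    and a small per-condition jitter, so conditions within a family have
    nearly identical interaction profiles while families differ.
    """
    repair = [f"RPR{i + 1:02d}" for i in range(26)]
    eps = {}
    for i, gi in enumerate(repair):
        for gj in repair[i + 1:]:
            base = rng.normal(0, 0.12)
            for fam, conds in FAMILIES.items():
                shift = rng.normal(0, 0.10)
                for cond in conds:
                    eps[(gi, gj, cond)] = base + shift + rng.normal(0, 0.02)
    return eps


def main() -> None:
    rng = np.random.default_rng(SEED)
    conditions = ("hetdip",) + tuple(c for f in FAMILIES.values() for c in f)
    cfg = SimulationConfig(
        n_repair_genes=26,
        n_neutral_genes=14,
        replicates_per_gene=2,
        conditions=conditions,
        true_epsilon=build_epsilons(rng),
        reads_per_sample=1_000_000,
        aneuploid_replicate_rate=0.05,
        seed=SEED,
    )
    truth, table, library = simulate_pool(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    library.write_tsv(OUT / "library.tsv")
    table.write_tsv(OUT / "counts.tsv", OUT / "samples.tsv")
    truth.strains.to_csv(OUT / "truth_strains.tsv", sep="\t", index=False)
    truth.epsilon_true.to_csv(OUT / "truth_epsilon.tsv", sep="\t", index=False)

    n_aneu = int(truth.strains["aneuploid"].sum())
    print(f"simulated {len(table.counts)} barcode pairs x {len(table.samples)} samples")
    print(f"{n_aneu} aneuploid barcode replicates injected: "
          f"{sorted(truth.strains.loc[truth.strains.aneuploid, 'barcode_id'])}")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
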