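"""Pair and replicate quality control on the reference screen.

Applies the three filters in order -- het-diploid coverage (C_xy >= 30),
genetic linkage (< 75 kbp), replicate-profile correlation (r >= 0.5) --
and compares the excluded replicates against the simulator's injected
aneuploids. Writes the QC tables under results/qc/.
"""

from pathlib import Path

import pandas as pd

from gipool.core import BarcodeLibrary, FusedCountTable
from gipool.qc import run_qc

ROOT = Path(__file__).resolve().parent.parent / "results"
SCREEN = ROOT / "screen"
OUT = ROOT / "qc"


def main() -> None:
    library = BarcodeLibrary.read_tsv(SCREEN / "library.tsv")
    table = FusedCountTable.read_tsv(SCREEN / "counts.tsv", SCREEN / "samples.tsv")
    truth = pd.read_csv(SCREEN / "truth_strains.tsv", sep="\t")

    cl = run_qc(table, library)
    OUT.mkdir(parents=True, exist_ok=True)
    cl.write_tsv(OUT / "qc_pairs.tsv")
    cl.replicate_report.to_csv(OUT / "qc_replicates.tsv", sep="\t", index=False)

    f = cl.frame
    print(f"pairs: {len(f)} total, {int(f['well_measured'].sum())} well-measured "
          f"(C_xy >= 30), {int(f['linked'].sum())} linked, "
          f"{int(f['retained'].sum())} retained")
    aneu = set(truth.loc[truth["aneuploid"], "barcode_id"])
    excl = set(cl.excluded_barcodes)
    print(f"replicates excluded by profile filter: {sorted(excl)}")
    print(f"injected aneuploids: {sorted(aneu)}")
    print(f"caught {len(aneu & excl)}/{len(aneu)} aneuploids; "
          f"{len(excl - aneu)} honest replicates excluded")


if __name__ == "__main__":
    main()
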