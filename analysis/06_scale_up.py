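"""Genome-scale pool-size arithmetic.

How many cells must each pooled step carry to keep every cross of a
genome-scale 5,500 x 5,500 deletion matrix represented by ~1,000 cells?
Writes results/scale_up.tsv.
"""

from pathlib import Path

import pandas as pd

from gipool.design import pool_cells_required

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rows = []
    for n, label in [(39, "this-study-scale (39 genes)"), (5500, "genome-scale")]:
        cells = pool_cells_required(n, n, cells_per_cross=1000)
        rows.append({"matrix": f"{n} x {n}", "label": label, "cells_required": cells})
        print(f"{label}: {n} x {n} crosses at 1,000 cells/cross -> {cells:.3e} cells")
    OUT.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "scale_up.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
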