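"""Scale-up arithmetic for pooled double-mutant screens."""

from __future__ import annotations


def pool_cells_required(
    n_donor_genes: int, n_recipient_genes: int, cells_per_cross: int = 1000
) -> float:
    """Cells needed at each pooled step to keep every cross represented.

    A matrix of ``n_donor_genes x n_recipient_genes`` crosses at
    ``cells_per_cross`` representative cells each; e.g. a genome-scale
    5,500 x 5,500 matrix at 1,000 cells per cross needs ~3e10 cells.
    """
    if n_donor_genes <= 0 or n_recipient_genes <= 0 or cells_per_cross <= 0:
        raise ValueError("all arguments must be positive")
    return float(n_donor_genes) * float(n_recipient_genes) * float(cells_per_cross)
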