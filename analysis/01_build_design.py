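#!/usr/bin/env python
"""Enumerate the 64-variant slippery-sequence design and its signed design matrix.

The combinatorial design crosses four tRNA pairs (Lys/Phe in P and A sites)
with four first-position nucleotides and the 2×2 synonymous codon choices.
Writes the variant table, the design matrix over the 16 canonical base-pair
change variables, and a summary (rank, used variables) under results/.

Finding: the 64×16 matrix uses all 16 variables but has numerical rank 14 —
two variable groups occur only in fixed sums, so two directions are flat.
"""

import json
from pathlib import Path

import fsthermo as ft
from fsthermo.io import write_design_matrix, write_variant_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    variants = ft.enumerate_invitro_design()
    registry = ft.invitro_change_registry()
    design = ft.build_design_matrix(variants, registry)
    rank = ft.matrix_rank(design)

    write_variant_table(OUT / "design_variants.tsv", variants)
    write_design_matrix(OUT / "design_matrix.tsv", design)
    summary = {
        "n_variants": design.n_variants,
        "n_variables": design.n_variables,
        "rank": rank,
        "flat_directions": design.n_variables - rank,
        "variables": design.col_labels,
        "zero_rows": [
            vid for vid, row in zip(design.row_labels, design.entries)
            if not row.any()
        ],
    }
    (OUT / "design_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(
        f"design: {design.n_variants} variants x {design.n_variables} variables, "
        f"rank {rank} ({design.n_variables - rank} flat directions); "
        f"identical-frame variants: {summary['zero_rows']}"
    )


if __name__ == "__main__":
    main()
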