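"""TSV input/output for variant tables, registries and results.

All tables are UTF-8 TSV (no quoting ambiguity for sequence fields).  Labels
use "·" and "→"; the ASCII fallback "." and "->" is accepted on input.
Percent/fraction conversion happens here only — every inner module works in
fractions.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import (
    Anticodon,
    ChangeVariableRegistry,
    DesignMatrix,
    MRNAVariant,
    NucleotideRegistry,
    SlipperyHeptamer,
)

__all__ = [
    "read_variant_table",
    "write_variant_table",
    "read_change_registry",
    "write_change_registry",
    "read_nucleotide_registry",
    "write_design_matrix",
    "write_json",
]

VARIANT_COLUMNS = [
    "variant_id",
    "heptamer",
    "p_anticodon_3to5",
    "a_anticodon_3to5",
    "fs",
    "sigma",
]


class TableValidationError(ValueError):
    """A variant table failed validation; message lists offending lines."""


def _percent_to_fraction(values: pd.Series) -> tuple[pd.Series, bool]:
    """Auto-detect percent columns: a maximum above 1.5 implies percent."""
    finite = values.dropna()
    if not finite.empty and finite.max() > 1.5:
        return values / 100.0, True
    return values, False


def read_variant_table(path, sep: str = "\t") -> list[MRNAVariant]:
    """Load and validate a variant table into MRNAVariant records."""
    table = pd.read_csv(path, sep=sep, dtype={"variant_id": str})
    missing = [c for c in VARIANT_COLUMNS[:4] if c not in table.columns]
    if missing:
        raise TableValidationError(f"{path}: missing column(s) {missing}")
    for col in ("fs", "sigma"):
        if col not in table.columns:
            table[col] = np.nan
    raw_fs = table["fs"].astype(float)
    if raw_fs.dropna().size and (raw_fs.dropna().min() < 0 or raw_fs.dropna().max() > 100):
        bad = table.index[(raw_fs < 0) | (raw_fs > 100)].tolist()
        raise TableValidationError(
            f"{path}: FS outside [0, 100] at data row(s) {[i + 2 for i in bad]}"
        )
    fs, was_percent = _percent_to_fraction(raw_fs)
    sigma = table["sigma"].astype(float)
    if was_percent:
        sigma = sigma / 100.0

    variants: list[MRNAVariant] = []
    errors: list[str] = []
    for i, row in table.iterrows():
        line = i + 2  # header is line 1
        try:
            fs_i = None if pd.isna(fs[i]) else float(fs[i])
            sigma_i = None if pd.isna(sigma[i]) else float(sigma[i])
            variants.append(
                MRNAVariant(
                    str(row["variant_id"]),
                    SlipperyHeptamer(str(row["heptamer"]).strip()),
                    Anticodon.from_string(str(row["p_anticodon_3to5"]).strip()),
                    Anticodon.from_string(str(row["a_anticodon_3to5"]).strip()),
                    fs_i,
                    sigma_i,
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise TableValidationError(f"{path}: " + "; ".join(errors))
    return variants


def write_variant_table(path, variants: Sequence[MRNAVariant]) -> None:
    rows = [
        {
            "variant_id": v.variant_id,
            "heptamer": str(v.heptamer),
            "p_anticodon_3to5": str(v.p_anticodon),
            "a_anticodon_3to5": str(v.a_anticodon),
            "fs": "" if v.fs_experiment is None else v.fs_experiment,
            "sigma": "" if v.sigma_experiment is None else v.sigma_experiment,
        }
        for v in variants
    ]
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_change_registry(path) -> ChangeVariableRegistry:
    """One canonical change label per line; blank lines and # comments skipped."""
    labels = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            labels.append(line)
    return ChangeVariableRegistry(labels)


def write_change_registry(path, registry: ChangeVariableRegistry) -> None:
    Path(path).write_text("\n".join(registry.labels) + "\n", encoding="utf-8")


def read_nucleotide_registry(path) -> NucleotideRegistry:
    """Key/value lines ``code<TAB>name`` merged over the built-in registry."""
    extra = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        code, _, name = line.partition("\t")
        if not name:
            raise ValueError(f"{path}: malformed registry line {line!r}")
        extra[code.strip()] = name.strip()
    return NucleotideRegistry(extra)


def write_design_matrix(path, design: DesignMatrix) -> None:
    design.to_frame().to_csv(path, sep="\t", index_label="variant_id")


def write_json(path, payload: dict) -> None:
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=False) + "\n", encoding="utf-8"
    )
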