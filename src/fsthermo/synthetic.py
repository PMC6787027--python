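"""Synthetic FS datasets with the statistical structure the analysis assumes.

The generator draws measured-looking frameshifting efficiencies from a known
ground truth: total ΔG per variant through the signed design matrix, the
Boltzmann two-state relation (optionally damped by a kinetic factor), and
Gaussian replicate noise of a few percentage points, truncated to keep FS
inside (0, 1).  Because the truth is known, full parameter-recovery tests of
the whole inference pipeline need no external data.

Also houses the in-text fixtures: the 64-variant combinatorial design, the
handful of FS values quoted in the running text, and the 26-variable in-vivo
change catalogue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from .catalog import (
    DesignMatrix,
    MRNAVariant,
    build_design_matrix,
    enumerate_invitro_design,
    invitro_change_registry,
    tsuchihashi_change_registry,
    variant_id,
)
from .thermo import DEFAULT_CONSTANTS, ThermoConstants, fs_from_dg, kappa_of_c, solve_c_for_mean_kappa

__all__ = [
    "SyntheticTruth",
    "default_invitro_truth",
    "simulate_fs_dataset",
    "paper_fixtures",
    "load_supplementary_table",
]

#: Truncation bounds: resampling (not clipping) keeps FS strictly inside (0,1)
#: without point masses at the boundary.
FS_LOW, FS_HIGH = 0.001, 0.999

#: Default replicate noise, 2 percentage points — the scale of triplicate
#: scatter in in-vitro end-point translation assays.
DEFAULT_NOISE_SIGMA = 0.02


@dataclass
class SyntheticTruth:
    """Ground truth for a recovery experiment."""

    dg_bp_true: np.ndarray  # kJ/mol, aligned with a design's columns
    kappa_bar_true: float = 0.0  # 0 = equilibrium (no kinetic damping)
    noise_sigma: Union[float, np.ndarray] = DEFAULT_NOISE_SIGMA
    seed: int = 0

    def __post_init__(self) -> None:
        self.dg_bp_true = np.asarray(self.dg_bp_true, dtype=float)
        if not 0.0 <= self.kappa_bar_true < 1.0:
            raise ValueError("kappa_bar_true must lie in [0, 1)")
        if np.any(np.asarray(self.noise_sigma) <= 0):
            raise ValueError("noise_sigma must be positive")


#: Plausible ground-truth ΔG_bp (kJ/mol) for the 16 in-vitro variables,
#: ordered as the canonical registry.  First-position mismatch penalties
#: follow the established stability ordering pyrimidine·pyrimidine >
#: purine·pyrimidine ≈ pyrimidine·purine > purine·purine; the wobble change
#: G·S→A·S is favourable (the modified U pairs A more strongly than G) and
#: C·G→U·G is a moderate penalty.
_INVITRO_TRUTH = {
    "P1 A·U→C·U": 6.0,
    "P1 A·U→U·U": 5.5,
    "P1 A·U→G·U": 5.1,
    "P1 U·A→A·A": 2.5,
    "P1 U·A→C·A": 4.5,
    "P1 U·A→G·A": 2.0,
    "P3 G·S→A·S": 1.5,
    "P3 C·G→U·G": 1.7,
    "A1 A·U→C·U": 6.0,
    "A1 A·U→U·U": 5.5,
    "A1 A·U→G·U": 1.8,
    "A1 U·A→A·A": 2.5,
    "A1 U·A→C·A": 4.0,
    "A1 U·A→G·A": 2.2,
    "A3 G·S→A·S": -2.9,
    "A3 C·G→U·G": 3.4,
}


def default_invitro_truth(
    noise_sigma: Union[float, np.ndarray] = DEFAULT_NOISE_SIGMA,
    kappa_bar_true: float = 0.0,
    seed: int = 0,
) -> tuple[DesignMatrix, SyntheticTruth]:
    """The 64-variant design with its default ground truth vector."""
    registry = invitro_change_registry()
    design = build_design_matrix(enumerate_invitro_design(), registry)
    dg = np.array([_INVITRO_TRUTH[lab] for lab in design.col_labels])
    return design, SyntheticTruth(dg, kappa_bar_true, noise_sigma, seed)


def simulate_fs_dataset(
    design: DesignMatrix,
    truth: SyntheticTruth,
    constants: ThermoConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Draw a measured-looking FS table from the ground truth.

    FS_i = logistic(−M_i·ΔG_true/kT) · (1−κ_i) + N(0, σ_i), resampled until
    inside (0.001, 0.999).  Reproducible from ``truth.seed``.
    """
    if truth.dg_bp_true.shape[0] != design.n_variables:
        raise ValueError("truth dimension does not match design")
    rng = np.random.default_rng(truth.seed)
    dg_total = design.entries @ truth.dg_bp_true
    fs_clean = fs_from_dg(dg_total, constants)
    if truth.kappa_bar_true > 0.0:
        c = solve_c_for_mean_kappa(truth.kappa_bar_true, dg_total, constants)
        fs_clean = fs_clean * (1.0 - kappa_of_c(c, dg_total, constants))
    sigma = np.broadcast_to(
        np.asarray(truth.noise_sigma, dtype=float), fs_clean.shape
    ).copy()
    fs = fs_clean + rng.normal(0.0, sigma)
    bad = (fs < FS_LOW) | (fs > FS_HIGH)
    while bad.any():
        fs[bad] = fs_clean[bad] + rng.normal(0.0, sigma[bad])
        bad = (fs < FS_LOW) | (fs > FS_HIGH)
    return pd.DataFrame(
        {
            "variant_id": design.row_labels,
            "fs": fs,
            "sigma": sigma,
            "fs_noiseless": fs_clean,
        }
    )


#: FS values quoted in the running text (fractions), keyed by variant id of
#: the combinatorial design.  Only a partial fixture: the full measured table
#: lives outside the public record.
_IN_TEXT_FS = {
    variant_id("A", "AAA", "AAG", "Lys", "Lys"): 0.80,  # wild type, ~80%
    variant_id("G", "AAA", "AAG", "Lys", "Lys"): 0.28,  # A1G
    variant_id("A", "AAG", "AAG", "Lys", "Lys"): 0.44,  # A4G
    variant_id("A", "AAA", "AAA", "Lys", "Lys"): 0.50,  # identical frames
    variant_id("U", "UUU", "UUU", "Phe", "Phe"): 0.50,  # identical frames
    variant_id("G", "AAG", "AAG", "Lys", "Lys"): 0.08,
    variant_id("C", "AAG", "AAG", "Lys", "Lys"): 0.09,
    variant_id("C", "AAG", "AAA", "Lys", "Lys"): 0.02,
}

#: Replicate σ assigned to the in-text fixture values (the per-variant σ of
#: the measured table is not in the public record; 2 pp is the assay scale).
_IN_TEXT_SIGMA = 0.02


def paper_fixtures() -> dict:
    """Named in-text fixtures.

    Returns a dict with:

    * ``design_variants`` – the 64 enumerated variants (no FS),
    * ``invitro_registry`` – the 16-variable change registry,
    * ``in_text_fs`` – DataFrame of the FS values quoted in the running text
      (variant_id, fs, sigma; fractions),
    * ``tsuchihashi_registry`` – the 26-variable in-vivo change registry.
    """
    variants = enumerate_invitro_design()
    by_id = {v.variant_id: v for v in variants}
    in_text = pd.DataFrame(
        {
            "variant_id": list(_IN_TEXT_FS),
            "fs": list(_IN_TEXT_FS.values()),
            "sigma": _IN_TEXT_SIGMA,
        }
    )
    assert all(v in by_id for v in in_text["variant_id"])
    return {
        "design_variants": variants,
        "invitro_registry": invitro_change_registry(),
        "in_text_fs": in_text,
        "tsuchihashi_registry": tsuchihashi_change_registry(),
    }


def in_text_variants() -> list[MRNAVariant]:
    """The in-text fixture as MRNAVariant records with FS ± σ attached."""
    fixture = paper_fixtures()
    by_id = {v.variant_id: v for v in fixture["design_variants"]}
    out = []
    for _, row in fixture["in_text_fs"].iterrows():
        base = by_id[row["variant_id"]]
        out.append(
            MRNAVariant(
                base.variant_id,
                base.heptamer,
                base.p_anticodon,
                base.a_anticodon,
                float(row["fs"]),
                float(row["sigma"]),
            )
        )
    return out


def load_supplementary_table(path, dialect: str = "tsv") -> list[MRNAVariant]:
    """Read a user-supplied variant table into validated records.

    Expected columns: ``variant_id heptamer p_anticodon_3to5 a_anticodon_3to5
    fs sigma`` (fs/sigma empty for prediction-only rows).  FS given in percent
    (column maximum > 1.5) is converted to fractions.  Rows failing validation
    are reported with their line numbers.
    """
    from .io import read_variant_table

    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    return read_variant_table(path, sep=sep)
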