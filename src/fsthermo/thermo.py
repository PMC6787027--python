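"""Closed-form thermodynamics of the two-state frameshifting model.

If the paused ribosome equilibrates between the 0-frame and the −1-frame,
the frameshifting efficiency is the Boltzmann occupancy of the −1 frame,

    FS = exp(−ΔG/kT) / (1 + exp(−ΔG/kT)),   ΔG = G(−1) − G(0),

a logistic function of the total free-energy difference ΔG, which itself is
the sum of per-base-pair contributions selected by the signed design matrix.
The kinetic extension models incomplete equilibration within the translocation
pause: FS_kinetic = FS·(1−κ) with κ = exp(−C·[1 + exp(ΔG/kT)]), where C lumps
attempt frequency, pause duration and barrier height into a single parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

__all__ = [
    "GAS_CONSTANT_KJ",
    "ThermoConstants",
    "DEFAULT_CONSTANTS",
    "fs_from_dg",
    "dg_from_fs",
    "total_dg",
    "kappa_of_c",
    "fs_kinetic",
    "solve_c_for_mean_kappa",
]

#: Molar gas constant, kJ mol^-1 K^-1.  The model's free energies are molar,
#: so k_B·T is realised as R·T.
GAS_CONSTANT_KJ = 8.314e-3


@dataclass(frozen=True)
class ThermoConstants:
    """Temperature and the thermal energy scale kT (kJ/mol)."""

    temperature: float = 310.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")

    @property
    def kT(self) -> float:
        return GAS_CONSTANT_KJ * self.temperature


#: 310 K physiological default; kT = 2.5773 kJ/mol.
DEFAULT_CONSTANTS = ThermoConstants()


def fs_from_dg(dg, constants: ThermoConstants = DEFAULT_CONSTANTS):
    """Equilibrium frameshifting efficiency for total ΔG (kJ/mol).

    Evaluated as the logistic 1/(1 + exp(ΔG/kT)), which is overflow-safe for
    |ΔG| ≫ kT; strictly decreasing in ΔG with range (0, 1).
    """
    return expit(-np.asarray(dg, dtype=float) / constants.kT)


def dg_from_fs(fs, constants: ThermoConstants = DEFAULT_CONSTANTS):
    """Total ΔG (kJ/mol) from an efficiency: −kT·ln(FS/(1−FS)).

    Exact inverse of :func:`fs_from_dg` on (0, 1).  FS of exactly 0 or 1 only
    bounds ΔG (from below/above) and raises.
    """
    fs = np.asarray(fs, dtype=float)
    if np.any((fs <= 0.0) | (fs >= 1.0)):
        raise ValueError(
            "FS must lie strictly inside (0, 1); FS = 0 or 1 only bounds ΔG "
            "(|ΔG| exceeds any finite value consistent with the data)"
        )
    out = -constants.kT * logit(fs)
    return out if out.shape else float(out)


def total_dg(row, dg_bp) -> float:
    """Total ΔG of one variant: signed sum Σ_j M_ij · ΔG_bp,j."""
    row = np.asarray(row, dtype=float)
    dg_bp = np.asarray(dg_bp, dtype=float)
    if row.shape != dg_bp.shape:
        raise ValueError(
            f"design row length {row.shape} != variable vector length {dg_bp.shape}"
        )
    return float(row @ dg_bp)


def _one_plus_exp(dg_over_kt):
    # clip keeps exp finite; beyond ~700 kappa underflows to 0 anyway
    return 1.0 + np.exp(np.clip(dg_over_kt, -745.0, 709.0))


def kappa_of_c(big_c, dg, constants: ThermoConstants = DEFAULT_CONSTANTS):
    """Kinetic factor κ = exp(−C·[1 + exp(ΔG/kT)]).

    κ(C=0) = 1 (no equilibration at all within the window), κ→0 as C→∞
    (full equilibration); strictly decreasing in both C and ΔG.
    """
    big_c = np.asarray(big_c, dtype=float)
    if np.any(big_c < 0):
        raise ValueError("C must be nonnegative")
    a = _one_plus_exp(np.asarray(dg, dtype=float) / constants.kT)
    out = np.exp(-big_c * a)
    return out if out.shape else float(out)


def fs_kinetic(fs, kappa):
    """FS corrected for incomplete equilibration: FS·(1−κ)."""
    kappa = np.asarray(kappa, dtype=float)
    if np.any((kappa < 0) | (kappa > 1)):
        raise ValueError("kappa must lie in [0, 1]")
    out = np.asarray(fs, dtype=float) * (1.0 - kappa)
    return out if out.shape else float(out)


def solve_c_for_mean_kappa(
    mean_kappa: float,
    dg_vector,
    constants: ThermoConstants = DEFAULT_CONSTANTS,
) -> float:
    """Invert the mean kinetic factor: find C with mean_i κ(C, ΔG_i) = κ̄.

    The mean is strictly decreasing in C from 1 (C=0) towards 0, so the root
    is unique; it is bracketed in log C and found by Brent's method.
    κ̄ = 0 or 1 is degenerate (C = ∞ or 0) and raises.
    """
    if not 0.0 < mean_kappa < 1.0:
        raise ValueError(
            "mean kappa must lie strictly in (0, 1); 0 and 1 correspond to the "
            "degenerate limits C = infinity and C = 0"
        )
    a = _one_plus_exp(np.asarray(dg_vector, dtype=float) / constants.kT)

    def gap(log_c: float) -> float:
        return float(np.mean(np.exp(-np.exp(log_c) * a))) - mean_kappa

    lo, hi = -50.0, 10.0
    while gap(lo) < 0.0 and lo > -700.0:
        lo -= 50.0
    while gap(hi) > 0.0 and hi < 700.0:
        hi += 50.0
    log_c = brentq(gap, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    return float(np.exp(log_c))
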