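"""Posterior-predictive checks: FS distributions, rmsd, convergence, LOO.

The posterior over ΔG_bp induces, through the additive model and the Boltzmann
relation, a distribution of model frameshifting efficiencies per variant.
Agreement with the measurements is summarised as the root-mean-square
deviation (in percentage points) between mean model FS and measured FS.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from .catalog import DesignMatrix
from .inference import (
    ChainSamples,
    FitConfig,
    pooled_kappa,
    pooled_samples,
    run_chains,
)
from .thermo import DEFAULT_CONSTANTS, ThermoConstants, _one_plus_exp, solve_c_for_mean_kappa

__all__ = [
    "PredictionResult",
    "predict_fs",
    "rmsd",
    "convergence_curve",
    "loo_crossvalidate",
]


@dataclass
class PredictionResult:
    variant_ids: list[str]
    fs_mean: np.ndarray
    fs_sd: np.ndarray
    fs_samples: Optional[np.ndarray] = None  # (S, N) when retained
    rmsd_pp: Optional[float] = None

    def to_frame(self, fs_measured=None):
        import pandas as pd

        data = {
            "variant_id": self.variant_ids,
            "fs_model_mean": self.fs_mean,
            "fs_model_sd": self.fs_sd,
        }
        if fs_measured is not None:
            data["fs_measured"] = np.asarray(fs_measured, dtype=float)
        return pd.DataFrame(data)


def _fs_samples(
    dg_samples: np.ndarray,
    entries: np.ndarray,
    kappa_bar_samples: Optional[np.ndarray],
    constants: ThermoConstants,
) -> np.ndarray:
    dg_total = dg_samples @ entries.T  # (S, N)
    fs = expit(-dg_total / constants.kT)
    if kappa_bar_samples is not None:
        a = _one_plus_exp(dg_total / constants.kT)
        for s in range(fs.shape[0]):
            c = solve_c_for_mean_kappa(
                float(kappa_bar_samples[s]), dg_total[s], constants
            )
            fs[s] *= 1.0 - np.exp(-c * a[s])
    return fs


def predict_fs(
    samples: np.ndarray,
    variable_labels: Sequence[str],
    design: DesignMatrix,
    kappa_bar_samples: Optional[np.ndarray] = None,
    fs_measured=None,
    constants: ThermoConstants = DEFAULT_CONSTANTS,
    keep_samples: bool = False,
) -> PredictionResult:
    """Posterior-predictive FS distribution for the design's variants.

    ``samples`` is an (S, n) array of ΔG_bp draws over ``variable_labels``;
    every design column must be present (pinned variables contribute their
    sampled constant 0).  When κ̄ draws are supplied the per-variant kinetic
    factor is recomputed for each sample.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    labels = list(variable_labels)
    missing = [lab for lab in design.col_labels if lab not in labels]
    if missing:
        raise KeyError(f"posterior lacks design variables: {missing}")
    order = [labels.index(lab) for lab in design.col_labels]
    fs = _fs_samples(samples[:, order], design.entries, kappa_bar_samples, constants)
    result = PredictionResult(
        variant_ids=list(design.row_labels),
        fs_mean=fs.mean(axis=0),
        fs_sd=fs.std(axis=0, ddof=0),
        fs_samples=fs if keep_samples else None,
    )
    if fs_measured is not None:
        result.rmsd_pp = rmsd(result.fs_mean, fs_measured)
    return result


def rmsd(fs_model_means, fs_experiment) -> float:
    """Root-mean-square deviation between FS fractions, in percentage points."""
    a = np.asarray(fs_model_means, dtype=float)
    b = np.asarray(fs_experiment, dtype=float)
    if a.shape != b.shape:
        raise ValueError("fs vectors must have equal length")
    return float(100.0 * np.sqrt(np.mean((a - b) ** 2)))


def convergence_curve(
    chain: ChainSamples,
    design: DesignMatrix,
    fs_experiment,
    checkpoints: Sequence[int],
    burn_in_fraction: float = 0.2,
    constants: ThermoConstants = DEFAULT_CONSTANTS,
) -> list[tuple[int, float]]:
    """In-sample rmsd as a function of chain length.

    For each checkpoint N the first 20% of that prefix is discarded, mean
    model FS computed from the remaining draws, and the rmsd against the
    measurements recorded.  Two independent chains plateauing at the same
    value indicate convergence.
    """
    checkpoints = list(checkpoints)
    if any(b <= a for a, b in zip(checkpoints, checkpoints[1:])):
        raise ValueError("checkpoints must be strictly increasing")
    if checkpoints and checkpoints[-1] > chain.n_steps:
        raise ValueError("checkpoint exceeds chain length")
    kappa = chain.kappa_samples
    curve = []
    for n in checkpoints:
        start = int(round(n * burn_in_fraction))
        prefix = chain.dg_samples[start:n]
        kap = None if kappa is None else kappa[start:n]
        pred = predict_fs(
            prefix, chain.variable_labels, design, kappa_bar_samples=kap,
            constants=constants,
        )
        curve.append((n, rmsd(pred.fs_mean, fs_experiment)))
    return curve


def loo_crossvalidate(
    fs_exp,
    sigma_exp,
    design: DesignMatrix,
    config: FitConfig,
    constants: ThermoConstants = DEFAULT_CONSTANTS,
):
    """Leave-one-out cross-validation.

    Each variant is predicted from a fit to all other variants; variables
    unique to the held-out variant stay prior-distributed, so such predictions
    honestly carry prior-wide uncertainty.  Returns (DataFrame, overall rmsd
    in percentage points).
    """
    import pandas as pd

    fs_exp = np.asarray(fs_exp, dtype=float)
    sigma_exp = np.asarray(sigma_exp, dtype=float)
    n = design.n_variants
    if n < 2:
        raise ValueError("need at least two variants for cross-validation")
    rows = []
    for i in range(n):
        keep = [k for k in range(n) if k != i]
        sub = design.subset(keep)
        cfg = replace(config, rng_seed=config.rng_seed + 1000 * i)
        chains = run_chains(fs_exp[keep], sigma_exp[keep], sub, cfg, constants)
        pooled = pooled_samples(chains, cfg.burn_in_fraction)
        kap = pooled_kappa(chains, cfg.burn_in_fraction)
        held = design.subset([i])
        pred = predict_fs(
            pooled,
            chains[0].variable_labels,
            held,
            kappa_bar_samples=kap,
            constants=constants,
        )
        rows.append(
            {
                "variant_id": design.row_labels[i],
                "fs_measured": float(fs_exp[i]),
                "fs_pred_mean": float(pred.fs_mean[0]),
                "fs_pred_sd": float(pred.fs_sd[0]),
            }
        )
    table = pd.DataFrame(rows)
    overall = rmsd(table["fs_pred_mean"].to_numpy(), table["fs_measured"].to_numpy())
    return table, overall
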