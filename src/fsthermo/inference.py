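"""Bayesian inference of base-pair free-energy differences by Metropolis sampling.

The posterior P(ΔG_bp | FS_experiment) ∝ likelihood × prior is sampled with a
Metropolis-within-Gibbs scheme: each Metropolis step performs one sub-step per
free variable, proposing from a Gaussian centred on the current value
(σ = 0.2 kJ/mol) and accepting with probability min(1, f_new/f_old).  The
likelihood is an independent Gaussian per variant with the replicate standard
deviation of the measured FS; the prior is a uniform box on [−25, 25] kJ/mol
per variable.  In the kinetic variant the mean kinetic factor κ̄ is sampled as
an additional nuisance parameter (uniform prior on [0, 1], Gaussian proposal);
at every likelihood evaluation the lumped rate parameter C is re-solved from κ̄
and the current total ΔG vector, and per-variant κ enters FS·(1−κ).

RNG contract: one ``numpy.random.Generator`` per chain, seeded explicitly.
Every sub-step draws exactly one proposal normal followed by one acceptance
uniform (the uniform is drawn even when the proposal is accepted outright or
rejected by the prior), so runs are bit-reproducible given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from .catalog import DesignMatrix
from .thermo import (
    DEFAULT_CONSTANTS,
    ThermoConstants,
    _one_plus_exp,
    solve_c_for_mean_kappa,
)

__all__ = [
    "FitConfig",
    "ChainSamples",
    "PosteriorSummary",
    "SIGMA_FLOOR",
    "prepare_sigma",
    "log_likelihood",
    "log_prior",
    "metropolis_run",
    "metropolis_run_kinetic",
    "run_chains",
    "summarize",
    "pooled_samples",
]

#: Replicate σ below half a percentage point is under the assay's resolution;
#: zeros would make the Gaussian likelihood singular.
SIGMA_FLOOR = 0.005


@dataclass(frozen=True)
class FitConfig:
    """Sampler settings.

    Defaults mirror the reference protocol: 10^6 Metropolis steps, two
    independent chains, 0.2 kJ/mol proposal width, uniform prior on
    [−25, 25] kJ/mol, 20% burn-in.
    """

    n_steps: int = 1_000_000
    n_chains: int = 2
    proposal_sigma: float = 0.2
    prior_low: float = -25.0
    prior_high: float = 25.0
    burn_in_fraction: float = 0.20
    kinetic_enabled: bool = False
    kappa_proposal_sigma: float = 0.001
    kappa_init: float = 0.01
    pinned_variables: frozenset = frozenset()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not 0.0 <= self.burn_in_fraction < 1.0:
            raise ValueError("burn_in_fraction must lie in [0, 1)")
        if not self.prior_low < self.prior_high:
            raise ValueError("prior_low must be below prior_high")
        object.__setattr__(self, "pinned_variables", frozenset(self.pinned_variables))


@dataclass
class ChainSamples:
    """States recorded after every Metropolis step of one chain."""

    dg_samples: np.ndarray  # (n_steps, n_variables), kJ/mol
    variable_labels: list[str]
    seed: int
    accept_counts: np.ndarray  # per variable, over all steps
    kappa_samples: Optional[np.ndarray] = None  # (n_steps,) when kinetic
    kappa_accepts: int = 0

    @property
    def n_steps(self) -> int:
        return self.dg_samples.shape[0]

    def post_burn_in(self, burn_in_fraction: float) -> np.ndarray:
        start = int(round(self.n_steps * burn_in_fraction))
        return self.dg_samples[start:]

    def kappa_post_burn_in(self, burn_in_fraction: float) -> Optional[np.ndarray]:
        if self.kappa_samples is None:
            return None
        start = int(round(self.n_steps * burn_in_fraction))
        return self.kappa_samples[start:]


@dataclass
class PosteriorSummary:
    variable_labels: list[str]
    mean: np.ndarray
    sd: np.ndarray
    histograms: list[tuple[np.ndarray, np.ndarray]]  # (bin_edges, densities)
    pooled_chains: bool
    kappa_mean: Optional[float] = None
    kappa_sd: Optional[float] = None
    kappa_histogram: Optional[tuple[np.ndarray, np.ndarray]] = None
    n_samples: int = 0

    def __getitem__(self, label: str) -> tuple[float, float]:
        j = self.variable_labels.index(label)
        return float(self.mean[j]), float(self.sd[j])

    def to_dict(self) -> dict:
        out = {
            "pooled_chains": self.pooled_chains,
            "n_samples": self.n_samples,
            "variables": [
                {
                    "label": lab,
                    "mean": float(self.mean[j]),
                    "sd": float(self.sd[j]),
                    "hist_edges": self.histograms[j][0].tolist(),
                    "hist_density": self.histograms[j][1].tolist(),
                }
                for j, lab in enumerate(self.variable_labels)
            ],
        }
        if self.kappa_mean is not None:
            out["kappa_bar"] = {"mean": self.kappa_mean, "sd": self.kappa_sd}
        return out


def prepare_sigma(sigma) -> np.ndarray:
    """Validate replicate σ, flooring values below :data:`SIGMA_FLOOR`."""
    sigma = np.asarray(sigma, dtype=float).copy()
    if np.any(sigma < 0):
        raise ValueError("replicate sigma must be nonnegative")
    low = sigma < SIGMA_FLOOR
    if np.any(low):
        warnings.warn(
            f"{int(low.sum())} replicate sigma value(s) below {SIGMA_FLOOR} "
            f"floored to {SIGMA_FLOOR}",
            stacklevel=2,
        )
        sigma[low] = SIGMA_FLOOR
    return sigma


def log_likelihood(
    fs_exp,
    sigma_exp,
    dg_bp,
    design: DesignMatrix,
    kappa=None,
    constants: ThermoConstants = DEFAULT_CONSTANTS,
) -> float:
    """Gaussian log-likelihood of the measured FS under the model.

    FS_model,i = logistic(−ΔG_i/kT), ΔG_i = Σ_j M_ij ΔG_bp,j, multiplied by
    (1−κ_i) when a kinetic factor is supplied.
    """
    fs_exp = np.asarray(fs_exp, dtype=float)
    sigma_exp = np.asarray(sigma_exp, dtype=float)
    if np.any(sigma_exp <= 0):
        raise ValueError("sigma_exp must be strictly positive")
    dg_bp = np.asarray(dg_bp, dtype=float)
    if fs_exp.shape[0] != design.n_variants or dg_bp.shape[0] != design.n_variables:
        raise ValueError("inconsistent lengths between data, design and variables")
    dg_total = design.entries @ dg_bp
    fs_model = expit(-dg_total / constants.kT)
    if kappa is not None:
        fs_model = fs_model * (1.0 - np.asarray(kappa, dtype=float))
    resid = fs_exp - fs_model
    return float(
        np.sum(-0.5 * np.log(2.0 * np.pi * sigma_exp**2) - resid**2 / (2.0 * sigma_exp**2))
    )


def log_prior(dg_bp, config: FitConfig) -> float:
    """Unnormalised log of the uniform box prior: 0 inside (closed), −inf outside."""
    dg_bp = np.asarray(dg_bp, dtype=float)
    inside = np.all((dg_bp >= config.prior_low) & (dg_bp <= config.prior_high))
    return 0.0 if inside else -np.inf


def _kappa_vector(kappa_bar: float, dg_total, constants: ThermoConstants) -> np.ndarray:
    """Per-variant κ at the C implied by the mean constraint mean(κ) = κ̄."""
    c = solve_c_for_mean_kappa(kappa_bar, dg_total, constants)
    a = _one_plus_exp(np.asarray(dg_total, dtype=float) / constants.kT)
    return np.exp(-c * a)


def _run_chain(
    fs_exp: np.ndarray,
    sigma_exp: np.ndarray,
    design: DesignMatrix,
    config: FitConfig,
    constants: ThermoConstants,
    seed: int,
    kinetic: bool,
) -> ChainSamples:
    m = design.entries.astype(float)
    n_var = design.n_variables
    labels = list(design.col_labels)
    free = [j for j, lab in enumerate(labels) if lab not in config.pinned_variables]
    if not free:
        raise ValueError("no free variables: everything is pinned")
    unknown = config.pinned_variables - set(labels)
    if unknown:
        raise ValueError(f"pinned variables not in design: {sorted(unknown)}")

    kt = constants.kT
    inv_two_var = 1.0 / (2.0 * sigma_exp**2)

    def loglik(dg_total: np.ndarray, kappa_bar: Optional[float]) -> float:
        fs_model = expit(-dg_total / kt)
        if kappa_bar is not None:
            fs_model = fs_model * (1.0 - _kappa_vector(kappa_bar, dg_total, constants))
        resid = fs_exp - fs_model
        # constant normalisation omitted: only ratios enter the acceptance rule
        return float(-np.sum(resid**2 * inv_two_var))

    rng = np.random.default_rng(seed)
    dg = np.zeros(n_var)
    dg_total = m @ dg
    kappa_bar: Optional[float] = config.kappa_init if kinetic else None
    ll = loglik(dg_total, kappa_bar)

    samples = np.empty((config.n_steps, n_var))
    kappa_samples = np.empty(config.n_steps) if kinetic else None
    accept_counts = np.zeros(n_var, dtype=int)
    kappa_accepts = 0
    cols = {j: m[:, j] for j in free}

    for step in range(config.n_steps):
        for j in free:
            prop = dg[j] + rng.normal(0.0, config.proposal_sigma)
            u = rng.uniform()
            if not (config.prior_low <= prop <= config.prior_high):
                continue  # rejected through the -inf prior
            dg_total_new = dg_total + cols[j] * (prop - dg[j])
            ll_new = loglik(dg_total_new, kappa_bar)
            if ll_new >= ll or np.log(u) <= ll_new - ll:
                dg[j] = prop
                dg_total = dg_total_new
                ll = ll_new
                accept_counts[j] += 1
        if kinetic:
            prop_k = kappa_bar + rng.normal(0.0, config.kappa_proposal_sigma)
            u = rng.uniform()
            if 0.0 < prop_k < 1.0:  # uniform prior on [0,1]; endpoints degenerate
                ll_new = loglik(dg_total, prop_k)
                if ll_new >= ll or np.log(u) <= ll_new - ll:
                    kappa_bar = prop_k
                    ll = ll_new
                    kappa_accepts += 1
            kappa_samples[step] = kappa_bar
        samples[step] = dg

    return ChainSamples(
        dg_samples=samples,
        variable_labels=labels,
        seed=seed,
        accept_counts=accept_counts,
        kappa_samples=kappa_samples,
        kappa_accepts=kappa_accepts,
    )


def metropolis_run(
    fs_exp,
    sigma_exp,
    design: DesignMatrix,
    config: FitConfig,
    constants: ThermoConstants = DEFAULT_CONSTANTS,
    seed: Optional[int] = None,
) -> ChainSamples:
    """One Metropolis-within-Gibbs chain over the free ΔG_bp variables."""
    fs_exp = np.asarray(fs_exp, dtype=float)
    sigma_exp = prepare_sigma(sigma_exp)
    return _run_chain(
        fs_exp,
        sigma_exp,
        design,
        config,
        constants,
        config.rng_seed if seed is None else seed,
        kinetic=False,
    )


def metropolis_run_kinetic(
    fs_exp,
    sigma_exp,
    design: DesignMatrix,
    config: FitConfig,
    constants: ThermoConstants = DEFAULT_CONSTANTS,
    seed: Optional[int] = None,
) -> ChainSamples:
    """As :func:`metropolis_run`, with the mean kinetic factor κ̄ as nuisance."""
    if not config.kinetic_enabled:
        raise ValueError("config.kinetic_enabled must be set for the kinetic run")
    fs_exp = np.asarray(fs_exp, dtype=float)
    sigma_exp = prepare_sigma(sigma_exp)
    return _run_chain(
        fs_exp,
        sigma_exp,
        design,
        config,
        constants,
        config.rng_seed if seed is None else seed,
        kinetic=True,
    )


def run_chains(
    fs_exp,
    sigma_exp,
    design: DesignMatrix,
    config: FitConfig,
    constants: ThermoConstants = DEFAULT_CONSTANTS,
) -> list[ChainSamples]:
    """``n_chains`` independent chains seeded ``rng_seed, rng_seed+1, ...``."""
    runner = metropolis_run_kinetic if config.kinetic_enabled else metropolis_run
    return [
        runner(fs_exp, sigma_exp, design, config, constants, seed=config.rng_seed + k)
        for k in range(config.n_chains)
    ]


def pooled_samples(
    chains: Sequence[ChainSamples], burn_in_fraction: float
) -> np.ndarray:
    """Post-burn-in ΔG_bp draws pooled across chains, shape (S, n_variables)."""
    if not chains:
        raise ValueError("at least one chain is required")
    return np.concatenate([c.post_burn_in(burn_in_fraction) for c in chains], axis=0)


def pooled_kappa(
    chains: Sequence[ChainSamples], burn_in_fraction: float
) -> Optional[np.ndarray]:
    parts = [c.kappa_post_burn_in(burn_in_fraction) for c in chains]
    if any(p is None for p in parts):
        return None
    return np.concatenate(parts)


def _histogram(x: np.ndarray, bins: int = 100) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = float(np.min(x)), float(np.max(x))
    if lo == hi:  # degenerate (e.g. pinned) variable: one unit-mass bin
        lo, hi = lo - 0.5, hi + 0.5
        bins = 1
    density, edges = np.histogram(x, bins=bins, range=(lo, hi), density=True)
    return edges, density


def summarize(
    chains: Sequence[ChainSamples],
    config: FitConfig,
    bins: int = 100,
) -> PosteriorSummary:
    """Pooled posterior means, standard deviations and histograms after burn-in."""
    pooled = pooled_samples(chains, config.burn_in_fraction)
    if pooled.shape[0] == 0:
        raise ValueError("no samples remain after burn-in")
    labels = list(chains[0].variable_labels)
    mean = pooled.mean(axis=0)
    sd = pooled.std(axis=0, ddof=0)
    hists = [_histogram(pooled[:, j], bins) for j in range(pooled.shape[1])]
    kap = pooled_kappa(chains, config.burn_in_fraction)
    return PosteriorSummary(
        variable_labels=labels,
        mean=mean,
        sd=sd,
        histograms=hists,
        pooled_chains=len(chains) > 1,
        kappa_mean=None if kap is None else float(kap.mean()),
        kappa_sd=None if kap is None else float(kap.std(ddof=0)),
        kappa_histogram=None if kap is None else _histogram(kap, bins),
        n_samples=pooled.shape[0],
    )
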