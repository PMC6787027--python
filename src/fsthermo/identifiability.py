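"""Identifiability analysis of the base-pair free-energy posterior.

Variables that only ever occur together in the design are not individually
determined: their marginals spread over the whole prior box while a linear
combination (in this design, a sum) is sharply determined.  Such couplings
show up as strong correlations between posterior sample series.  Following
the pin-to-zero convention, one representative of each coupled group is fixed
at 0 kJ/mol and the fit repeated; the remaining members' marginals then equal
the determined combinations ("pinned + variable").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .catalog import DesignMatrix
from .inference import (
    ChainSamples,
    FitConfig,
    PosteriorSummary,
    pooled_samples,
    run_chains,
    summarize,
)

__all__ = [
    "DeterminedCombination",
    "IdentifiabilityReport",
    "SD_THRESHOLD_KJ",
    "STRONG_CORRELATION",
    "flag_underdetermined",
    "sample_correlations",
    "pin_and_refit",
    "iterative_pinning",
    "site_comparison",
]

#: Posterior σ above this (kJ/mol) marks a variable as underdetermined.
#: Determined variables in practice have sub-kJ/mol σ while prior-scale σ is
#: ≈ 50/sqrt(12) ≈ 14 kJ/mol, so any threshold in 2–8 separates the two.
SD_THRESHOLD_KJ = 2.0

#: |Pearson r| at or above this counts as strong coupling.
STRONG_CORRELATION = 0.9


@dataclass
class DeterminedCombination:
    """A determined sum of variables, reported as pinned representative + member."""

    pinned: str
    member: str
    mean: float
    sd: float

    @property
    def label(self) -> str:
        return f"{self.pinned} + {self.member}"


@dataclass
class IdentifiabilityReport:
    variable_labels: list[str]
    posterior_sd: np.ndarray
    underdetermined: list[str]
    correlations: np.ndarray
    combinations: list[DeterminedCombination]
    pin_history: list[dict] = field(default_factory=list)
    final_summary: Optional[PosteriorSummary] = None

    def to_dict(self) -> dict:
        return {
            "variables": self.variable_labels,
            "posterior_sd": [float(s) for s in self.posterior_sd],
            "underdetermined": self.underdetermined,
            "correlations": self.correlations.tolist(),
            "combinations": [
                {
                    "label": c.label,
                    "pinned": c.pinned,
                    "member": c.member,
                    "mean": c.mean,
                    "sd": c.sd,
                }
                for c in self.combinations
            ],
            "pin_history": self.pin_history,
        }


def flag_underdetermined(
    summary: PosteriorSummary, sd_threshold: float = SD_THRESHOLD_KJ
) -> list[str]:
    """Labels whose posterior σ exceeds the threshold."""
    if not summary.variable_labels:
        raise ValueError("empty posterior summary")
    return [
        lab
        for lab, sd in zip(summary.variable_labels, summary.sd)
        if sd > sd_threshold
    ]


def sample_correlations(
    chains: Sequence[ChainSamples], burn_in_fraction: float = 0.2
) -> np.ndarray:
    """Pearson correlation matrix of the pooled post-burn-in sample series.

    Zero-variance series (pinned variables) get correlation 0 off-diagonal,
    with a warning, and 1 on the diagonal.
    """
    x = pooled_samples(chains, burn_in_fraction)
    sd = x.std(axis=0)
    degenerate = sd == 0.0
    if degenerate.any():
        warnings.warn(
            "zero-variance sample series; correlations involving them set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr = np.atleast_2d(corr)
    corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr


def _coupling_counts(
    corr: np.ndarray, labels: list[str], candidates: list[str]
) -> dict[str, tuple[int, int]]:
    """Per candidate: (# strong anticorrelations, # strong couplings) within the set."""
    idx = {lab: labels.index(lab) for lab in candidates}
    out = {}
    for lab in candidates:
        i = idx[lab]
        anti = strong = 0
        for other in candidates:
            if other == lab:
                continue
            r = corr[i, idx[other]]
            if r <= -STRONG_CORRELATION:
                anti += 1
            if abs(r) >= STRONG_CORRELATION:
                strong += 1
        out[lab] = (anti, strong)
    return out


def _choose_representative(
    corr: np.ndarray, labels: list[str], candidates: list[str]
) -> str:
    """Representative to pin: the sum-shared variable.

    The shared term of k sum-constraints is anticorrelated with each of its k
    partners, so the candidate with the most strong anticorrelations is pinned;
    ties fall back to total strong couplings, then lexicographic order.
    """
    counts = _coupling_counts(corr, labels, candidates)
    return min(candidates, key=lambda lab: (-counts[lab][0], -counts[lab][1], lab))


def pin_and_refit(
    fs_exp,
    sigma_exp,
    design: DesignMatrix,
    pin_labels: Sequence[str],
    config: FitConfig,
    baseline: Optional[PosteriorSummary] = None,
    sd_threshold: float = SD_THRESHOLD_KJ,
) -> tuple[list[ChainSamples], list[DeterminedCombination], PosteriorSummary]:
    """Re-fit with the given variables fixed at 0 kJ/mol.

    The design matrix is unchanged; only the sampler's free-variable set
    shrinks.  Variables that are design-coupled to a pinned representative and
    come out with small σ are reported as determined combinations
    ``pinned + variable`` (their marginal now equals the combination's value).
    When a ``baseline`` (unpinned) summary is supplied, only variables that
    were underdetermined there are reported.
    """
    missing = set(pin_labels) - set(design.col_labels)
    if missing:
        raise ValueError(f"pin labels not in design: {sorted(missing)}")
    if baseline is not None:
        already = set(pin_labels) - set(flag_underdetermined(baseline, sd_threshold))
        if already:
            warnings.warn(
                f"pinning already-determined variable(s): {sorted(already)}",
                stacklevel=2,
            )
    cfg = replace(
        config, pinned_variables=config.pinned_variables | frozenset(pin_labels)
    )
    chains = run_chains(fs_exp, sigma_exp, design, cfg)
    summary = summarize(chains, cfg)

    prev_under = (
        set(flag_underdetermined(baseline, sd_threshold))
        if baseline is not None
        else set(design.col_labels)
    )
    combos: list[DeterminedCombination] = []
    m = design.entries
    col = {lab: j for j, lab in enumerate(design.col_labels)}
    for pin in pin_labels:
        jp = col[pin]
        coupled_rows = m[:, jp] != 0
        for lab, mean, sd in zip(summary.variable_labels, summary.mean, summary.sd):
            if lab in cfg.pinned_variables or lab not in prev_under:
                continue
            jv = col[lab]
            if sd <= sd_threshold and np.any(coupled_rows & (m[:, jv] != 0)):
                combos.append(DeterminedCombination(pin, lab, float(mean), float(sd)))
    return chains, combos, summary


def iterative_pinning(
    fs_exp,
    sigma_exp,
    design: DesignMatrix,
    config: FitConfig,
    sd_threshold: float = SD_THRESHOLD_KJ,
) -> IdentifiabilityReport:
    """Iterative pin-to-zero protocol.

    Step 1 fits all variables.  Each later step pins (alone) one variable that
    has had large σ in every previous step — chosen as the most anticorrelated
    member of the strong-coupling graph — and records which variables become
    determined.  The final step pins all chosen representatives simultaneously.
    """
    chains = run_chains(fs_exp, sigma_exp, design, config)
    base_summary = summarize(chains, config)
    corr = sample_correlations(chains, config.burn_in_fraction)
    under = flag_underdetermined(base_summary, sd_threshold)
    labels = list(design.col_labels)

    history = [
        {
            "step": 1,
            "pinned": [],
            "determined": [
                lab for lab in labels if lab not in under
            ],
            "underdetermined": list(under),
        }
    ]

    reps: list[str] = []
    combos: list[DeterminedCombination] = []
    persistent = list(under)  # large sigma in all previous steps
    step = 1
    max_steps = design.n_variables
    while persistent and step <= max_steps:
        step += 1
        rep = _choose_representative(corr, labels, persistent)
        reps.append(rep)
        _, new_combos, step_summary = pin_and_refit(
            fs_exp,
            sigma_exp,
            design,
            [rep],
            config,
            baseline=base_summary,
            sd_threshold=sd_threshold,
        )
        combos.extend(new_combos)
        step_under = set(flag_underdetermined(step_summary, sd_threshold))
        newly_determined = [
            lab for lab in persistent if lab != rep and lab not in step_under
        ]
        history.append(
            {
                "step": step,
                "pinned": [rep],
                "determined": newly_determined,
                "underdetermined": sorted(step_under),
            }
        )
        persistent = [
            lab for lab in persistent if lab != rep and lab in step_under
        ]

    final_summary = base_summary
    if reps:
        _, _, final_summary = pin_and_refit(
            fs_exp,
            sigma_exp,
            design,
            reps,
            config,
            baseline=base_summary,
            sd_threshold=sd_threshold,
        )
        history.append(
            {
                "step": step + 1,
                "pinned": list(reps),
                "determined": sorted(
                    set(final_summary.variable_labels)
                    - set(flag_underdetermined(final_summary, sd_threshold))
                    - set(reps)
                ),
                "underdetermined": flag_underdetermined(final_summary, sd_threshold),
            }
        )

    # deduplicate combinations, keep first occurrence per member
    seen = set()
    unique_combos = []
    for c in combos:
        if c.member not in seen:
            unique_combos.append(c)
            seen.add(c.member)

    return IdentifiabilityReport(
        variable_labels=labels,
        posterior_sd=base_summary.sd,
        underdetermined=under,
        correlations=corr,
        combinations=unique_combos,
        pin_history=history,
        final_summary=final_summary,
    )


#: Site-comparison recipe: first-position mismatch free-energy differences that
#: are not directly observable but follow from differences of observed (or
#: sum-determined) variables, assuming A·U and U·A pairs are isoenergetic.
#: Each entry: derived change -> (site, minuend labels, subtrahend labels);
#: label lists are summed per posterior sample before subtracting, so shared
#: (underdetermined) terms cancel exactly.
SITE_COMPARISON_RECIPE = {
    ("C·A→C·U", "P"): (["P1 A·U→C·U"], ["P1 U·A→C·A"]),
    ("C·A→C·U", "A"): (
        ["P3 C·G→U·G", "A1 A·U→C·U"],
        ["P3 C·G→U·G", "A1 U·A→C·A"],
    ),
    ("G·A→G·U", "P"): (["P1 A·U→G·U"], ["P1 U·A→G·A"]),
    ("G·A→G·U", "A"): (
        ["P3 G·S→A·S", "A1 A·U→G·U"],
        ["P3 G·S→A·S", "A1 U·A→G·A"],
    ),
}


def site_comparison(
    chains: Sequence[ChainSamples],
    burn_in_fraction: float = 0.2,
    recipe: Optional[dict] = None,
):
    """P-site vs A-site first-position mismatch penalties derived per sample.

    Returns a DataFrame with one row per (change, site): mean ± sd of the
    sampled difference.  Underdetermined shared terms cancel within each
    sample, so the derived differences are determined even when the individual
    marginals are prior-wide.
    """
    import pandas as pd

    recipe = SITE_COMPARISON_RECIPE if recipe is None else recipe
    x = pooled_samples(chains, burn_in_fraction)
    labels = list(chains[0].variable_labels)
    col = {lab: j for j, lab in enumerate(labels)}
    rows = []
    for (change, site), (minuend, subtrahend) in recipe.items():
        for lab in [*minuend, *subtrahend]:
            if lab not in col:
                raise KeyError(f"site comparison needs variable {lab!r} in posterior")
        diff = x[:, [col[lab] for lab in minuend]].sum(axis=1) - x[
            :, [col[lab] for lab in subtrahend]
        ].sum(axis=1)
        rows.append(
            {
                "change": change,
                "site": site,
                "mean": float(diff.mean()),
                "sd": float(diff.std(ddof=0)),
            }
        )
    return pd.DataFrame(rows)
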