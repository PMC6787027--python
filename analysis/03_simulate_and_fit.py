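#!/usr/bin/env python
"""Parameter-recovery study: simulate the 64-variant dataset and re-infer it.

Generates frameshifting efficiencies from the default ground truth (2 pp
replicate noise, equilibrium kinetics), runs the Metropolis-within-Gibbs fit
(two chains), and compares posterior means against the truth.

Finding: the 10 individually identifiable variables and the four
sum-determined P3+A1 combinations are recovered within ~2 posterior sigma;
the in-sample rmsd lands at the injected noise scale (~1.5–2 pp).
"""

import argparse
import json
from pathlib import Path

import numpy as np

import fsthermo as ft
from fsthermo.synthetic import default_invitro_truth, simulate_fs_dataset
from fsthermo.validation import predict_fs

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--steps", type=int, default=50_000)
    parser.add_argument("--seed", type=int, default=11)
    args = parser.parse_args()
    OUT.mkdir(exist_ok=True)

    design, truth = default_invitro_truth(seed=args.seed)
    data = simulate_fs_dataset(design, truth)
    fs, sigma = data["fs"].to_numpy(), data["sigma"].to_numpy()

    config = ft.FitConfig(n_steps=args.steps, n_chains=2, rng_seed=5)
    chains = ft.run_chains(fs, sigma, design, config)
    summary = ft.summarize(chains, config)
    pooled = ft.pooled_samples(chains, config.burn_in_fraction)
    pred = predict_fs(pooled, summary.variable_labels, design, fs_measured=fs)

    recovery = []
    for lab, mean, sd, true in zip(
        summary.variable_labels, summary.mean, summary.sd, truth.dg_bp_true
    ):
        recovery.append(
            {
                "label": lab,
                "truth": float(true),
                "posterior_mean": round(float(mean), 3),
                "posterior_sd": round(float(sd), 3),
                "z": None if sd == 0 else round(float((mean - true) / sd), 2),
            }
        )
        print(
            f"{lab:16s} truth {true:5.1f}  posterior {mean:7.2f} ± {sd:5.2f}"
        )
    print(f"in-sample rmsd: {pred.rmsd_pp:.2f} pp (noise 2 pp)")

    payload = {
        "steps": args.steps,
        "chains": config.n_chains,
        "rmsd_pp": pred.rmsd_pp,
        "recovery": recovery,
    }
    (OUT / "recovery_fit.json").write_text(json.dumps(payload, indent=2) + "\n")


if __name__ == "__main__":
    main()
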