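#!/usr/bin/env python
"""Convenience plot: mean event-probability trajectories by arm.

Draws the marginal probability of an event at each visit for the two
design prevalences (0.1 solid, 0.5 dashed), control flat and treatment
rising by 0.05 per visit.

Usage: python scripts/plot_trajectories.py [--out trajectories.png]
"""

import argparse

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from longbinrct import ScenarioConfig, generate_complete_replicate


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", default="trajectories.png")
    parser.add_argument("--rho", type=float, default=0.3)
    args = parser.parse_args()

    fig, ax = plt.subplots(figsize=(6, 4))
    for prevalence, style in ((0.1, "-"), (0.5, "--")):
        cfg = ScenarioConfig(prevalence=prevalence, rho=args.rho,
                             n_total=100_000, n_reps=1, seed=0)
        df = generate_complete_replicate(cfg, cfg.beta_params,
                                         np.random.default_rng(0))
        means = df.groupby(["arm", "visit"])["y"].mean()
        for arm, label in ((1, "treatment"), (0, "control")):
            ax.plot([1, 2, 3], means[arm], style, marker="o",
                    label=f"p={prevalence}, {label}")
    ax.set_xlabel("visit")
    ax.set_ylabel("Pr(event)")
    ax.set_xticks([1, 2, 3])
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(args.out, dpi=150)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
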