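#!/usr/bin/env python
"""Plot crude KM vs DR-adjusted cumulative relapse incidence per arm.

Reads results/<comparison>/curves.csv from the estimation step and
writes results/figures/incidence_<comparison>.png (two panels: crude
Kaplan-Meier and DR-adjusted g-computation curves).
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

ROOT = Path(__file__).resolve().parents[1]

ARMS = {
    "standard": {0: "dimethyl fumarate", 1: "fingolimod"},
    "higher": {0: "rituximab", 1: "natalizumab"},
}


def main() -> None:
    argparse.ArgumentParser(description=__doc__).parse_args()
    figdir = ROOT / "results" / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    for name in ("standard", "higher"):
        curves = pd.read_csv(ROOT / "results" / name / "curves.csv")
        fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
        for ax, kind, title in zip(
            axes, ("crude_km", "dr_adjusted"),
            ("Crude (Kaplan-Meier)", "DR-adjusted"),
        ):
            sub = curves[curves["kind"] == kind]
            for arm, label in ARMS[name].items():
                c = sub[sub["arm"] == arm].sort_values("time")
                ax.step(c["time"], c["incidence"], where="post", label=label)
            ax.set_xlim(0, 730)
            ax.set_xlabel("days since treatment initiation")
            ax.set_title(title)
        axes[0].set_ylabel("cumulative relapse incidence")
        axes[0].legend()
        fig.tight_layout()
        path = figdir / f"incidence_{name}.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        print(f"[{name}] wrote {path}")


if __name__ == "__main__":
    main()
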