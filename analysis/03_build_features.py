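#!/usr/bin/env python
"""Build confounder feature matrices: expert-defined + full EHR.

Constructs the expert feature set (utilization, normalized MS code
frequencies, corticosteroid/MRI/hospitalization/emergency procedure
frequencies, prior DMT and relapse history, demographics) and the
high-dimensional full-EHR counts (PheCode rollups, CPT groups with MRI
exceptions, positive CUI mentions) over pre-treatment windows, then
applies the <10% sparsity filter and BH-FDR marginal screening at q=0.1.

Writes results/<comparison>/features*.csv and screen.json.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from msdr.features import marginal_screen, sparsity_filter
from msdr.pipeline import build_features, save_feature_matrix

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--q", type=float, default=0.1)
    args = parser.parse_args()

    for name in ("standard", "higher"):
        data = ROOT / "data" / "synth" / name
        out = ROOT / "results" / name
        cohort = pd.read_csv(out / "cohort.csv")
        tables = {
            t: pd.read_csv(data / f"{t}.csv")
            for t in ("patients", "events", "episodes", "relapses")
        }
        kept = tables["patients"][
            tables["patients"]["patient_id"].isin(cohort["patient_id"])
        ]
        fm = build_features(
            kept, tables["events"], tables["relapses"], tables["episodes"]
        )
        n_expert, n_full = len(fm.expert_columns), len(fm.full_columns)
        fm = sparsity_filter(fm, 0.10)
        n_after_sparsity = len(fm.full_columns)
        labels = (
            cohort.set_index("patient_id")["relapse_2y"]
            .reindex(fm.data.index).fillna(0).astype(int)
        )
        screen = marginal_screen(fm, labels.to_numpy(), q=args.q)
        fm = fm.select(screen.retained)
        save_feature_matrix(fm, out, stem="features_screened")
        (out / "screen.json").write_text(json.dumps(
            {"q": args.q, "retained": screen.retained}, indent=2))
        print(f"[{name}] {n_expert} expert + {n_full} full-EHR features; "
              f"{n_after_sparsity} full-EHR past the sparsity filter; "
              f"{len(fm.full_columns)} screened in at q={args.q} "
              f"(total {fm.data.shape[1]} confounders)")


if __name__ == "__main__":
    main()
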