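"""State temporal properties and nodal temporal variability.

From the window labels of 02: per-participant dwell times (occupancy),
transition counts and transition-frequency distributions, plus the
nodal temporal variability V_k of every region over all 126 windows.
Writes results/temporal_properties.csv and results/variability.csv and
prints the group means.

Run after 02:  python analysis/03_temporal_properties.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from dynfc import pipeline
from dynfc.clustering import StateModel
from dynfc.windows import WindowParams

COHORT = Path("results/cohort")
STATES = Path("results/states")
OUT = Path("results")


def load_model(windows) -> StateModel:
    labels = pd.read_csv(STATES / "labels.csv")
    k = int(labels["state"].max())
    cent = np.vstack(
        [np.loadtxt(STATES / f"centroid_state{s + 1}.tsv") for s in range(k)]
    )
    by_pid = {
        pid: grp.sort_values("window_index")["state"].to_numpy()
        for pid, grp in labels.groupby("participant")
    }
    return StateModel(centroids=cent, labels=by_pid, cost=np.nan, n_iter=0)


def main() -> None:
    windows, manifest = pipeline.load_cohort(COHORT, WindowParams())
    model = load_model(windows)

    props = pipeline.compute_temporal_properties(model, manifest)
    props.to_csv(OUT / "temporal_properties.csv", index=False, float_format="%.10g")
    print("group mean dwell times (windows):")
    for g, grp in props.groupby("group"):
        dwell = {s: round(float(grp[f"dwell_{s}"].mean()), 1)
                 for s in range(1, model.k + 1)}
        print(f"  {g}: {dwell}, transitions {grp['transitions'].mean():.2f}")

    vtab, masks = pipeline.variability_table(windows, manifest)
    vtab.to_csv(OUT / "variability.csv", index=False, float_format="%.10g")
    regions = [c for c in vtab.columns if c.startswith("R")]
    for g, grp in vtab.groupby("group"):
        print(f"  {g}: mean V over regions {np.nanmean(grp[regions].to_numpy()):.3f}")


if __name__ == "__main__":
    main()
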