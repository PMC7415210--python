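"""Between-group and brain-behavior statistics.

Edgewise GLM (FC ~ group + age + sex) with BH-FDR per state on the
participant-specific median state FC; covariate-adjusted Mann-Whitney
tests with FDR over the temporal-property family; regionwise GLM with
FDR for temporal variability; ROC on the median strength of each
state's significant edges; and partial correlations (age, sex
controlled) between dFC indicators and MMSE/NPI in the patient group.
Writes the stats tables under results/stats/ and prints a summary.

Run after 03:  python analysis/04_group_statistics.py
"""

from pathlib import Path

import json
import pandas as pd

from dynfc import pipeline, stats
from dynfc.windows import WindowParams

COHORT = Path("results/cohort")
OUT = Path("results/stats")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    windows, manifest = pipeline.load_cohort(COHORT, WindowParams())
    import importlib.util

    spec = importlib.util.spec_from_file_location(
        "detect", Path(__file__).parent / "03_temporal_properties.py"
    )
    mod = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(mod)
    model = mod.load_model(windows)

    state_fc = pipeline.compute_state_fc(windows, model)
    edge_tables = {}
    for s in range(1, model.k + 1):
        tab = stats.edgewise_glm(state_fc, manifest, s)
        edge_tables[s] = tab
        if tab is not None:
            tab.to_csv(OUT / f"edges_state{s}.tsv", sep="\t", index=False,
                       float_format="%.10g")
            n_sig = int(tab["significant"].sum())
            print(f"state {s}: {n_sig} FDR-significant edges "
                  f"of {len(tab)} tested")

    props = pipeline.compute_temporal_properties(model, manifest)
    ttests = pipeline.temporal_property_tests(props)
    ttests.to_csv(OUT / "temporal_stats.tsv", sep="\t", index=False,
                  float_format="%.10g")
    sig_props = ttests.loc[ttests["significant"], "property"].tolist()
    print("significant temporal properties:", sig_props or "none")

    vtab, _ = pipeline.variability_table(windows, manifest)
    vstats = pipeline.variability_statistics(vtab)
    vstats.to_csv(OUT / "variability_stats.tsv", sep="\t", index=False,
                  float_format="%.10g")
    print(f"regions with significant variability difference: "
          f"{int(vstats['significant'].sum())} of {len(vstats)}")

    roc, roc_scores = pipeline.roc_analysis(state_fc, edge_tables, manifest)
    with open(OUT / "roc.json", "w") as fh:
        json.dump(roc, fh, indent=1, default=float)
    for name, entry in roc.items():
        print(f"ROC {name}: AUC {entry['auc']:.3f} "
              f"({entry['n_edges']} edges, {entry['n_participants']} participants)")

    pcorr = pipeline.clinical_partial_correlations(
        props, vtab, vstats, roc_scores, manifest
    )
    pcorr.to_csv(OUT / "partialcorr.tsv", sep="\t", index=False,
                 float_format="%.10g")
    sig = pcorr[pcorr["p"] < 0.05]
    print(f"clinical partial correlations with p < 0.05: {len(sig)}")
    if len(sig):
        print(sig.to_string(index=False))

    demo = stats.demographics_table(manifest)
    demo.to_csv(OUT / "demographics.tsv", sep="\t", index=False,
                float_format="%.10g")


if __name__ == "__main__":
    main()
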