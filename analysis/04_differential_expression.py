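#!/usr/bin/env python
"""Time-course differential expression in both species compartments.

Simulates the planted two-species count experiment (antibody vs vehicle
at 4 h, 8 h, 168 h; host responds twice as broadly as the graft) and
runs the NB exact-test pipeline per compartment and time point. The
expected picture: many significant genes at 4 h and 8 h under the
effector-competent IgG1 antibody, none by 168 h, essentially none under
the effector-silent IgG4 variant, and roughly twice as many mouse as
human DE genes. Writes per-contrast summaries and full tables under
results/diffexp/.
"""

from pathlib import Path

import pandas as pd

from xenorna.deseq import run_differential
from xenorna.sim.counts import DesignConfig, simulate_count_experiment

OUT = Path(__file__).parents[1] / "results" / "diffexp"
SEED = 2


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    exp = simulate_count_experiment(DesignConfig(n_genes=1500, n_replicates=5, seed=SEED))
    rows = []
    for species in ("human", "mouse"):
        counts = exp.counts[species]
        for compound in ("antibody_IgG1", "antibody_IgG4"):
            for time in ("4h", "8h", "168h"):
                sheet = exp.samples[
                    (exp.samples["time"] == time)
                    & exp.samples["compound"].isin(["vehicle", compound])
                ]
                res = run_differential(
                    counts[sheet["sample"]], list(sheet["compound"]),
                    ("vehicle", compound), alpha_adj=0.1,
                )
                truth = exp.truth_de[species][(compound, time)]
                called = set(res.index[res["padj"] < 0.1])
                rows.append(
                    {"species": species, "compound": compound, "time": time,
                     "n_significant": len(called), "n_planted": len(truth),
                     "n_recovered": len(called & truth)}
                )
                res.to_csv(OUT / f"de_{species}_{compound}_{time}.tsv", sep="\t")
    summary = pd.DataFrame(rows)
    summary.to_csv(OUT / "summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    igg1_8h = summary[(summary["compound"] == "antibody_IgG1") & (summary["time"] == "8h")]
    n_h = int(igg1_8h.loc[igg1_8h["species"] == "human", "n_significant"].iloc[0])
    n_m = int(igg1_8h.loc[igg1_8h["species"] == "mouse", "n_significant"].iloc[0])
    print(f"\nmouse/human DE ratio at 8h (IgG1): {n_m / n_h:.2f} (planted 2.0)")


if __name__ == "__main__":
    main()
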