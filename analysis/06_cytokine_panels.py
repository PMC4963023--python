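#!/usr/bin/env python
"""Cytokine panel: Ward clustering and per-analyte factorial models.

Simulates the dual-panel bead assay (29 human / 27 mouse analytes, 22
shared) with an acute host-side response to the IgG1 antibody at 8 h
that resolves by 168 h, clusters samples on the shared analytes with
Ward's method, and fits the species x compound x time factorial model
per analyte. Writes the linkage, leaf order and model table under
results/cytokines/.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster

from xenorna.immunoassay import cytokine_matrix, panel_factorial_models, ward_cluster
from xenorna.sim.cytokines import PanelConfig, simulate_cytokine_table

OUT = Path(__file__).parents[1] / "results" / "cytokines"
SEED = 4


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = simulate_cytokine_table(PanelConfig(n_replicates=4), seed=SEED)
    table.to_csv(OUT / "cytokine_table.csv", index=False)

    mat = cytokine_matrix(table, shared_only=True)
    z, order = ward_cluster(mat, axis="samples")
    pd.DataFrame(z, columns=["left", "right", "height", "size"]).to_csv(
        OUT / "linkage.tsv", sep="\t", index=False
    )
    (OUT / "leaf_order.txt").write_text("\n".join(order) + "\n")
    two = fcluster(z, 2, "maxclust")
    species = np.array([c.split("/")[0] for c in mat.columns])
    pure = all(len(set(two[species == sp])) == 1 for sp in ("human", "mouse"))
    print(f"clustered {mat.shape[1]} samples on {mat.shape[0]} shared analytes; "
          f"top split separates species: {pure}")

    fits = panel_factorial_models(table)
    fits.to_csv(OUT / "factorial_models.tsv", sep="\t", index=False)
    interaction = fits[fits["term"] == "C(compound):C(time)"]
    hits = interaction[interaction["p"] < 0.05 / len(interaction)]
    print(f"analytes with compound x time interaction after Bonferroni: "
          f"{sorted(hits['analyte'])}")
    print("(planted responders are CYT_S01-S06 in mouse, CYT_S01-S03 in human)")


if __name__ == "__main__":
    main()
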