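"""Multiplex cytokine panel simulation.

Emulates a dual-panel bead assay on xenograft lysates: a human panel of
29 analytes and a mouse panel of 27, with 22 analytes covered by both
under the same name. Every lysate (compound x time x replicate) is
measured with both panels. Planted responders are elevated at 8 h after
treatment and back at their baseline by 168 h, mirroring an acute
cytokine release that decays to control levels. Concentrations are
log-normal around the analyte baseline; values below the detection
limit can be censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: (analyte, species, compound) -> log10 elevation at 8h; default plants an
#: acute host (mouse) response to the effector-competent antibody plus a
#: smaller graft-side response, all resolved by 168h.
DEFAULT_RESPONDERS: dict[tuple[str, str, str], float] = {
    **{(f"CYT_S{i:02d}", "mouse", "antibody_IgG1"): 0.8 for i in range(1, 7)},
    **{(f"CYT_S{i:02d}", "human", "antibody_IgG1"): 0.5 for i in range(1, 4)},
}


@dataclass(frozen=True)
class PanelConfig:
    """Panel layout, factor structure, planted effects and noise.

    ``responders`` maps (analyte, species, compound) to the log10-scale
    elevation planted at the acute (8 h) time point; all groups sit at
    the analyte baseline at 168 h. ``noise_sd`` is the replicate SD on
    the log10 scale; ``lod`` the lower detection limit in pg/ml (values
    below it are censored when ``censor=True``).
    """

    n_analytes_A: int = 29
    n_analytes_B: int = 27
    n_shared: int = 22
    compounds: tuple[str, ...] = ("vehicle", "antibody_IgG1", "antibody_IgG4")
    times: tuple[str, ...] = ("8h", "168h")
    n_replicates: int = 5
    baseline_log10_mean: float = 1.5  # ~30 pg/ml
    baseline_log10_sd: float = 0.6
    noise_sd: float = 0.15
    responders: dict[tuple[str, str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_RESPONDERS)
    )
    acute_time: str = "8h"
    lod: float = 1.0
    censor: bool = False

    def __post_init__(self) -> None:
        if self.n_shared > min(self.n_analytes_A, self.n_analytes_B):
            raise ValueError("more shared analytes than either panel holds")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def panel_analytes(panel: PanelConfig) -> dict[str, list[str]]:
    """Analyte names per species; shared analytes carry one name in both."""
    shared = [f"CYT_S{i:02d}" for i in range(1, panel.n_shared + 1)]
    human_only = [f"CYT_H{i:02d}" for i in range(1, panel.n_analytes_A - panel.n_shared + 1)]
    mouse_only = [f"CYT_M{i:02d}" for i in range(1, panel.n_analytes_B - panel.n_shared + 1)]
    return {"human": shared + human_only, "mouse": shared + mouse_only}


def simulate_cytokine_table(panel: PanelConfig, seed: int) -> pd.DataFrame:
    """Long-format cytokine table: analyte, species, compound, time,
    replicate, concentration (pg/ml), censored."""
    rng = np.random.default_rng(seed)
    analytes = panel_analytes(panel)
    # one fixed baseline per (analyte, species): the two panels measure the
    # same molecule with different kits, so baselines may differ by species
    baselines = {
        (a, sp): rng.normal(panel.baseline_log10_mean, panel.baseline_log10_sd)
        for sp in ("human", "mouse")
        for a in analytes[sp]
    }
    rows = []
    for sp in ("human", "mouse"):
        for analyte in analytes[sp]:
            base = baselines[(analyte, sp)]
            for compound in panel.compounds:
                effect = panel.responders.get((analyte, sp, compound), 0.0)
                for time in panel.times:
                    level = base + (effect if time == panel.acute_time else 0.0)
                    for rep in range(1, panel.n_replicates + 1):
                        logc = level + rng.normal(0.0, panel.noise_sd)
                        conc = 10.0**logc
                        censored = panel.censor and conc < panel.lod
                        rows.append(
                            {
                                "analyte": analyte,
                                "species": sp,
                                "compound": compound,
                                "time": time,
                                "replicate": rep,
                                "concentration": panel.lod / 2.0 if censored else conc,
                                "censored": censored,
                            }
                        )
    return pd.DataFrame(rows)
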