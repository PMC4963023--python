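"""Negative-binomial count experiments with planted differential expression.

Emulates the two-species count data of an antibody-treatment time
course: groups are compound (vehicle / IgG1 effector-competent antibody /
IgG4 effector-silent variant) crossed with time after a single dose
(4 h, 8 h, 168 h). The default profile plants the study's qualitative
pattern — acute changes at 4 h and 8 h under the IgG1 antibody that have
vanished by 168 h, essentially nothing under the IgG4 variant, and about
twice as many responding genes in the host (mouse) compartment as in the
graft (human) one.

Per-gene baseline means follow a log-normal distribution (a stand-in for
a realistic per-gene depth profile, which the sequencing summary alone
does not pin down); counts are NB with Var = mu + alpha * mu^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..genemodel import GeneModel

COMPOUNDS = ("vehicle", "antibody_IgG1", "antibody_IgG4")
TIMES = ("4h", "8h", "168h")

#: fraction of genes DE vs the time-matched vehicle group, human compartment
STUDY_FRAC_DE_HUMAN = {
    ("antibody_IgG1", "4h"): 0.10,
    ("antibody_IgG1", "8h"): 0.10,
    ("antibody_IgG1", "168h"): 0.0,
    ("antibody_IgG4", "4h"): 0.0,
    ("antibody_IgG4", "8h"): 0.0,
    ("antibody_IgG4", "168h"): 0.0,
}


@dataclass(frozen=True)
class DesignConfig:
    """Design of a two-species planted-DE count experiment.

    ``frac_de`` maps (compound, time) to the fraction of genes DE against
    vehicle at that time in the HUMAN compartment; the mouse fractions
    are ``mouse_to_human_de_ratio`` times larger (capped at 1). Planted
    log2 fold changes are drawn N(log2fc_mean, log2fc_sd) with random
    sign. ``library_multipliers`` (sample -> factor) scale sequencing
    depth; None draws mild log-normal variation.
    """

    n_genes: int = 2000
    n_replicates: int = 5
    compounds: tuple[str, ...] = COMPOUNDS
    times: tuple[str, ...] = TIMES
    frac_de: dict = field(default_factory=lambda: dict(STUDY_FRAC_DE_HUMAN))
    log2fc_mean: float = 2.0
    log2fc_sd: float = 0.5
    dispersion: float = 0.1
    baseline_log_mean: float = np.log(50.0)
    baseline_log_sd: float = 1.0
    library_multipliers: dict | None = None
    mouse_to_human_de_ratio: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for key, f in self.frac_de.items():
            if not (0 <= f <= 1):
                raise ValueError(f"frac_de[{key}] outside [0, 1]")
        if "vehicle" not in self.compounds:
            raise ValueError("design needs a vehicle group")


@dataclass
class CountExperiment:
    """Counts per species plus the sample sheet and planted truth."""

    counts: dict[str, pd.DataFrame]  # species -> genes x samples
    samples: pd.DataFrame  # sample, compound, time, replicate
    truth_de: dict[str, dict[tuple[str, str], set[str]]]  # species -> group -> DE genes
    size_factors_true: pd.Series


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    if alpha <= 0:
        return rng.poisson(mu)
    r = 1.0 / alpha
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_count_experiment(design: DesignConfig) -> CountExperiment:
    """Generate the two-species count matrices with planted truth.

    Deterministic in (design, design.seed). The human compartment uses
    ``frac_de`` as given; the mouse compartment multiplies each fraction
    by ``mouse_to_human_de_ratio``.
    """
    rng = np.random.default_rng(design.seed)
    sample_rows = []
    for compound in design.compounds:
        for time in design.times:
            for rep in range(1, design.n_replicates + 1):
                sample_rows.append(
                    {
                        "sample": f"{compound}_{time}_r{rep}",
                        "compound": compound,
                        "time": time,
                        "replicate": rep,
                    }
                )
    samples = pd.DataFrame(sample_rows)

    if design.library_multipliers is None:
        mult = np.exp(rng.normal(0.0, 0.15, size=len(samples)))
    else:
        mult = np.array([design.library_multipliers.get(s, 1.0) for s in samples["sample"]])
    size_factors = pd.Series(mult, index=samples["sample"], name="size_factor")

    counts: dict[str, pd.DataFrame] = {}
    truth: dict[str, dict[tuple[str, str], set[str]]] = {}
    for species, ratio in (("human", 1.0), ("mouse", design.mouse_to_human_de_ratio)):
        genes = [f"{species[:2].upper()}_g{i:05d}" for i in range(design.n_genes)]
        base = np.exp(
            rng.normal(design.baseline_log_mean, design.baseline_log_sd, design.n_genes)
        )
        # planted per-group log2 fold changes vs the time-matched vehicle
        lfc = {}
        truth[species] = {}
        for (compound, time), frac in design.frac_de.items():
            frac_sp = min(1.0, frac * ratio)
            n_de = int(round(frac_sp * design.n_genes))
            de_idx = rng.choice(design.n_genes, size=n_de, replace=False)
            effects = np.zeros(design.n_genes)
            magnitudes = rng.normal(design.log2fc_mean, design.log2fc_sd, n_de)
            signs = rng.choice([-1.0, 1.0], size=n_de)
            effects[de_idx] = signs * np.abs(magnitudes)
            lfc[(compound, time)] = effects
            truth[species][(compound, time)] = {genes[i] for i in de_idx}

        mat = np.empty((design.n_genes, len(samples)), dtype=int)
        for j, row in samples.iterrows():
            group = (row["compound"], row["time"])
            effects = lfc.get(group, np.zeros(design.n_genes))
            mu = base * np.power(2.0, effects) * mult[j]
            mat[:, j] = _nb_draw(rng, mu, design.dispersion)
        counts[species] = pd.DataFrame(mat, index=genes, columns=samples["sample"])

    return CountExperiment(counts, samples, truth, size_factors)


def simulate_gene_models(
    n_genes: int,
    seed: int,
    species: str = "A",
    max_transcripts: int = 3,
    max_exons: int = 5,
    max_coord: int = 10_000,
) -> list[GeneModel]:
    """Random multi-transcript gene models for exercising the exon-union
    machinery: exon intervals overlap, nest and duplicate freely."""
    rng = np.random.default_rng(seed)
    models = []
    for i in range(n_genes):
        n_tx = int(rng.integers(1, max_transcripts + 1))
        transcripts = {}
        for t in range(n_tx):
            n_ex = int(rng.integers(1, max_exons + 1))
            exons = []
            for _ in range(n_ex):
                start = int(rng.integers(0, max_coord - 1))
                end = int(rng.integers(start + 1, min(max_coord, start + 2000) + 1))
                exons.append((start, end))
            transcripts[f"g{i:05d}.t{t}"] = sorted(exons)
        models.append(GeneModel(f"g{i:05d}", species, transcripts))
    return models
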