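"""Phagocytosis co-culture simulation.

Tumor cells are plated with macrophages at a 1:2 tumor:macrophage ratio;
each tumor cell is engulfed independently with a configurable
probability (the antibody's opsonization effect). Engulfed cells land in
uniformly chosen macrophages, so the double-positive macrophage count is
the number of distinct macrophages that received at least one cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..immunoassay import PhagocytosisAssay


@dataclass(frozen=True)
class PhagocytosisConfig:
    initial_tumor_count: int = 1000
    macrophage_count: int | None = None  # default: 2x tumor (1:2 ratio)
    engulfment_probability: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_tumor_count <= 0:
            raise ValueError("initial_tumor_count must be positive")
        if self.macrophage_count is not None and self.macrophage_count <= 0:
            raise ValueError("macrophage_count must be positive")
        if not (0.0 <= self.engulfment_probability <= 1.0):
            raise ValueError("engulfment_probability must be in [0, 1]")

    @property
    def n_macrophages(self) -> int:
        return self.macrophage_count or 2 * self.initial_tumor_count


def simulate_phagocytosis(config: PhagocytosisConfig) -> PhagocytosisAssay:
    """Draw one assay record; deterministic in (config, config.seed)."""
    rng = np.random.default_rng(config.seed)
    n0 = config.initial_tumor_count
    m = config.n_macrophages
    engulfed = int(rng.binomial(n0, config.engulfment_probability))
    hosts = rng.integers(0, m, size=engulfed)
    return PhagocytosisAssay(
        initial_tumor_count=n0,
        final_tumor_count=n0 - engulfed,
        macrophages_counted=m,
        macrophages_with_engulfed=int(np.unique(hosts).size),
    )
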