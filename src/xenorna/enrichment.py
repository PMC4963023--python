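"""Gene-set enrichment and directional downstream-effects scoring.

Two generic machineries over a directional gene-set knowledge base:

* over-representation of a DE gene list in a process's member genes,
  tested with the one-sided hypergeometric (Fisher) tail;
* the activation z-score, which compares the observed regulation
  directions of a process's member genes with the directions expected
  when the process is active: z = (N_consistent - N_inconsistent) / sqrt(N)
  over the N member genes present in the DE results. |z| >= 2 calls an
  "Increased" / "Decreased" activation state (the conventional cutoff);
  processes with no scoreable gene are reported unscored.

The z-score is the unweighted form of the published downstream-effects
statistic: per-edge weights require curated content that is not
reproducible, so all edges count equally and the implementation says so.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

#: process_id -> list of (gene_id, expected direction when active: +1 / -1)
GeneSetKB = dict[str, list[tuple[str, int]]]


@dataclass
class ActivationResult:
    process_id: str
    n_overlap: int
    p_enrich: float
    z: float | None
    state: str  # "Increased" | "Decreased" | "none" | "unscored"


def validate_kb(kb: GeneSetKB) -> None:
    for pid, entries in kb.items():
        seen = set()
        for gene, direction in entries:
            if direction not in (1, -1):
                raise ValueError(f"{pid}: direction for {gene} must be +1 or -1")
            if gene in seen:
                raise ValueError(f"{pid}: gene {gene} listed twice")
            seen.add(gene)


def fisher_enrichment(de_genes: set, process_genes: set, universe: set) -> float:
    """One-sided over-representation p: P(overlap >= observed) under the
    hypergeometric null on the 2x2 table."""
    if not universe:
        raise ValueError("empty gene universe")
    if not de_genes <= universe or not process_genes <= universe:
        raise ValueError("de_genes and process_genes must be subsets of the universe")
    k = len(de_genes & process_genes)
    # P(X >= k), X ~ Hypergeom(M=|universe|, n=|process|, N=|de|)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(process_genes), len(de_genes)))


def activation_zscore(
    observed_directions: dict[str, int],
    kb_entry: list[tuple[str, int]],
    z_threshold: float = 2.0,
) -> tuple[float | None, str, int]:
    """Directional consistency z for one process.

    ``observed_directions`` maps gene -> sign of its log2 fold change.
    Only genes present in both the observations and the knowledge-base
    entry are scored. Returns (z, state, N); with N = 0 the process is
    unscored (z None), mirroring processes for which no activity
    assessment is possible.
    """
    consistent = inconsistent = 0
    for gene, expected in kb_entry:
        obs = observed_directions.get(gene)
        if obs is None or obs == 0:
            continue
        if obs * expected == 1:
            consistent += 1
        else:
            inconsistent += 1
    n = consistent + inconsistent
    if n == 0:
        return None, "unscored", 0
    z = (consistent - inconsistent) / n**0.5
    if z >= z_threshold:
        state = "Increased"
    elif z <= -z_threshold:
        state = "Decreased"
    else:
        state = "none"
    return z, state, n


def downstream_effects(
    de_table: pd.DataFrame,
    kb: GeneSetKB,
    padj_threshold: float = 0.1,
    lfc_threshold: float = 0.0,
    z_threshold: float = 2.0,
    universe: set | None = None,
) -> pd.DataFrame:
    """Score every process against a DE result table.

    ``de_table`` must carry ``log2FoldChange`` and ``padj`` indexed by
    gene. Genes passing the padj and |log2FC| filters define the DE set;
    their fold-change signs feed the z-score. Results are sorted by
    descending z (unscored processes last), ties broken by process_id
    for stable output.
    """
    validate_kb(kb)
    if universe is None:
        universe = set(de_table.index)
    sig = de_table[
        (de_table["padj"] < padj_threshold)
        & (de_table["log2FoldChange"].abs() >= lfc_threshold)
    ]
    de_genes = set(sig.index)
    directions = {g: (1 if lfc > 0 else -1 if lfc < 0 else 0)
                  for g, lfc in sig["log2FoldChange"].items()}

    rows = []
    for pid in sorted(kb):
        entry = kb[pid]
        process_genes = {g for g, _ in entry} & universe
        p = fisher_enrichment(de_genes, process_genes, universe)
        z, state, n = activation_zscore(directions, entry, z_threshold)
        rows.append(ActivationResult(pid, n, p, z, state))
    df = pd.DataFrame(
        [(r.process_id, r.n_overlap, r.p_enrich, r.z, r.state) for r in rows],
        columns=["process_id", "n_overlap", "p_enrich", "z", "state"],
    )
    df = df.sort_values(
        by=["z", "process_id"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    return df


def zscore_matrix(per_contrast: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Processes x contrasts matrix of activation z-scores (heatmap-ready)."""
    cols = {}
    for name, df in per_contrast.items():
        cols[name] = df.set_index("process_id")["z"]
    return pd.DataFrame(cols)


def read_kb(path: str) -> GeneSetKB:
    """Read a directional gene-set KB from GMT-like TSV:
    process_id <tab> gene:direction <tab> gene:direction ..."""
    kb: GeneSetKB = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or not parts[0]:
                continue
            entries = []
            for tok in parts[1:]:
                if not tok:
                    continue
                gene, _, d = tok.rpartition(":")
                entries.append((gene, int(d)))
            kb[parts[0]] = entries
    validate_kb(kb)
    return kb


def write_kb(kb: GeneSetKB, path: str) -> None:
    with open(path, "w") as fh:
        for pid in sorted(kb):
            toks = [f"{g}:{d:+d}" for g, d in kb[pid]]
            fh.write("\t".join([pid] + toks) + "\n")
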