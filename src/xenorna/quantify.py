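"""Gene-level counting of species-assigned read pairs and RPKM.

Counting is fragment-level: a pair counts once, to a gene, if its
species-unique alignments hit transcripts of exactly one gene. Pairs
hitting transcripts of more than one gene are tallied as gene-ambiguous
and contribute to no gene; pairs hitting transcripts assigned to no
gene count as intergenic. The per-sample denominator N_s is the number
of pairs uniquely assigned to THAT species, so each compartment is
quantified against its own transcriptome and the minority (host)
compartment is not distorted by graft reads.

RPKM follows the classic definition with the composite exon-union
length: rpkm[g, s] = 1e9 * C[g, s] / (N_s * L_g).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .classify import AlignmentRecord, ReadClass
from .genemodel import MergedGeneModel


@dataclass
class CountMatrix:
    """Integer gene x sample counts for one species, plus per-sample
    species-assigned read-pair totals N_s (the RPKM denominator)."""

    species: str
    counts: pd.DataFrame
    totals: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if list(self.counts.columns) != list(self.totals.index):
            raise ValueError("totals must cover exactly the count-matrix samples")
        if (self.counts.sum(axis=0) > self.totals).any():
            raise ValueError("per-sample gene counts exceed assigned-read total N_s")


@dataclass
class CountAudit:
    """Read-conservation ledger for one sample: every species-assigned
    pair is counted, gene-ambiguous, or intergenic."""

    n_assigned: int
    n_counted: int
    n_gene_ambiguous: int
    n_intergenic: int

    def __post_init__(self) -> None:
        if self.n_counted + self.n_gene_ambiguous + self.n_intergenic != self.n_assigned:
            raise ValueError("conservation violated: counted + ambiguous + intergenic != assigned")


_TARGET = {"A": ReadClass.A_UNIQUE, "B": ReadClass.B_UNIQUE}


def count_to_genes(
    assignments: Mapping[str, ReadClass],
    alignments: Iterable[AlignmentRecord],
    tx2gene: Mapping[str, str],
    species: str,
    gene_ids: list[str] | None = None,
) -> tuple[pd.Series, CountAudit]:
    """Count species-unique pairs per gene for one sample.

    ``alignments`` are this sample's hits against the ``species``
    transcriptome; only pairs classified unique to that species count.
    An alignment to a transcript absent from ``tx2gene`` raises unless
    the transcript id maps to ``None`` (explicitly intergenic).
    """
    if species not in _TARGET:
        raise ValueError("species must be 'A' or 'B'")
    target = _TARGET[species]

    genes_per_read: dict[str, set[str | None]] = {}
    for rec in alignments:
        if assignments.get(rec.read_id) is not target:
            continue
        if rec.transcript_id not in tx2gene:
            raise KeyError(
                f"alignment to unknown transcript {rec.transcript_id!r}; "
                "add it to the transcript-to-gene map (None marks intergenic)"
            )
        genes_per_read.setdefault(rec.read_id, set()).add(tx2gene[rec.transcript_id])

    n_assigned = sum(1 for cls in assignments.values() if cls is target)
    counts: dict[str, int] = {}
    n_ambiguous = 0
    n_intergenic = 0
    for rid, genes in genes_per_read.items():
        real = {g for g in genes if g is not None}
        if len(real) == 1:
            g = next(iter(real))
            counts[g] = counts.get(g, 0) + 1
        elif len(real) > 1:
            n_ambiguous += 1
        else:
            n_intergenic += 1
    # pairs assigned to the species but absent from the alignment stream
    # (should not happen with consistent inputs) count as intergenic
    n_intergenic += n_assigned - len(genes_per_read)

    if gene_ids is None:
        gene_ids = sorted({g for g in tx2gene.values() if g is not None})
    series = pd.Series(0, index=pd.Index(gene_ids, name="gene_id"), dtype=int)
    for g, c in counts.items():
        series.loc[g] = c
    n_counted = int(series.sum())
    return series, CountAudit(n_assigned, n_counted, n_ambiguous, n_intergenic)


def build_count_matrix(
    species: str,
    per_sample: Mapping[str, tuple[pd.Series, CountAudit]],
) -> CountMatrix:
    """Assemble per-sample gene counts into one CountMatrix."""
    samples = list(per_sample)
    counts = pd.DataFrame({s: per_sample[s][0] for s in samples}).fillna(0).astype(int)
    totals = pd.Series({s: per_sample[s][1].n_assigned for s in samples}, name="N_s")
    return CountMatrix(species, counts, totals)


def compute_rpkm(
    counts: CountMatrix, merged: Mapping[str, MergedGeneModel] | Mapping[str, int]
) -> pd.DataFrame:
    """RPKM with the composite-length normalization.

    ``merged`` maps gene_id to a MergedGeneModel or directly to a
    composite length in bases. Every gene in the matrix needs a positive
    length; every sample needs N_s > 0.
    """
    lengths = pd.Series(
        {
            g: (m.composite_length if isinstance(m, MergedGeneModel) else int(m))
            for g, m in merged.items()
        }
    )
    missing = counts.counts.index.difference(lengths.index)
    if len(missing):
        raise KeyError(f"no composite length for gene(s): {list(missing)[:5]}")
    lengths = lengths.reindex(counts.counts.index)
    if (lengths <= 0).any():
        raise ValueError("composite lengths must be positive")
    if (counts.totals <= 0).any():
        bad = counts.totals[counts.totals <= 0].index.tolist()
        raise ValueError(f"sample(s) with no assigned reads: {bad}")
    c = counts.counts.to_numpy(dtype=float)
    rpkm = 1e9 * c / np.outer(lengths.to_numpy(), counts.totals.to_numpy())
    return pd.DataFrame(rpkm, index=counts.counts.index, columns=counts.counts.columns)
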