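"""Gene models and the composite exon-union length.

Expression is normalized by a gene's *composite length*: the summed
length of the non-overlapping exon groups obtained by taking the
interval union of all exons of all of the gene's transcripts. Coordinates
are 0-based half-open internally; GTF input (1-based inclusive) is
converted on read, and the BED output keeps the 0-based convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gffutils

Interval = tuple[int, int]


@dataclass
class GeneModel:
    """One gene with per-transcript exon intervals on a common gene axis."""

    gene_id: str
    species: str = ""
    transcripts: dict[str, list[Interval]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, exons in self.transcripts.items():
            if not exons:
                raise ValueError(f"transcript {tid} has no exons")
            for s, e in exons:
                if s >= e:
                    raise ValueError(f"zero-length or inverted exon [{s}, {e}) in {tid}")

    def all_exons(self) -> list[Interval]:
        return [iv for exons in self.transcripts.values() for iv in exons]


@dataclass
class MergedGeneModel:
    """Non-overlapping exon groups of a gene and their total length."""

    gene_id: str
    merged_groups: list[Interval]
    composite_length: int

    def __post_init__(self) -> None:
        for (s1, e1), (s2, e2) in zip(self.merged_groups, self.merged_groups[1:]):
            if e1 > s2:
                raise ValueError("merged groups must be disjoint and sorted")
        if self.composite_length != sum(e - s for s, e in self.merged_groups):
            raise ValueError("composite_length inconsistent with groups")


def merge_exon_groups(model: GeneModel) -> MergedGeneModel:
    """Union all exon intervals of all transcripts into disjoint groups.

    Touching intervals ([0,100) and [100,150)) merge into one group, so
    groups are maximal runs of exonic bases. Idempotent: merging a model
    whose exons are already the merged groups returns the same groups.
    """
    exons = sorted(model.all_exons())
    groups: list[Interval] = []
    for s, e in exons:
        if groups and s <= groups[-1][1]:
            groups[-1] = (groups[-1][0], max(groups[-1][1], e))
        else:
            groups.append((s, e))
    length = sum(e - s for s, e in groups)
    return MergedGeneModel(model.gene_id, groups, length)


def read_gtf(path: str) -> list[GeneModel]:
    """Load gene models from a GTF file (exon features only).

    GTF coordinates are 1-based inclusive and converted to 0-based
    half-open. Requires ``gene_id`` and ``transcript_id`` attributes.
    """
    db = gffutils.create_db(
        path,
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    models: dict[str, GeneModel] = {}
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        gene_id = feat.attributes["gene_id"][0]
        tx_id = feat.attributes["transcript_id"][0]
        model = models.setdefault(gene_id, GeneModel(gene_id))
        model.transcripts.setdefault(tx_id, []).append((feat.start - 1, feat.end))
    # re-validate after incremental fill
    for model in models.values():
        GeneModel(model.gene_id, model.species, model.transcripts)
    return list(models.values())


def write_gtf(models: list[GeneModel], path: str, seqname_of: dict[str, str] | None = None) -> None:
    """Write gene models as GTF exon features (1-based inclusive on write)."""
    with open(path, "w") as fh:
        for m in models:
            seqname = (seqname_of or {}).get(m.gene_id, m.gene_id)
            for tid, exons in m.transcripts.items():
                for s, e in sorted(exons):
                    attrs = f'gene_id "{m.gene_id}"; transcript_id "{tid}";'
                    fh.write(
                        f"{seqname}\tsim\texon\t{s + 1}\t{e}\t.\t+\t.\t{attrs}\n"
                    )


def write_merged_bed(merged: list[MergedGeneModel], path: str) -> None:
    """Merged exon groups as BED (0-based half-open), one line per group."""
    with open(path, "w") as fh:
        for m in merged:
            for i, (s, e) in enumerate(m.merged_groups):
                fh.write(f"{m.gene_id}\t{s}\t{e}\t{m.gene_id}.group{i}\n")
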