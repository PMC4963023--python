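"""Species assignment of read pairs aligned against two transcriptomes.

A xenograft sample mixes graft (human) and host (mouse) RNA. After
competitive alignment of the same reads against both transcriptomes,
each read PAIR is assigned to exactly one of four classes:

* ``A_UNIQUE`` — hits only in reference A (the human surrogate),
* ``B_UNIQUE`` — hits only in reference B,
* ``AMBIGUOUS`` — any hit in both references, from either mate; these
  pairs are discarded from quantification,
* ``UNMAPPED`` — no hit anywhere.

The rule is strict and unconditional: a pair with one strong hit in A
and one weak hit in B is still ambiguous; there is no score-based
rescue. The unit is the pair because the library is paired-end and
splitting mates would double-count fragments.
"""

from __future__ import annotations

import json
import warnings
from collections import defaultdict
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Iterator

import pysam


class ReadClass(str, Enum):
    A_UNIQUE = "A_UNIQUE"
    B_UNIQUE = "B_UNIQUE"
    AMBIGUOUS = "AMBIGUOUS"
    UNMAPPED = "UNMAPPED"


@dataclass(frozen=True)
class AlignmentRecord:
    """One alignment of one mate against one reference.

    ``position`` is the 0-based leftmost coordinate on the transcript
    (SAM POS minus one).
    """

    read_id: str
    mate: int  # 1 or 2
    reference_species: str  # "A" or "B"
    transcript_id: str
    position: int
    mapq: int = 0

    def __post_init__(self) -> None:
        if not self.read_id:
            raise ValueError("read_id must be non-empty")
        if self.mate not in (1, 2):
            raise ValueError("mate must be 1 or 2")
        if self.position < 0 or self.mapq < 0:
            raise ValueError("position and mapq must be non-negative")


@dataclass
class ReadPairAlignments:
    """All alignment evidence for one read pair against both references."""

    read_id: str
    hits_A: list[AlignmentRecord]
    hits_B: list[AlignmentRecord]

    def __post_init__(self) -> None:
        for rec in self.hits_A:
            if rec.read_id != self.read_id or rec.reference_species != "A":
                raise ValueError(f"inconsistent record in hits_A for {self.read_id}")
        for rec in self.hits_B:
            if rec.read_id != self.read_id or rec.reference_species != "B":
                raise ValueError(f"inconsistent record in hits_B for {self.read_id}")


@dataclass
class ClassificationStats:
    """Read-fate partition and the derived mapping fractions.

    ``frac_mapped_either`` is the fraction of all pairs with at least one
    hit (the study reports ~70%), ``frac_ambiguous`` the fraction hitting
    both species (~7%, discarded), and ``frac_A_of_assignable`` the share
    of species-assignable pairs on the A side (~80% human).
    """

    n_total: int
    n_A: int
    n_B: int
    n_ambiguous: int
    n_unmapped: int

    def __post_init__(self) -> None:
        if self.n_A + self.n_B + self.n_ambiguous + self.n_unmapped != self.n_total:
            raise ValueError("class counts do not partition n_total")

    @property
    def frac_mapped_either(self) -> float:
        return (self.n_A + self.n_B + self.n_ambiguous) / self.n_total if self.n_total else 0.0

    @property
    def frac_ambiguous(self) -> float:
        return self.n_ambiguous / self.n_total if self.n_total else 0.0

    @property
    def frac_A_of_assignable(self) -> float:
        assignable = self.n_A + self.n_B
        return self.n_A / assignable if assignable else 0.0

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_A": self.n_A,
            "n_B": self.n_B,
            "n_ambiguous": self.n_ambiguous,
            "n_unmapped": self.n_unmapped,
            "frac_mapped_either": self.frac_mapped_either,
            "frac_ambiguous": self.frac_ambiguous,
            "frac_A_of_assignable": self.frac_A_of_assignable,
        }


def classify_pair(pair: ReadPairAlignments, min_mapq: int = 0) -> ReadClass:
    """Assign one read pair; hits below ``min_mapq`` are ignored first.

    Deterministic and independent of hit order. Cross-species evidence
    from either mate (including mate1-in-A with mate2-in-B) makes the
    pair AMBIGUOUS.
    """
    has_a = any(r.mapq >= min_mapq for r in pair.hits_A)
    has_b = any(r.mapq >= min_mapq for r in pair.hits_B)
    if has_a and has_b:
        return ReadClass.AMBIGUOUS
    if has_a:
        return ReadClass.A_UNIQUE
    if has_b:
        return ReadClass.B_UNIQUE
    return ReadClass.UNMAPPED


def classify_set(
    alignments_A: Iterable[AlignmentRecord],
    alignments_B: Iterable[AlignmentRecord],
    min_mapq: int = 0,
    n_total: int | None = None,
) -> tuple[dict[str, ReadClass], ClassificationStats]:
    """Classify every read pair seen in either alignment stream.

    Records are grouped by ``read_id`` (duplicates collapse), so input
    order never matters. Because SAM files omit unaligned reads, the
    total read universe cannot be recovered from the streams alone:
    pass ``n_total`` (e.g. from a FASTQ manifest) to count UNMAPPED
    pairs; by default only the pairs present in the streams are counted.
    """
    hits_a: dict[str, list[AlignmentRecord]] = defaultdict(list)
    hits_b: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for rec in alignments_A:
        hits_a[rec.read_id].append(rec)
    for rec in alignments_B:
        hits_b[rec.read_id].append(rec)

    assignments: dict[str, ReadClass] = {}
    for rid in sorted(hits_a.keys() | hits_b.keys()):
        pair = ReadPairAlignments(rid, hits_a.get(rid, []), hits_b.get(rid, []))
        assignments[rid] = classify_pair(pair, min_mapq=min_mapq)

    n_a = sum(1 for c in assignments.values() if c is ReadClass.A_UNIQUE)
    n_b = sum(1 for c in assignments.values() if c is ReadClass.B_UNIQUE)
    n_amb = sum(1 for c in assignments.values() if c is ReadClass.AMBIGUOUS)
    n_unmapped_seen = len(assignments) - n_a - n_b - n_amb
    if n_total is None:
        n_total = len(assignments)
    elif n_total < len(assignments):
        raise ValueError("n_total smaller than the number of read pairs observed")
    n_unmapped = n_total - n_a - n_b - n_amb
    stats = ClassificationStats(n_total, n_a, n_b, n_amb, n_unmapped)
    assert n_unmapped >= n_unmapped_seen
    return assignments, stats


# --- SAM / FASTQ plumbing -------------------------------------------------
#
# Only QNAME, FLAG, RNAME, POS, MAPQ (and CIGAR on write) are consulted;
# secondary alignments count as evidence like any other hit. Unaligned
# reads are never written.


def _mate_from_flag(flag: int) -> int:
    if flag & 0x40 and not flag & 0x80:
        return 1
    if flag & 0x80 and not flag & 0x40:
        return 2
    return 1  # unpaired records are treated as mate 1


def read_sam(
    path: str, reference_species: str, malformed: set[str] | None = None
) -> Iterator[AlignmentRecord]:
    """Stream alignment records from a SAM file for one reference.

    Read ids whose FLAG carries both (or, while paired, neither) mate bit
    are collected into ``malformed`` for ambiguous-safe handling upstream.
    """
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for seg in sam:
            if seg.is_unmapped or seg.reference_name is None:
                continue
            if malformed is not None and seg.flag & 0x1:
                mate_bits = seg.flag & (0x40 | 0x80)
                if mate_bits in (0, 0x40 | 0x80):
                    malformed.add(seg.query_name)
            yield AlignmentRecord(
                read_id=seg.query_name,
                mate=_mate_from_flag(seg.flag),
                reference_species=reference_species,
                transcript_id=seg.reference_name,
                position=seg.reference_start,
                mapq=seg.mapping_quality,
            )


def write_sam(
    records: Iterable[AlignmentRecord],
    reference_lengths: dict[str, int],
    path: str,
    read_length: int = 50,
) -> None:
    """Write alignment records as plain-text SAM with proper @SQ headers."""
    names = list(reference_lengths)
    header = pysam.AlignmentHeader.from_references(
        names, [reference_lengths[n] for n in names]
    )
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for rec in records:
            seg = pysam.AlignedSegment(header)
            seg.query_name = rec.read_id
            seg.flag = 0x1 | 0x2 | (0x40 if rec.mate == 1 else 0x80) | (
                0x10 if rec.mate == 2 else 0x20
            )
            seg.reference_id = tid[rec.transcript_id]
            seg.reference_start = rec.position
            seg.mapping_quality = rec.mapq
            seg.cigarstring = f"{read_length}M"
            out.write(seg)


def count_fastq_reads(path: str) -> int:
    """Number of records in a FASTQ manifest (read-pair denominator)."""
    n = 0
    with pysam.FastxFile(path) as fq:
        for _ in fq:
            n += 1
    return n


def classify_sam(
    sam_a: str,
    sam_b: str,
    min_mapq: int = 0,
    manifest: str | None = None,
    n_total: int | None = None,
) -> tuple[dict[str, ReadClass], ClassificationStats]:
    """Classify from two SAM files, with an optional FASTQ manifest giving
    the full read universe (needed to count fully unmapped pairs)."""
    if manifest is not None:
        n_total = count_fastq_reads(manifest)
    malformed: set[str] = set()
    assignments, stats = classify_set(
        read_sam(sam_a, "A", malformed),
        read_sam(sam_b, "B", malformed),
        min_mapq=min_mapq,
        n_total=n_total,
    )
    demoted = {rid for rid in malformed if assignments.get(rid) is not ReadClass.AMBIGUOUS}
    if demoted:
        warnings.warn(
            f"{len(demoted)} read pair(s) with inconsistent mate flags "
            "counted AMBIGUOUS", stacklevel=2,
        )
        n_a, n_b, n_amb = stats.n_A, stats.n_B, stats.n_ambiguous
        for rid in demoted:
            cls = assignments[rid]
            if cls is ReadClass.A_UNIQUE:
                n_a -= 1
            elif cls is ReadClass.B_UNIQUE:
                n_b -= 1
            assignments[rid] = ReadClass.AMBIGUOUS
            n_amb += 1
        stats = ClassificationStats(
            stats.n_total, n_a, n_b, n_amb,
            stats.n_total - n_a - n_b - n_amb,
        )
    return assignments, stats


def write_assignments(assignments: dict[str, ReadClass], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tclass\n")
        for rid in sorted(assignments):
            fh.write(f"{rid}\t{assignments[rid].value}\n")


def write_stats(stats: ClassificationStats, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(stats.to_dict(), fh, indent=2)
        fh.write("\n")
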