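"""Paired-end read simulation over a two-species surrogate transcriptome.

Emulates the sequencing layout of a xenograft RNA-seq run: 50-nt
paired-end fragments drawn from a graft/host mixture in which roughly
70% of reads map to at least one transcriptome, 7% map to both species
(and are discarded downstream), and ~80% of the species-assignable reads
come from the human compartment. Alignments are emitted directly from
the known placement of each fragment — no external aligner runs — so the
truth table is exact: a pair labelled SPECIES_A has hits only in A, a
SHARED pair hits both references, a NONE pair is random sequence with no
hits anywhere.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np

from ..classify import AlignmentRecord
from .references import ReferenceConfig, ReferencePair, build_reference_pair

SPECIES_A, SPECIES_B, SHARED, NONE = "SPECIES_A", "SPECIES_B", "SHARED", "NONE"

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass(frozen=True)
class MixtureConfig:
    """Composition of the simulated read mixture.

    Fractions refer to the truth labels, not to downstream classification:
    ``frac_cross_mappable`` pairs are drawn from verbatim-shared segments
    (they will hit both references), ``frac_unmappable`` pairs are random
    sequence with no alignment anywhere, and the remaining assignable mass
    splits ``frac_species_A_of_assignable`` : 1 − that between the two
    species.
    """

    n_pairs: int = 10_000
    frac_species_A_of_assignable: float = 0.80
    frac_cross_mappable: float = 0.07
    frac_unmappable: float = 0.30
    read_length: int = 50
    fragment_length: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_species_A_of_assignable", "frac_cross_mappable", "frac_unmappable"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frac_cross_mappable + self.frac_unmappable > 1.0:
            raise ValueError("cross-mappable + unmappable fractions exceed 1")
        if self.fragment_length < 2 * self.read_length:
            raise ValueError("fragment_length must fit two non-overlapping mates")

    @property
    def label_probabilities(self) -> dict[str, float]:
        assignable = 1.0 - self.frac_cross_mappable - self.frac_unmappable
        return {
            SPECIES_A: assignable * self.frac_species_A_of_assignable,
            SPECIES_B: assignable * (1.0 - self.frac_species_A_of_assignable),
            SHARED: self.frac_cross_mappable,
            NONE: self.frac_unmappable,
        }


def study_profile(n_pairs: int = 200_000, seed: int = 0) -> MixtureConfig:
    """The mixture matching the study's reported mapping statistics:
    70% of pairs map somewhere, 7% map to both species, and 80% of the
    assignable pairs are human (species A)."""
    return MixtureConfig(
        n_pairs=n_pairs,
        frac_species_A_of_assignable=0.80,
        frac_cross_mappable=0.07,
        frac_unmappable=0.30,
        seed=seed,
    )


@dataclass
class SimulatedReadSet:
    """Reads, per-pair truth, and truth-derived alignments for both references."""

    reads: list[tuple[str, str, str]]  # (read_id, mate1 seq, mate2 seq)
    truth: dict[str, str]  # read_id -> SPECIES_A | SPECIES_B | SHARED | NONE
    alignments_A: list[AlignmentRecord]
    alignments_B: list[AlignmentRecord]
    config: MixtureConfig

    @property
    def n_pairs(self) -> int:
        return len(self.reads)


def _unique_start_positions(
    length: int, segments: list[tuple[int, int]], read_len: int, frag_len: int
) -> np.ndarray:
    """Fragment starts from which NEITHER mate lies entirely inside a shared
    segment — reads placed there cannot match the other species."""
    starts = np.arange(0, length - frag_len + 1)
    ok = np.ones(starts.size, dtype=bool)
    for s, e in segments:
        m1_in = (starts >= s) & (starts + read_len <= e)
        m2_start = starts + frag_len - read_len
        m2_in = (m2_start >= s) & (starts + frag_len <= e)
        ok &= ~(m1_in | m2_in)
    return starts[ok]


def _shared_start_ranges(
    segments: list[tuple[int, int]], frag_len: int
) -> list[tuple[int, int]]:
    """(lo, hi] fragment-start ranges fully inside a shared segment."""
    return [(s, e - frag_len) for s, e in segments if e - s >= frag_len]


def simulate_read_pairs(
    refpair: ReferencePair, mixture: MixtureConfig
) -> SimulatedReadSet:
    """Draw ``mixture.n_pairs`` read pairs from the surrogate mixture.

    Returns reads, the truth table, and SAM-convention alignment records
    against each reference a read matches, computed by exact placement.
    """
    cfg = mixture
    rng = np.random.default_rng(cfg.seed)
    rl, fl = cfg.read_length, cfg.fragment_length

    seqs_a = {tid: seq for tid, seq in refpair.transcripts_A}
    seqs_b = {tid: seq for tid, seq in refpair.transcripts_B}
    ids_a = [tid for tid, _ in refpair.transcripts_A]
    ids_b = [tid for tid, _ in refpair.transcripts_B]
    b_for_a = {a: b for a, b, _ in refpair.homology_map}

    for tid, seq in list(seqs_a.items()) + list(seqs_b.items()):
        if len(seq) < fl:
            raise ValueError(f"transcript {tid} shorter than fragment length")

    # Precompute legal fragment starts per transcript and per truth label.
    uniq_a = {
        tid: _unique_start_positions(len(seqs_a[tid]), refpair.shared_segments(tid), rl, fl)
        for tid in ids_a
    }
    segs_b = {b: segs for _a, b, segs in refpair.homology_map}
    uniq_b = {
        tid: _unique_start_positions(len(seqs_b[tid]), segs_b.get(tid, []), rl, fl)
        for tid in ids_b
    }
    shared_sites: list[tuple[str, str, int, int]] = []  # (tidA, tidB, lo, hi)
    for a, b, segs in refpair.homology_map:
        for lo, hi in _shared_start_ranges(segs, fl):
            shared_sites.append((a, b, lo, hi))

    probs = cfg.label_probabilities
    if probs[SHARED] > 0 and not shared_sites:
        raise ValueError(
            "cross-mappable reads requested but no shared segment fits a fragment"
        )
    labels = rng.choice(
        [SPECIES_A, SPECIES_B, SHARED, NONE],
        size=cfg.n_pairs,
        p=[probs[SPECIES_A], probs[SPECIES_B], probs[SHARED], probs[NONE]],
    )

    reads: list[tuple[str, str, str]] = []
    truth: dict[str, str] = {}
    aln_a: list[AlignmentRecord] = []
    aln_b: list[AlignmentRecord] = []
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)

    def _emit(rec_list: list[AlignmentRecord], rid: str, species: str, tid: str, pos: int) -> None:
        rec_list.append(AlignmentRecord(rid, 1, species, tid, pos, 42))
        rec_list.append(AlignmentRecord(rid, 2, species, tid, pos + fl - rl, 42))

    for i, label in enumerate(labels):
        rid = f"rp{i:07d}"
        truth[rid] = label
        if label == NONE:
            s1 = bases[rng.integers(0, 4, rl)].tobytes().decode()
            s2 = bases[rng.integers(0, 4, rl)].tobytes().decode()
            reads.append((rid, s1, s2))
            continue
        if label == SHARED:
            tid_a, tid_b, lo, hi = shared_sites[rng.integers(0, len(shared_sites))]
            pos = int(rng.integers(lo, hi + 1))
            frag = seqs_a[tid_a][pos : pos + fl]
            _emit(aln_a, rid, "A", tid_a, pos)
            _emit(aln_b, rid, "B", tid_b, pos)
        elif label == SPECIES_A:
            tid_a = ids_a[rng.integers(0, len(ids_a))]
            starts = uniq_a[tid_a]
            pos = int(starts[rng.integers(0, starts.size)])
            frag = seqs_a[tid_a][pos : pos + fl]
            _emit(aln_a, rid, "A", tid_a, pos)
        else:  # SPECIES_B
            tid_b = ids_b[rng.integers(0, len(ids_b))]
            starts = uniq_b[tid_b]
            pos = int(starts[rng.integers(0, starts.size)])
            frag = seqs_b[tid_b][pos : pos + fl]
            _emit(aln_b, rid, "B", tid_b, pos)
        reads.append((rid, frag[:rl], _revcomp(frag[-rl:])))

    return SimulatedReadSet(reads, truth, aln_a, aln_b, cfg)


def simulate_study_run(
    n_pairs: int = 200_000,
    seed: int = 0,
    ref_config: ReferenceConfig | None = None,
) -> tuple[ReferencePair, SimulatedReadSet]:
    """Reference pair + study-profile read set in one call.

    The default reference keeps one 200-bp verbatim-shared segment per
    1-kb transcript so that whole fragments fit inside shared sequence.
    """
    if ref_config is None:
        ref_config = ReferenceConfig(
            n_transcripts=20, transcript_length=1000, homology_fraction=0.20
        )
    refpair = build_reference_pair(ref_config, seed=seed)
    mix = replace(study_profile(n_pairs=n_pairs), seed=seed + 1)
    return refpair, simulate_read_pairs(refpair, mix)


def write_fastq(readset: SimulatedReadSet, prefix: str) -> tuple[str, str]:
    """Write mates to ``<prefix>_1.fastq`` / ``<prefix>_2.fastq``."""
    paths = (f"{prefix}_1.fastq", f"{prefix}_2.fastq")
    qual = "I" * readset.config.read_length
    for mate, path in enumerate(paths, start=1):
        with open(path, "w") as fh:
            for rid, s1, s2 in readset.reads:
                seq = s1 if mate == 1 else s2
                fh.write(f"@{rid}/{mate}\n{seq}\n+\n{qual}\n")
    return paths


def write_truth(readset: SimulatedReadSet, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttrue_origin\n")
        for rid, _s1, _s2 in readset.reads:
            fh.write(f"{rid}\t{readset.truth[rid]}\n")


def write_alignments(readset: SimulatedReadSet, refpair: ReferencePair, out_dir: str) -> tuple[str, str]:
    """Write the per-reference alignments as plain SAM (unaligned reads omitted)."""
    from ..classify import write_sam  # local import: classify owns the SAM dialect

    path_a = os.path.join(out_dir, "alignments_A.sam")
    path_b = os.path.join(out_dir, "alignments_B.sam")
    write_sam(readset.alignments_A, refpair.lengths("A"), path_a,
              read_length=readset.config.read_length)
    write_sam(readset.alignments_B, refpair.lengths("B"), path_b,
              read_length=readset.config.read_length)
    return path_a, path_b
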