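"""Surrogate transcriptome pair for a two-species (graft/host) mixture.

A xenograft sample yields reads from two species whose transcriptomes
share stretches of high conservation. The surrogate models this with
transcript pairs derived from a common ancestor: a designated segment is
kept verbatim identical ("shared"), the remainder is mutated per-position
at a divergence high enough that no read-length window of non-shared
sequence occurs exactly in the other species. That screening makes
"maps to both references" exactly equivalent to "drawn from a shared
segment", which gives clean truth labels for the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ReferenceConfig:
    """Sizing of the surrogate transcriptome pair.

    Parameters
    ----------
    n_transcripts
        Number of homologous transcript pairs.
    transcript_length
        Length of every transcript, bases. Must be >= 2 * read_length of
        any read simulation run against the pair.
    homology_fraction
        Fraction of each transcript kept verbatim identical between the
        two species, in [0, 1). 0 means no shared segments at all.
    divergence
        Per-position substitution probability applied to non-shared
        sequence (each substitution always changes the base). Kept >= 0.3
        so 50-mer windows essentially never survive identically; an
        explicit screen enforces it regardless.
    """

    n_transcripts: int = 20
    transcript_length: int = 1000
    homology_fraction: float = 0.10
    divergence: float = 0.35

    def __post_init__(self) -> None:
        if not (0 <= self.homology_fraction < 1):
            raise ValueError("homology_fraction must be in [0, 1)")
        if not (0 < self.divergence <= 1):
            raise ValueError("divergence must be in (0, 1]")
        if self.n_transcripts < 1:
            raise ValueError("need at least one transcript")
        seg = round(self.homology_fraction * self.transcript_length)
        if seg >= self.transcript_length:
            raise ValueError("homology segment longer than transcript")


@dataclass
class ReferencePair:
    """Two surrogate transcriptomes plus the map of their shared segments.

    ``homology_map`` lists ``(transcript_A_id, transcript_B_id, segments)``
    where ``segments`` are 0-based half-open intervals, valid in both
    transcripts of the pair (homologs share coordinates by construction),
    inside which the sequences are verbatim identical.
    """

    transcripts_A: list[tuple[str, str]]
    transcripts_B: list[tuple[str, str]]
    homology_map: list[tuple[str, str, list[tuple[int, int]]]] = field(default_factory=list)

    def lengths(self, species: str) -> dict[str, int]:
        recs = self.transcripts_A if species == "A" else self.transcripts_B
        return {tid: len(seq) for tid, seq in recs}

    def shared_segments(self, tid_a: str) -> list[tuple[int, int]]:
        for a, _b, segs in self.homology_map:
            if a == tid_a:
                return segs
        return []


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=n)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Substitute each position with probability `rate`, always to a new base."""
    out = seq.copy()
    hit = np.nonzero(rng.random(seq.size) < rate)[0]
    for i in hit:
        choices = BASES[BASES != out[i]]
        out[i] = rng.choice(choices)
    return out


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def build_reference_pair(
    config: ReferenceConfig, seed: int, screen_k: int = 50, max_rescreens: int = 100
) -> ReferencePair:
    """Build a screened two-species surrogate transcriptome.

    `screen_k` is the read length against which divergence is screened:
    after mutation, any `screen_k`-window of one species that touches
    non-shared sequence and still occurs verbatim in the other species is
    re-mutated until none remains.
    """
    rng = np.random.default_rng(seed)
    cfg = config
    seg_len = round(cfg.homology_fraction * cfg.transcript_length)

    transcripts_a: list[tuple[str, str]] = []
    transcripts_b: list[tuple[str, str]] = []
    homology: list[tuple[str, str, list[tuple[int, int]]]] = []

    for i in range(cfg.n_transcripts):
        tid_a, tid_b = f"txA_{i:04d}", f"txB_{i:04d}"
        ancestor = _random_seq(rng, cfg.transcript_length)
        seq_a = ancestor
        seq_b = _mutate(rng, ancestor, cfg.divergence)
        segments: list[tuple[int, int]] = []
        if seg_len > 0:
            start = int(rng.integers(0, cfg.transcript_length - seg_len + 1))
            seq_b[start : start + seg_len] = seq_a[start : start + seg_len]
            segments = [(start, start + seg_len)]
        sa, sb = seq_a.tobytes().decode(), seq_b.tobytes().decode()

        # Screen: no k-window touching non-shared sequence may match the
        # homolog exactly. With >=30% divergence collisions are vanishingly
        # rare; the loop guarantees it.
        for _ in range(max_rescreens):
            bad = _colliding_windows(sa, sb, segments, screen_k)
            if not bad:
                break
            arr_b = np.frombuffer(sb.encode(), dtype=np.uint8).copy()
            for w in bad:
                arr_b[w : w + screen_k] = _mutate(
                    rng, arr_b[w : w + screen_k], max(cfg.divergence, 0.5)
                )
            # restore shared segments verbatim after re-mutation
            for s, e in segments:
                arr_b[s:e] = np.frombuffer(sa.encode(), dtype=np.uint8)[s:e]
            sb = arr_b.tobytes().decode()
        else:
            raise RuntimeError(f"could not screen transcript pair {tid_a}/{tid_b}")

        transcripts_a.append((tid_a, sa))
        transcripts_b.append((tid_b, sb))
        if segments:
            homology.append((tid_a, tid_b, segments))

    return ReferencePair(transcripts_a, transcripts_b, homology)


def _window_is_shared(pos: int, k: int, segments: list[tuple[int, int]]) -> bool:
    return any(s <= pos and pos + k <= e for s, e in segments)


def _colliding_windows(
    seq_a: str, seq_b: str, segments: list[tuple[int, int]], k: int
) -> list[int]:
    """Start positions (in B) of non-shared k-windows of B found verbatim in A,
    plus positions of A-windows found in B (returned as B positions to remutate:
    homologs share coordinates, so re-mutating the same window in B fixes both)."""
    kmers_a = _kmer_set(seq_a, k)
    kmers_b = _kmer_set(seq_b, k)
    bad: list[int] = []
    for pos in range(len(seq_b) - k + 1):
        if _window_is_shared(pos, k, segments):
            continue
        if seq_b[pos : pos + k] in kmers_a or seq_a[pos : pos + k] in kmers_b:
            bad.append(pos)
    return bad


def write_fasta(records: list[tuple[str, str]], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
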