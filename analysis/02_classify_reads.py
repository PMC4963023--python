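#!/usr/bin/env python
"""Classify the simulated read pairs from their two SAM files.

Re-reads the alignments written by 01_simulate_reads.py, applies the
strict pair-level rule (any cross-species hit discards the pair), and
checks the classification against the generator's truth table. Writes
assignments and the mapping statistics under results/classify/.
"""

import json
from pathlib import Path

import pandas as pd

from xenorna.classify import classify_sam, write_assignments, write_stats

READS = Path(__file__).parents[1] / "results" / "reads"
OUT = Path(__file__).parents[1] / "results" / "classify"

EXPECTED = {"SPECIES_A": "A_UNIQUE", "SPECIES_B": "B_UNIQUE",
            "SHARED": "AMBIGUOUS", "NONE": "UNMAPPED"}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    assignments, stats = classify_sam(
        str(READS / "alignments_A.sam"),
        str(READS / "alignments_B.sam"),
        manifest=str(READS / "reads_1.fastq"),
    )
    write_assignments(assignments, str(OUT / "assignments.tsv"))
    write_stats(stats, str(OUT / "stats.json"))
    print(json.dumps(stats.to_dict(), indent=2))

    truth = pd.read_csv(READS / "truth.tsv", sep="\t").set_index("read_id")["true_origin"]
    got = {rid: cls.value for rid, cls in assignments.items()}
    mismatches = sum(
        1 for rid, origin in truth.items()
        if got.get(rid, "UNMAPPED") != EXPECTED[origin]
    )
    print(f"pairs disagreeing with truth: {mismatches} of {len(truth)}")
    print(f"mapped-either {100 * stats.frac_mapped_either:.2f}%  "
          f"ambiguous {100 * stats.frac_ambiguous:.2f}%  "
          f"human-of-assignable {100 * stats.frac_A_of_assignable:.2f}%")


if __name__ == "__main__":
    main()
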