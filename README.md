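# xenorna

Dual-species xenograft RNA-seq deconvolution and companion statistics,
as a tested, synthetic-data-driven pipeline.

When a human tumor is grown in a mouse host, one RNA-seq run profiles
both species at once: graft (tumor) and host (stroma, immune
infiltrate) transcripts are mixed in every lysate. `xenorna` implements
the analysis chain for such experiments:

* **Read disambiguation** — each read pair, aligned competitively
  against the human and mouse transcriptomes, is assigned
  human-unique / mouse-unique / ambiguous (hit in both species,
  discarded) / unmapped. The rule is strict and pair-level: any
  cross-species hit, from either mate, discards the pair.
* **Quantification** — per-gene fragment counts and RPKM,
  `1e9·C/(N·L)`, with `L` the gene's *composite length* (the summed
  length of the non-overlapping exon groups forming the union of all
  transcripts' exons) and `N` the pairs assigned to that species.
* **Differential expression** — the classic NB exact-test procedure:
  median-of-ratios size factors, method-of-moments dispersions shared
  conservatively with a fitted mean–dispersion trend, a conditional
  exact test on the two groups' summed counts, Benjamini–Hochberg.
* **Downstream-effects scoring** — Fisher over-representation plus the
  directional activation z-score
  `z = (N_consistent − N_inconsistent)/√N`, with |z| ≥ 2 calling an
  Increased/Decreased activation state.
* **Immunoassay statistics** — Ward clustering and species × compound
  × time factorial models for dual-panel cytokine data (29 human / 27
  mouse analytes, 22 shared), the phagocytic index
  `PI = (engulfed/M)·(M⁺⁺/M)·100`, two-way ANOVA with Bonferroni
  post-tests, tumor volume `TV = length·width²/2` and growth
  inhibition (TGI).
* **Synthetic data** — every input above is generated with planted
  truth (read origins, DE genes, cytokine responders, engulfment
  rates), so the whole pipeline is testable with no external data.

## Worked example

Simulate a study-profile read set (70% of pairs mapping to at least one
transcriptome, 7% to both, 80% of assignable pairs human) and classify
it:

```python
from xenorna.sim.reads import simulate_study_run
from xenorna.classify import classify_set

refpair, readset = simulate_study_run(n_pairs=50_000, seed=1)
assignments, stats = classify_set(
    readset.alignments_A, readset.alignments_B, n_total=readset.n_pairs
)
print(f"mapped-either {100 * stats.frac_mapped_either:.2f}%  "
      f"ambiguous {100 * stats.frac_ambiguous:.2f}%  "
      f"human-of-assignable {100 * stats.frac_A_of_assignable:.2f}%")
```

prints

```
mapped-either 70.03%  ambiguous 7.09%  human-of-assignable 80.02%
```

— the classifier recovers the planted mixture: 70.03% of pairs hit at
least one reference, 7.09% hit both species and are discarded, and
80.02% of the species-assignable pairs go to the human side. Because
the generator's divergence screening makes "maps to both" equivalent to
"drawn from conserved sequence", classification agrees with the truth
table on every single pair (checked in `analysis/02_classify_reads.py`).

The numbered scripts under `analysis/` walk the full chain — read
simulation, classification, composite-length RPKM, the two-species DE
time course (acute changes at 4 h/8 h that vanish by 168 h, with about
twice as many mouse as human DE genes), activation-score ranking,
cytokine clustering/modelling, and the assay statistics — writing their
tables under `results/`:

```bash
for s in analysis/0*.py; do python "$s"; done
```

A `xenorna` console command exposes the same steps for file-based use
(`xenorna simulate reads`, `xenorna classify`, `xenorna diffexp`, …);
see `xenorna --help`.

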