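# almask

Probabilistic masking of protein multiple sequence alignments.

A multiple sequence alignment is a hypothesis of positional homology, not
an observation: every column asserts that its residues descend from one
ancestral position, and in divergent or indel-rich regions that assertion
is often wrong.  Columns of dubious homology inject noise into downstream
phylogenetic inference, and removing ("masking") them — or down-weighting
them — is standard practice before tree building.  `almask` makes that
step objective: instead of conservation heuristics or sliding windows, it
assigns every column a confidence score in [0, 1] derived from an
explicit probabilistic model of pairwise sequence alignment.

It is written for phylogeneticists and comparative genomicists who run
alignment pipelines at scale and want a principled, scriptable masking
step (hard masking, or per-column integer weights for maximum-likelihood
tree programs that accept a column-weight file).

## The model

**Pairwise posterior homology.**  For each pair of sequences (gaps
removed), a pair hidden Markov model with a match state M, short-gap
states X/Y and long-gap extension states LX/LY emits the two sequences
jointly.  Match emissions are joint residue probabilities
`p(a, b) = π_a · PAM_n[a → b]` derived from the Dayhoff substitution
process (PAM120 by default); gap states emit background frequencies.  The
forward–backward algorithm gives, for residues x and y,

    Pr[x ◊ y] = P(all alignments passing through match (x, y)) / P(all alignments)

— the posterior probability that x and y are homologous *over the whole
alignment space* of the pair, not in any single optimal alignment.

**Tree-weighted sum of pairs.**  Sequence pairs are not independent: two
near-identical sequences agree trivially, and pairs whose evolutionary
paths overlap are correlated.  `almask` builds a neighbor-joining guide
tree from corrected pairwise distances and distributes each branch length
`w_e` among the pairs whose path crosses that branch, using per-side
correlation weights `lw`/`rw` (an equal-split scheme, each side summing
to 1).  A pair's weight is

    w_ij = sqrt( Σ_{e ∈ path(i,j)} w_e · lw_i(e) · rw_j(e) )

and the confidence of column C is the normalised weighted sum of pairs

    S(C) = Σ_{(i,j)} w_ij · P_ij(C) / Σ_{(i,j)} w_ij ,

where `P_ij(C)` is the match posterior of the two residues in C (zero if
either is a gap).  Scores therefore lie in [0, 1]; gappy and ambiguous
columns score low.  Columns with `S(C) ≥ cutoff` (default 0.4) are kept.

**Pair sampling.**  Full scoring costs `O(N² L²)`.  For large families a
seeded uniform sample of at least N of the N(N−1)/2 pairs reproduces the
masking decisions almost exactly at a fraction of the cost
(`--sample N`).

The package also ships the evaluation toolkit (masking sensitivity and
specificity against a true alignment, and the discrepancy fraction
between two alternative alignments of the same sequences) plus a
protein-family simulator with site-specific rates and indels that emits
true alignments for benchmarking — see `docs/methods.md`.

## Worked example

Simulate a small divergent family with a known true alignment, score it,
mask it, and export tree-program column weights:

```sh
almask simulate --taxa 8 --length 120 --divergence 1.1 --seed 7 \
    --out-alignment true.fa --out-sequences seqs.fa
almask score --in true.fa --scores-out scores.txt --masked-out masked.fa \
    --weights-out weights.txt --tree-out guide.nwk --cutoff 0.4
```

which logs

```
almask: true alignment: 8 sequences x 132 columns
almask: read 8 sequences x 132 columns from true.fa
almask: guide tree written to guide.nwk
almask: scored 132 columns using 28 pairs (0.4 s)
almask: kept 115/132 columns at cutoff 0.40
```

`scores.txt` holds one confidence per column (`0.977182`, `0.963156`,
`0.933906`, `0.895180`, …): this family's columns are mostly confidently
homologous, and the 17 columns scoring below 0.4 — the indel-riddled ones
— are dropped from `masked.fa`.  `weights.txt` holds the same information
as integers (`round(score · 100)`) for weighted-likelihood tree building.

Benchmarking the masking against the (here, identical) reference:

```sh
almask benchmark --test true.fa --ref true.fa --scores scores.txt --cutoff 0.4
```

```
sensitivity	0.980849	3133
specificity	nan	3133
```

98.1% of the correctly aligned residue pairs sit in kept columns;
specificity is undefined (with a warning) because a test alignment equal
to its reference contains no incorrectly aligned pairs.  The same metrics
are available programmatically (`almask.masking_sensitivity`,
`almask.masking_specificity`, `almask.discrepancy_fraction`).

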