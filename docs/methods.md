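# Methods

This note documents the models, parameter choices and numerical decisions
behind `almask`, and what the synthetic benchmarks do and do not show.

## Pair HMM

### State space

Five emitting states: match `M` (emits one residue of each sequence),
short-gap states `X`/`Y` (emit a residue of one sequence against a gap in
the other) and long-gap extensions `LX`/`LY`.  Long gaps are entered only
through the corresponding short-gap state, and there is no direct
`X <-> Y` transition (two opposite gaps may not abut without an
intervening match).  A single long-gap state cannot record which sequence
carries the gap, so the long-gap machinery is a symmetric pair; gap
lengths are consequently a two-component geometric mixture, which matches
the empirically heavy tail of indel lengths better than one geometric.

### Transitions

All values configurable (`--config`, `default_params` keyword arguments):

| parameter     | default | meaning                                            |
| ------------- | ------- | -------------------------------------------------- |
| `gap_open`    | 0.02    | M→X and M→Y                                        |
| `gap_extend`  | 0.6     | X→X, Y→Y; mean short gap 1/(1−0.6) = 2.5 residues  |
| `long_open`   | 0.1     | X→LX, Y→LY                                         |
| `long_extend` | 0.9     | LX→LX, LY→LY; mean long-gap extension 10 residues  |
| `tau`         | 0.005   | per-step termination, 1/(mean emitted length 200)  |

Remaining row mass returns to `M`; each row plus `tau` sums to 1 exactly
(validated to 1e-12).  The start distribution is the stationary
distribution of the transition matrix conditioned on not terminating, so
the model is approximately position-homogeneous.  These are deliberately
moderate, protein-scale settings — the column scores are ratios of path
masses and are fairly insensitive to `tau`.

### Emissions

Match emissions are the symmetric joint distribution
`p(a, b) = π_a · PAM_n[a → b]`, gap emissions the background `π`.  The
PAM process is built from the shipped Dayhoff exchangeabilities and
equilibrium frequencies (`src/almask/data/*.txt`, plain text, residue
order ARNDCQEGHILKMFPSTWYV): the normalised reversible rate matrix `Q` is
scaled so one time unit is one expected substitution per site, `t₁` is
solved so that `expm(Q t₁)` substitutes 1% of sites (the PAM unit), and
`PAM_n = expm(n t₁ Q)`, identically `PAM₁ⁿ`.  Default distance PAM120
(appropriate for the moderate divergences where masking matters);
PAM30/60/160/250 selectable.  Ambiguity codes are accepted on input: B
and Z emit the unweighted mean of their member residues' emissions, X the
background mixture; gaps may only appear in the alignment, never inside a
pair-HMM input.

### Posterior decoding and numerics

`Pr[x ◊ y]` is computed by forward–backward.  The DP runs in probability
space on *odds ratios*: every emission is divided by the background
probability of the residues it emits.  Each complete path emits every
residue exactly once, so this divides all path probabilities by one
constant — posteriors are unchanged and the log full probability is
recovered by adding the background log-mass back.  Without the transform,
raw probabilities underflow for long dissimilar pairs (the within-row
dynamic range exceeds 1e308); with it, cells compare alignment quality
only.  Per-row max-rescaling (log-accumulated) guards the remainder; a
cell that still underflows is one whose true posterior is below ~1e-300.
Cell-wise log-sum-exp would be numerically equivalent but an order of
magnitude slower; the kernels are numba-compiled and exact (no banding),
costing O(m·n) time and memory per pair.  Posteriors are validated
against exhaustive path enumeration to 1e-9 in the test suite.

Memory per pair is ~5 double matrices of (m+1)(n+1); pairs of a few
thousand residues are comfortable, and tests exercise 1500-residue pairs.

## Guide tree and pair weights

* Distances: mismatch fraction `p` over columns where neither sequence is
  gapped, corrected as `d = −ln(1 − p − 0.2 p²)`; pairs at `p ≥ 0.85`
  (where the correction diverges) are clamped to `d = 5.203`.  A pair
  with no comparable column is an error, not a guess.  Guide-tree quality
  only needs coarse accuracy, so a fast corrected distance is preferred
  over model fitting.
* Tree: Saitou–Nei neighbor joining (scikit-bio), negative branch
  estimates clamped to zero; `N = 2` degenerates to a single branch of
  length `d₁₂`.  A user tree (`--tree-in`, newick, leaf names matching
  the FASTA ids) replaces the internal one; degree-2 nodes from rooted
  inputs are harmless (they split a branch without changing any weight).
* Correlation weights: for a branch `e`, each side's subtree is rooted at
  the branch endpoint and every node splits its incoming share equally
  among its child subtrees; leaf weights on each side sum to 1.  This
  equal-split recursion down-weights members of dense clades — exactly
  the redundancy the weighting must correct.  Branch-length-proportional
  splitting would be a plausible alternative; equal split was chosen for
  robustness to the noisy short branches NJ produces inside clades.
* Pair weights: `w_ij² = Σ_e w_e · lw_i(e) · rw_j(e)` over the path
  between i and j.  Because the per-side weights sum to 1, each branch's
  length is fully distributed over the pairs crossing it.  Identical
  sequences (zero-length path) get weight 0 and contribute nothing; in
  the degenerate case where *all* pairs have weight 0 (an alignment of
  identical sequences) the scorer falls back to uniform pair weights
  rather than reporting zero confidence for perfect columns.

## Column scores, masking, export

`S(C) = Σ w_ij P_ij(C) / Σ w_ij` over the pair set in use.  A pair whose
residue is gapped in C contributes 0 to the numerator but its weight
stays in the denominator: the score is "probability-weighted support from
all informative pairs", and heavily gapped columns — precisely the
regions masking targets — score low.  The denominator normalisation is
what pins scores to [0, 1].

Masking keeps columns with `S(C) ≥ cutoff` (default 0.4, a good
sensitivity/specificity balance on the synthetic benchmarks; 0.4–0.6 all
behave reasonably).  Scores are written one per line at 6 decimals;
integer column weights are `round(score · scale)` (default scale 100) on
a single whitespace-separated line, the dialect ML tree programs accept.

Pair sampling draws uniformly without replacement, never fewer than N
pairs (a sample covering each sequence once on average), clamped with a
warning to all pairs if more are requested.  All randomness flows from
one seed; identical inputs and seed give bit-identical scores.

## Synthetic families

The simulator provides ground truth the real world cannot: the true
alignment (exact positional homology) alongside the ungapped sequences.

* Root sequence drawn from the Dayhoff background; evolution along a
  birth–death tree (birth 1.0, death 0.0) or a user tree.
* Site rates: gamma with shape 1.0, normalised to mean 1 — strong,
  realistic heterogeneity (conserved motifs next to fast loops).
* Substitution: per site, `P = expm(Q · r_k · rate_scale · t)` via one
  eigendecomposition of Q.
* Indels: Poisson events at 0.02 per substitution per site, insertion or
  deletion equally likely, geometric lengths of mean 2.0, inserted
  residues drawn from the background with fresh rates.  These values give
  simulated families whose alignments grow ~10–40% beyond the root
  length — gap densities comparable to real divergent marker-gene
  families; substantially higher event rates produce majority-gap
  alignments unlike anything a curator would score.
* Homology tracking: every site carries a persistent identity; the true
  alignment has one column per surviving site, ordered by insertion
  history.  Degapping row i reproduces the emitted sequence i exactly.

`rate_scale` is calibrated analytically: given the tree's path lengths
and the realised site-rate draw, the expected corrected mean pairwise
distance is a closed-form, monotone function of the scale (from the
eigendecomposition of Q), and a root find hits the requested divergence.
A simulated family then deviates from the target only by realisation
noise and the small downward/upward pull of indels (a few percent each);
the default working point is 1.1 substitutions/site, a divergence at
which masking demonstrably matters.

`shuffle_gap_placement` emulates *realignment uncertainty*: it picks a
few gap-rich windows (2 per 100 columns, width 15, sampled proportionally
to gap content) and redistributes every row's gaps uniformly within each
window, preserving residue order.  This mirrors how alternative
alignments of the same sequences (e.g. a head-to-tail versus
tail-to-head run of one aligner) actually differ: identical over most of
their length, regionally scrambled around indels.  Perturbing every gap
run slightly instead spreads damage so thinly that no column's score
drops below the cutoff, which defeats the purpose of a masking benchmark.

### What the synthetic benchmarks show — and don't

Passing tests show the pipeline is internally coherent: posteriors match
brute-force enumeration; probability mass is conserved everywhere;
sampled scoring reproduces full-scoring masking decisions on ≥95% of
columns at the study conditions (20 families, N=50, ~300 sites, ~1.1
substitutions/site); sensitivity/specificity trade off monotonically with
the cutoff; and masking lowers the kept-column discrepancy between
alternative gap placements in ≥9/10 families.  They do **not** show
performance on real data: the simulator's indel process is simpler than
real evolution (no rate variation of indels along the sequence, no
domain-level events), its substitution process matches the scorer's
emission family (Dayhoff) rather than challenging it, and the
realignment perturbation is a stylised model of aligner disagreement.
Problem sizes in the test suite (families of 5–50 sequences, 60–300
sites) were chosen as the smallest at which the studied effects are
clearly resolved.

## Evaluation metrics

All metrics reduce alignments to sets of residue pairs in ungapped
coordinates, so differently gapped alignments of the same sequences are
comparable.  Sensitivity = fraction of correctly aligned pairs (present
in both test and reference) in columns marked reliable; specificity =
fraction of incorrectly aligned pairs in columns marked unreliable; each
is NaN-with-warning when its denominator is empty.  The discrepancy
fraction between two alignments is the Jaccard distance of their pair
sets — symmetric, bounded, a metric, and equal to the intuitive value in
both degenerate cases (0 for identical pairings, 1 for disjoint ones).
Its masked variant restricts each alignment's pair set to its own kept
columns while keeping original residue coordinates.

## Known limitations

* Transition parameters are defaults, not fitted; no Baum–Welch training.
* Protein only; no DNA model, no Viterbi alignment output.
* The score is global per column: a column misaligned overall may still
  contain correctly aligned subgroups, which a clade-aware local score
  would detect; that is out of scope here.
* NJ tie handling follows the underlying library; outputs are
  deterministic for identical inputs but ties are not broken by any
  documented rule.
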