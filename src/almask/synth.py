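"""Desk-scale protein-family simulator.

Evolves protein sequences along a phylogeny under the Dayhoff substitution
process with site-specific rates and a simple indel process, tracking
positional homology exactly.  The emitted *true* alignment is the ground
truth for the masking benchmarks; the emitted ungapped sequences are what
an aligner (or the scorer, directly) consumes.

Model summary
-------------
* Root sequence drawn from the Dayhoff equilibrium frequencies.
* Site k substitutes along a branch of length t according to
  ``P = expm(Q * r_k * rate_scale * t)``; per-site rates r_k are gamma
  distributed with mean 1 (shape ``site_rate_shape``).
* Indel events are Poisson along each branch with expectation
  ``indel_rate * rate_scale * t * L`` (events per substitution), equally
  likely insertions or deletions, with geometric lengths of mean
  ``indel_mean_length``; inserted residues are drawn from the background
  and receive freshly drawn site rates.

Everything is driven by a single integer seed; identical seeds give
byte-identical output.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import dendropy
import numpy as np

from .guide_weights import GuideTree, pairwise_distances
from .msa_io import AMINO_ACIDS, Alignment
from .substitution import background_frequencies, transition_matrix


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated protein family."""

    tree: GuideTree
    root_length: int = 300
    rate_scale: float = 1.0
    indel_rate: float = 0.02
    indel_mean_length: float = 2.0
    site_rate_shape: float = 1.0
    site_rates: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.root_length < 1:
            raise ValueError("root_length must be >= 1")
        if self.rate_scale <= 0:
            raise ValueError("rate_scale must be positive")
        if self.site_rates is not None:
            r = np.asarray(self.site_rates, dtype=float)
            if r.shape != (self.root_length,) or np.any(r < 0):
                raise ValueError("site_rates must be non-negative, one per site")
            if abs(r.mean() - 1.0) > 1e-9:
                raise ValueError("site_rates must average to 1")


def random_tree(n_taxa: int, seed: int, birth_rate: float = 1.0,
                death_rate: float = 0.0) -> GuideTree:
    """Random birth–death tree with ``n_taxa`` leaves (labels s1..sN)."""
    rng = random.Random(seed)
    dt = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=death_rate,
        num_extant_tips=n_taxa,
        rng=rng,
    )
    for k, leaf in enumerate(dt.leaf_node_iter(), start=1):
        leaf.taxon.label = f"s{k}"
    return GuideTree.from_newick(dt.as_string(schema="newick"))


def _leaf_order(tree: GuideTree) -> list[int]:
    return sorted(tree.leaf_labels, key=lambda k: tree.leaf_labels[k])


def simulate(config: SimConfig) -> tuple[Alignment, dict[str, str]]:
    """Evolve one family; returns the true alignment and ungapped sequences.

    Homology bookkeeping: every residue site carries a persistent identity;
    the true alignment has one column per site that survives in at least
    one leaf, in the order implied by the insertion history.
    """
    rng = np.random.default_rng(config.seed)
    pi = background_frequencies()
    L0 = config.root_length

    if config.site_rates is not None:
        rates0 = np.asarray(config.site_rates, dtype=float)
    else:
        rates0 = _draw_rates(rng, L0, config.site_rate_shape)

    site_rate: dict[int, float] = {k: float(rates0[k]) for k in range(L0)}
    column_order: list[int] = list(range(L0))
    next_id = [L0]

    root_seq = list(range(L0))
    root_draw = _categorical(rng, np.tile(pi, (L0, 1)))
    root_state = {k: int(root_draw[k]) for k in root_seq}

    # pick a root for the traversal: any internal node (or leaf for N = 2)
    root = next(
        (k for k in range(config.tree.n_nodes)
         if k not in config.tree.leaf_labels),
        0,
    )

    leaf_seqs: dict[str, tuple[list[int], dict[int, int]]] = {}

    def evolve_branch(seq: list[int], state: dict[int, int], t: float):
        seq = list(seq)
        state = dict(state)
        tau = config.rate_scale * t
        if tau > 0 and seq:
            rates = np.array([site_rate[s] for s in seq])
            pmats = transition_matrix(tau, rates)  # (L, 20, 20)
            cur = np.array([state[s] for s in seq])
            rows = pmats[np.arange(len(seq)), cur]
            new_states = _categorical(rng, rows)
            for idx, s in enumerate(seq):
                state[s] = int(new_states[idx])
            n_events = rng.poisson(config.indel_rate * tau * len(seq))
            for _ in range(n_events):
                if not seq:
                    break
                length = int(rng.geometric(1.0 / config.indel_mean_length))
                if rng.random() < 0.5:  # deletion
                    start = int(rng.integers(len(seq)))
                    removed = seq[start:start + length]
                    del seq[start:start + length]
                    for s in removed:
                        state.pop(s, None)
                else:  # insertion
                    pos = int(rng.integers(len(seq) + 1))
                    new_ids = list(range(next_id[0], next_id[0] + length))
                    next_id[0] += length
                    new_rates = _draw_rates(rng, length, config.site_rate_shape,
                                            normalise=False)
                    new_aas = _categorical(rng, np.tile(pi, (length, 1)))
                    for s, r, aa in zip(new_ids, new_rates, new_aas):
                        site_rate[s] = float(r)
                        state[s] = int(aa)
                    # place new columns in the global order right after the
                    # column preceding the insertion point in this lineage
                    if pos == 0:
                        gpos = 0 if not seq else column_order.index(seq[0])
                    else:
                        gpos = column_order.index(seq[pos - 1]) + 1
                    column_order[gpos:gpos] = new_ids
                    seq[pos:pos] = new_ids
        return seq, state

    def walk(node: int, parent: int, seq: list[int], state: dict[int, int]):
        if node in config.tree.leaf_labels:
            leaf_seqs[config.tree.leaf_labels[node]] = (seq, state)
        for nb, eid in config.tree.adj[node]:
            if nb == parent:
                continue
            t = config.tree.edges[eid][2]
            child_seq, child_state = evolve_branch(seq, state, t)
            walk(nb, node, child_seq, child_state)

    walk(root, -1, root_seq, root_state)

    ids = tuple(config.tree.leaf_labels[k] for k in _leaf_order(config.tree))
    alive = set()
    for sid in ids:
        alive.update(leaf_seqs[sid][0])
    columns = [c for c in column_order if c in alive]
    col_pos = {c: k for k, c in enumerate(columns)}

    rows = []
    for sid in ids:
        seq, state = leaf_seqs[sid]
        row = ["-"] * len(columns)
        for s in seq:
            row[col_pos[s]] = AMINO_ACIDS[state[s]]
        rows.append("".join(row))
    aln = Alignment(ids, tuple(rows))
    ungapped = {sid: aln.degapped_row(k) for k, sid in enumerate(ids)}
    return aln, ungapped


def _draw_rates(rng: np.random.Generator, n: int, shape: float,
                normalise: bool = True) -> np.ndarray:
    r = rng.gamma(shape, 1.0 / shape, size=n)
    if normalise and n > 0:
        r = r / r.mean()
    return r


def mean_pairwise_divergence(aln: Alignment) -> float:
    """Mean corrected pairwise distance (substitutions/site) of a family."""
    if aln.N < 2:
        raise ValueError("need at least two sequences")
    d = pairwise_distances(aln)
    iu = np.triu_indices(aln.N, k=1)
    return float(d[iu].mean())


def calibrate_rate_scale(
    tree: GuideTree,
    root_length: int = 300,
    target: float = 1.1,
    seed: int = 0,
    site_rate_shape: float = 1.0,
) -> float:
    """Rate scale at which the family's expected mean pairwise divergence
    equals ``target`` substitutions/site.

    Works analytically rather than by simulate-and-measure: for a pair at
    path length T and a site of relative rate r, the expected mismatch
    probability under the substitution model is ``1 - sum_a pi_a
    P_aa(r * scale * T)``, available in closed form from the
    eigendecomposition of Q.  Averaging over the realised site-rate draw
    (the same draw the production run will use, because it consumes the
    seed's stream first) and applying the same saturation-clamped
    correction as the distance measurement gives a smooth, deterministic
    scale -> divergence map to root-find on.  The production run then
    deviates from the target only by single-realisation noise and the
    small effect of indels.
    """
    from scipy.optimize import brentq

    from .guide_weights import MAX_DISTANCE, MAX_MISMATCH
    from .substitution import _eigen, background_frequencies

    rng = np.random.default_rng(seed)
    rates = _draw_rates(rng, root_length, site_rate_shape)
    lam, v, vinv = _eigen()
    pi = background_frequencies()
    # g(t) = sum_a pi_a P_aa(t) = sum_m c_m exp(lam_m t)
    c = np.einsum("a,am,ma->m", pi, v, vinv)

    leaves = _leaf_order(tree)
    paths = []
    for a in range(len(leaves)):
        for b in range(a + 1, len(leaves)):
            path = tree.path_edges(leaves[a], leaves[b])
            paths.append(sum(tree.edges[e][2] for e in path))
    paths = np.array(paths)
    if paths.size == 0 or paths.max() == 0.0:
        raise ValueError("tree has no positive leaf-to-leaf path length")
    if paths.size > 300:  # subsample pairs; the mean is what matters
        paths = np.random.default_rng(seed).choice(paths, 300, replace=False)

    def expected_divergence(scale: float) -> float:
        tau = np.outer(paths, rates) * scale  # (pairs, sites)
        g = np.exp(tau[..., None] * lam[None, None, :]) @ c
        p = 1.0 - g.mean(axis=1)
        d = np.where(
            p >= MAX_MISMATCH,
            MAX_DISTANCE,
            -np.log(np.clip(1.0 - p - 0.2 * p * p, 1e-12, None)),
        )
        return float(d.mean())

    d0 = float(paths.mean())
    lo, hi = 1e-3 * target / d0, 50.0 * target / d0
    return float(
        brentq(lambda s: expected_divergence(s) - target, lo, hi, xtol=1e-10)
    )


def _mean_leaf_path(tree: GuideTree) -> float:
    leaves = _leaf_order(tree)
    tot, cnt = 0.0, 0
    for a in range(len(leaves)):
        for b in range(a + 1, len(leaves)):
            path = tree.path_edges(leaves[a], leaves[b])
            tot += sum(tree.edges[e][2] for e in path)
            cnt += 1
    return tot / cnt if cnt else 1.0


def simulate_family(
    n_taxa: int = 50,
    root_length: int = 300,
    divergence: float = 1.1,
    indel_rate: float = 0.02,
    indel_mean_length: float = 2.0,
    site_rate_shape: float = 1.0,
    seed: int = 0,
) -> tuple[Alignment, dict[str, str], SimConfig]:
    """One random family at a requested mean pairwise divergence.

    Generates a birth–death tree, calibrates ``rate_scale`` so that the
    substitution-only divergence matches ``divergence``, then simulates
    with indels.
    """
    tree = random_tree(n_taxa, seed=seed)
    scale = calibrate_rate_scale(
        tree, root_length=root_length, target=divergence, seed=seed + 1,
        site_rate_shape=site_rate_shape,
    )
    cfg = SimConfig(
        tree=tree,
        root_length=root_length,
        rate_scale=scale,
        indel_rate=indel_rate,
        indel_mean_length=indel_mean_length,
        site_rate_shape=site_rate_shape,
        seed=seed + 1,
    )
    aln, ungapped = simulate(cfg)
    return aln, ungapped, cfg


def shuffle_gap_placement(aln: Alignment, seed: int = 0,
                          region_width: int = 15,
                          regions_per_100: float = 2.0) -> Alignment:
    """Emulate realignment noise by re-placing gaps within indel windows.

    Alternative alignments of the same sequences (e.g. head vs tail runs
    of one aligner) agree over most of their length and disagree
    *regionally*, around indel placement, where every sequence's gaps are
    uncertain at once.  This perturbation picks gap-containing windows
    (``regions_per_100`` per 100 columns, width ``region_width``, sampled
    proportionally to gap content) and, within each, independently
    redistributes every row's gap positions uniformly while preserving
    residue order — so degapped sequences are untouched but positional
    homology inside the windows is scrambled.
    """
    rng = np.random.default_rng(seed)
    rows = [list(r) for r in aln.rows]
    L = aln.L
    if L == 0:
        return aln
    gap_count = np.array(
        [sum(1 for r in rows if r[k] == "-") for k in range(L)], dtype=float
    )
    # weight window starts by the gaps they contain
    width = min(region_width, L)
    win = np.convolve(gap_count, np.ones(width), mode="valid")
    if win.sum() == 0:
        return aln
    n_regions = max(1, int(round(regions_per_100 * L / 100.0)))
    starts = rng.choice(len(win), size=min(n_regions, len(win)),
                        replace=False, p=win / win.sum())
    for w0 in sorted(int(s) for s in starts):
        w1 = w0 + width
        for r in rows:
            seg = r[w0:w1]
            residues = [c for c in seg if c != "-"]
            n_gaps = len(seg) - len(residues)
            if n_gaps == 0:
                continue
            gap_pos = set(
                int(g) for g in rng.choice(len(seg), size=n_gaps, replace=False)
            )
            it = iter(residues)
            r[w0:w1] = [
                "-" if k in gap_pos else next(it) for k in range(len(seg))
            ]
    return Alignment(aln.ids, tuple("".join(r) for r in rows))


def _categorical(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """One draw per row of ``probs`` (rows renormalised defensively)."""
    p = np.clip(probs, 0.0, None)
    p = p / p.sum(axis=1, keepdims=True)
    u = rng.random(p.shape[0])
    draw = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return np.minimum(draw, p.shape[1] - 1)
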