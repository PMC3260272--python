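import numpy as np
import pytest

from almask.guide_weights import (
    MAX_DISTANCE,
    GuideTree,
    build_nj_tree,
    correlation_weights,
    pair_weights,
    pairwise_distances,
    tree_from_alignment,
)
from almask.msa_io import Alignment


def test_identical_rows_distance_zero():
    aln = Alignment(("a", "b"), ("ACDE", "ACDE"))
    assert pairwise_distances(aln)[0, 1] == 0.0


def test_kimura_correction_value():
    # 1 mismatch in 10 comparable columns: p = 0.1,
    # d = -ln(1 - 0.1 - 0.2*0.01) = -ln(0.898)
    aln = Alignment(("a", "b"), ("ACDEFGHIKL", "ACDEFGHIKV"))
    assert pairwise_distances(aln)[0, 1] == pytest.approx(0.1075852, abs=1e-6)


def test_gapped_columns_excluded():
    aln = Alignment(("a", "b"), ("AC-E", "ACD-"))
    # only columns 1-2 comparable, both match
    assert pairwise_distances(aln)[0, 1] == 0.0


def test_saturated_pair_clamped():
    aln = Alignment(("a", "b"), ("AAAAAAAAAA", "CCCCCCCCCC"))
    assert pairwise_distances(aln)[0, 1] == pytest.approx(MAX_DISTANCE)


def test_no_comparable_columns_error():
    aln = Alignment(("a", "b"), ("A--", "-CC"))
    with pytest.raises(ValueError, match="'a' and 'b'"):
        pairwise_distances(aln)


def test_distances_permutation_equivariant():
    rows = ("ACDEFG", "ACDEYG", "WCDEFG", "ACDEFW")
    aln = Alignment(("a", "b", "c", "d"), rows)
    d = pairwise_distances(aln)
    perm = [2, 0, 3, 1]
    aln2 = Alignment(
        tuple(aln.ids[k] for k in perm), tuple(rows[k] for k in perm)
    )
    d2 = pairwise_distances(aln2)
    for i, pi_ in enumerate(perm):
        for j, pj in enumerate(perm):
            assert d2[i, j] == d[pi_, pj]


def test_nj_two_sequences():
    t = build_nj_tree(np.array([[0.0, 0.5], [0.5, 0.0]]), ("a", "b"))
    assert len(t.edges) == 1
    assert t.edges[0][2] == pytest.approx(0.5)


def test_nj_recovers_additive_quartet():
    # ((A:1,B:2):1,(C:3,D:4)) -> additive distances
    d = np.array(
        [
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ],
        dtype=float,
    )
    ids = ("A", "B", "C", "D")
    t = build_nj_tree(d, ids)
    leaf_of = {lbl: k for k, lbl in t.leaf_labels.items()}
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i >= j:
                continue
            path = t.path_edges(leaf_of[a], leaf_of[b])
            plen = sum(t.edges[e][2] for e in path)
            assert plen == pytest.approx(d[i, j], abs=1e-9)


def test_nj_rejects_bad_matrix():
    with pytest.raises(ValueError):
        build_nj_tree(np.array([[0.0, -1.0], [-1.0, 0.0]]), ("a", "b"))
    with pytest.raises(ValueError):
        build_nj_tree(np.array([[0.0, 1.0], [2.0, 0.0]]), ("a", "b"))


def test_correlation_weights_single_leaf_and_cherry():
    t = GuideTree.from_newick("((A:1,B:1):1,C:2);")
    for eid, (u, v, w) in enumerate(t.edges):
        part = correlation_weights(t, eid)
        assert sum(part.lw.values()) == pytest.approx(1.0)
        assert sum(part.rw.values()) == pytest.approx(1.0)
        if part.left == ("A", "B"):
            assert part.lw == {"A": 0.5, "B": 0.5}
            assert part.rw == {"C": 1.0}


def test_correlation_weights_equal_split_three_leaves():
    # side ((A,B),C) of the central branch: A 0.25, B 0.25, C 0.5
    t = GuideTree.from_newick("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);")
    for eid in range(len(t.edges)):
        part = correlation_weights(t, eid)
        if part.left == ("A", "B", "C"):
            assert part.lw == pytest.approx({"A": 0.25, "B": 0.25, "C": 0.5})
            assert part.rw == pytest.approx({"D": 0.5, "E": 0.5})
            break
    else:
        pytest.fail("central branch not found")


def test_pair_weights_two_leaves_sqrt_of_length():
    t = build_nj_tree(np.array([[0.0, 0.49], [0.49, 0.0]]), ("a", "b"))
    w = pair_weights(t, ("a", "b"))
    assert w[0, 1] == pytest.approx(np.sqrt(0.49))


def test_pair_weights_three_leaf_hand_expansion():
    # star (A:0.3, B:0.5, C:0.1): w_AB^2 = 0.3*0.5 + 0.5*0.5 = 0.4, etc.
    t = GuideTree.from_newick("(A:0.3,B:0.5,C:0.1);")
    w = pair_weights(t, ("A", "B", "C"))
    assert w[0, 1] == pytest.approx(np.sqrt(0.4))
    assert w[0, 2] == pytest.approx(np.sqrt(0.2))
    assert w[1, 2] == pytest.approx(np.sqrt(0.3))


def test_pair_weights_symmetric_quartet():
    t = GuideTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    ids = ("A", "B", "C", "D")
    w = pair_weights(t, ids)
    assert np.allclose(w, w.T)
    cross = [w[0, 2], w[0, 3], w[1, 2], w[1, 3]]
    assert max(cross) - min(cross) < 1e-12
    assert w[0, 1] == pytest.approx(w[2, 3])


def test_branch_shares_fully_distribute_each_branch():
    t = GuideTree.from_newick("(((A:1,B:2):0.5,C:1):0.7,(D:2,E:1):0.3);")
    for eid in range(len(t.edges)):
        part = correlation_weights(t, eid)
        total = sum(
            part.lw[i] * part.rw[j] for i in part.left for j in part.right
        )
        assert total == pytest.approx(1.0)


def test_pair_weights_scale_as_sqrt_of_branch_lengths():
    nwk = "(((A:1,B:2):0.5,C:1):0.7,(D:2,E:1):0.3);"
    t1 = GuideTree.from_newick(nwk)
    k = 4.0
    t2 = GuideTree.from_newick(
        "(((A:4,B:8):2,C:4):2.8,(D:8,E:4):1.2);"
    )
    ids = tuple(sorted(t1.leaf_labels.values()))
    assert np.allclose(
        pair_weights(t2, ids), np.sqrt(k) * pair_weights(t1, ids)
    )


def test_close_cherry_weighed_down():
    """A near-identical cherry C-D carries less weight than a pair
    spanning the deep split."""
    t = GuideTree.from_newick("((C:0.01,D:0.01):1,(A:1,B:1):1);")
    ids = ("A", "B", "C", "D")
    w = pair_weights(t, ids)
    w_cd = w[2, 3]
    w_ac = w[0, 2]
    assert w_cd < w_ac


def test_zero_length_path_zero_weight():
    aln = Alignment(("a", "b", "c"), ("ACDEFGHIKL", "ACDEFGHIKL", "ACDEFGYIKV"))
    t = tree_from_alignment(aln)
    w = pair_weights(t, aln.ids)
    assert w[0, 1] == 0.0
    assert w[0, 2] > 0.0


def test_newick_roundtrip_preserves_metric():
    nwk = "(((A:1,B:2):0.5,C:1):0.7,(D:2,E:1):0.3);"
    t1 = GuideTree.from_newick(nwk)
    t2 = GuideTree.from_newick(t1.to_newick())
    ids = tuple(sorted(t1.leaf_labels.values()))
    assert np.allclose(pair_weights(t1, ids), pair_weights(t2, ids))


def test_pair_weights_id_mismatch_error():
    t = GuideTree.from_newick("(A:1,B:1);")
    with pytest.raises(ValueError, match="do not match"):
        pair_weights(t, ("A", "X"))
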