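"""Tests for distances, UPGMA, Robinson-Foulds, nulls and supports."""

import itertools

import numpy as np
import pytest

from hypercascade.cascade import CascadeError, build_site_graph
from hypercascade.lineage import DivisionModel, grow_tree
from hypercascade.reconstruct import (
    BarcodeMatrix,
    barcode_distances,
    benchmark_sweep,
    clade_support,
    cophenetic_group_distance,
    mean_tip_depth,
    reconstruct_lineage,
    robinson_foulds_normalized,
    scramble_barcodes,
    transfer_distance,
    upgma,
)
from hypercascade.simulate import EditModel


# ---------------------------------------------------------------------------
# distances


def test_hamming_examples():
    m = BarcodeMatrix(np.array([[0, 1, 1, 0], [0, 1, 0, 1], [0, 1, 1, 0]]), ["a", "b", "c"])
    d = barcode_distances(m)
    assert d[0, 1] == 2  # 0110 vs 0101
    assert d[0, 2] == 0  # identical rows
    assert (d == d.T).all() and (np.diag(d) == 0).all()


def test_triangle_inequality(rng):
    for _ in range(100):
        m = BarcodeMatrix(rng.integers(0, 2, (6, 15)), [f"t{i}" for i in range(6)])
        d = barcode_distances(m)
        for i, j, k in itertools.permutations(range(6), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


def test_duplicate_labels_rejected():
    with pytest.raises(CascadeError):
        BarcodeMatrix(np.zeros((2, 3)), ["x", "x"])


# ---------------------------------------------------------------------------
# UPGMA


def test_upgma_three_taxa_hand_example():
    d = np.array([[0.0, 2, 6], [2, 0, 6], [6, 6, 0]])
    t = upgma(d, ["A", "B", "C"])
    assert sorted(round(h, 9) for h in t.heights.values()) == [1.0, 3.0]
    assert t.leafset(3) == frozenset({"A", "B"})  # first merge is the cherry


def test_upgma_two_taxa_cherry():
    t = upgma(np.array([[0.0, 5.0], [5.0, 0.0]]), ["x", "y"])
    assert t.node_height(t.root) == pytest.approx(2.5)


def test_upgma_recovers_ultrametric_topology(rng):
    """On ultrametric input UPGMA returns the generating tree exactly and
    its cophenetic matrix refits the input."""
    for seed in range(5):
        r = np.random.default_rng(seed)
        n = 12
        # build a random ultrametric via a random coalescent-like merge order
        active = [frozenset([i]) for i in range(n)]
        coph = np.zeros((n, n))
        h = 0.0
        clades = []
        while len(active) > 1:
            h += float(r.uniform(0.5, 2.0))
            i, j = sorted(r.choice(len(active), 2, replace=False))
            a, b = active[i], active[j]
            for x in a:
                for y in b:
                    coph[x, y] = coph[y, x] = 2 * h
            merged = a | b
            clades.append(merged)
            active = [c for k, c in enumerate(active) if k not in (i, j)] + [merged]
        labels = [f"t{i:02d}" for i in range(n)]
        t = upgma(coph, labels)
        assert np.allclose(t.cophenetic, coph)
        got = {frozenset(labels[i] for i in c) for c in clades if 1 < len(c) < n}
        want = {c for c in t.clades().values() if 1 < len(c) < n}
        assert got == want


def test_upgma_rejects_nan():
    d = np.array([[0.0, np.nan], [np.nan, 0.0]])
    with pytest.raises(CascadeError):
        upgma(d, ["a", "b"])


def test_upgma_deterministic_under_ties():
    d = np.ones((5, 5)) - np.eye(5)
    t1 = upgma(d, list("edcba"))
    t2 = upgma(d, list("edcba"))
    assert t1.newick() == t2.newick()
    # first merge under the lexicographic rule is the (a, b) pair
    first = min(t1.children)
    assert t1.leafset(first) == frozenset({"a", "b"})


# ---------------------------------------------------------------------------
# Robinson-Foulds


def _caterpillar(labels):
    """Rooted caterpillar as a ReconstructedTree via chained distances."""
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                d[i, j] = 2.0 * max(i, j)
    return upgma(d, labels)


def test_rf_identity():
    t = _caterpillar(list("abcdef"))
    assert robinson_foulds_normalized(t, t) == 0.0


def test_rf_maximally_different_six_leaves():
    """A caterpillar and a maximally conflicting resolution share no
    nontrivial splits -> normalized RF = 1."""
    t1 = _caterpillar(list("abcdef"))
    # balanced tree pairing leaves from opposite ends of the caterpillar:
    # cherries (a,d), (b,e), (c,f) conflict with every caterpillar split
    labels = list("abcdef")
    d = np.full((6, 6), 8.0)
    np.fill_diagonal(d, 0.0)
    for x, y in [("a", "d"), ("b", "e"), ("c", "f")]:
        i, j = labels.index(x), labels.index(y)
        d[i, j] = d[j, i] = 2.0
    # join the (a,d) and (b,e) cherries below the root
    d[labels.index("a"), labels.index("b")] = d[labels.index("b"), labels.index("a")] = 4.0
    d[labels.index("a"), labels.index("e")] = d[labels.index("e"), labels.index("a")] = 4.0
    d[labels.index("d"), labels.index("b")] = d[labels.index("b"), labels.index("d")] = 4.0
    d[labels.index("d"), labels.index("e")] = d[labels.index("e"), labels.index("d")] = 4.0
    t2 = upgma(d, labels)
    assert robinson_foulds_normalized(t1, t2) == 1.0


def _five_leaf_topologies():
    """All 15 unrooted binary topologies on 5 leaves as dendropy trees."""
    import dendropy

    taxa = dendropy.TaxonNamespace(list("abcde"))
    newicks = set()
    # every unrooted 5-leaf binary tree is determined by its two cherries
    labels = list("abcde")
    for cherry1 in itertools.combinations(labels, 2):
        rest = [x for x in labels if x not in cherry1]
        for cherry2 in itertools.combinations(rest, 2):
            center = [x for x in rest if x not in cherry2][0]
            key = tuple(sorted([tuple(sorted(cherry1)), tuple(sorted(cherry2))]))
            if key in newicks:
                continue
            newicks.add(key)
    trees = []
    for (c1, c2) in sorted(newicks):
        nw = f"(({c1[0]},{c1[1]}),({c2[0]},{c2[1]}),{[x for x in labels if x not in c1 + c2][0]});"
        trees.append(dendropy.Tree.get(data=nw, schema="newick", taxon_namespace=taxa))
    assert len(trees) == 15
    return trees


def test_rf_agrees_with_bipartition_oracle_on_all_five_leaf_topologies():
    import dendropy
    from dendropy.calculate import treecompare

    trees = _five_leaf_topologies()
    for t1, t2 in itertools.combinations(trees, 2):
        a, b = t1.clone(), t2.clone()
        a.is_rooted = False
        b.is_rooted = False
        a.encode_bipartitions()
        b.encode_bipartitions()
        oracle = treecompare.symmetric_difference(a, b) / (2 * (5 - 3))
        assert robinson_foulds_normalized(t1, t2) == pytest.approx(oracle)


def test_rf_metric_properties_on_five_leaf_topologies():
    trees = _five_leaf_topologies()
    vals = {}
    for i, j in itertools.combinations(range(len(trees)), 2):
        v = robinson_foulds_normalized(trees[i], trees[j])
        assert v == pytest.approx(robinson_foulds_normalized(trees[j], trees[i]))
        assert 0.0 < v <= 1.0  # distinct topologies are at positive distance
        vals[(i, j)] = vals[(j, i)] = v
    for i in range(len(trees)):
        vals[(i, i)] = 0.0
    for i, j, k in itertools.permutations(range(6), 3):
        assert vals[(i, j)] <= vals[(i, k)] + vals[(k, j)] + 1e-12


def test_rf_leaf_set_mismatch():
    t1 = _caterpillar(list("abcd"))
    t2 = _caterpillar(list("abce"))
    with pytest.raises(CascadeError):
        robinson_foulds_normalized(t1, t2)


# ---------------------------------------------------------------------------
# scrambling


def test_scramble_preserves_column_sums(rng):
    m = BarcodeMatrix(rng.integers(0, 2, (12, 40)), [f"t{i}" for i in range(12)])
    s = scramble_barcodes(m, seed=3)
    assert (m.data.sum(axis=0) == s.data.sum(axis=0)).all()
    assert m.data.sum() == s.data.sum()


def test_scramble_destroys_tree_structure():
    """RF to ground truth worsens after scrambling in >= 95% of simulations."""
    g = build_site_graph(20)
    m = EditModel(variant="strict_hypercascade", layer_rates=(0.01,) * 4)
    worse = 0
    n_trials = 20
    for seed in range(n_trials):
        t = grow_tree(g, m, DivisionModel("exponential", 24.0), copies=3,
                      stop=("mean_depth", 6.0), seed=seed)
        if t.n_leaves < 8:
            n_trials -= 1
            continue
        recon, bm = reconstruct_lineage(t)
        rf0 = robinson_foulds_normalized(t, recon)
        scrambled = scramble_barcodes(bm, seed=seed + 1000)
        recon_s = upgma(barcode_distances(scrambled), scrambled.labels)
        rf1 = robinson_foulds_normalized(t, recon_s)
        if rf1 > rf0:
            worse += 1
    assert worse / n_trials >= 0.95


# ---------------------------------------------------------------------------
# cophenetic groups and tip depth


def test_cophenetic_two_clades():
    """Two clades = two groups: the cross-group mean equals the root merge
    distance (2x the root-adjacent height)."""
    d = np.array(
        [[0.0, 2, 8, 8], [2, 0, 8, 8], [8, 8, 0, 2], [8, 8, 2, 0]]
    )
    t = upgma(d, list("abcd"))
    groups = {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}
    out = cophenetic_group_distance(t, groups)
    assert out["mean_cophenetic"].iloc[0] == pytest.approx(2 * t.node_height(t.root))


def test_cophenetic_single_group_rejected():
    t = _caterpillar(list("abcd"))
    with pytest.raises(CascadeError):
        cophenetic_group_distance(t, {l: "only" for l in "abcd"})


def test_mean_tip_depth_balanced_and_caterpillar():
    # balanced 8-leaf tree: every tip has 3 internal ancestors
    d = np.zeros((8, 8))
    for i in range(8):
        for j in range(8):
            if i != j:
                lvl = (max(i, j) ^ min(i, j)).bit_length()  # differing level
                d[i, j] = 2.0 * lvl
    bal = upgma(d, [f"t{i}" for i in range(8)])
    assert mean_tip_depth(bal) == pytest.approx(3.0)
    cat = _caterpillar(list("abcd"))
    assert mean_tip_depth(cat) == pytest.approx((3 + 3 + 2 + 1) / 4)


# ---------------------------------------------------------------------------
# clade support


def test_clade_support_clean_data_all_one():
    data = np.zeros((6, 24), dtype=int)
    data[:3, :8] = 1
    data[3:, 8:16] = 1
    data[:2, 16:20] = 1
    m = BarcodeMatrix(data, list("abcdef"))
    _, sup = clade_support(m, n_boot=25, seed=0)
    assert np.allclose(sup["support"].to_numpy(), 1.0)


def test_clade_support_bounded(rng):
    m = BarcodeMatrix(rng.integers(0, 2, (8, 30)), [f"t{i}" for i in range(8)])
    _, sup = clade_support(m, n_boot=15, seed=1)
    assert ((sup["support"] >= 0) & (sup["support"] <= 1)).all()


def test_transfer_distance_exact_match():
    t = _caterpillar(list("abcdef"))
    for clade in t.clades().values():
        if 1 < len(clade) < 6:
            assert transfer_distance(clade, t) == 0


def test_clade_support_needs_four_taxa():
    m = BarcodeMatrix(np.eye(3, dtype=int), list("abc"))
    with pytest.raises(CascadeError):
        clade_support(m, n_boot=2)


# ---------------------------------------------------------------------------
# benchmark sweep


def test_benchmark_zero_rate_uninformative():
    df = benchmark_sweep(["hypercascade"], rates=[0.0], copies=[1], depths=[4.0],
                         n_replicates=3, seed=0)
    # with no signal, reconstruction is far from the truth
    assert df["mean_rf"].iloc[0] > 0.6


def test_benchmark_more_copies_not_worse():
    """Mean RF is non-increasing in copy number within 2 SE."""
    df = benchmark_sweep(["hypercascade"], rates=[0.01], copies=[1, 3],
                         depths=[6.0], n_replicates=8, seed=5)
    one = df[df.copies == 1].iloc[0]
    three = df[df.copies == 3].iloc[0]
    se = np.sqrt(one.se_rf**2 + three.se_rf**2)
    assert three.mean_rf <= one.mean_rf + 2 * se
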