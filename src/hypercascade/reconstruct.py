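"""Lineage reconstruction from endpoint barcodes and its benchmarks.

Barcode matrices (taxa x concatenated array features) are turned into
pairwise Hamming distances and clustered by UPGMA into a rooted ultrametric
tree.  Reconstructions are scored against ground truth with the normalized
Robinson-Foulds distance and against permutation nulls (column-scrambled
barcodes); transfer-bootstrap support, cophenetic group distances and tip
depths mirror the standard phylogenetic toolbox for these recorders.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .cascade import CascadeError, EditState, SiteGraph
from .lineage import DivisionModel, LineageTree, grow_tree
from .simulate import EditModel, make_control_model

# ---------------------------------------------------------------------------
# barcode matrices


@dataclass
class BarcodeMatrix:
    """Taxa x feature matrix of site states (0/1, or outcome labels)."""

    data: np.ndarray
    labels: list[str]
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise CascadeError("barcode matrix must be 2-D")
        if len(self.labels) != self.data.shape[0]:
            raise CascadeError("label count does not match row count")
        if len(set(self.labels)) != len(self.labels):
            raise CascadeError("duplicate taxon labels")

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    def filter_min_edits(self, min_edits: int) -> "BarcodeMatrix":
        """Drop taxa with fewer than ``min_edits`` edited features."""
        keep = (self.data != 0).sum(axis=1) >= min_edits
        return BarcodeMatrix(
            data=self.data[keep],
            labels=[l for l, k in zip(self.labels, keep) if k],
            metadata=self.metadata.loc[keep] if self.metadata is not None else None,
        )

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            self.data, index=self.labels,
            columns=[f"f{j}" for j in range(self.data.shape[1])],
        )
        df.to_csv(path, sep="\t", index_label="taxon")

    @classmethod
    def from_tsv(cls, path) -> "BarcodeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="taxon")
        return cls(data=df.to_numpy(), labels=[str(i) for i in df.index])


def barcode_distances(
    m: BarcodeMatrix, metric: Literal["hamming_count", "hamming_fraction"] = "hamming_count"
) -> np.ndarray:
    """Symmetric pairwise distance matrix (default: raw Hamming counts)."""
    if m.n_taxa < 2:
        raise CascadeError("need at least 2 taxa")
    frac = pdist(m.data, metric="hamming")
    if metric == "hamming_count":
        frac = frac * m.data.shape[1]
    elif metric != "hamming_fraction":
        raise CascadeError(f"unknown metric {metric!r}")
    return squareform(frac)


def scramble_barcodes(m: BarcodeMatrix, scheme: str = "columns", seed: int | None = None) -> BarcodeMatrix:
    """Permutation null: shuffle each feature column independently across
    taxa, preserving per-site edit frequencies exactly."""
    rng = np.random.default_rng(seed)
    data = m.data.copy()
    if scheme == "columns":
        for j in range(data.shape[1]):
            data[:, j] = data[rng.permutation(data.shape[0]), j]
    else:
        raise CascadeError(f"unknown scramble scheme {scheme!r}")
    return BarcodeMatrix(data=data, labels=list(m.labels), metadata=m.metadata)


# ---------------------------------------------------------------------------
# UPGMA


@dataclass
class ReconstructedTree:
    """Rooted ultrametric tree from average-linkage clustering.

    ``children`` maps internal node ids to child ids (leaves are ``0..n-1``
    in label order), ``heights`` the merge height of each internal node
    (half the between-cluster mean distance); the cophenetic matrix stores
    full between-merge distances (2x height), matching the convention of R's
    ``cophenetic`` on an hclust tree.
    """

    labels: list[str]
    children: dict[int, tuple[int, int]]
    heights: dict[int, float]
    root: int
    cophenetic: np.ndarray
    support: dict[int, float] | None = None
    _leaf_cache: dict[int, frozenset[str]] = field(default_factory=dict, repr=False)

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    def leafset(self, node: int) -> frozenset[str]:
        if node in self._leaf_cache:
            return self._leaf_cache[node]
        if node < self.n_taxa:
            out = frozenset([self.labels[node]])
        else:
            a, b = self.children[node]
            out = self.leafset(a) | self.leafset(b)
        self._leaf_cache[node] = out
        return out

    def clades(self) -> dict[int, frozenset[str]]:
        return {nid: self.leafset(nid) for nid in self.children}

    def node_height(self, node: int) -> float:
        return self.heights.get(node, 0.0)

    def mean_tip_depth(self) -> float:
        """Mean number of internal nodes on root-to-leaf paths."""
        depth: dict[int, int] = {self.root: 1}
        order = [self.root]
        while order:
            nid = order.pop()
            if nid < self.n_taxa:
                continue
            for c in self.children[nid]:
                depth[c] = depth[nid] + 1
                order.append(c)
        # a leaf at depth d has d-1 internal ancestors plus none of its own
        return float(np.mean([depth[i] - 1 for i in range(self.n_taxa)]))

    def newick(self) -> str:
        def rec(nid: int, parent_h: float) -> str:
            h = self.node_height(nid)
            bl = parent_h - h
            if nid < self.n_taxa:
                return f"{self.labels[nid]}:{bl:.6g}"
            a, b = self.children[nid]
            return f"({rec(a, h)},{rec(b, h)}):{bl:.6g}"

        h = self.node_height(self.root)
        a, b = self.children[self.root]
        return f"({rec(a, h)},{rec(b, h)});"


def upgma(d: np.ndarray, labels: Sequence[str] | None = None) -> ReconstructedTree:
    """Average-linkage agglomeration with deterministic tie-breaking.

    Among equal-distance merge candidates the pair whose representative
    (lexicographically smallest member) labels sort first is merged, so
    repeated runs on tied data give identical trees.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or n < 2:
        raise CascadeError("distance matrix must be square with >= 2 taxa")
    if np.isnan(d).any():
        raise CascadeError("distance matrix contains NaN")
    labels = [str(l) for l in labels] if labels is not None else [f"t{i}" for i in range(n)]
    if len(labels) != n:
        raise CascadeError("label count mismatch")

    work = d.astype(float).copy()
    np.fill_diagonal(work, np.inf)
    active = list(range(n))  # current cluster ids, indexing into `work` rows
    sizes = {i: 1 for i in range(n)}
    reps = {i: labels[i] for i in range(n)}
    rows = {i: i for i in range(n)}  # cluster id -> row in work
    children: dict[int, tuple[int, int]] = {}
    heights: dict[int, float] = {}
    coph = np.zeros((n, n))
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    next_id = n

    while len(active) > 1:
        rows_idx = np.array([rows[c] for c in active])
        sub = work[np.ix_(rows_idx, rows_idx)]
        dmin = sub.min()
        cand = np.argwhere(np.isclose(sub, dmin, rtol=1e-12, atol=0.0))
        cand = cand[cand[:, 0] < cand[:, 1]]
        # tie rule: merge the pair whose sorted representative labels come first
        rep_rank = {c: r for r, c in enumerate(sorted(active, key=lambda c: reps[c]))}
        ranks = np.array([rep_rank[c] for c in active])
        ra_, rb_ = ranks[cand[:, 0]], ranks[cand[:, 1]]
        lo, hi = np.minimum(ra_, rb_), np.maximum(ra_, rb_)
        pick = np.lexsort((hi, lo))[0]
        a, b = int(cand[pick, 0]), int(cand[pick, 1])
        ca, cb = active[a], active[b]
        dij = float(sub[a, b])
        ia, ib = members[ca], members[cb]
        coph[np.ix_(ia, ib)] = dij
        coph[np.ix_(ib, ia)] = dij
        # average-linkage update into ca's row
        ra, rb = rows[ca], rows[cb]
        na, nb = sizes[ca], sizes[cb]
        merged_row = (na * work[ra] + nb * work[rb]) / (na + nb)
        work[ra] = merged_row
        work[:, ra] = merged_row
        work[ra, ra] = np.inf
        work[rb] = np.inf
        work[:, rb] = np.inf

        node = next_id
        next_id += 1
        children[node] = (ca, cb)
        heights[node] = dij / 2.0
        sizes[node] = na + nb
        reps[node] = min(reps[ca], reps[cb])
        rows[node] = ra
        members[node] = members[ca] + members[cb]
        active.remove(ca)
        active.remove(cb)
        active.append(node)

    root = active[0]
    return ReconstructedTree(
        labels=list(labels), children=children, heights=heights, root=root, cophenetic=coph
    )


# ---------------------------------------------------------------------------
# Robinson-Foulds


def _nontrivial_splits(clades: Sequence[frozenset[str]], taxa: frozenset[str]) -> set[frozenset[str]]:
    """Normalize clades to unrooted bipartitions: the side not containing the
    anchor (lexicographically smallest taxon); trivial splits dropped."""
    anchor = min(taxa)
    out: set[frozenset[str]] = set()
    for clade in clades:
        side = taxa - clade if anchor in clade else clade
        if 2 <= len(side) <= len(taxa) - 2:
            out.add(frozenset(side))
    return out


def tree_splits(tree) -> tuple[set[frozenset[str]], frozenset[str]]:
    """Extract nontrivial unrooted bipartitions from any supported tree."""
    if isinstance(tree, ReconstructedTree):
        clades = list(tree.clades().values())
        taxa = frozenset(tree.labels)
    elif isinstance(tree, LineageTree):
        clades = tree.clades()
        taxa = frozenset(f"c{n.id}" for n in tree.leaves())
    elif hasattr(tree, "leaf_node_iter"):  # dendropy
        taxa = frozenset(l.taxon.label for l in tree.leaf_node_iter())
        clades = []
        for node in tree.preorder_node_iter():
            if not node.is_leaf():
                clades.append(frozenset(l.taxon.label for l in node.leaf_iter()))
    else:
        raise CascadeError(f"unsupported tree type {type(tree)!r}")
    return _nontrivial_splits(clades, taxa), taxa


def robinson_foulds_normalized(t1, t2) -> float:
    """Symmetric-difference of nontrivial bipartitions divided by its
    maximum (the total nontrivial split count of both trees; 2(n-3) for a
    pair of binary trees).  0 = identical topology, 1 = maximally different."""
    s1, taxa1 = tree_splits(t1)
    s2, taxa2 = tree_splits(t2)
    if taxa1 != taxa2:
        raise CascadeError("trees have different leaf sets")
    denom = len(s1) + len(s2)
    if denom == 0:
        return 0.0
    return len(s1 ^ s2) / denom


# ---------------------------------------------------------------------------
# cophenetic groups, tip depth


def cophenetic_group_distance(t: ReconstructedTree, groups: Mapping[str, str]) -> pd.DataFrame:
    """Mean cophenetic distance over cross-group taxon pairs, per label pair."""
    label_groups = sorted(set(groups.values()))
    if len(label_groups) < 2:
        raise CascadeError("need at least two groups")
    idx = {lab: i for i, lab in enumerate(t.labels)}
    rows = []
    for g1, g2 in itertools.combinations(label_groups, 2):
        i1 = [idx[l] for l in t.labels if groups.get(l) == g1]
        i2 = [idx[l] for l in t.labels if groups.get(l) == g2]
        if not i1 or not i2:
            continue
        vals = t.cophenetic[np.ix_(i1, i2)]
        rows.append({"group_a": g1, "group_b": g2, "mean_cophenetic": float(vals.mean()),
                     "n_pairs": vals.size})
    return pd.DataFrame(rows)


def mean_tip_depth(tree) -> float:
    """Mean number of internal nodes on root-to-leaf paths."""
    if isinstance(tree, ReconstructedTree):
        return tree.mean_tip_depth()
    if isinstance(tree, LineageTree):
        return tree.mean_leaf_depth()
    if hasattr(tree, "leaf_node_iter"):
        depths = []
        for leaf in tree.leaf_node_iter():
            d = 0
            node = leaf.parent_node
            while node is not None:
                d += 1
                node = node.parent_node
            depths.append(d)
        return float(np.mean(depths))
    raise CascadeError(f"unsupported tree type {type(tree)!r}")


# ---------------------------------------------------------------------------
# transfer-bootstrap clade support


def transfer_distance(clade: frozenset[str], tree: ReconstructedTree) -> int:
    """Minimum leaf moves turning some clade/side of ``tree`` into ``clade``."""
    taxa = frozenset(tree.labels)
    best = min(len(clade) - 1, len(taxa) - len(clade) - 1) if len(taxa) > len(clade) else len(clade) - 1
    best = max(best, 0)
    sides: list[frozenset[str]] = [frozenset([l]) for l in tree.labels]
    sides.extend(tree.clades().values())
    for side in sides:
        for cand in (side, taxa - side):
            delta = len(clade ^ cand)
            if delta < best:
                best = delta
    return best


def clade_support(
    m: BarcodeMatrix,
    n_boot: int = 100,
    seed: int | None = None,
    metric: str = "hamming_count",
) -> tuple[ReconstructedTree, pd.DataFrame]:
    """Transfer-bootstrap support for every clade of the UPGMA tree.

    Feature columns are resampled with replacement, trees rebuilt, and each
    reference clade scored as ``1 - mean(transfer distance) / (clade size - 1)``.
    """
    if m.n_taxa < 4:
        raise CascadeError("need at least 4 taxa for clade support")
    if n_boot < 1:
        raise CascadeError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    ref = upgma(barcode_distances(m, metric), m.labels)
    clades = {nid: c for nid, c in ref.clades().items() if 1 < len(c) < m.n_taxa}
    dists: dict[int, list[int]] = {nid: [] for nid in clades}
    n_feat = m.data.shape[1]
    for _ in range(n_boot):
        cols = rng.integers(0, n_feat, size=n_feat)
        bm = BarcodeMatrix(data=m.data[:, cols], labels=list(m.labels))
        bt = upgma(barcode_distances(bm, metric), bm.labels)
        for nid, clade in clades.items():
            dists[nid].append(transfer_distance(clade, bt))
    rows = []
    support: dict[int, float] = {}
    for nid, clade in clades.items():
        size = len(clade)
        norm = max(size - 1, 1)
        sup = 1.0 - float(np.mean(dists[nid])) / norm
        support[nid] = sup
        rows.append({"clade_id": nid, "size": size, "support": sup})
    ref.support = support
    return ref, pd.DataFrame(rows).set_index("clade_id")


# ---------------------------------------------------------------------------
# benchmark sweep


def reconstruct_lineage(
    tree: LineageTree, metric: str = "hamming_count", min_edits: int = 0
) -> tuple[ReconstructedTree, BarcodeMatrix]:
    """UPGMA reconstruction from a simulated tree's leaf barcodes."""
    data, labels = tree.leaf_barcode_matrix()
    m = BarcodeMatrix(data=data, labels=labels)
    if min_edits:
        m = m.filter_min_edits(min_edits)
    return upgma(barcode_distances(m, metric), m.labels), m


def benchmark_sweep(
    systems: Sequence[str],
    rates: Sequence[float],
    copies: Sequence[int],
    depths: Sequence[float],
    n_replicates: int = 30,
    n_units: int = 20,
    division_model: DivisionModel | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Forward-simulate, reconstruct and score every grid cell.

    ``systems`` draws from {"hypercascade", "length_matched", "site_matched",
    "cas9"}; editing is strict (perfect-homology only) with every site at
    the same per-site rate, matching the idealized benchmarking regime.
    Returns per-cell mean/SE of the normalized RF distance; infeasible
    replicates (fewer than 4 leaves) are recorded as missing.
    """
    from .cascade import build_site_graph

    division_model = division_model or DivisionModel("exponential", tau=24.0)
    ss = np.random.SeedSequence(seed)
    ref = build_site_graph(n_units, terminal_pam_present=True)
    rows = []
    cells = list(itertools.product(systems, rates, copies, depths))
    seeds = ss.spawn(len(cells))
    for (system, rate, c, depth), cell_ss in zip(cells, seeds):
        rep_seeds = cell_ss.spawn(n_replicates)
        rfs = []
        for rs in rep_seeds:
            if system == "hypercascade":
                graph = ref
                model = EditModel(variant="strict_hypercascade", layer_rates=(rate,) * 4)
            else:
                graph, model = make_control_model(system, ref, rate=rate)
            t = grow_tree(
                graph, model, division_model, copies=c,
                stop=("mean_depth", depth), seed=int(rs.generate_state(1)[0] % (2**31)),
            )
            if t.n_leaves < 4:
                continue
            recon, _ = reconstruct_lineage(t)
            rfs.append(robinson_foulds_normalized(t, recon))
        rows.append(
            {
                "system": system, "rate": rate, "copies": c, "depth": depth,
                "n_ok": len(rfs),
                "mean_rf": float(np.mean(rfs)) if rfs else np.nan,
                "se_rf": float(np.std(rfs, ddof=1) / np.sqrt(len(rfs))) if len(rfs) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)
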