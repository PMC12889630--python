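"""Recovering per-locus edit-rate (chromatin proxy) histories from barcodes.

Pipeline: reconstruct the lineage by UPGMA from endpoint barcodes, infer
ancestral barcodes by bottom-up intersection (valid because editing is
irreversible), estimate per-edge per-locus edit rates from the ancestral
states and calibrated edge durations, featurize each cell's rate history
with low-degree polynomials, cluster cells with a Gaussian mixture, and
smooth per-cluster per-locus curves with penalized splines.  The edit rate
of a locus tracks its chromatin accessibility, so the recovered curves are
read as open/closed chromatin histories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import linear_sum_assignment
from sklearn.mixture import GaussianMixture

from .cascade import CascadeError
from .lineage import (
    ChromatinProgram,
    DifferentiationResult,
    DivisionModel,
    default_chromatin_program,
    simulate_differentiation,
)
from .reconstruct import BarcodeMatrix, ReconstructedTree, barcode_distances, upgma

# ---------------------------------------------------------------------------
# ancestral inference


def infer_ancestral_barcodes(
    tree: ReconstructedTree, leaf_states: Mapping[str, np.ndarray]
) -> dict[int, np.ndarray]:
    """Bottom-up intersection of child edit patterns at every internal node.

    With irreversible editing, any edit present in the true ancestor is
    present in all its descendants, so the intersection is a superset of the
    true ancestral edit set.  Returns node id -> 0/1 state vector (leaves
    are ids ``0..n-1`` in label order).
    """
    states: dict[int, np.ndarray] = {}
    for i, label in enumerate(tree.labels):
        if label not in leaf_states:
            raise CascadeError(f"missing leaf state for {label!r}")
        states[i] = np.asarray(leaf_states[label]).astype(np.int8)

    def rec(nid: int) -> np.ndarray:
        if nid in states:
            return states[nid]
        a, b = tree.children[nid]
        st = rec(a) & rec(b)
        states[nid] = st
        return st

    rec(tree.root)
    return states


# ---------------------------------------------------------------------------
# branch rates


@dataclass
class RateTrajectories:
    """Per-cell, per-locus piecewise-constant rates sampled on a time grid."""

    grid_days: np.ndarray  # (G,)
    rates: dict[str, np.ndarray]  # leaf label -> (n_loci, G) edits/array/day
    loci: list[str]


def calibrate_heights(tree: ReconstructedTree, total_duration_days: float) -> dict[int, float]:
    """Map merge heights to ages in days so the root sits at the experiment
    duration (the UPGMA height scale is arbitrary; a linear rescaling to the
    known duration is the default calibration)."""
    root_h = tree.node_height(tree.root)
    if root_h <= 0:
        raise CascadeError("degenerate tree: zero root height")
    scale = total_duration_days / root_h
    ages = {nid: h * scale for nid, h in tree.heights.items()}
    for i in range(tree.n_taxa):
        ages[i] = 0.0
    return ages


def branch_rates(
    tree: ReconstructedTree,
    node_states: Mapping[int, np.ndarray],
    total_duration_days: float,
    loci_slices: Sequence[slice],
    grid_points: int = 25,
    node_ages: Mapping[int, float] | None = None,
    include_root_edge: bool = True,
) -> RateTrajectories:
    """Per-edge per-locus rates along every root-to-leaf path.

    Edge rate = (child edits - parent edits) per locus / edge duration; ages
    come from :func:`calibrate_heights` unless ground-truth ``node_ages``
    are supplied.  Each leaf's piecewise-constant rate profile is sampled on
    ``grid_points`` evenly spaced times.

    With ``include_root_edge`` (default), edits shared by every cell — the
    MRCA's pre-divergence edits, visible as the root intersection — are
    assigned to a virtual root edge from an unedited origin at time 0.
    Since cophenetic heights and the root edit count are both measured on
    the recorder's edit clock (one-sided edits since divergence), the time
    scale becomes ``duration / (root height + root edits)``, which removes
    the downward bias that full-span calibration puts on every branch rate.
    """
    if node_ages is None and include_root_edge:
        root_h = tree.node_height(tree.root)
        root_state = np.asarray(node_states[tree.root], dtype=int)
        e_root = float(root_state.sum())
        if root_h + e_root <= 0:
            raise CascadeError("degenerate tree: zero root height and no shared edits")
        scale = total_duration_days / (root_h + e_root)
        ages = {nid: h * scale for nid, h in tree.heights.items()}
        for i in range(tree.n_taxa):
            ages[i] = 0.0
        virtual_root_span = total_duration_days - ages[tree.root]
        return _rate_profiles(
            tree, node_states, total_duration_days, loci_slices, grid_points, ages,
            root_edge=(virtual_root_span, root_state),
        )
    ages = dict(node_ages) if node_ages is not None else calibrate_heights(tree, total_duration_days)
    return _rate_profiles(
        tree, node_states, total_duration_days, loci_slices, grid_points, ages, root_edge=None
    )


def _rate_profiles(
    tree: ReconstructedTree,
    node_states: Mapping[int, np.ndarray],
    total_duration_days: float,
    loci_slices: Sequence[slice],
    grid_points: int,
    ages: Mapping[int, float],
    root_edge: tuple[float, np.ndarray] | None,
) -> RateTrajectories:
    parent: dict[int, int] = {}
    for nid, (a, b) in tree.children.items():
        parent[a] = nid
        parent[b] = nid

    # mass-preserving discretization: each edge's edits are spread uniformly
    # over the grid cells its time span overlaps (a zero-duration edge drops
    # its edits into the single containing cell), so the grid profile's time
    # integral equals the path's edit count exactly and near-zero-duration
    # reconstruction edges cannot produce unbounded point rates
    cell_edges = np.linspace(0.0, total_duration_days, grid_points + 1)
    centers = 0.5 * (cell_edges[:-1] + cell_edges[1:])
    cell_w = total_duration_days / grid_points
    rates: dict[str, np.ndarray] = {}
    n_loci = len(loci_slices)
    for i, label in enumerate(tree.labels):
        # path from root to this leaf
        path = [i]
        while path[-1] in parent:
            path.append(parent[path[-1]])
        path.reverse()  # root ... leaf
        segs: list[tuple[float, float, np.ndarray]] = []  # (t0, t1, per-locus edits)
        if root_edge is not None:
            span, root_state = root_edge
            if span > 0:
                segs.append(
                    (0.0, span,
                     np.array([root_state[sl].sum() for sl in loci_slices], dtype=float))
                )
        for up, dn in zip(path[:-1], path[1:]):
            t0 = total_duration_days - ages[up]
            t1 = total_duration_days - ages[dn]
            d_edits = node_states[dn].astype(int) - node_states[up].astype(int)
            per_locus = np.array([d_edits[sl].sum() for sl in loci_slices], dtype=float)
            segs.append((t0, t1, per_locus))
        mass = np.zeros((n_loci, grid_points))
        for t0, t1, per_locus in segs:
            t0 = min(max(t0, 0.0), total_duration_days)
            t1 = min(max(t1, 0.0), total_duration_days)
            if t1 - t0 <= 1e-12:
                cell = min(int(t0 / cell_w), grid_points - 1)
                mass[:, cell] += per_locus
                continue
            lo_cell = int(t0 / cell_w)
            hi_cell = min(int(np.ceil(t1 / cell_w)), grid_points)
            for cell in range(lo_cell, hi_cell):
                overlap = min(t1, cell_edges[cell + 1]) - max(t0, cell_edges[cell])
                if overlap > 0:
                    mass[:, cell] += per_locus * overlap / (t1 - t0)
        rates[label] = mass / cell_w
    return RateTrajectories(
        grid_days=centers, rates=rates, loci=[f"locus_{j}" for j in range(n_loci)]
    )


# ---------------------------------------------------------------------------
# featurization and clustering


@dataclass
class CellFeatures:
    labels: list[str]
    coefficients: np.ndarray  # (n_cells, (degree+1) * n_loci)
    degree: int
    loci: list[str]


def featurize_cells(
    traj: RateTrajectories,
    degree: int = 4,
    loci: Sequence[int] | None = None,
    normalize_by: Sequence[int] | None = None,
) -> CellFeatures:
    """Least-squares polynomial coefficients of each cell's rate history.

    ``loci`` selects which loci enter the feature vector (default: all);
    ``normalize_by`` optionally divides each cell's rates by its mean rate
    over those (static) loci first, removing global activity variation.
    """
    if len(traj.grid_days) < degree + 1:
        raise CascadeError("fewer grid points than polynomial degree + 1")
    loci = list(loci) if loci is not None else list(range(len(traj.loci)))
    x = traj.grid_days / traj.grid_days.max()  # scale to [0,1] for conditioning
    labels = sorted(traj.rates)
    feats = []
    for label in labels:
        prof = traj.rates[label]
        norm = 1.0
        if normalize_by is not None:
            base = float(np.nanmean(prof[list(normalize_by)]))
            norm = base if base > 1e-9 else 1.0
        row = []
        for l in loci:
            coeffs = np.polyfit(x, prof[l] / norm, degree)
            row.append(coeffs)
        feats.append(np.concatenate(row))
    return CellFeatures(
        labels=labels,
        coefficients=np.asarray(feats),
        degree=degree,
        loci=[traj.loci[l] for l in loci],
    )


def cluster_cells(
    features: CellFeatures, k: int = 4, seed: int | None = 0
) -> tuple[np.ndarray, GaussianMixture]:
    """Gaussian-mixture clustering of polynomial features."""
    if features.coefficients.shape[0] < k:
        raise CascadeError(f"need at least {k} cells to fit {k} components")
    gmm = GaussianMixture(
        n_components=k, covariance_type="full", random_state=seed, reg_covar=1e-5, n_init=3
    )
    labels = gmm.fit_predict(features.coefficients)
    return labels, gmm


def best_permutation_accuracy(pred: Sequence[int], truth: Sequence[str]) -> float:
    """Label agreement under the best cluster-to-class permutation."""
    pred = np.asarray(pred)
    classes = sorted(set(truth))
    truth_idx = np.array([classes.index(t) for t in truth])
    k = max(len(classes), int(pred.max()) + 1)
    cont = np.zeros((k, k))
    for p, t in zip(pred, truth_idx):
        cont[p, t] += 1
    row, col = linear_sum_assignment(-cont)
    return float(cont[row, col].sum() / len(pred))


# ---------------------------------------------------------------------------
# penalized-spline smoothing


def penalized_spline_fit(
    x: np.ndarray, y: np.ndarray, n_basis: int = 10, lambdas: np.ndarray | None = None
):
    """Cubic penalized B-spline with GCV-selected smoothing.

    Returns ``(fitted_fn, lambda)``: a callable evaluating the smooth at new
    points and the selected penalty.  Second-difference penalty on basis
    coefficients; GCV = n * RSS / (n - tr(H))^2 minimized over a log grid.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    good = np.isfinite(y)
    x, y = x[good], y[good]
    if len(x) < 4:
        raise CascadeError("too few points for spline smoothing")
    lo, hi = x.min(), x.max()
    degree = 3
    n_interior = max(n_basis - degree - 1, 0)
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    nb = len(knots) - degree - 1
    B = BSpline.design_matrix(x, knots, degree).toarray()
    D = np.diff(np.eye(nb), n=2, axis=0)
    P = D.T @ D
    BtB = B.T @ B
    Bty = B.T @ y
    if lambdas is None:
        lambdas = np.logspace(-5, 5, 31)
    best = None
    n = len(y)
    for lam in lambdas:
        A = BtB + lam * P
        try:
            coef = np.linalg.solve(A, Bty)
        except np.linalg.LinAlgError:  # pragma: no cover
            continue
        H_trace = float(np.trace(np.linalg.solve(A, BtB)))
        resid = y - B @ coef
        rss = float(resid @ resid)
        denom = max(n - H_trace, 1e-9)
        gcv = n * rss / denom**2
        if best is None or gcv < best[0]:
            best = (gcv, lam, coef)
    _, lam, coef = best
    spline = BSpline(knots, coef, degree, extrapolate=True)

    def fn(xnew):
        xnew = np.clip(np.asarray(xnew, dtype=float), lo, hi)
        return spline(xnew)

    return fn, float(lam)


def smooth_group_trajectories(
    traj: RateTrajectories,
    cell_clusters: Mapping[str, int],
    loci: Sequence[int] | None = None,
    n_basis: int = 10,
) -> pd.DataFrame:
    """Per-cluster, per-locus smooth rate-vs-time curves pooled over cells.

    Clusters with a single cell fall back to that cell's profile (flagged in
    the ``smoothed`` column).
    """
    loci = list(loci) if loci is not None else list(range(len(traj.loci)))
    clusters = sorted(set(cell_clusters.values()))
    rows = []
    for cl in clusters:
        members = [lab for lab, c in cell_clusters.items() if c == cl]
        if not members:
            raise CascadeError(f"cluster {cl} is empty")
        for l in loci:
            xs = np.tile(traj.grid_days, len(members))
            ys = np.concatenate([traj.rates[m][l] for m in members])
            if len(members) == 1:
                warnings.warn(f"cluster {cl} has one cell; using its raw profile", stacklevel=2)
                fitted = traj.rates[members[0]][l]
                smoothed = False
            else:
                fn, _ = penalized_spline_fit(xs, ys, n_basis=n_basis)
                fitted = fn(traj.grid_days)
                smoothed = True
            for t, v in zip(traj.grid_days, fitted):
                rows.append(
                    {"cluster": cl, "locus": traj.loci[l], "time_days": float(t),
                     "rate": float(v), "smoothed": smoothed, "n_cells": len(members)}
                )
    return pd.DataFrame(rows)


def match_curves_to_program(
    curves: pd.DataFrame, program: ChromatinProgram
) -> tuple[dict[int, str], float]:
    """Assign recovered per-cluster curves to programmed trajectories.

    Correlates each cluster's smoothed per-locus rate curves with every
    trajectory's programmed open/closed rate schedule and solves the best
    one-to-one assignment; returns (cluster -> trajectory name, mean
    correlation of the assigned pairs).  A qualitative match means the
    assigned correlations are clearly positive.
    """
    clusters = sorted(curves["cluster"].unique())
    grid = np.sort(curves["time_days"].unique())
    loci = sorted(curves["locus"].unique())
    sched = np.zeros((len(program.trajectories), len(loci), len(grid)))
    for r in range(len(program.trajectories)):
        for d in range(len(loci)):
            for gi, t in enumerate(grid):
                sched[r, d, gi] = program.locus_rate(r, d, t * 24.0)
    corr = np.zeros((len(clusters), len(program.trajectories)))
    for ci, cl in enumerate(clusters):
        sub = curves[curves["cluster"] == cl]
        mat = np.stack([
            sub[sub["locus"] == loc].sort_values("time_days")["rate"].to_numpy()
            for loc in loci
        ])
        x = mat.ravel()
        for r in range(len(program.trajectories)):
            y = sched[r].ravel()
            if x.std() < 1e-12 or y.std() < 1e-12:
                corr[ci, r] = 0.0
            else:
                corr[ci, r] = float(np.corrcoef(x, y)[0, 1])
    rows, cols = linear_sum_assignment(-corr)
    assignment = {clusters[i]: program.trajectories[j] for i, j in zip(rows, cols)}
    return assignment, float(corr[rows, cols].mean())


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class ChromatinPipelineReport:
    n_trees: int
    n_cells: int
    cluster_accuracy: float
    static_rate_mean: float
    static_rate_se: float
    curves: pd.DataFrame
    per_tree: pd.DataFrame
    cell_clusters: dict[str, int] = field(default_factory=dict)
    cell_truth: dict[str, str] = field(default_factory=dict)


def run_chromatin_pipeline(
    program: ChromatinProgram | None = None,
    n_trees: int = 200,
    seed: int | None = 0,
    division_model: DivisionModel | None = None,
    max_cells_per_tree: int = 400,
    k: int = 4,
    degree: int = 4,
    normalize: bool = True,
) -> ChromatinPipelineReport:
    """Simulate -> reconstruct -> infer ancestors -> branch rates ->
    features -> clusters -> smoothed per-cluster curves -> accuracy.

    Cells are pooled across replicate trees for clustering and smoothing;
    failures in one replicate are isolated and reported in ``per_tree``.
    """
    program = program or default_chromatin_program()
    ss = np.random.SeedSequence(seed)
    duration_days = program.duration_days
    n_arrays = program.n_static + program.n_dynamic
    sites_per_array = None

    all_feats: list[np.ndarray] = []
    all_labels: list[str] = []
    truth: dict[str, str] = {}
    static_rates: list[float] = []
    per_tree_rows = []
    pooled_traj_rates: dict[str, np.ndarray] = {}
    grid = None
    loci_names = None

    for rep, child in enumerate(ss.spawn(n_trees)):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        try:
            sim = simulate_differentiation(
                program, division_model=division_model, seed=rep_seed,
                max_cells=max_cells_per_tree,
            )
            tree = sim.tree
            if tree.n_leaves < max(k, 8):
                raise CascadeError(f"tree too small ({tree.n_leaves} leaves)")
            data, labels = tree.leaf_barcode_matrix()
            labels = [f"r{rep}_{l}" for l in labels]
            m = BarcodeMatrix(data=data, labels=labels)
            recon = upgma(barcode_distances(m), m.labels)
            leaf_states = {lab: row for lab, row in zip(labels, data)}
            node_states = infer_ancestral_barcodes(recon, leaf_states)
            n_sites = tree.graph.n_sites
            sites_per_array = n_sites
            slices = [slice(a * n_sites, (a + 1) * n_sites) for a in range(n_arrays)]
            traj = branch_rates(recon, node_states, duration_days, slices)
            # static-locus recovery (negative control / calibration readout)
            static_idx = list(range(program.n_static))
            for lab in traj.rates:
                static_rates.append(float(np.nanmean(traj.rates[lab][static_idx])))
            dyn_idx = list(range(program.n_static, n_arrays))
            feats = featurize_cells(
                traj, degree=degree, loci=dyn_idx,
                normalize_by=static_idx if normalize else None,
            )
            all_feats.append(feats.coefficients)
            all_labels.extend(feats.labels)
            for lab in labels:
                truth[lab] = sim.leaf_trajectories[lab.split("_", 1)[1]]
            for lab in traj.rates:
                pooled_traj_rates[lab] = traj.rates[lab]
            grid = traj.grid_days
            loci_names = traj.loci
            per_tree_rows.append({"tree": rep, "n_leaves": tree.n_leaves, "ok": True, "error": ""})
        except Exception as exc:  # stage failure isolated per replicate
            per_tree_rows.append({"tree": rep, "n_leaves": 0, "ok": False, "error": str(exc)})

    if not all_feats:
        raise CascadeError("every replicate failed")
    X = np.vstack(all_feats)
    features = CellFeatures(
        labels=all_labels, coefficients=X, degree=degree,
        loci=loci_names[len(loci_names) - program.n_dynamic :] if loci_names else [],
    )
    cluster_seed = int(ss.generate_state(1)[0] % (2**31))
    pred, _ = cluster_cells(features, k=k, seed=cluster_seed)
    truth_list = [truth[lab] for lab in all_labels]
    acc = best_permutation_accuracy(pred, truth_list)

    pooled = RateTrajectories(grid_days=grid, rates=pooled_traj_rates, loci=loci_names)
    cell_clusters = {lab: int(c) for lab, c in zip(all_labels, pred)}
    dyn_idx = list(range(program.n_static, n_arrays))
    curves = smooth_group_trajectories(pooled, cell_clusters, loci=dyn_idx)

    static_arr = np.asarray(static_rates)
    return ChromatinPipelineReport(
        n_trees=n_trees,
        n_cells=len(all_labels),
        cluster_accuracy=acc,
        static_rate_mean=float(static_arr.mean()),
        static_rate_se=float(static_arr.std(ddof=1) / np.sqrt(len(static_arr))),
        curves=curves,
        per_tree=pd.DataFrame(per_tree_rows),
        cell_clusters=cell_clusters,
        cell_truth=truth,
    )
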