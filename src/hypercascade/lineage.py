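"""Ground-truth lineage trees of dividing cells carrying editing arrays.

Cells divide with stochastic waiting times; between divisions their barcode
arrays edit continuously (exact Gillespie clocks per cell).  Both daughters
inherit the parent's exact edit states, so edits are heritable and
irreversible along every root-to-leaf path.  The differentiation simulator
adds a chromatin program: a set of scheduled open/closed trajectories over
dynamic loci that modulate the per-array edit rate, with trajectory
switching at divisions governed by per-epoch transition matrices.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

from .cascade import CascadeError, EditState, SiteGraph, available_sites, build_site_graph
from .simulate import EditModel, run_editing

# ---------------------------------------------------------------------------
# division-time models


@dataclass(frozen=True)
class DivisionModel:
    """Waiting-time distribution between cell divisions.

    ``tau`` is the characteristic time in hours (the mean for the shipped
    distributions); ``alpha`` is a dimensionless shape parameter where
    applicable.  Additional distributions can be registered via
    :func:`register_division_sampler`.
    """

    distribution: str = "exponential"
    tau: float = 24.0
    alpha: float = 0.9

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise CascadeError("tau must be positive")


_SAMPLERS: dict[str, Callable[[DivisionModel, np.random.Generator], float]] = {}


def register_division_sampler(
    name: str, fn: Callable[[DivisionModel, np.random.Generator], float]
) -> None:
    _SAMPLERS[name] = fn


register_division_sampler("exponential", lambda m, rng: float(rng.exponential(m.tau)))
register_division_sampler(
    "gamma", lambda m, rng: float(rng.gamma(m.alpha, m.tau / m.alpha))
)


def sample_division_time(model: DivisionModel, rng: np.random.Generator) -> float:
    """Draw one strictly positive division waiting time (hours)."""
    if model.distribution == "eyring_stover":
        fn = _SAMPLERS.get("eyring_stover")
        if fn is None:
            raise NotImplementedError(
                "The Eyring-Stover cell-cycle distribution is a reserved slot: its "
                "survival function is defined in the cell-division-time literature "
                "and is not shipped here. Register a sampler with "
                "register_division_sampler('eyring_stover', fn) or use the "
                "'exponential'/'gamma' models (tau=24 h reproduces roughly one "
                "division per day)."
            )
        w = fn(model, rng)
    else:
        fn = _SAMPLERS.get(model.distribution)
        if fn is None:
            raise CascadeError(f"unknown division distribution {model.distribution!r}")
        w = fn(model, rng)
    if w <= 0:
        w = np.finfo(float).tiny
    return w


# ---------------------------------------------------------------------------
# lineage trees


@dataclass
class Node:
    id: int
    parent: int | None
    birth_time: float
    depth: int
    children: list[int] = field(default_factory=list)
    end_time: float = np.nan  # division time (internal) or sampling time (leaf)
    states: list[EditState] = field(default_factory=list)
    trajectory: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class LineageTree:
    """Rooted binary tree with node times and per-node array edit states."""

    nodes: dict[int, Node]
    root: int
    graph: SiteGraph
    copies: int
    duration: float  # hours; sampling time of all leaves

    def leaves(self) -> list[Node]:
        return [n for n in self.nodes.values() if n.is_leaf]

    def internal(self) -> list[Node]:
        return [n for n in self.nodes.values() if not n.is_leaf]

    @property
    def n_leaves(self) -> int:
        return sum(1 for n in self.nodes.values() if n.is_leaf)

    def mean_leaf_depth(self) -> float:
        ls = self.leaves()
        return float(np.mean([n.depth for n in ls]))

    def leaf_labels(self) -> list[str]:
        return [f"c{n.id}" for n in self.leaves()]

    def leaf_barcode_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Concatenated per-copy status vectors for every leaf."""
        ls = self.leaves()
        mat = np.stack([np.concatenate([st.status for st in n.states]) for n in ls])
        return mat, [f"c{n.id}" for n in ls]

    def newick(self) -> str:
        """Newick string; branch lengths in hours, leaf labels carry cell ids."""

        def rec(nid: int) -> str:
            node = self.nodes[nid]
            if node.is_leaf:
                label = f"c{node.id}"
            else:
                label = "(" + ",".join(rec(c) for c in node.children) + ")"
            parent_t = self.nodes[node.parent].end_time if node.parent is not None else 0.0
            bl = node.end_time - parent_t
            return f"{label}:{bl:.6g}"

        return rec(self.root) + ";"

    def clades(self) -> list[frozenset[str]]:
        """Leaf-label sets of all internal nodes (root included)."""
        memo: dict[int, frozenset[str]] = {}

        def rec(nid: int) -> frozenset[str]:
            node = self.nodes[nid]
            if node.is_leaf:
                memo[nid] = frozenset([f"c{node.id}"])
            else:
                memo[nid] = frozenset().union(*(rec(c) for c in node.children))
            return memo[nid]

        rec(self.root)
        return [memo[n.id] for n in self.internal()]


StopRule = tuple[Literal["duration", "mean_depth"], float]


def grow_tree(
    graph: SiteGraph,
    edit_model: EditModel,
    division_model: DivisionModel,
    copies: int = 3,
    stop: StopRule = ("duration", 144.0),
    seed: int | None = None,
    max_cells: int = 50_000,
) -> LineageTree:
    """Grow a lineage tree with continuous editing on every extant cell.

    ``stop`` is either ``("duration", hours)`` or ``("mean_depth", target)``;
    the latter divides cells until the leaf-count-weighted mean division
    depth first reaches the target, then halts divisions at the last
    division time (editing runs to that time on all extant cells).
    """
    kind, value = stop
    if kind not in ("duration", "mean_depth"):
        raise CascadeError(f"unknown stop rule {kind!r}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    nodes: dict[int, Node] = {}
    next_id = 0

    def new_node(parent: int | None, birth: float, depth: int, states: list[EditState]) -> Node:
        nonlocal next_id
        node = Node(id=next_id, parent=parent, birth_time=birth, depth=depth, states=states)
        nodes[next_id] = node
        next_id += 1
        return node

    root = new_node(None, 0.0, 0, [EditState.unedited(graph) for _ in range(copies)])

    heap: list[tuple[float, int]] = []
    heapq.heappush(heap, (sample_division_time(division_model, rng), root.id))

    depth_sum = 0
    n_extant = 1
    t_last_division = 0.0
    truncated = False

    while heap:
        td, nid = heapq.heappop(heap)
        if kind == "duration" and td > value:
            break
        if kind == "mean_depth" and n_extant > 1 and depth_sum / n_extant >= value:
            break
        if n_extant >= max_cells:
            truncated = True
            break
        node = nodes[nid]
        # edit this cell's arrays over its lifespan, then divide
        for st in node.states:
            run_editing(graph, edit_model, st, node.birth_time, td, rng)
        node.end_time = td
        t_last_division = td
        for _ in range(2):
            child = new_node(nid, td, node.depth + 1, [st.copy() for st in node.states])
            node.children.append(child.id)
            heapq.heappush(heap, (td + sample_division_time(division_model, rng), child.id))
        depth_sum += node.depth + 2
        n_extant += 1

    if truncated:
        warnings.warn(
            f"tree growth stopped at max_cells={max_cells} before the stop rule was reached; "
            "returning the partial tree",
            stacklevel=2,
        )
    t_end = value if kind == "duration" else t_last_division
    if kind == "mean_depth" and t_end == 0.0:
        t_end = sample_division_time(division_model, rng)  # degenerate: no division happened
    for node in nodes.values():
        if node.is_leaf:
            for st in node.states:
                run_editing(graph, edit_model, st, node.birth_time, t_end, rng)
            node.end_time = t_end
    return LineageTree(nodes=nodes, root=root.id, graph=graph, copies=copies, duration=t_end)


# ---------------------------------------------------------------------------
# chromatin programs


@dataclass
class ChromatinProgram:
    """Scheduled open/closed chromatin states over dynamic loci.

    ``patterns[r][e]`` is the open (True) / closed (False) vector over the
    ``n_dynamic`` loci for trajectory ``r`` during epoch ``e``; transitions
    between trajectories happen at divisions via the epoch's row-stochastic
    matrix and are only allowed between trajectories whose current-epoch
    patterns are identical.  Static loci are open throughout.  Rates are in
    edits per array per day; closed loci edit ``fold_reduction``-fold slower.
    """

    trajectories: list[str]
    patterns: np.ndarray  # (n_traj, n_epochs, n_dynamic) bool, True = open
    transition_matrices: np.ndarray  # (n_epochs, n_traj, n_traj)
    duration_days: float = 6.0
    n_static: int = 15
    n_dynamic: int = 5
    open_rate: float = 2.0
    fold_reduction: float = 4.0
    n_units: int = 20

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=bool)
        self.transition_matrices = np.asarray(self.transition_matrices, dtype=float)
        n_traj, n_epochs, n_dyn = self.patterns.shape
        if n_dyn != self.n_dynamic:
            raise CascadeError("pattern width does not match n_dynamic")
        if self.transition_matrices.shape != (n_epochs, n_traj, n_traj):
            raise CascadeError("transition matrix shape mismatch")
        if not np.allclose(self.transition_matrices.sum(axis=2), 1.0):
            raise CascadeError("transition matrices must be row-stochastic")
        for e in range(n_epochs):
            for a in range(n_traj):
                for b in range(n_traj):
                    if a != b and self.transition_matrices[e, a, b] > 0:
                        if not np.array_equal(self.patterns[a, e], self.patterns[b, e]):
                            raise CascadeError(
                                f"epoch {e}: transition {self.trajectories[a]} -> "
                                f"{self.trajectories[b]} allowed despite differing "
                                "chromatin patterns"
                            )

    @property
    def n_epochs(self) -> int:
        return self.patterns.shape[1]

    @property
    def closed_rate(self) -> float:
        return self.open_rate / self.fold_reduction

    def epoch_of(self, t_hours: float) -> int:
        epoch_h = self.duration_days * 24.0 / self.n_epochs
        e = int(t_hours // epoch_h)
        return min(max(e, 0), self.n_epochs - 1)

    def epoch_bounds_h(self) -> np.ndarray:
        return np.linspace(0.0, self.duration_days * 24.0, self.n_epochs + 1)

    def locus_rate(self, trajectory_idx: int, locus: int, t_hours: float) -> float:
        """Edits/array/day of dynamic ``locus`` for a trajectory at ``t``."""
        e = self.epoch_of(t_hours)
        return self.open_rate if self.patterns[trajectory_idx, e, locus] else self.closed_rate


def _patterns_from_strings(rows: Sequence[Sequence[str]]) -> np.ndarray:
    return np.array([[[c == "O" for c in epoch] for epoch in traj] for traj in rows])


def default_chromatin_program() -> ChromatinProgram:
    """The shipped five-epoch, four-trajectory differentiation schedule.

    All trajectories share one pattern in epoch 1 (free mixing); blue and
    pink stay identical through epoch 3 before diverging to distinct
    terminal fates; orange and green are distinct from epoch 2 onward but
    converge on the same terminal pattern (convergent differentiation).
    """
    rows = [
        ["OOOOC", "OOOCC", "OOCCC", "OCCCC", "CCCCC"],  # blue
        ["OOOOC", "OOOCC", "OOCCC", "OOCCO", "OOCOO"],  # pink
        ["OOOOC", "COOOC", "CCOOC", "CCCOC", "CCCCO"],  # orange
        ["OOOOC", "OCOOC", "OCCOC", "OCCCO", "CCCCO"],  # green
    ]
    names = ["blue", "pink", "orange", "green"]
    n = 4
    mats = np.zeros((5, n, n))
    mats[0] = np.full((n, n), 0.1) + np.eye(n) * 0.6  # all patterns identical in epoch 1
    for e in (1, 2):
        m = np.eye(n)
        m[0, 0] = m[1, 1] = 0.8
        m[0, 1] = m[1, 0] = 0.2
        mats[e] = m
    mats[3] = np.eye(n)
    mats[4] = np.eye(n)  # orange/green patterns match but fates are canalized
    return ChromatinProgram(
        trajectories=names,
        patterns=_patterns_from_strings(rows),
        transition_matrices=mats,
    )


# ---------------------------------------------------------------------------
# differentiation simulation


@dataclass
class DifferentiationResult:
    tree: LineageTree
    program: ChromatinProgram
    leaf_trajectories: dict[str, str]  # leaf label -> terminal trajectory name
    node_trajectories: dict[int, str]  # node id -> trajectory during its lifespan
    #: ground-truth rate (edits/array/day) per leaf, locus and epoch, along its history
    true_rate_functions: dict[str, np.ndarray]  # leaf label -> (n_dynamic, n_epochs)


def _edit_array_poisson(
    graph: SiteGraph,
    state: EditState,
    rate_per_day: Callable[[float], float],
    t0: float,
    t1: float,
    breakpoints: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Edit one array over [t0, t1) as a Poisson process at an array-level,
    piecewise-constant rate, each event editing a uniformly chosen currently
    available site (cascade order respected)."""
    cuts = [t0] + [float(b) for b in breakpoints if t0 < b < t1] + [t1]
    events: list[float] = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        r = rate_per_day(0.5 * (a + b)) / 24.0  # per hour
        n = rng.poisson(r * (b - a))
        if n:
            events.extend(rng.uniform(a, b, size=n))
    for t in sorted(events):
        avail = sorted(available_sites(graph, state))
        if not avail:
            continue  # saturated array: event lost
        site = avail[int(rng.integers(len(avail)))]
        state.record(graph, site, t)


def simulate_differentiation(
    program: ChromatinProgram,
    division_model: DivisionModel | None = None,
    seed: int | None = None,
    max_cells: int = 1500,
) -> DifferentiationResult:
    """Grow a lineage under the chromatin program for its full duration.

    Every cell carries ``n_static + n_dynamic`` cascade arrays.  Static
    arrays edit at the open rate throughout; dynamic array ``d`` follows the
    cell's current trajectory pattern, switching rate at epoch boundaries.
    Daughters re-draw their trajectory from the division-epoch's transition
    matrix row.
    """
    division_model = division_model or DivisionModel("exponential", tau=24.0)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    graph = build_site_graph(program.n_units, terminal_pam_present=True)
    n_arrays = program.n_static + program.n_dynamic
    duration_h = program.duration_days * 24.0
    bounds = program.epoch_bounds_h()
    traj_index = {name: k for k, name in enumerate(program.trajectories)}

    nodes: dict[int, Node] = {}
    node_traj: dict[int, str] = {}
    next_id = 0

    def new_node(parent, birth, depth, states, traj) -> Node:
        nonlocal next_id
        node = Node(
            id=next_id, parent=parent, birth_time=birth, depth=depth,
            states=states, trajectory=traj,
        )
        nodes[next_id] = node
        node_traj[next_id] = traj
        next_id += 1
        return node

    root_traj = program.trajectories[int(rng.integers(len(program.trajectories)))]
    root = new_node(None, 0.0, 0, [EditState.unedited(graph) for _ in range(n_arrays)], root_traj)
    heap: list[tuple[float, int]] = []
    heapq.heappush(heap, (sample_division_time(division_model, rng), root.id))
    n_extant = 1

    def edit_lifespan(node: Node, t_end: float) -> None:
        k = traj_index[node.trajectory]
        for a, st in enumerate(node.states):
            if a < program.n_static:
                rate = lambda t: program.open_rate
            else:
                locus = a - program.n_static
                rate = lambda t, locus=locus: program.locus_rate(k, locus, t)
            _edit_array_poisson(graph, st, rate, node.birth_time, t_end, bounds, rng)

    while heap:
        td, nid = heapq.heappop(heap)
        if td > duration_h:
            break
        if n_extant >= max_cells:
            warnings.warn(
                f"differentiation stopped dividing at max_cells={max_cells}", stacklevel=2
            )
            break
        node = nodes[nid]
        edit_lifespan(node, td)
        node.end_time = td
        epoch = program.epoch_of(td)
        row = program.transition_matrices[epoch, traj_index[node.trajectory]]
        for _ in range(2):
            new_traj = program.trajectories[int(rng.choice(len(row), p=row))]
            child = new_node(nid, td, node.depth + 1, [st.copy() for st in node.states], new_traj)
            node.children.append(child.id)
            heapq.heappush(heap, (td + sample_division_time(division_model, rng), child.id))
        n_extant += 1

    for node in nodes.values():
        if node.is_leaf:
            edit_lifespan(node, duration_h)
            node.end_time = duration_h

    tree = LineageTree(nodes=nodes, root=root.id, graph=graph, copies=n_arrays, duration=duration_h)

    # ground truth: per-leaf, per-locus, per-epoch rate along its history
    leaf_traj: dict[str, str] = {}
    true_rates: dict[str, np.ndarray] = {}
    for leaf in tree.leaves():
        label = f"c{leaf.id}"
        leaf_traj[label] = leaf.trajectory
        # trajectory label active at each epoch midpoint along the leaf's history
        path: list[Node] = []
        cur: Node | None = leaf
        while cur is not None:
            path.append(cur)
            cur = nodes[cur.parent] if cur.parent is not None else None
        path.reverse()
        rates = np.zeros((program.n_dynamic, program.n_epochs))
        mids = 0.5 * (bounds[:-1] + bounds[1:])
        for e, tm in enumerate(mids):
            holder = next(
                (n for n in path if n.birth_time <= tm < n.end_time), path[-1]
            )
            k = traj_index[holder.trajectory]
            for d in range(program.n_dynamic):
                rates[d, e] = program.locus_rate(k, d, tm)
        true_rates[label] = rates

    return DifferentiationResult(
        tree=tree,
        program=program,
        leaf_trajectories=leaf_traj,
        node_trajectories=node_traj,
        true_rate_functions=true_rates,
    )
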