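"""Stochastic (Gillespie) simulation of edit accumulation.

Each unedited target site carries a propensity (per hour).  Under the strict
cascade model a site's propensity is its layer rate once all prerequisites
are edited and zero before; under the mismatch model, editing at a partially
unlocked site proceeds at the layer rate attenuated multiplicatively by one
penalty per unrepaired mismatch position (plus a PAM penalty while the
PAM-breaking mismatch is unrepaired).  Independent control arrays assign
every site a constant propensity; the Cas9-style control additionally draws
one of ``n_outcomes`` terminal states at edit time.

Simulation is exact: exponential waiting times at the total propensity,
event site chosen proportionally to propensity.  Propensity recomputation
after an edit is incremental over the edited site's structural dependents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .cascade import (
    PAM_POSITION,
    CascadeError,
    EditState,
    SiteGraph,
    build_site_graph,
    independent_graph,
)

Variant = Literal["strict_hypercascade", "mismatch_hypercascade", "independent", "cas9_independent"]

#: mismatch positions penalizable in the shipped geometry (21 = PAM)
DEFAULT_PENALTY_POSITIONS = (1, 11, 16)


@dataclass(frozen=True)
class EditModel:
    """Kinetic parameters of an editing system.

    ``layer_rates`` are per-site rates in edits per site per hour, indexed by
    layer (independent variants use the layer-1 entry).  ``mismatch_penalties``
    maps protospacer positions to multiplicative factors in [0, 1];
    ``pam_penalty`` applies while the PAM-breaking mismatch is unrepaired.
    The strict variant is the mismatch variant with all penalties zero.
    """

    variant: Variant = "strict_hypercascade"
    layer_rates: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    mismatch_penalties: Mapping[int, float] = field(
        default_factory=lambda: {p: 0.0 for p in DEFAULT_PENALTY_POSITIONS}
    )
    pam_penalty: float = 0.0
    n_outcomes: int = 9

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.layer_rates):
            raise CascadeError("layer rates must be non-negative")
        if not 0.0 <= self.pam_penalty <= 1.0:
            raise CascadeError("pam_penalty must lie in [0, 1]")
        for pos, p in self.mismatch_penalties.items():
            if not 0.0 <= p <= 1.0:
                raise CascadeError(f"penalty at position {pos} must lie in [0, 1]")
        if self.variant == "cas9_independent" and self.n_outcomes < 2:
            raise CascadeError("cas9 variant needs n_outcomes >= 2")

    def rate_for_layer(self, layer: int) -> float:
        return self.layer_rates[layer - 1]


@dataclass
class Trajectory:
    """Edit accumulation of one replicate sampled on a fixed time grid."""

    replicate: int
    times: np.ndarray  # hours
    cumulative_edits: np.ndarray
    available_sites: np.ndarray


def site_propensity(model: EditModel, graph: SiteGraph, site, state: EditState) -> float:
    """Per-hour edit propensity of an unedited ``site`` in ``state``."""
    idx = graph.site_index[site]
    if state.status[idx]:
        raise CascadeError(f"site {site} is already edited")
    rate = model.rate_for_layer(site[0])
    if model.variant in ("independent", "cas9_independent"):
        return rate
    if model.variant == "strict_hypercascade":
        deps_ok = all(state.status[graph.site_index[d]] for d in graph.deps[site])
        return rate if deps_ok else 0.0
    # mismatch model: multiplicative attenuation over unrepaired positions
    for pos, repairer in graph.repair_map[site].items():
        if not state.status[graph.site_index[repairer]]:
            factor = model.pam_penalty if pos == PAM_POSITION else model.mismatch_penalties.get(pos, 0.0)
            rate *= factor
    return rate


def _all_propensities(model: EditModel, graph: SiteGraph, state: EditState) -> np.ndarray:
    prop = np.zeros(graph.n_sites)
    for s in graph.sites:
        if not state.status[graph.site_index[s]]:
            prop[graph.site_index[s]] = site_propensity(model, graph, s, state)
    return prop


def run_editing(
    graph: SiteGraph,
    model: EditModel,
    state: EditState,
    t_start: float,
    t_end: float,
    rng: np.random.Generator,
) -> EditState:
    """Advance ``state`` in place from ``t_start`` to ``t_end`` (hours).

    This is the resumable core used both by :func:`simulate_editing` and by
    the lineage simulator (per-cell lifespans).  All-zero total propensity
    idles to the end time.
    """
    prop = _all_propensities(model, graph, state)
    dependents = graph.dependents()
    t = t_start
    while True:
        total = prop.sum()
        if total <= 0.0:
            return state
        t = t + rng.exponential(1.0 / total)
        if t >= t_end:
            return state
        idx = int(np.searchsorted(np.cumsum(prop), rng.random() * total, side="right"))
        idx = min(idx, graph.n_sites - 1)
        site = graph.sites[idx]
        outcome = 1
        if model.variant == "cas9_independent":
            outcome = int(rng.integers(1, model.n_outcomes + 1))
        state.record(graph, site, t, outcome=outcome)
        prop[idx] = 0.0
        for dep in dependents[site]:
            j = graph.site_index[dep]
            if not state.status[j]:
                prop[j] = site_propensity(model, graph, dep, state)


def _trajectory_from_log(
    graph: SiteGraph, model: EditModel, state: EditState, times: np.ndarray, replicate: int
) -> Trajectory:
    """Replay an edit log into cumulative-edit / availability step functions."""
    edit_times = np.array([t for _, t in state.log])
    cum = np.searchsorted(edit_times, times, side="right").astype(float)

    # availability replay (all deps edited & site unedited); an out-of-order
    # mismatch edit consumes a site that was never counted available
    replay = EditState.unedited(graph)
    dependents = graph.dependents()
    base_avail = sum(1 for s in graph.sites if not graph.deps[s])
    avail_now = base_avail
    avail_at_event = []
    for site, _t in state.log:
        was_available = all(replay.status[graph.site_index[d]] for d in graph.deps[site])
        replay.status[graph.site_index[site]] = 1
        if was_available:
            avail_now -= 1
        for dep in dependents[site]:
            j = graph.site_index[dep]
            if not replay.status[j] and all(
                replay.status[graph.site_index[d]] for d in graph.deps[dep]
            ):
                # `site` was necessarily the last missing prerequisite
                avail_now += 1
        avail_at_event.append(avail_now)
    counts = np.searchsorted(edit_times, times, side="right")
    lookup = np.concatenate([[float(base_avail)], np.asarray(avail_at_event, dtype=float)])
    return Trajectory(
        replicate=replicate,
        times=times,
        cumulative_edits=cum,
        available_sites=lookup[counts],
    )


def simulate_editing(
    graph: SiteGraph,
    model: EditModel,
    duration: float,
    n_replicates: int = 1,
    seed: int | None = None,
    n_grid: int = 101,
) -> tuple[list[Trajectory], list[EditState]]:
    """Simulate ``n_replicates`` independent arrays for ``duration`` hours."""
    if duration <= 0:
        raise CascadeError("duration must be positive")
    ss = np.random.SeedSequence(seed)
    times = np.linspace(0.0, duration, n_grid)
    trajectories: list[Trajectory] = []
    finals: list[EditState] = []
    for rep, child in enumerate(ss.spawn(n_replicates)):
        rng = np.random.default_rng(child)
        state = EditState.unedited(graph)
        run_editing(graph, model, state, 0.0, duration, rng)
        trajectories.append(_trajectory_from_log(graph, model, state, times, rep))
        finals.append(state)
    return trajectories, finals


def mean_trajectory(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    """Average cumulative edits / availability over replicates."""
    times = trajectories[0].times
    cum = np.mean([t.cumulative_edits for t in trajectories], axis=0)
    avail = np.mean([t.available_sites for t in trajectories], axis=0)
    return pd.DataFrame({"time_h": times, "mean_cumulative_edits": cum, "mean_available_sites": avail})


def make_control_model(
    kind: Literal["length_matched", "site_matched", "cas9"],
    reference_graph: SiteGraph,
    rate: float = 1.0,
    n_outcomes: int = 9,
) -> tuple[SiteGraph, EditModel]:
    """Independent control systems matched to a hypercascade reference.

    ``length_matched``: one independent site per 20-bp unit, same DNA length.
    ``site_matched``: as many independent sites as the reference has in total
    (20 bp each, so a 74-site reference occupies 1.48 kb).
    ``cas9``: the length-matched layout with ``n_outcomes`` equiprobable
    terminal outcomes per site, mimicking multi-outcome nuclease repair.
    """
    if reference_graph.independent:
        raise CascadeError("reference must be a hypercascade graph")
    rates = (rate, rate, rate, rate)
    if kind == "length_matched":
        g = independent_graph(reference_graph.n_units, bp_length=reference_graph.bp_length)
        return g, EditModel(variant="independent", layer_rates=rates)
    if kind == "site_matched":
        g = independent_graph(reference_graph.n_sites)
        return g, EditModel(variant="independent", layer_rates=rates)
    if kind == "cas9":
        g = independent_graph(reference_graph.n_units, bp_length=reference_graph.bp_length)
        return g, EditModel(variant="cas9_independent", layer_rates=rates, n_outcomes=n_outcomes)
    raise CascadeError(f"unknown control kind {kind!r}")


def layer_distribution(states: Sequence[EditState], graph: SiteGraph) -> pd.DataFrame:
    """Mean edits per layer, grouped by total edits per array.

    Returns a frame indexed by total edit count with one ``layer_k`` column
    per layer present in the graph plus the group size ``n``.
    """
    if len(states) == 0:
        raise CascadeError("no states supplied")
    layers = graph.layers
    layer_masks = {l: np.array([s[0] == l for s in graph.sites]) for l in layers}
    rows = []
    for st in states:
        edited = st.status > 0
        row = {"total": int(edited.sum())}
        for l in layers:
            row[f"layer_{l}"] = int((edited & layer_masks[l]).sum())
        rows.append(row)
    df = pd.DataFrame(rows)
    out = df.groupby("total").agg(["mean", "size"])
    result = pd.DataFrame(index=out.index)
    for l in layers:
        result[f"layer_{l}"] = out[(f"layer_{l}", "mean")]
    result["n"] = out[(f"layer_{layers[0]}", "size")]
    return result


def trajectories_to_tsv(trajectories: Sequence[Trajectory], path) -> None:
    frames = []
    for t in trajectories:
        frames.append(
            pd.DataFrame(
                {
                    "time_h": t.times,
                    "replicate": t.replicate,
                    "total_edits": t.cumulative_edits,
                    "available_sites": t.available_sites,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def half_saturation_time(trajectories: Sequence[Trajectory], n_sites: int) -> float:
    """First grid time at which the replicate-mean cumulative edits reach half the sites."""
    m = mean_trajectory(trajectories)
    half = n_sites / 2.0
    above = m["mean_cumulative_edits"].to_numpy() >= half
    if not above.any():
        return float("inf")
    return float(m["time_h"].to_numpy()[np.argmax(above)])


def linearity_r2(trajectories: Sequence[Trajectory], n_sites: int, fraction: float = 0.8) -> float:
    """R^2 of a straight-line fit to mean cumulative edits over the first
    ``fraction`` of total editing (the regime where a regenerative array
    should look linear and an independent one exponential)."""
    m = mean_trajectory(trajectories)
    y = m["mean_cumulative_edits"].to_numpy()
    x = m["time_h"].to_numpy()
    cutoff = fraction * y[-1] if y[-1] > 0 else 0.0
    mask = y <= cutoff
    if mask.sum() < 3:
        mask = np.ones_like(y, dtype=bool)
    coeffs = np.polyfit(x[mask], y[mask], 1)
    resid = y[mask] - np.polyval(coeffs, x[mask])
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y[mask] - y[mask].mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
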