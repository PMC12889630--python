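"""Kinetic estimators for polyclonal editing data.

Three estimators live here:

* per-pattern rate constants ``k`` from endpoint reads, using the relation
  ``dG/dt = k * phi * s`` — ``G`` the number of edits matching an edit
  pattern, ``phi`` a cell-intrinsic activity factor estimated as the overall
  edit rate per read, and ``s`` the number of currently editable sites for
  the pattern, extracted empirically as a function of total edits per read;
* non-linear least-squares fitting of the multiplicative mismatch model
  (per-layer rates, per-position penalties, PAM penalty) to layer
  distributions;
* the closed-form edit-accumulation curve
  ``E(T) = (1/gamma) * ln((1 - p e^{-gamma T}) / (1 - p))`` with parameters
  ``p`` (initial per-transfection edit probability) and ``gamma`` (gRNA
  decay rate), plus open/closed editing ratios with propagated errors.

An "edit pattern" is the observable mismatch context of a target: its layer
plus the set of unrepaired mismatch positions (PAM included).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .cascade import PAM_POSITION, CascadeError, EditState, SiteGraph
from .simulate import DEFAULT_PENALTY_POSITIONS, EditModel

# ---------------------------------------------------------------------------
# patterns


@dataclass(frozen=True)
class EditPattern:
    """Layer plus unrepaired mismatch positions (21 = broken PAM)."""

    layer: int
    unrepaired: frozenset[int] = frozenset()

    @property
    def pam_broken(self) -> bool:
        return PAM_POSITION in self.unrepaired

    @property
    def is_perfect(self) -> bool:
        return not self.unrepaired

    def __str__(self) -> str:
        if self.is_perfect:
            return f"L{self.layer}:perfect"
        pos = ",".join("PAM" if p == PAM_POSITION else str(p) for p in sorted(self.unrepaired))
        return f"L{self.layer}:mm[{pos}]"


def perfect_pattern(layer: int) -> EditPattern:
    return EditPattern(layer=layer)


def site_context(graph: SiteGraph, site, status: np.ndarray) -> EditPattern:
    """The pattern a site presents in a given state (which of its engineered
    mismatches are still unrepaired)."""
    unrep = frozenset(
        pos
        for pos, repairer in graph.repair_map[site].items()
        if not status[graph.site_index[repairer]]
    )
    return EditPattern(layer=site[0], unrepaired=unrep)


def pattern_site_count(graph: SiteGraph, status: np.ndarray, pattern: EditPattern) -> int:
    """Number of unedited sites currently presenting ``pattern``."""
    n = 0
    for s in graph.sites:
        if s[0] != pattern.layer or status[graph.site_index[s]]:
            continue
        if site_context(graph, s, status) == pattern:
            n += 1
    return n


def pattern_edit_counts(graph: SiteGraph, status: np.ndarray) -> dict[EditPattern, int]:
    """Attribute each edited site to a pattern from the final state.

    A site whose prerequisites are all edited in the endpoint state is
    attributed to its layer's perfect-match pattern; one with unrepaired
    mismatches in the endpoint state must have edited out of order under at
    least those mismatches.  (Order within fully-repaired sites is not
    observable from endpoint data; ground-truth sidecars from the fixture
    generator carry exact per-edit attributions where needed.)
    """
    counts: dict[EditPattern, int] = {}
    for s in graph.sites:
        if not status[graph.site_index[s]]:
            continue
        pat = site_context(graph, s, status)
        counts[pat] = counts.get(pat, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# read kinetics


@dataclass
class PatternRateEstimate:
    pattern: EditPattern
    k: float
    se: float
    per_read_k: np.ndarray
    n_reads: int


def estimate_phi(total_edits: float, T: float) -> float:
    """Cell-intrinsic activity proxy: overall edit rate per read (per hour).

    Reads with zero edits get phi = 0 and are excluded downstream.
    """
    if T <= 0:
        raise CascadeError("collection time must be positive")
    return total_edits / T


def empirical_s_curve(
    reads: pd.DataFrame, graph: SiteGraph, pattern: EditPattern
) -> pd.Series:
    """Mean pattern-available site count as a function of total edits per read.

    ``reads`` must carry one row per read with columns ``site_0..site_{S-1}``
    holding 0/1 states (reads with N calls at the pattern's sites should be
    excluded upstream).  Gaps in the total-edit axis are linearly
    interpolated and logged.
    """
    site_cols = [c for c in reads.columns if c.startswith("site_")]
    status_mat = reads[site_cols].to_numpy(dtype=np.int16)
    totals = status_mat.sum(axis=1)
    by_total: dict[int, list[int]] = {}
    for status, tot in zip(status_mat, totals):
        by_total.setdefault(int(tot), []).append(pattern_site_count(graph, status, pattern))
    grid = np.arange(0, int(totals.max()) + 1)
    known = sorted(by_total)
    means = np.array([np.mean(by_total[t]) for t in known], dtype=float)
    if len(known) < len(grid):
        warnings.warn(
            f"{len(grid) - len(known)} total-edit values unobserved; interpolating s-curve",
            stacklevel=2,
        )
    values = np.interp(grid, known, means)
    return pd.Series(values, index=grid, name=str(pattern))


def integrate_s(total_edits: int, T: float, s_curve: pd.Series) -> float:
    """Trapezoidal ``integral of s dt`` over [0, T] for one read, assuming its
    total edit count grew linearly in time (edit-count axis rescaled to real
    time through the read's own endpoint)."""
    if total_edits <= 0:
        return float(s_curve.iloc[0]) * T
    grid = np.arange(0, total_edits + 1)
    svals = np.interp(grid, s_curve.index.to_numpy(), s_curve.to_numpy())
    times = T * grid / total_edits
    return float(np.trapezoid(svals, times))


def estimate_k(
    reads: pd.DataFrame,
    graph: SiteGraph,
    pattern: EditPattern,
    s_curve: pd.Series | None = None,
) -> PatternRateEstimate:
    """Per-pattern rate constant, one estimate per read, mean +/- SE.

    ``reads`` needs ``time_h`` plus ``site_*`` columns.  Reads with phi = 0
    (no edits) or a non-positive availability integral are excluded; if all
    reads are excluded the estimate fails explicitly.
    """
    if s_curve is None:
        s_curve = empirical_s_curve(reads, graph, pattern)
    site_cols = [c for c in reads.columns if c.startswith("site_")]
    ks = []
    for _, row in reads.iterrows():
        status = row[site_cols].to_numpy(dtype=np.int16)
        total = int(status.sum())
        T = float(row["time_h"])
        phi = estimate_phi(total, T)
        if phi <= 0:
            continue
        integral = integrate_s(total, T, s_curve)
        if integral <= 0:
            continue
        g_t = pattern_edit_counts(graph, status).get(pattern, 0)
        ks.append(g_t / (phi * integral))
    if not ks:
        raise CascadeError(f"no usable reads for pattern {pattern}")
    ks = np.asarray(ks)
    se = float(ks.std(ddof=1) / np.sqrt(len(ks))) if len(ks) > 1 else 0.0
    return PatternRateEstimate(
        pattern=pattern, k=float(ks.mean()), se=se, per_read_k=ks, n_reads=len(ks)
    )


def mean_total_availability(
    graph: SiteGraph, max_total: int, n_chains: int = 200, seed: int = 0
) -> float:
    """Mean count of available sites over the strict embedded jump chain,
    averaged over total-edit values ``0..max_total``.

    Used to pick phi-consistent simulation rates: the estimator assumes the
    overall edit rate per read estimates ``phi``, which holds when
    ``sum_p k_p s_p ~ 1``, i.e. when the per-site rate is the reciprocal of
    the mean total availability over the sampled editing regime.  For equal
    layer rates the jump chain (and hence availability vs total edits) does
    not depend on the rate scale.
    """
    from .simulate import EditModel, simulate_editing

    model = EditModel(variant="strict_hypercascade", layer_rates=(1.0,) * 4)
    horizon = 2.0 * max_total / max(graph.n_sites, 1) + 1.0  # enough to pass max_total
    trajs, _ = simulate_editing(graph, model, horizon, n_replicates=n_chains, seed=seed,
                                n_grid=20 * max_total + 1)
    per_total: dict[int, list[float]] = {}
    for t in trajs:
        seen: set[int] = set()
        for c, a in zip(t.cumulative_edits, t.available_sites):
            c = int(c)
            if c <= max_total and c not in seen:
                per_total.setdefault(c, []).append(a)
                seen.add(c)
    means = [np.mean(v) for _, v in sorted(per_total.items())]
    return float(np.mean(means))


def phi_consistent_rate(graph: SiteGraph, max_total: int, seed: int = 0) -> float:
    """Per-site rate making the overall per-read edit rate an unbiased phi
    estimate over the regime reaching ``max_total`` edits (see
    :func:`mean_total_availability`)."""
    return 1.0 / mean_total_availability(graph, max_total, seed=seed)


# ---------------------------------------------------------------------------
# mismatch-model fitting


def mean_field_layer_curves(
    graph: SiteGraph,
    layer_rates: Sequence[float],
    penalties: Mapping[int, float],
    pam_penalty: float,
    max_total: int,
) -> np.ndarray:
    """Deterministic surrogate for the expected per-layer edit counts as a
    function of total edits.

    Propagates a per-site edit probability ``q`` through the embedded jump
    chain under an independence approximation: at each step, site weights
    are the layer rate times, per mismatch position, the probability the
    repairer has edited plus the penalty-weighted probability it has not.
    Returns an array of shape ``(max_total + 1, n_layers)``; layer
    distributions depend only on rate *ratios*, so the overall scale of
    ``layer_rates`` is immaterial here.
    """
    n = graph.n_sites
    layers = np.array([s[0] for s in graph.sites])
    n_layers = int(layers.max())
    layer_masks = [layers == l for l in range(1, n_layers + 1)]
    q = np.zeros(n)
    out = np.zeros((max_total + 1, n_layers))
    rate_vec = np.array([layer_rates[l - 1] for l in layers], dtype=float)
    pen = {int(p): float(v) for p, v in penalties.items()}
    # flattened (site, repairer, penalty factor) triples for vectorized updates
    tri_site, tri_rep, tri_pen = [], [], []
    for s in graph.sites:
        for pos, rep in graph.repair_map[s].items():
            tri_site.append(graph.site_index[s])
            tri_rep.append(graph.site_index[rep])
            tri_pen.append(pam_penalty if pos == PAM_POSITION else pen.get(pos, 0.0))
    tri_site = np.asarray(tri_site, dtype=np.intp)
    tri_rep = np.asarray(tri_rep, dtype=np.intp)
    tri_pen = np.asarray(tri_pen, dtype=float)
    for m in range(1, max_total + 1):
        w = rate_vec * (1.0 - q)
        if tri_site.size:
            factors = q[tri_rep] + (1.0 - q[tri_rep]) * tri_pen
            agg = np.ones(n)
            np.multiply.at(agg, tri_site, factors)
            w *= agg
        total_w = w.sum()
        if total_w <= 0:
            out[m:] = out[m - 1]
            break
        q = np.clip(q + w / total_w, 0.0, 1.0)
        for l in range(n_layers):
            out[m, l] = q[layer_masks[l]].sum()
    return out


def simulated_layer_curves(
    graph: SiteGraph,
    layer_rates: Sequence[float],
    penalties: Mapping[int, float],
    pam_penalty: float,
    max_total: int,
    n_chains: int = 300,
    uniforms: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Expected per-layer edit counts vs total edits by Monte Carlo over the
    embedded jump chain (no waiting times: layer distributions conditional
    on total edits depend only on relative propensities).

    ``uniforms`` of shape ``(max_total, n_chains)`` enables common random
    numbers across objective evaluations during fitting.  Chains that stall
    (zero total propensity) stop contributing beyond their last total.
    Returns ``(max_total + 1, n_layers)`` means.
    """
    n = graph.n_sites
    layers = np.array([s[0] for s in graph.sites])
    n_layers = int(layers.max())
    layer_onehot = np.stack([(layers == l).astype(float) for l in range(1, n_layers + 1)])
    rate_vec = np.array([layer_rates[l - 1] for l in layers], dtype=float)
    pen = {int(p): float(v) for p, v in penalties.items()}
    # pad repair entries of each site into fixed slots for vectorized products
    max_slots = max((len(graph.repair_map[s]) for s in graph.sites), default=0)
    rep_idx = np.zeros((max_slots, n), dtype=np.intp)
    pen_val = np.ones((max_slots, n))
    has_slot = np.zeros((max_slots, n), dtype=bool)
    for s in graph.sites:
        for k, (pos, rep) in enumerate(sorted(graph.repair_map[s].items())):
            j = graph.site_index[s]
            rep_idx[k, j] = graph.site_index[rep]
            pen_val[k, j] = pam_penalty if pos == PAM_POSITION else pen.get(pos, 0.0)
            has_slot[k, j] = True
    if uniforms is None:
        uniforms = np.random.default_rng(seed).random((max_total, n_chains))
    C = uniforms.shape[1]
    status = np.zeros((C, n))
    out = np.zeros((max_total + 1, n_layers))
    active = np.ones(C, dtype=bool)
    counts = np.zeros(C, dtype=int)  # kept for clarity; all active chains share total m
    for m in range(1, max_total + 1):
        prop = np.broadcast_to(rate_vec, (C, n)) * (1.0 - status)
        for k in range(max_slots):
            q = status[:, rep_idx[k]]
            factor = np.where(has_slot[k], q + (1.0 - q) * pen_val[k], 1.0)
            prop = prop * factor
        total = prop.sum(axis=1)
        newly_stalled = active & (total <= 0)
        active = active & (total > 0)
        if not active.any():
            out[m:] = out[m - 1]
            break
        cum = np.cumsum(prop[active], axis=1)
        u = uniforms[m - 1, : active.sum()] * total[active]
        choice = (cum < u[:, None]).sum(axis=1)
        choice = np.minimum(choice, n - 1)
        rows = np.flatnonzero(active)
        status[rows, choice] = 1.0
        counts[rows] += 1
        out[m] = (status[rows] @ layer_onehot.T).mean(axis=0)
    return out


@dataclass
class MismatchFit:
    model: EditModel
    sse: float
    converged: bool
    n_starts: int
    message: str = ""


def fit_mismatch_model(
    layer_dist: pd.DataFrame,
    graph: SiteGraph,
    min_total_edits: int = 0,
    penalty_positions: Sequence[int] = DEFAULT_PENALTY_POSITIONS,
    n_starts: int = 5,
    seed: int | None = 0,
    l1: float = 1.0,
    n_chains: int = 300,
    maxiter: int = 400,
) -> MismatchFit:
    """Bounded least-squares fit of the multiplicative mismatch model.

    ``layer_dist`` is the observed table from
    :func:`hypercascade.simulate.layer_distribution` (index: total edits;
    columns ``layer_k``).  The forward model is the jump-chain Monte Carlo
    of :func:`simulated_layer_curves` evaluated with common random numbers,
    making the objective deterministic; it is minimized with bounded
    Nelder-Mead from ``n_starts`` seeded initializations (best SSE kept).
    Because layer distributions constrain only rate ratios, the layer-1
    rate is held at ``l1`` and ``l_2..l_4``, the shared per-position
    penalties and the PAM penalty are fitted relative to it.
    ``min_total_edits`` drops low-total bins dominated by sequencing noise.
    """
    obs = layer_dist[layer_dist.index > min_total_edits]
    if len(obs) < 4:
        raise CascadeError("need at least 4 total-edit bins to fit")
    layer_cols = [c for c in obs.columns if c.startswith("layer_")]
    n_layers = len(layer_cols)
    y = obs[layer_cols].to_numpy(dtype=float)
    weights = np.sqrt(obs["n"].to_numpy(dtype=float)) if "n" in obs.columns else np.ones(len(obs))
    totals = obs.index.to_numpy(dtype=int)
    max_total = int(totals.max())
    n_pen = len(penalty_positions)

    rng = np.random.default_rng(seed)
    uniforms = rng.random((max_total, n_chains))  # common random numbers

    def unpack(theta):
        rates = [l1] + list(theta[: n_layers - 1])
        pens = dict(zip(penalty_positions, theta[n_layers - 1 : n_layers - 1 + n_pen]))
        pam = theta[-1]
        return rates, pens, pam

    def objective(theta):
        rates, pens, pam = unpack(theta)
        curves = simulated_layer_curves(
            graph, rates, pens, pam, max_total, uniforms=uniforms
        )
        pred = curves[totals][:, :n_layers]
        return float((((pred - y) * weights[:, None]) ** 2).sum())

    lo = np.concatenate([np.full(n_layers - 1, 1e-6), np.zeros(n_pen + 1)])
    hi = np.concatenate([np.full(n_layers - 1, 100.0 * l1), np.ones(n_pen + 1)])
    best = None
    for start in range(n_starts):
        if start == 0:
            x0 = np.concatenate([np.full(n_layers - 1, l1), np.full(n_pen + 1, 0.05)])
        else:
            x0 = lo + (hi - lo) * rng.uniform(0.02, 0.6, size=lo.shape)
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            bounds=optimize.Bounds(lo, hi),
            options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-3},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None:  # pragma: no cover
        raise CascadeError("mismatch-model fit failed from every start")
    rates, pens, pam = unpack(best.x)
    model = EditModel(
        variant="mismatch_hypercascade",
        layer_rates=tuple(rates[:4]) if len(rates) >= 4 else tuple(rates) + (l1,) * (4 - len(rates)),
        mismatch_penalties={int(k): float(v) for k, v in pens.items()},
        pam_penalty=float(pam),
    )
    return MismatchFit(
        model=model,
        sse=float(best.fun),
        converged=bool(best.success),
        n_starts=n_starts,
        message=str(best.message),
    )


# ---------------------------------------------------------------------------
# edit-accumulation curve


def edit_accumulation(t, p: float, gamma: float):
    """Closed form of the accumulation integral
    ``E(T) = int_0^T p e^{-g t} / (1 - p e^{-g t}) dt
           = (1/g) ln((1 - p e^{-g T}) / (1 - p))``."""
    t = np.asarray(t, dtype=float)
    return np.log((1.0 - p * np.exp(-gamma * t)) / (1.0 - p)) / gamma


def edit_accumulation_quadrature(T: float, p: float, gamma: float) -> float:
    """Adaptive numerical quadrature of the accumulation integrand (used as
    an independent check of the closed form)."""
    from scipy.integrate import quad

    val, _ = quad(lambda t: p * np.exp(-gamma * t) / (1.0 - p * np.exp(-gamma * t)), 0.0, T)
    return val


@dataclass
class AccumulationFit:
    p: float
    gamma: float
    p_se: float
    gamma_se: float
    fitted: np.ndarray
    converged: bool = True


def fit_edit_accumulation(timepoints: Sequence[float], edited: Sequence[float]) -> AccumulationFit:
    """Fit (p, gamma) of the accumulation curve to a time course."""
    t = np.asarray(timepoints, dtype=float)
    y = np.asarray(edited, dtype=float)
    if len(t) < 3:
        raise CascadeError("need at least 3 timepoints")
    if np.ptp(y) <= 0:
        raise CascadeError("degenerate accumulation data (constant E)")
    # crude initialization: late plateau ~ -ln(1-p)/gamma, early slope ~ p
    slope0 = max((y[1] - y[0]) / (t[1] - t[0] + 1e-12), 1e-4)
    p0 = min(max(slope0, 1e-3), 0.95)
    g0 = 1.0 / max(t.max() / 3.0, 1e-6)
    popt, pcov = optimize.curve_fit(
        edit_accumulation, t, y, p0=(p0, g0),
        bounds=([1e-9, 1e-9], [1 - 1e-9, np.inf]), maxfev=20000,
    )
    ses = np.sqrt(np.diag(pcov))
    return AccumulationFit(
        p=float(popt[0]), gamma=float(popt[1]),
        p_se=float(ses[0]), gamma_se=float(ses[1]),
        fitted=edit_accumulation(t, *popt),
    )


def editing_ratio(fit_open: AccumulationFit, fit_closed: AccumulationFit) -> tuple[float, float]:
    """Open/closed editing ratio ``p_open / p_closed`` with first-order
    propagated standard error."""
    if fit_closed.p <= 1e-12:
        raise CascadeError("closed-chromatin p is ~0; ratio undefined")
    ratio = fit_open.p / fit_closed.p
    se = abs(ratio) * np.sqrt(
        (fit_open.p_se / fit_open.p) ** 2 + (fit_closed.p_se / fit_closed.p) ** 2
    )
    return float(ratio), float(se)
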