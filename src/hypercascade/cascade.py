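"""Hypercascade designs as site-dependency graphs.

A hypercascade barcode is a tandem repeat of a 20-bp unit carrying four
logical "layers" of A-to-G base-editor target sites.  Only layer-1 sites are
initially editable; editing a site converts its target A to G, and those Gs
repair engineered mismatches in the protospacers and PAMs of deeper-layer
sites, progressively unlocking them.  This module represents that unlock
logic as a DAG over sites ``(layer, index)`` together with a repair map that
records *which* edit fixes *which* mismatch position, renders concrete DNA
sequences for arbitrary edit states, and validates the structural
invariants (site counts, density, acyclicity).

Coordinates
-----------
Sites are 1-based ``(layer, index)`` pairs, layer in 1..4.  Sequence
positions are 1-based.  Protospacer positions run 1 (PAM-distal) to 20
(PAM-proximal); positions 21-23 are the PAM.  ``PAM_POSITION`` (21) is the
engineered PAM-breaking mismatch position.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

Site = tuple[int, int]

#: length of one repeat unit in bp
UNIT_LENGTH = 20
#: number of logical layers
N_LAYERS = 4
#: per-layer protospacer frame offset in bp
LAYER_OFFSET = 5
#: edited A sits at this protospacer position (ABEs edit position 5 or 6)
EDIT_PROTOSPACER_POSITION = 6
#: repair-map key denoting the PAM-breaking mismatch
PAM_POSITION = 21


class CascadeError(ValueError):
    """Raised on invalid designs, states or queries."""


@dataclass(frozen=True)
class UnitDesign:
    """A concrete 20-bp repeat unit with declared constrained/free positions.

    The shipped reference design is synthetic: it satisfies every structural
    constraint of the cascade geometry (edited A positions, layer PAMs,
    repairable mismatches; 9 constrained + 11 free positions) and documents
    its own PAM convention, without claiming to reproduce any published
    sequence.
    """

    name: str
    unit_sequence: str
    constrained_positions: Mapping[int, str]  # 1-based unit position -> base
    terminal_tail: str = "AGG"  # 3-bp tail providing the last layer-1 PAM

    def __post_init__(self) -> None:
        if len(self.unit_sequence) != UNIT_LENGTH:
            raise CascadeError(
                f"unit_sequence must be {UNIT_LENGTH} bp, got {len(self.unit_sequence)}"
            )
        if len(self.terminal_tail) != 3:
            raise CascadeError("terminal_tail must be 3 bp")
        for pos, base in self.constrained_positions.items():
            if not 1 <= pos <= UNIT_LENGTH:
                raise CascadeError(f"constrained position {pos} outside unit")
            if self.unit_sequence[pos - 1] != base:
                raise CascadeError(
                    f"unit_sequence[{pos}] = {self.unit_sequence[pos - 1]!r} "
                    f"contradicts constrained base {base!r}"
                )

    @property
    def free_positions(self) -> frozenset[int]:
        return frozenset(range(1, UNIT_LENGTH + 1)) - frozenset(self.constrained_positions)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "unit_sequence": self.unit_sequence,
            "constrained_positions": {str(k): v for k, v in self.constrained_positions.items()},
            "terminal_tail": self.terminal_tail,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "UnitDesign":
        return cls(
            name=d["name"],
            unit_sequence=d["unit_sequence"],
            constrained_positions={int(k): v for k, v in d["constrained_positions"].items()},
            terminal_tail=d.get("terminal_tail", "AGG"),
        )


def default_unit_design() -> UnitDesign:
    """The synthetic reference unit.

    Per-unit coordinates: the edited As sit at positions 1, 6, 11, 16 (layer
    4 of the previous index, then layers 1-3 of this index); each layer's PAM
    is the following dinucleotide, with the layer-1 PAM (GG at 2-3) intact
    from the start and the layer-2/3/4 PAMs completed by the repairing edit
    plus one constrained G (positions 7, 12, 17).  That leaves 11 free
    positions, filled here with pyrimidines so that A/G readout at target
    positions is unambiguous.
    """
    seq = "AGGCTAGCTCAGTCCAGTCT"
    constrained = {1: "A", 2: "G", 3: "G", 6: "A", 7: "G", 11: "A", 12: "G", 16: "A", 17: "G"}
    return UnitDesign(name="SYN01", unit_sequence=seq, constrained_positions=constrained)


@dataclass
class SiteGraph:
    """Unlock-dependency DAG of a hypercascade (or independent control) array.

    ``deps[s]`` holds every site whose edit is structurally required before
    ``s`` can edit at full rate (direct layer-(l-1) parents plus the in-frame
    implied layer-(l-2)/(l-3) sites).  ``repair_map[s]`` maps each engineered
    mismatch position of ``s`` (protospacer coordinates; 21 = PAM) to the
    site whose edit repairs it.
    """

    n_units: int
    terminal_pam_present: bool
    sites: list[Site]
    deps: dict[Site, frozenset[Site]]
    repair_map: dict[Site, dict[int, Site]]
    independent: bool = False
    bp_length: int = 0
    site_index: dict[Site, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.site_index:
            self.site_index = {s: i for i, s in enumerate(self.sites)}

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def layer_sites(self, layer: int) -> list[Site]:
        return [s for s in self.sites if s[0] == layer]

    @property
    def layers(self) -> list[int]:
        return sorted({s[0] for s in self.sites})

    def dependents(self) -> dict[Site, set[Site]]:
        """Reverse dependency map: site -> sites whose deps/repairs cite it."""
        cached = getattr(self, "_dependents_cache", None)
        if cached is None:
            rev: dict[Site, set[Site]] = {s: set() for s in self.sites}
            for s, ds in self.deps.items():
                for d in ds:
                    rev[d].add(s)
            object.__setattr__(self, "_dependents_cache", rev)
            cached = rev
        return cached

    def edit_position(self, site: Site) -> int:
        """1-based sequence position of the edited A of ``site``."""
        if self.independent:
            # one site per 20-bp unit, edited A at unit position 6
            return UNIT_LENGTH * (site[1] - 1) + EDIT_PROTOSPACER_POSITION
        layer, i = site
        return UNIT_LENGTH * (i - 1) + LAYER_OFFSET * (layer - 1) + EDIT_PROTOSPACER_POSITION

    def to_dict(self) -> dict:
        return {
            "n_units": self.n_units,
            "terminal_pam_present": self.terminal_pam_present,
            "independent": self.independent,
            "bp_length": self.bp_length,
            "sites": [list(s) for s in self.sites],
            "deps": {f"{l},{i}": sorted(map(list, ds)) for (l, i), ds in self.deps.items()},
            "repair_map": {
                f"{l},{i}": {str(pos): list(rep) for pos, rep in rm.items()}
                for (l, i), rm in self.repair_map.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SiteGraph":
        def key(k: str) -> Site:
            l, i = k.split(",")
            return (int(l), int(i))

        return cls(
            n_units=d["n_units"],
            terminal_pam_present=d["terminal_pam_present"],
            independent=d.get("independent", False),
            bp_length=d.get("bp_length", 0),
            sites=[tuple(s) for s in d["sites"]],
            deps={key(k): frozenset(tuple(s) for s in v) for k, v in d["deps"].items()},
            repair_map={
                key(k): {int(pos): tuple(rep) for pos, rep in v.items()}
                for k, v in d["repair_map"].items()
            },
        )


@dataclass
class EditState:
    """Per-array edit status with an optional timestamped, irreversible log.

    ``status`` is 0 for unedited, 1 for an A->G edit; the Cas9-style control
    model stores outcome labels 1..n_outcomes instead.  ``log`` records
    ``(site, time_h)`` in strictly increasing time order.
    """

    status: np.ndarray
    log: list[tuple[Site, float]] = field(default_factory=list)

    @classmethod
    def unedited(cls, graph: SiteGraph) -> "EditState":
        return cls(status=np.zeros(graph.n_sites, dtype=np.int16))

    def copy(self) -> "EditState":
        return EditState(status=self.status.copy(), log=list(self.log))

    @property
    def n_edited(self) -> int:
        return int(np.count_nonzero(self.status))

    def is_edited(self, graph: SiteGraph, site: Site) -> bool:
        return bool(self.status[graph.site_index[site]])

    def edited_sites(self, graph: SiteGraph) -> list[Site]:
        return [graph.sites[i] for i in np.flatnonzero(self.status)]

    def record(self, graph: SiteGraph, site: Site, time_h: float, outcome: int = 1) -> None:
        idx = graph.site_index[site]
        if self.status[idx]:
            raise CascadeError(f"site {site} already edited (edits are irreversible)")
        if self.log and time_h < self.log[-1][1]:
            raise CascadeError("edit log times must be non-decreasing")
        self.status[idx] = outcome
        self.log.append((site, time_h))

    def hash(self) -> str:
        return hashlib.sha1(self.status.tobytes()).hexdigest()[:12]


def build_site_graph(n_units: int, terminal_pam_present: bool = True) -> SiteGraph:
    """Construct the unlock DAG for ``n_units`` tandem repeats.

    Layer ``l`` has ``max(0, m - l + 1)`` sites, where ``m`` is ``n_units``
    when the terminal PAM is present and ``n_units - 1`` otherwise (the last
    layer-1 site needs a PAM in the 3-bp tail; without it, everything
    cascading from that site disappears too).
    """
    if not isinstance(n_units, (int, np.integer)) or n_units < 1:
        raise CascadeError(f"n_units must be a positive integer, got {n_units!r}")
    m = n_units if terminal_pam_present else n_units - 1

    sites: list[Site] = []
    for layer in range(1, N_LAYERS + 1):
        sites.extend((layer, i) for i in range(1, max(0, m - layer + 1) + 1))

    site_set = set(sites)
    deps: dict[Site, frozenset[Site]] = {}
    repair: dict[Site, dict[int, Site]] = {}
    for layer, i in sites:
        if layer == 1:
            deps[(layer, i)] = frozenset()
            repair[(layer, i)] = {}
            continue
        d: set[Site] = {(layer - 1, i), (layer - 1, i + 1)}
        # protospacer position 1 repaired by the left parent, PAM by the right
        rm: dict[int, Site] = {1: (layer - 1, i), PAM_POSITION: (layer - 1, i + 1)}
        if layer >= 3:
            d.add((layer - 2, i + 1))
            rm[16] = (layer - 2, i + 1)
        if layer == 4:
            d.add((layer - 3, i + 1))
            rm[11] = (layer - 3, i + 1)
        missing = d - site_set
        if missing:  # pragma: no cover - construction guarantees closure
            raise CascadeError(f"site {(layer, i)} depends on missing sites {missing}")
        deps[(layer, i)] = frozenset(d)
        repair[(layer, i)] = rm

    bp = UNIT_LENGTH * n_units + (3 if terminal_pam_present else 0)
    return SiteGraph(
        n_units=n_units,
        terminal_pam_present=terminal_pam_present,
        sites=sites,
        deps=deps,
        repair_map=repair,
        bp_length=bp,
    )


def independent_graph(n_sites: int, bp_length: int | None = None) -> SiteGraph:
    """A control array of ``n_sites`` non-interacting target sites."""
    if n_sites < 1:
        raise CascadeError("n_sites must be positive")
    sites = [(1, i) for i in range(1, n_sites + 1)]
    return SiteGraph(
        n_units=n_sites,
        terminal_pam_present=True,
        sites=sites,
        deps={s: frozenset() for s in sites},
        repair_map={s: {} for s in sites},
        independent=True,
        bp_length=bp_length if bp_length is not None else UNIT_LENGTH * n_sites,
    )


def _check_state(graph: SiteGraph, state: EditState) -> None:
    if state.status.shape[0] != graph.n_sites:
        raise CascadeError(
            f"state dimension {state.status.shape[0]} does not match graph "
            f"with {graph.n_sites} sites"
        )


def available_sites(graph: SiteGraph, state: EditState) -> set[Site]:
    """Sites that are unedited and whose prerequisites are all edited."""
    _check_state(graph, state)
    out: set[Site] = set()
    for s in graph.sites:
        idx = graph.site_index[s]
        if state.status[idx]:
            continue
        if all(state.status[graph.site_index[d]] for d in graph.deps[s]):
            out.add(s)
    return out


def _closure(graph: SiteGraph, site: Site, memo: dict[Site, frozenset[Site]]) -> frozenset[Site]:
    if site in memo:
        return memo[site]
    acc: set[Site] = set()
    for d in graph.deps[site]:
        acc.add(d)
        acc |= _closure(graph, d, memo)
    memo[site] = frozenset(acc)
    return memo[site]


def min_edits_to_unlock(graph: SiteGraph, layer: int) -> int:
    """Minimum prior edits before any site of ``layer`` becomes available."""
    layer_sites = graph.layer_sites(layer)
    if not layer_sites:
        raise CascadeError(f"layer {layer} has no sites in this graph")
    memo: dict[Site, frozenset[Site]] = {}
    return min(len(_closure(graph, s, memo)) for s in layer_sites)


def count_design_space(n_free: int) -> int:
    """Number of distinct units with ``n_free`` unconstrained positions."""
    if n_free < 0:
        raise CascadeError("n_free must be non-negative")
    return 4**n_free


def render_sequence(design: UnitDesign, graph: SiteGraph, state: EditState) -> str:
    """Render the array's DNA for ``state``: edited site As become Gs."""
    if graph.independent:
        raise CascadeError("rendering is defined for cascade graphs, not independent controls")
    _check_state(graph, state)
    chars = list(design.unit_sequence * graph.n_units)
    if graph.terminal_pam_present:
        chars.extend(design.terminal_tail)
    for i in np.flatnonzero(state.status):
        pos = graph.edit_position(graph.sites[i])
        if chars[pos - 1] != "A":  # pragma: no cover - design validation
            raise CascadeError(f"edit position {pos} is not an A in this design")
        chars[pos - 1] = "G"
    return "".join(chars)


def read_state_from_sequence(design: UnitDesign, graph: SiteGraph, seq: str) -> EditState:
    """Invert :func:`render_sequence`: recover the edit state from bases."""
    expected = UNIT_LENGTH * graph.n_units + (3 if graph.terminal_pam_present else 0)
    if len(seq) != expected:
        raise CascadeError(f"sequence length {len(seq)} != expected {expected}")
    state = EditState.unedited(graph)
    for s in graph.sites:
        base = seq[graph.edit_position(s) - 1]
        if base == "G":
            state.status[graph.site_index[s]] = 1
        elif base != "A":
            raise CascadeError(f"unexpected base {base!r} at target position of {s}")
    return state


def write_fasta(
    path,
    design: UnitDesign,
    graph: SiteGraph,
    states: Sequence[EditState],
    ids: Iterable[str] | None = None,
) -> None:
    """Write rendered arrays as FASTA, one record per array copy."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = []
    ids = list(ids) if ids is not None else [f"array_{k}" for k in range(len(states))]
    for rid, st in zip(ids, states):
        rec = SeqRecord(
            Seq(render_sequence(design, graph, st)),
            id=rid,
            description=f"design={design.name} state={st.hash()} edits={st.n_edited}",
        )
        records.append(rec)
    seqio_write(records, path, "fasta")


def graph_to_json(graph: SiteGraph, path) -> None:
    with open(path, "w") as fh:
        json.dump(graph.to_dict(), fh, indent=1)


def graph_from_json(path) -> SiteGraph:
    with open(path) as fh:
        return SiteGraph.from_dict(json.load(fh))
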