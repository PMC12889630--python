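"""Synthetic fixture generation emulating the recorder's real data modes.

Every generator draws from the same stochastic machinery the simulators
use, so fixtures carry the statistical structure the analyses assume:
polyclonal read populations with heterogeneous per-read editing activity
(lognormal phi spread), layer-ordered edit accumulation with configurable
out-of-order (mismatch) leakage, multi-timepoint sampling, and hybrid-line
allele reads with disjoint SNP sets and a configurable sequencing error
rate.  A ground-truth sidecar (JSON) is always produced.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .calling import AlleleReferences
from .cascade import EditState, SiteGraph, build_site_graph
from .lineage import DivisionModel, default_chromatin_program, grow_tree
from .simulate import EditModel, run_editing


def _scaled_model(model: EditModel, phi: float) -> EditModel:
    return EditModel(
        variant=model.variant,
        layer_rates=tuple(r * phi for r in model.layer_rates),
        mismatch_penalties=dict(model.mismatch_penalties),
        pam_penalty=model.pam_penalty,
        n_outcomes=model.n_outcomes,
    )


def polyclonal_reads(
    graph: SiteGraph,
    model: EditModel,
    timepoints_h: Sequence[float] = (120.0, 240.0, 360.0),
    n_reads_per_timepoint: int = 300,
    phi_sigma: float = 0.5,
    base_quality: float = 37.0,
    low_quality_fraction: float = 0.0,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, dict]:
    """Polyclonal endpoint reads of one recorder array.

    Each read represents one sequenced molecule from a cell with its own
    activity multiplier ``phi ~ lognormal(-sigma^2/2, sigma)`` (unit mean);
    the read's sites are a Gillespie endpoint of the scaled model at its
    timepoint.  ``low_quality_fraction`` of calls get quality 5 (masked to N
    by the standard filter).  Returns (read table, ground-truth sidecar).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    phis = []
    for t in timepoints_h:
        for r in range(n_reads_per_timepoint):
            phi = float(rng.lognormal(-(phi_sigma**2) / 2.0, phi_sigma))
            phis.append(phi)
            state = EditState.unedited(graph)
            run_editing(graph, _scaled_model(model, phi), state, 0.0, t, rng)
            calls = np.where(state.status > 0, "G", "A")
            quals = np.full(graph.n_sites, base_quality)
            if low_quality_fraction > 0:
                mask = rng.random(graph.n_sites) < low_quality_fraction
                quals[mask] = 5.0
            row = {"read_id": f"t{t:g}_r{r}", "sample": "polyclonal", "timepoint": t,
                   "time_h": t}
            row.update({f"site_{i}": calls[i] for i in range(graph.n_sites)})
            row.update({f"qual_{i}": quals[i] for i in range(graph.n_sites)})
            rows.append(row)
    truth = {
        "kind": "polyclonal_reads",
        "model": {
            "variant": model.variant,
            "layer_rates": list(model.layer_rates),
            "mismatch_penalties": {str(k): v for k, v in model.mismatch_penalties.items()},
            "pam_penalty": model.pam_penalty,
        },
        "phi_sigma": phi_sigma,
        "phi_values": phis,
        "timepoints_h": list(timepoints_h),
        "n_units": graph.n_units,
        "seed": seed,
    }
    return pd.DataFrame(rows), truth


def lineage_barcodes(
    n_units: int = 20,
    rate: float = 0.01,
    copies: int = 3,
    mean_depth: float = 10.0,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, str, dict]:
    """Simulated tree -> (leaf barcode table, ground-truth newick, sidecar)."""
    graph = build_site_graph(n_units)
    model = EditModel(variant="strict_hypercascade", layer_rates=(rate,) * 4)
    tree = grow_tree(
        graph, model, DivisionModel("exponential", tau=24.0), copies=copies,
        stop=("mean_depth", mean_depth), seed=seed,
    )
    data, labels = tree.leaf_barcode_matrix()
    df = pd.DataFrame(data, index=labels, columns=[f"f{j}" for j in range(data.shape[1])])
    df.index.name = "taxon"
    sidecar = {
        "kind": "lineage_barcodes", "n_units": n_units, "rate": rate,
        "copies": copies, "mean_depth_target": mean_depth,
        "mean_depth_realized": tree.mean_leaf_depth(),
        "n_leaves": tree.n_leaves, "duration_h": tree.duration, "seed": seed,
    }
    return df, tree.newick(), sidecar


def patski_alleles(
    n_reads: int = 2000,
    p_edit_open: float = 0.4,
    p_edit_closed: float = 0.1,
    error_rate: float = 0.01,
    n_snps: int = 5,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, AlleleReferences, dict]:
    """Hybrid-line amplicon reads: one target site plus ``n_snps`` disjoint
    SNPs distinguishing the active (open) from the silenced (closed) allele.

    Sequencing errors flip each SNP base to a random other base at
    ``error_rate``, so the expected unassigned fraction is about
    ``1 - (1 - error_rate)^n_snps``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    bases = np.array(list("ACGT"))
    ref1 = tuple(rng.choice(bases, n_snps))
    ref2 = tuple(
        str(rng.choice([b for b in bases if b != r])) for r in ref1
    )  # disjoint at every position
    refs = AlleleReferences(allele_1=ref1, allele_2=ref2, name_1="spretus_open", name_2="musculus_closed")
    rows = []
    for i in range(n_reads):
        is_open = bool(rng.random() < 0.5)
        true_snps = list(ref1 if is_open else ref2)
        snps = [
            str(rng.choice([b for b in bases if b != s])) if rng.random() < error_rate else s
            for s in true_snps
        ]
        p_edit = p_edit_open if is_open else p_edit_closed
        call = "G" if rng.random() < p_edit else "A"
        row = {"read_id": f"r{i}", "sample": "patski", "timepoint": 48.0,
               "site_0": call, "qual_0": 37.0,
               "true_allele": "spretus_open" if is_open else "musculus_closed"}
        row.update({f"snp_{j + 1}": snps[j] for j in range(n_snps)})
        row.update({f"snpq_{j + 1}": 37.0 for j in range(n_snps)})
        rows.append(row)
    truth = {
        "kind": "patski_alleles", "p_edit_open": p_edit_open,
        "p_edit_closed": p_edit_closed, "error_rate": error_rate,
        "references": {"spretus_open": list(ref1), "musculus_closed": list(ref2)},
        "seed": seed,
    }
    return pd.DataFrame(rows), refs, truth


def generate_fixtures(kind: str, outdir, seed: int = 0, **params) -> list[Path]:
    """Write fixture files for ``kind`` into ``outdir``; returns paths.

    Kinds: ``polyclonal_reads``, ``lineage_barcodes``, ``chromatin_program``,
    ``patski_alleles``.  Ground-truth sidecars are always emitted.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def dump(obj, name):
        path = outdir / name
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, default=float)
        written.append(path)

    if kind == "polyclonal_reads":
        n_units = int(params.pop("n_units", 20))
        graph = build_site_graph(n_units)
        model = params.pop("model", None) or EditModel(
            variant="mismatch_hypercascade",
            layer_rates=(0.01, 0.008, 0.008, 0.006),
            mismatch_penalties={1: 0.05, 11: 0.08, 16: 0.1},
            pam_penalty=0.02,
        )
        reads, truth = polyclonal_reads(graph, model, seed=seed, **params)
        path = outdir / "polyclonal_reads.tsv"
        reads.to_csv(path, sep="\t", index=False)
        written.append(path)
        dump(truth, "polyclonal_reads.truth.json")
    elif kind == "lineage_barcodes":
        df, newick, truth = lineage_barcodes(seed=seed, **params)
        p1 = outdir / "lineage_barcodes.tsv"
        df.to_csv(p1, sep="\t")
        p2 = outdir / "lineage_ground_truth.nwk"
        p2.write_text(newick + "\n")
        written.extend([p1, p2])
        dump(truth, "lineage_barcodes.truth.json")
    elif kind == "chromatin_program":
        program = default_chromatin_program()
        spec = {
            "trajectories": program.trajectories,
            "patterns": [
                ["".join("O" if o else "C" for o in epoch) for epoch in traj]
                for traj in program.patterns
            ],
            "transition_matrices": program.transition_matrices.tolist(),
            "duration_days": program.duration_days,
            "n_static": program.n_static,
            "n_dynamic": program.n_dynamic,
            "open_rate": program.open_rate,
            "fold_reduction": program.fold_reduction,
            "n_units": program.n_units,
        }
        import yaml

        path = outdir / "chromatin_program.yaml"
        path.write_text(yaml.safe_dump(spec, sort_keys=False))
        written.append(path)
    elif kind == "patski_alleles":
        reads, refs, truth = patski_alleles(seed=seed, **params)
        path = outdir / "patski_alleles.tsv"
        reads.to_csv(path, sep="\t", index=False)
        written.append(path)
        dump(truth, "patski_alleles.truth.json")
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return written


def load_chromatin_program(path):
    """Read a chromatin-program YAML back into a ChromatinProgram."""
    import yaml

    from .lineage import ChromatinProgram

    with open(path) as fh:
        spec = yaml.safe_load(fh)
    patterns = np.array(
        [[[c == "O" for c in epoch] for epoch in traj] for traj in spec["patterns"]]
    )
    return ChromatinProgram(
        trajectories=spec["trajectories"],
        patterns=patterns,
        transition_matrices=np.asarray(spec["transition_matrices"], dtype=float),
        duration_days=spec["duration_days"],
        n_static=spec["n_static"],
        n_dynamic=spec["n_dynamic"],
        open_rate=spec["open_rate"],
        fold_reduction=spec["fold_reduction"],
        n_units=spec["n_units"],
    )
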