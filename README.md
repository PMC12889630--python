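# hypercascade

Simulation, reconstruction and inference toolkit for **regenerative
base-editing lineage recorders** — tandem-repeat DNA barcodes in which
A-to-G base edits repair engineered mismatches and thereby unlock new
target sites, layer by layer.

## The problem

Cells carrying an editable barcode accumulate heritable, irreversible edits
as they divide; the endpoint edit patterns let one reconstruct the lineage
tree relating the cells, like a phylogeny. Ordinary recorder arrays edit
each site independently, so the pool of unedited sites — and with it the
edit rate — decays exponentially: most information is written in the first
few generations. A *regenerative* array avoids this: its 20-bp repeat packs
four logical layers of target sites (4 sites per 20 bp; 74 sites in 403 bp
for 20 repeats), and each edit repairs mismatches that unlock deeper-layer
sites at roughly a 1:1 ratio, keeping the edit rate approximately constant
until the array is nearly exhausted. Sustained editing means deeper,
more accurate lineage reconstruction — and, because every genomic
integration reports its local edit rate over time, the same records can
reveal chromatin-state dynamics at each integration locus.

The package is aimed at people designing such recorders or analyzing their
(real or simulated) output. It provides:

* `hypercascade.cascade` — the site-dependency DAG of a design: unlock
  logic, repair maps, sequence rendering and FASTA/JSON I/O;
* `hypercascade.simulate` — exact Gillespie simulation of editing under
  strict or mismatch-penalized kinetics, with length-matched, site-matched
  and multi-outcome (Cas9-style) independent controls;
* `hypercascade.lineage` — lineage trees of dividing cells with continuous
  editing, and chromatin-programmed differentiation simulations;
* `hypercascade.reconstruct` — Hamming distances, deterministic UPGMA,
  normalized Robinson–Foulds scoring, barcode-scrambling nulls,
  transfer-bootstrap clade support, benchmark sweeps;
* `hypercascade.rates` — kinetic estimators: per-pattern rate constants
  `k = G_T/(φ∫s dt)`, non-linear least-squares fitting of the
  multiplicative mismatch model, and the edit-accumulation curve
  `E(T) = (1/γ)·ln((1 − p e^{−γT})/(1 − p))` with open/closed editing
  ratios;
* `hypercascade.chromatin` — ancestral-state inference by intersection,
  branch-rate estimation, polynomial featurization, Gaussian-mixture
  clustering and penalized-spline group curves;
* `hypercascade.calling` — base-call masking, edited fractions, layer
  filters and SNP-based allele classification;
* `hypercascade.fixtures` + a `hypercascade` CLI tying it together.

See `docs/methods.md` for the models and numerical choices.

## Worked example

```python
import hypercascade as hc
from hypercascade.simulate import (EditModel, simulate_editing,
                                   make_control_model, linearity_r2,
                                   half_saturation_time)

g = hc.build_site_graph(20)          # 20 repeats
print(g.n_sites, g.bp_length)        # -> 74 403

rate = 0.02                          # edits/site/hour
hyper = EditModel(variant="strict_hypercascade", layer_rates=(rate,) * 4)
trajs_h, _ = simulate_editing(g, hyper, 600, n_replicates=200, seed=101)
gi, mi = make_control_model("site_matched", g, rate=rate)   # 74 sites, 1.48 kb
trajs_i, _ = simulate_editing(gi, mi, 600, n_replicates=200, seed=102)

print(round(linearity_r2(trajs_h, 74), 4))       # -> 0.9917
print(round(linearity_r2(trajs_i, 74), 4))       # -> 0.9647
print(half_saturation_time(trajs_h, 74))         # -> 150.0  (hours)
print(half_saturation_time(trajs_i, 74))         # -> 40.0
```

At the same per-site rate, the regenerative array accumulates edits nearly
linearly (straight-line R² 0.99 over the first 80% of editing, against
0.96 for the independent control) and reaches half-saturation almost four
times later (150 h vs 40 h): the recorder keeps writing long after an
independent array of the same size has spent its memory. The same
advantage shows up in reconstruction accuracy:

```python
from hypercascade.reconstruct import benchmark_sweep
hi = benchmark_sweep(["hypercascade", "site_matched"], rates=[0.05],
                     copies=[3], depths=[10.0], n_replicates=10, seed=202)
print(hi[["system", "mean_rf"]].round(2))
#          system  mean_rf
#    hypercascade     0.57
#    site_matched     0.97
```

At a high edit rate and mean tree depth 10, trees reconstructed from the
regenerative barcodes sit at normalized Robinson–Foulds distance 0.57 from
the ground truth (0 = identical topology, 1 = maximally different), while
the saturated site-matched independent array is near the random-tree
ceiling at 0.97.

The chromatin-recording pipeline runs end to end from the CLI:

```sh
hypercascade chromatin --trees 20 --seed 404 --out out/
# 5455 cells, cluster accuracy 0.488, static rate 2.00 edits/array/day
```

The statically open loci recover their programmed 2 edits/array/day and the
four-way clustering of inferred rate histories groups cells by their true
differentiation trajectory at double the 0.25 chance level.

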