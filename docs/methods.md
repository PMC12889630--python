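# Methods

This note documents the models, estimators and numerical choices behind the
`hypercascade` package: a toolkit for simulating and analyzing regenerative
A-to-G base-editing lineage recorders.

## The recorder model

A recorder array is a tandem repeat of a 20-bp unit carrying four logical
*layers* of base-editor target sites, one gRNA per layer. Only layer-1 sites
are initially editable; every edit converts a target A to G, and those Gs
repair engineered protospacer/PAM mismatches of deeper-layer sites. A
layer-ℓ site (ℓ ≥ 2) unlocks after its two flanking layer-(ℓ−1) edits;
transitively this implies specific layer-(ℓ−2) and layer-(ℓ−3) edits, which
are stored explicitly in the dependency graph because the mismatch model
needs to know *which* edit repairs *which* position.

Geometry. Layer frames are successive 5-bp offsets of the 20-bp protospacer
across the repeat boundary, with the edited A at protospacer position 6.
Under this geometry the in-frame repairable mismatches of a layer-ℓ site sit
at protospacer positions 1 (left parent), 16 (grand-parent layer), 11
(great-grand-parent layer) and the PAM (right parent). An array of `n`
units has `n, n−1, n−2, n−3` sites per layer (a site whose parent does not
exist can never unlock and is not counted), i.e. `4n − 6` sites for n ≥ 4:
74 sites in 403 bp for n = 20, and 70 when the terminal 3-bp PAM tail is
omitted. The shipped reference unit (`default_unit_design`) is synthetic: it
satisfies every structural constraint (9 constrained + 11 free positions, 4
edited As per unit, layer PAMs completed by the repairing edit under a
simplified GG-dinucleotide PAM convention documented in its docstring) but
does not claim to reproduce any experimentally used sequence, whose exact
bases are not public in machine-readable form.

## Stochastic editing

Editing is simulated exactly with the Gillespie algorithm: exponential
waiting times at the summed propensity, event site chosen proportionally to
propensity, incremental propensity updates over the edited site's
structural dependents. Model variants:

* `strict_hypercascade` — propensity is the layer rate `l_k` (per site per
  hour) once all prerequisites are edited, zero before;
* `mismatch_hypercascade` — a partially unlocked site edits at
  `l_k · Π_j p_j · (pam_penalty if the PAM mismatch is unrepaired)`, one
  multiplicative penalty per unrepaired position, shared across layers
  (per-position classes 1, 11, 16 plus PAM in the shipped geometry);
* `independent` / `cas9_independent` — non-interacting control sites at a
  constant rate; the Cas9-style control draws one of 9 equiprobable terminal
  outcomes per edit (≈ log₂9 ≈ 3.2 bits per site). The length-matched
  control has 20 sites in 403 bp; the site-matched control has 74 sites in
  1.48 kb. The Cas9 control uses the 20-site, length-matched layout with
  multi-outcome states.

## Lineage simulation

Cells divide with pluggable waiting-time distributions (`exponential`,
`gamma`, both with mean τ; default τ = 24 h and shape α = 0.9 where
applicable, modeling stem-like cells dividing roughly once per day). An
`eyring_stover` slot is reserved for the cell-cycle survival model of that
name; its closed form is not shipped, and a sampler can be registered via
`register_division_sampler`. All shipped configurations default to the
exponential model.

Editing runs continuously on every extant cell's arrays (per-cell Gillespie
clocks over each lifespan); both daughters inherit the parent's exact edit
states, so edits are heritable and irreversible along every path. Stop
rules: a fixed duration, or a target leaf-count-weighted mean division
depth — divisions proceed until the mean depth of extant cells first
reaches the target, then stop, with editing continuing to the last division
time. A `max_cells` cap (a crude carrying capacity) bounds memory on
heavy-tailed growth realizations and returns a flagged partial tree.

## Reconstruction

Endpoint barcodes (concatenated array copies, 0/1 per site) are compared by
raw Hamming counts (a normalized option exists) and clustered by UPGMA.
The UPGMA implementation is deterministic: among equal-distance merge
candidates, the pair whose lexicographically smallest member labels sort
first is merged. Merge heights are half the between-cluster mean distance;
the cophenetic matrix stores the full merge distance, matching R's
`cophenetic` on an `hclust` tree. Trees are scored with the normalized
Robinson–Foulds distance: the symmetric difference of nontrivial unrooted
bipartitions divided by the total nontrivial split count of both trees
(2(n−3) for two binary trees; multifurcating trees contribute their actual
split counts). Permutation nulls scramble each barcode column independently
across taxa, preserving per-site edit frequencies. Clade support is the
transfer bootstrap: feature columns resampled with replacement, support
`1 − mean(transfer distance)/(clade size − 1)`.

The benchmark sweep simulates forward (strict kinetics, equal per-site
rates in all systems), reconstructs by UPGMA and averages the normalized RF
over replicates per grid cell. Default replication in the shipped configs
is 10 per cell on a reduced grid (two rate regimes at mean depth 10, copy
number 3), which resolves the qualitative regimes cleanly: at low rates the
regenerative array matches the length-matched control within sampling
error; at high rates it clearly beats the site-matched control, whose
targets saturate early.

## Rate estimation

**Per-pattern rate constants.** An *edit pattern* is a target's observable
mismatch context: layer plus the set of unrepaired positions. The estimator
implements `k = G_T / (φ ∫₀ᵀ s(t) dt)` per read, averaging over reads
(mean ± SE): `G_T` is the number of edits attributed to the pattern at
collection time `T`; `φ`, the cell-intrinsic activity, is estimated as the
read's overall edit rate (edits per hour; zero-edit reads are excluded);
and `s`, the number of currently editable sites for the pattern, is
extracted from the data as a function of total edits per read (mean at each
total, gaps interpolated linearly) and rescaled to real time through the
read's own endpoint assuming totals grow linearly in time. The integral
uses trapezoidal quadrature. Endpoint attribution assigns an edited site to
the perfect-match pattern of its layer when its prerequisites are all
edited in the final state, and to the corresponding mismatch pattern
otherwise; exact per-edit attributions are available from the fixture
generator's ground-truth sidecars.

Because φ is itself estimated from the data, the absolute scale of `k` is
tied to the φ convention: the estimate is unbiased when the overall edit
rate per read is an unbiased φ estimate, i.e. when `Σ_p k_p s_p ≈ 1` over
the sampled regime. `phi_consistent_rate` computes the per-site rate
satisfying this from the mean total availability of the strict jump chain
(availability settles near ~12 of 74 sites after the initial transient).
Uniform rescaling of all rates cancels in the estimator by construction;
what is recoverable absolutely is the rate in φ-consistent units, and
relatively, the ratios between patterns.

**Mismatch-model fitting.** The multiplicative model's parameters
(`l_2..l_4` relative to a fixed `l_1`, shared per-position penalties, PAM
penalty) are fitted to observed layer distributions (mean edits per layer
vs total edits) by bounded least squares. The forward model is a Monte
Carlo of the embedded jump chain — layer distributions conditional on total
edits depend only on relative propensities, so no waiting times are needed —
evaluated with common random numbers so the objective is deterministic, and
minimized with bounded Nelder–Mead from five seeded starts (best SSE kept).
A deterministic mean-field surrogate (`mean_field_layer_curves`) is also
provided for fast exploration; it tracks the simulation to a few tenths of
an edit but its bias exceeds the faint out-of-order signal, so the fit uses
the simulation objective. Identifiability caveat: a layer's locked-state
propensity constrains only the product of its unrepaired penalties, so
individual penalties are resolved through partially repaired contexts and
small penalties may tie; strongly separated penalties order correctly in
recovery tests.

**Edit accumulation.** The accumulation curve
`E(T) = (1/γ) ln((1 − p e^{−γT}) / (1 − p))` (closed form of the integral of
`p e^{−γt} / (1 − p e^{−γt})`; verified against adaptive quadrature to
1e−8) is fitted by `scipy.optimize.curve_fit` with bounds p ∈ (0, 1),
γ > 0; SEs come from the covariance. The open/closed editing ratio is
`p_open/p_closed` with first-order error propagation (checked against a
parametric bootstrap).

## Chromatin-state recording

The differentiation simulator gives every cell 20 arrays of 74 sites: 15
*static* (always-open chromatin) and 5 *dynamic* loci whose open/closed
state follows the cell's trajectory through 5 evenly spaced epochs over 6
days. Open loci edit at 2 edits/array/day, closed loci 4-fold slower.
Array-level editing is a Poisson process at the scheduled rate, each event
editing a uniformly chosen currently available cascade site: this realizes
the stated array-level rates exactly (the regenerative design's
constant-rate regime) without reverse-engineering per-site propensities.
The default program has four trajectories: all identical in epoch 1 (free
mixing), two ("blue"/"pink") identical through epoch 3 before diverging to
distinct fates, and two ("orange"/"green") distinct from epoch 2 but
converging on one terminal pattern (convergent differentiation).
Trajectory switches happen at divisions via per-epoch row-stochastic
matrices; transitions are only allowed between trajectories whose
current-epoch patterns are identical, enforced at load.

Inference proceeds: UPGMA reconstruction → ancestral barcodes by bottom-up
intersection (irreversibility makes the intersection a superset of the true
ancestral edit set) → per-edge per-locus rates → per-cell featurization →
4-component Gaussian mixture → penalized-spline group curves.

*Time calibration.* UPGMA heights are linear in the edit clock; the scale
maps `root height + root-intersection edit count` to the experiment
duration, and the root intersection's edits are assigned to a virtual root
edge from an unedited origin. This removes the systematic underestimate
that full-span calibration puts on every branch (the MRCA's pre-divergence
edits would otherwise consume barcode signal without consuming time).
Ground-truth node ages can be supplied instead for ablation.

*Rate profiles.* Each leaf's path is discretized onto 25 grid cells (5 per
epoch) by mass-preserving binning: an edge's edits are spread uniformly
over the cells its time span overlaps, so the profile's time integral
equals the path's edit count exactly and near-zero-duration reconstruction
edges cannot produce unbounded rates. Features are degree-4 polynomial
coefficients per dynamic locus (degree configurable), optionally normalized
by the cell's static-loci mean rate (default on, removing global activity
variation). Cluster accuracy is best-permutation label agreement against
the true terminal trajectory. Group curves are cubic penalized B-splines
(basis size 10, second-difference penalty) with the smoothing parameter
chosen by generalized cross-validation; single-cell clusters fall back to
the raw profile with a flag. Sharp programmed transitions come out blurred
in time, as expected from reconstruction noise; recovered curves are
matched to programmed schedules by best-assignment correlation.

## Synthetic data

The fixture generators produce, programmatically: polyclonal read tables
with lognormal per-read activity (unit mean, σ = 0.5), layer-ordered edits
with configurable mismatch leakage, multi-timepoint sampling and per-site
qualities; lineage barcode matrices with ground-truth Newick trees;
the default chromatin program as YAML; and hybrid-line allele reads with 5
position-wise disjoint SNPs and a configurable per-base error rate (so the
unassigned fraction follows `1 − (1−ε)⁵`). Ground-truth sidecars (JSON) are
always emitted. These fixtures emulate the statistical structure of real
amplicon data but not alignment artifacts, PCR duplication/collapse of
repetitive arrays, indels, or copy-number variation between integrants —
passing tests therefore validate the algorithms, not the upstream
sequencing pipeline.

## Problem sizes in shipped configurations

Defaults mirror the recorder's printed parameters: τ = 24 h, depth 10,
copies 3, 6-day chromatin runs at 2 edits/array/day with 4-fold modulation,
degree-4 features, 4 mixture components, quality thresholds 10/20, group
floor 30, taxon filter 22 edits. The acceptance script runs the sustained-
recording comparison at 200 replicates, the benchmark at 10 replicates per
cell on a two-regime grid, estimator recoveries at ~10³ reads, and the
chromatin pipeline at 20 trees (a few hundred cells each) — sizes chosen so
the full reproduction completes on a laptop-class single core in a few
minutes while keeping every comparison's sampling error well below the
effect sizes being checked.

## Known limitations

* The recovered `k` scale depends on the φ convention (above); only
  φ-consistent absolute rates and between-pattern ratios are meaningful.
* Ancestral intersection over-assigns convergent edits to ancestors; deep
  cophenetic distances are homoplasy-deflated. The virtual-root calibration
  corrects the aggregate time scale but relative deep-node ages remain
  noisy, which blurs early-epoch rate estimates.
* Penalties of the mismatch model are weakly identified near zero.
* No cell death, selection, spatial structure, or fitness cost of editing;
  no sequence-level indel or barcode-collapse modeling.
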