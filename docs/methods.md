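# Methods

## Scope and model

`neulite` implements a modular workflow for heterogeneous neuronal network
models in three separable stages — build, simulate, virtually record —
that interface only through files. The design premise is the
*type-instance* relational representation: everything shared by a group of
cells or connections lives in a small editable CSV type table, while the
large per-instance tables (HDF5) hold nothing but ids and per-instance
arrays. Changing a type-level parameter (a synaptic weight, a parameter
file reference) is a one-cell CSV edit that leaves the instance tables
byte-identical; this is asserted by the test suite via checksums.

External inputs are strictly feed-forward: their spike trains are
precomputed, saved to file and replayed; an external population that would
receive connections is rejected at setup.

## Building and determinism

`add_nodes` appends a group of cells sharing one node type; gids are
0-based and contiguous. `add_edges` registers a deferred rule (source
query, target query, connection callable, edge-type properties);
`build_edges(seed)` enumerates the query cross-product in (target
ascending, source ascending) order and asks the callable for an integer
synapse count per pair.

Every random draw — connection sampling, synapse placement, Poisson spike
generation — comes from a Philox counter-based generator keyed by the
drawing entity's identity, e.g. `(seed, tag, edge_type_id, source_gid,
target_gid)`. A build or simulation outcome is therefore a pure function
of (specification, seed): independent of iteration order, of chunking, and
of the number of logical ranks. This is the mechanism behind both the
reproducibility guarantee and partition invariance; it costs one generator
initialization per pair, which is negligible at the scales the package
targets.

Queries see type-level and instance-level properties in one flat
namespace; name collisions are rejected at `add_nodes` time, and a
predicate touching a property a node lacks is a non-match rather than an
error, so heterogeneous populations (e.g. cells with and without
morphologies) are queryable uniformly. Reciprocal or repeated `add_edges`
calls are not deduplicated.

## Morphologies, discretization, synapse placement

SWC files are parsed into a sample tree and partitioned into sections
(maximal unbranched same-type chains; type codes 1 somatic, 2 axonal,
3 basal, 4 apical). Each section is cut into `ceil(L / max_seg_len)`
*equal-length* segments whose endpoints and radii interpolate the sampled
polyline linearly; equal lengths serve the uniform-current assumption of
the forward model best. The soma is always a single segment — its path
extent, or a 2·radius segment rendered along +y for the common one-point
soma. Total membrane length is conserved under rediscretization (property
test).

Path distance is measured from the soma center along the tree, in μm.
Synapse eligibility under `(target_sections, distance_range)` uses the
segment **midpoint** distance — a single unambiguous rule, chosen over
any-overlap semantics and documented rather than claimed canonical.
Placement draws a segment with probability proportional to its length
among eligible segments and a uniform offset along it. An empty candidate
set is an error naming the constraints; constraints on point (LIF) targets
are meaningless and rejected implicitly by the model-kind check.

## Dynamics

Fixed-step integration only; `dt` comes from the run config (default
0.1 ms; 0.025 ms is the sensible choice when cable cells are present).
Variable-step methods are excluded on purpose: determinism and partition
invariance demand a shared global grid.

**LIF** (`lif` template): `tau_m dV/dt = -(V - v_rest) + r_m I_syn`,
advanced by exponential Euler (exact on the grid for piecewise-constant
input). Threshold is tested at step end, equality counts as a crossing;
reset to `v_reset` with an absolute refractory clamp of
`round(t_ref/dt)` steps. Synaptic input is a sum of exponentially
decaying currents (nA), one state per distinct decay constant. With
constant drive the first grid crossing lands within one `dt` of the
closed-form time `τ ln(RI / (RI - (V_th - V_rest)))` (asserted).

**Passive cable** (`passive_cable` template): per segment
`C_n dV_n/dt = -g_pas,n (V_n - e_pas) - Σ g_syn (V_n - e_rev) + axial +
I_inj`, advanced by backward Euler. Axial conductances are series
half-resistances between segment midpoints from `ra` and the cylinder
geometry; the per-cell dense system (tridiagonal-plus-branches, typically
a few dozen unknowns) is solved directly each step. Units are mV/ms/nA/
μS/nF/MΩ/μm throughout, so μS·mV = nA and MΩ·nA = mV without conversion
factors in the inner loop.

The per-step transmembrane current of segment n is computed from the
membrane-side terms of the discrete equation, `I_n = C_n ΔV_n/dt +
g_pas,n (V_n⁺ - e_pas) + Σ g_syn (V_n⁺ - e_rev)` (outward positive, axial
excluded). Because the same discrete system was just solved, Kirchhoff
holds to solver round-off: `Σ_n I_n` equals the injected current at every
step (measured ~1e-14 nA; asserted at 1e-9 nA). Passive cells do not
reset; spikes are rising somatic threshold crossings (detection only).

**Synapses**: conductance synapses are double-exponentials normalized so
the peak of a unit activation equals the weight, using the peak time
`t_p = τ1 τ2/(τ2 - τ1) · ln(τ2/τ1)`; they are linear in weight, so an
`nsyns`-fold connection is exactly `nsyns` unit activations. LIF targets
take exponential *current* synapses (`syn_weight` in nA), cable targets
take conductance synapses (`syn_weight` in μS); a mismatch is a setup
error. `weight_function` names resolve through a registry at setup
(default: identity); for edges whose source is an external spike-file
population the function receives `None` as the source node (no node table
is loaded for pure spike sources), so weight functions that inspect
source properties apply to recurrent edges only. Delays round to the
nearest step with half-step ties
rounding up; a zero-delay delivery lands on the next step (causality on
the grid).

## Partitioning and spike exchange

Cells are assigned to `M` logical ranks by `gid mod M` (round-robin),
balancing counts to within one. Ranks are a logical contract exercised
in-process: per-rank state (report buffers, temp files, LFP accumulators)
is fully segregated, and a distributed transport could be slotted in
without changing results because nothing else depends on rank layout.
Spike exchange is a global queue ordered by (delivery step, source
population, source gid, wiring index). The invariance is quantified, not
assumed: merged spike files are byte-identical across `M ∈ {1,2,4}` and
buffer sizes `{1,1000}`, and LFP traces agree to ≤1e-12 mV (the residual
is float summation order across ranks, ~1e-19).

## Extracellular forward model

Homogeneous isotropic medium of conductivity σ (default 0.3 S/m).
Transfer resistance of a segment (endpoints a, b, length Δs) at a site:
with r the radial distance to the segment's line, h the signed
longitudinal distance from the site's projection to the near end and
l = h + Δs,

    R = 1/(4πσΔs) · ln| (√(h²+r²) − h) / (√(l²+r²) − l) |   [MΩ, μm, S/m]

evaluated with a cancellation-free branch on each factor. This is the
standard potential of a finite line of uniform current density; since the
citation trail does not pin one printed expression, correctness is
established against a numerical-quadrature point-source oracle (≤1e-6
relative over 1000 random geometries; measured ~5e-15) and against the
point-source closed form `1/(4πσd)` in the far field. `r` is clamped
below at the segment radius: the log diverges on the axis and a physical
electrode cannot sit inside the membrane. The soma is treated as a line
segment like any other — the uniform-current assumption is global.

Per cell, `R_mn` is computed once at setup; each step then costs one
matrix-vector product `Φ += R @ I`. Superposition across cells is exact
by construction. Only cable cells contribute (point cells have no spatial
current distribution). For a one-segment cell the reported potential
equals `R · I_inj(t)` exactly, which the tests use as a closed-form
anchor.

## Reports

Recorders keep an in-memory block per rank and append to that rank's
temporary HDF5 file every `buffer_steps` steps (default 1000), so a
running simulation is observable by reading the flushed prefix and memory
use is bounded. At end of run: spikes are concatenated and sorted by
(time, gid); voltage columns are concatenated in gid order; extracellular
blocks are summed elementwise. Temp files are deleted on success. Final
files are bit-for-bit independent of the buffer size.

## Synthetic data

The fixture generators define the study conditions for every test:

* **ball-and-stick SWC** — one-point soma plus a straight dendrite whose
  first sample sits at the soma center, so the loaded dendritic length
  equals the requested length exactly.
* **two-population network** — excitatory passive-cable cells and
  inhibitory LIF cells in a 150 μm disc, all four connection classes via
  the Gaussian distance-tapered rule (`p = p0 e^{-d²/2σ²}`, p0 = 0.25,
  σ = 120 μm, 1–3 synapses per connected pair), driven by an external
  Poisson population (50 Hz) through a deterministic fan-out. Defaults
  are 80/20 cells; the invariance measurements use 20/5 cells and 100 ms
  at dt = 0.025 ms, sizes chosen so the full 6-run sweep is a desk-scale
  computation while still producing tens of spikes and a nonzero LFP.
* **layer-4 composition** — 10,000 biophysical cells uniform in a
  400 μm-radius, 100 μm-high cylinder across five types (Scnn1a 3400,
  Rorb 3300, Nr5a1 1800 — the 85% excitatory total is fixed, the
  three-way split is our choice; PV1/PV2 750 each) plus 35,000 LIF cells
  in the 400–845 μm annulus split evenly between one excitatory and one
  inhibitory type. Scaled counts use largest-remainder apportionment so
  the scaled totals are exact. Recurrent edges are optional and
  desk-scaled (p0 = 0.002); the composition, not the dynamics, is the
  reproduced object.
* **external spike files** — per-cell (in)homogeneous Poisson trains by
  thinning, including an ON/OFF two-state profile and a
  gray-screen-then-stimulus timing profile.

What the fixtures deliberately do not emulate: reconstructed
morphologies, active conductances, cell-type-specific connectivity
matrices, or any visual-response model. Passing tests therefore
demonstrate the correctness of the machinery (building, file format,
integration, placement, partitioning, forward model) under controlled
conditions — not the biological validity of any particular network.

## Numerical choices and degenerate inputs

* Backward Euler is first-order; the RC charging error at dt = 0.025 ms
  is ~0.02% (asserted ≤0.5%). Exponential Euler for LIF is exact on the
  grid.
* Delay/refractory rounding: nearest step, `x.5` up. Spike threshold at
  step end, equality spikes.
* Zero-length segments and degenerate SWC geometry are format errors with
  line numbers; a singular cable system surfaces as an error rather than
  NaN propagation.
* Empty networks save and load as valid zero-row tables. Rules returning
  0 everywhere, or queries matching nothing, build zero edges silently —
  that is a modeling statement, not an error.
* CSV cells holding lists (`distance_range`, `target_sections`) are JSON
  strings; absent values are empty fields.

## Known limitations

* No active conductances, calcium dynamics or gap junctions; the cable
  model is passive, so the extracellular signatures lack the sharp
  sodium-spike deflections of active models.
* Per-instance node properties are numeric scalars (positions as x/y/z);
  string-valued per-instance properties are not supported.
* The file layout is a faithful re-expression of the type-instance
  relational design, not byte-compatible with any other tool's schema.
* Ranks are logical; wall-clock parallel speedup is out of scope.
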