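# neulite

Build, simulate and virtually record heterogeneous neuronal network
models — a self-contained Python toolkit for computational
neuroscientists who want a modular, file-based workflow at desk scale:
declare cell populations and connection rules at a high level, persist
the instantiated network in a compact relational format, simulate it with
built-in leaky integrate-and-fire and passive multi-compartment cell
models, and forward-model the extracellular potential any multi-electrode
layout would record.

## What it does

**Building.** A network is a graph built in two passes. Each
`add_nodes(N, ...)` call appends a population and creates one *node type*
holding everything those cells share (`model_type`, `model_template`,
`dynamics_params`, `morphology_file`, ...) while per-cell values
(positions, tuning angles) are arrays. Each `add_edges(...)` call
registers a *rule* — source/target node queries plus a connection
callable returning the synapse count `nsyns` for a pair — together with
the shared edge-type properties (`syn_weight`, `weight_function`,
`delay`, `model_template`, `dynamics_params`, `target_sections`,
`distance_range`). `build_edges(seed)` instantiates the rules; every
pair draws from a counter-based random stream keyed by
`(seed, edge_type_id, source_gid, target_gid)`, so a build is exactly
reproducible and independent of iteration order.

**Files.** Per network `<name>`, instances go to HDF5
(`<name>_nodes.h5`, `<name>_edges.h5`: ids and per-instance arrays only)
and types to editable CSVs (`<name>_node_types.csv`,
`<name>_edge_types.csv`). Changing a synaptic weight for a whole edge
type is a one-cell CSV edit; the HDF5 tables are untouched.

**Simulation.** Fixed-step integration of two cell models: LIF point
neurons (`tau_m dV/dt = -(V - v_rest) + r_m I_syn`, exponential Euler,
threshold/reset/refractory) and passive cables on discretized SWC
morphologies (backward Euler; double-exponential conductance synapses
normalized so peak conductance equals `syn_weight`, placed under the
`(target_sections, distance_range)` constraints). External populations
drive the network from precomputed HDF5 spike files and receive nothing
back. Cells are distributed over `M` logical ranks round-robin
(`gid mod M`); all outputs are invariant to `M`.

**Virtual recording.** Every step, each cable cell returns its
per-segment transmembrane currents `I_n` (capacitive + leak + synaptic;
`Σ_n I_n` equals the injected current to solver precision). The
extracellular potential at electrode site m is `Φ_m = Σ_n R_mn I_n`,
where the transfer resistances `R_mn` come from the line-source model —
each segment is a finite line of uniform current density in a homogeneous
isotropic medium of conductivity σ, reducing to `1/(4πσd)` in the far
field. `R_mn` is precomputed per cell; cell contributions superpose
exactly. Spikes, somatic voltages and LFP are recorded through buffered
per-rank HDF5 writers merged at end of run.

## Worked example

Generate a complete desk-scale setup (network files, components,
external Poisson input, electrode layout, JSON config) and run it:

```python
from neulite import fixtures
from neulite.config import parse_config
from neulite.simulation import run_simulation
import h5py, numpy as np

cfg_path = fixtures.two_pop_sim_files(
    "demo", n_exc=20, n_inh=5, seed=0, tstop=100.0)
out = run_simulation(parse_config(cfg_path))

with h5py.File(out["spikes"]) as f:
    ts, gids = f["timestamps"][:], f["gids"][:]
print(f"{len(ts)} spikes from {len(set(gids))} cells")
print("first five:", [(round(float(t), 3), int(g))
                      for t, g in zip(ts[:5], gids[:5])])
with h5py.File(out["extracellular"]) as f:
    lfp = f["data"][:]
print(f"LFP: {lfp.shape[0]} steps x {lfp.shape[1]} sites, "
      f"peak |phi| = {np.abs(lfp).max()*1000:.3f} uV")
```

Output:

```
41 spikes from 17 cells
first five: [(25.1, 12), (25.1, 13), (25.1, 14), (25.3, 15), (33.1, 19)]
LFP: 4000 steps x 6 sites, peak |phi| = 0.774 uV
```

The 20 excitatory ball-and-stick cells and 5 LIF interneurons sit in a
150 μm disc; a 6-cell external population fires at 50 Hz into the
network, and a 6-site linear probe 30 μm off-center records the summed
line-source potentials — sub-μV amplitudes, as expected for a few tens
of passive cells. Rerunning with `ranks=4` or `buffer_steps=1` in the
config produces byte-identical spike files and LFP traces equal to
within 1e-12 mV.

The same workflow is available from a shell:

```bash
neulite build two_pop --out demo/network --n-exc 20 --n-inh 5
neulite validate demo/config.json
neulite run demo/config.json --ranks 4
```

A larger build fixture reproduces the composition of a layer-4 cortical
column model: `fixtures.layer4_composition_spec(scale=1.0)` creates
10,000 biophysical cells across five types (85% excitatory / 15% PV
inhibitory) in a 400 μm-radius core cylinder plus 35,000 LIF cells in a
surrounding annulus out to 845 μm.

## Layout

```
src/neulite/
  netbuild.py     population/rule builder, distance-tapered example rule
  netio.py        HDF5 + CSV persistence and validation
  morphology.py   SWC parsing, discretization, synapse placement
  simcore.py      LIF and passive-cable dynamics, partitioning, Poisson
  simulation.py   setup + fixed-step loop + spike exchange
  xpotential.py   line-source transfer resistances, LFP accumulation
  reports.py      buffered per-rank recorders and merging
  config.py       JSON run configuration (unknown keys rejected)
  fixtures.py     synthetic morphologies, networks, spike files
  cli.py          `neulite run | validate | build`
docs/methods.md   model equations, conventions, design choices, limits
```
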