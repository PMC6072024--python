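"""Simulation orchestration.

``Simulation`` instantiates cells from a loaded network (per the
round-robin partition plan), places synapses under the edge-type
constraints, wires precomputed external spike trains, and advances the
fixed-step loop, firing report hooks at begin, on each step and at end.
``run_simulation`` is the config-file entry point used by the CLI.

Determinism contract: with fixed seeds, every output file is independent
of the logical rank count and of the report buffer size.  This holds
because (a) per-cell dynamics depend only on that cell's inputs, (b) all
random draws use counter-based streams keyed by entity identity, and
(c) spike exchange is a global sorted queue keyed by (delivery step,
source population, source gid, wiring index).
"""

from __future__ import annotations

import os
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .config import ReportConfig, RunConfig
from .morphology import Morphology, discretize, load_swc, place_synapses
from .netbuild import Network, NodeView
from .netio import NetworkFileSet, load_network, validate
from .registry import get_weight_function
from .reports import LFPRecorder, SpikeRecorder, VoltageRecorder
from .simcore import (LIFCell, LIFParams, PassiveCableCell,
                      PassiveCellParams, SynapseParams, delivery_step,
                      load_dynamics_params, load_external_spikes,
                      make_partition)
from .streams import TAG_PLACEMENT, pair_stream
from .xpotential import ElectrodeArray, ExtracellularMedium, \
    build_transfer_matrix

__all__ = ["Simulation", "SetupError", "run_simulation"]


class SetupError(RuntimeError):
    pass


@dataclass
class _SynapseTarget:
    target_gid: int
    channel: object
    segments: Optional[List[int]]     # one entry per synapse; None for LIF
    weight: float                     # per-synapse effective weight
    delay_steps: int
    order: int                        # wiring index, for queue determinism


class Simulation:
    """One fixed-step run of a recurrent network plus external inputs."""

    def __init__(self, net: Network, components_dir: str, dt: float,
                 tstop: float, seed: int = 0, ranks: int = 1,
                 external_spikes: Optional[Dict[str, Dict[int, np.ndarray]]]
                 = None,
                 electrode_array: Optional[ElectrodeArray] = None,
                 medium: Optional[ExtracellularMedium] = None,
                 reports: Optional[List[ReportConfig]] = None,
                 output_dir: str = "output",
                 max_seg_len: float = 20.0):
        if dt <= 0 or tstop <= 0:
            raise SetupError("dt and tstop must be > 0")
        self.net = net
        self.components_dir = components_dir
        self.dt = float(dt)
        self.tstop = float(tstop)
        self.nsteps = int(round(tstop / dt))
        self.seed = int(seed)
        self.plan = make_partition(np.arange(net.n_nodes), ranks)
        self.M = int(ranks)
        self.external_spikes = external_spikes or {}
        self.electrode_array = electrode_array
        self.medium = medium or ExtracellularMedium()
        self.report_configs = reports or []
        self.output_dir = output_dir
        self.max_seg_len = float(max_seg_len)

        self._params_cache: Dict[str, object] = {}
        self._morph_cache: Dict[str, Morphology] = {}
        self.cells: Dict[int, object] = {}
        self.cell_morphs: Dict[int, Morphology] = {}
        self._targets_by_source: Dict[Tuple[str, int],
                                      List[_SynapseTarget]] = defaultdict(list)
        self._queue: Dict[int, List[Tuple]] = defaultdict(list)
        self._transfer: Dict[int, np.ndarray] = {}
        self._setup_cells()
        self._setup_edges()
        self._setup_external_events()
        if self.electrode_array is not None:
            self._setup_transfer_matrices()

    # ------------------------------------------------------------------ setup

    def _component(self, name: str) -> str:
        return os.path.join(self.components_dir, name)

    def _dynamics(self, name):
        if name not in self._params_cache:
            path = self._component(name)
            if not os.path.exists(path):
                raise SetupError(f"dynamics_params file not found: {path}")
            self._params_cache[name] = load_dynamics_params(path)
        return self._params_cache[name]

    def _morphology(self, name: str) -> Morphology:
        if name not in self._morph_cache:
            path = self._component(name)
            if not os.path.exists(path):
                raise SetupError(f"morphology file not found: {path}")
            self._morph_cache[name] = discretize(load_swc(path),
                                                 self.max_seg_len)
        return self._morph_cache[name]

    def _setup_cells(self) -> None:
        net = self.net
        for ntid, props in net.node_types.items():
            for key in ("model_type", "model_template", "dynamics_params"):
                if props.get(key) in (None, ""):
                    raise SetupError(
                        f"node type {ntid} is missing mandatory key {key!r}")
        for gid in range(net.n_nodes):
            node = net.node(gid)
            template = node["model_template"]
            params = self._dynamics(node["dynamics_params"])
            if template == "lif":
                if not isinstance(params, LIFParams):
                    raise SetupError(
                        f"node type {node.node_type_id}: dynamics_params "
                        "does not describe a LIF cell")
                self.cells[gid] = LIFCell(params, self.dt)
            elif template == "passive_cable":
                if not isinstance(params, PassiveCellParams):
                    raise SetupError(
                        f"node type {node.node_type_id}: dynamics_params "
                        "does not describe a passive cable cell")
                morph = self._morphology(node["morphology_file"])
                translation = (node.position if "x" in node
                               else np.zeros(3))
                rot = float(node.get("rotation_angle_yaxis", 0.0))
                placed = morph.transformed(translation - morph.soma_center,
                                           rotation_y=rot)
                self.cell_morphs[gid] = placed
                self.cells[gid] = PassiveCableCell(placed, params, self.dt)
            else:
                raise SetupError(
                    f"node type {node.node_type_id}: unknown model_template "
                    f"{template!r}")

    def _setup_edges(self) -> None:
        net = self.net
        et = net.edge_table
        order = 0
        for row in range(net.n_edges):
            etid = int(et["edge_type_id"][row])
            props = net.edge_types.get(etid)
            if props is None:
                raise SetupError(f"edge type {etid} missing from type table")
            for key in ("syn_weight", "delay", "dynamics_params"):
                if props.get(key) in (None, ""):
                    raise SetupError(
                        f"edge type {etid} is missing mandatory key {key!r}")
            sgid = int(et["source_node_id"][row])
            tgid = int(et["target_node_id"][row])
            nsyns = int(et["nsyns"][row])
            src_pop = props.get("source_population", net.name)
            syn_params = self._dynamics(props["dynamics_params"])
            if not isinstance(syn_params, SynapseParams):
                raise SetupError(
                    f"edge type {etid}: dynamics_params does not describe "
                    "a synapse")
            target_cell = self.cells[tgid]
            tgt_node = net.node(tgid)
            if isinstance(target_cell, LIFCell):
                if syn_params.kind != "current_exp":
                    raise SetupError(
                        f"edge type {etid}: intfire target requires a "
                        f"current_exp synapse, got {syn_params.kind!r}")
                channel = target_cell.add_channel(syn_params.tau1)
                segments = None
            else:
                channel = target_cell.add_channel(syn_params)
                ts = props.get("target_sections")
                dr = props.get("distance_range")
                if not ts or dr is None:
                    raise SetupError(
                        f"edge type {etid}: biophysical target requires "
                        "target_sections and distance_range")
                stream = pair_stream(self.seed, TAG_PLACEMENT, etid,
                                     sgid, tgid)
                placements = place_synapses(
                    self.cell_morphs[tgid], ts, dr, n=nsyns, rng=stream)
                segments = [p.segment_index for p in placements]
            wf_name = props.get("weight_function") or "identity"
            wf = get_weight_function(wf_name)
            src_node = (net.node(sgid) if src_pop == net.name else None)
            weight = float(props["syn_weight"]) * float(
                wf(props, src_node, tgt_node))
            self._targets_by_source[(src_pop, sgid)].append(_SynapseTarget(
                target_gid=tgid, channel=channel, segments=segments,
                weight=weight,
                delay_steps=delivery_step(float(props["delay"]), self.dt),
                order=order))
            order += 1

    def _setup_external_events(self) -> None:
        for pop, trains in self.external_spikes.items():
            if pop == self.net.name:
                raise SetupError(
                    f"external population {pop!r} has the same name as the "
                    "simulated network")
            for gid, times in trains.items():
                key = (pop, int(gid))
                targets = self._targets_by_source.get(key)
                if not targets:
                    continue
                for t in np.asarray(times, dtype=float):
                    base = delivery_step(t, self.dt)
                    self._schedule(base, key, targets)

    def _schedule(self, spike_step: int, source_key: Tuple[str, int],
                  targets: List[_SynapseTarget]) -> None:
        for tg in targets:
            step = max(spike_step + tg.delay_steps, spike_step + 1)
            if step > self.nsteps:
                continue
            self._queue[step].append(
                (source_key[0], source_key[1], tg.order, tg))

    def _setup_transfer_matrices(self) -> None:
        for gid, morph in self.cell_morphs.items():
            self._transfer[gid] = build_transfer_matrix(
                self.medium, self.electrode_array, morph.segments)

    # -------------------------------------------------------------------- run

    def run(self) -> Dict[str, str]:
        """Advance ``nsteps`` steps; returns {report variable: output path}."""
        gids_by_rank = [self.plan.cells_on(r) for r in range(self.M)]
        rank_of = {int(g): r for r, gs in enumerate(gids_by_rank)
                   for g in gs}
        spike_rec = volt_rec = lfp_rec = None
        for rc in self.report_configs:
            if rc.variable == "spikes":
                spike_rec = SpikeRecorder(self.output_dir, rc.file_name,
                                          self.M, rc.buffer_steps)
            elif rc.variable == "v_soma":
                wanted = (gids_by_rank if rc.node_ids == "all" else
                          [np.asarray([g for g in gs
                                       if g in set(rc.node_ids)])
                           for gs in gids_by_rank])
                volt_rec = VoltageRecorder(self.output_dir, rc.file_name,
                                           self.M, rc.buffer_steps,
                                           wanted, self.dt)
            elif rc.variable == "extracellular":
                if self.electrode_array is None:
                    raise SetupError(
                        "extracellular report requires an electrode array")
                lfp_rec = LFPRecorder(self.output_dir, rc.file_name, self.M,
                                      rc.buffer_steps,
                                      self.electrode_array.ids, self.dt)
        recorders = [r for r in (spike_rec, volt_rec, lfp_rec)
                     if r is not None]
        for r in recorders:
            r.begin()
        volt_gids = ({int(g) for gs in volt_rec.gids_by_rank for g in gs}
                     if volt_rec else set())

        for step in range(1, self.nsteps + 1):
            t = step * self.dt
            for item in sorted(self._queue.pop(step, []),
                               key=lambda it: it[:3]):
                tg: _SynapseTarget = item[3]
                cell = self.cells[tg.target_gid]
                if tg.segments is None:
                    cell.activate(tg.channel, tg.weight)
                else:
                    for seg in tg.segments:
                        cell.activate(tg.channel, tg.weight, segment=seg)
            spiked: List[int] = []
            for rank, gids in enumerate(gids_by_rank):
                phi = lfp_rec.phi(rank) if lfp_rec else None
                for gid in gids:
                    cell = self.cells[int(gid)]
                    if cell.step():
                        spiked.append(int(gid))
                    if volt_rec and int(gid) in volt_gids:
                        v = (cell.v_soma
                             if isinstance(cell, PassiveCableCell)
                             else cell.v)
                        volt_rec.record(rank, int(gid), v)
                    if phi is not None and int(gid) in self._transfer:
                        phi += self._transfer[int(gid)] @ cell.i_membrane
            for gid in sorted(spiked):
                if spike_rec:
                    spike_rec.record(rank_of[gid], t, gid)
                targets = self._targets_by_source.get((self.net.name, gid))
                if targets:
                    self._schedule(step, (self.net.name, gid), targets)
            for r in recorders:
                r.step_end(step)
        outputs = {}
        if spike_rec:
            outputs["spikes"] = spike_rec.end()
        if volt_rec:
            outputs["v_soma"] = volt_rec.end()
        if lfp_rec:
            outputs["extracellular"] = lfp_rec.end()
        return outputs


def run_simulation(config: RunConfig) -> Dict[str, str]:
    """Load network files per ``config``, simulate, merge reports.

    Returns the mapping {report variable: final output path}.
    """
    fs = NetworkFileSet.in_directory(config.network_dir, config.network_name)
    findings = validate(fs, for_simulation=True)
    if findings:
        raise SetupError("network validation failed:\n  "
                         + "\n  ".join(findings))
    net = load_network(fs)

    external = {}
    for item in config.inputs:
        pop = item["population"]
        external[pop] = load_external_spikes(item["spikes_file"])
        # feed-forward contract: an external population must not itself
        # receive connections
        ext_fs = NetworkFileSet.in_directory(config.network_dir, pop)
        if os.path.exists(ext_fs.edges_file):
            import h5py
            with h5py.File(ext_fs.edges_file, "r") as f:
                if pop in f and f[pop]["edge_type_id"].shape[0] > 0:
                    raise SetupError(
                        f"external population {pop!r} has incoming edges on "
                        "file; feed-forward inputs must be sources only")

    electrode = None
    for rc in config.reports:
        if rc.variable == "extracellular":
            electrode = ElectrodeArray.from_csv(rc.electrode_file)
    sim = Simulation(
        net=net, components_dir=config.components_dir, dt=config.dt,
        tstop=config.tstop, seed=config.seed, ranks=config.ranks,
        external_spikes=external, electrode_array=electrode,
        reports=config.reports, output_dir=config.output_dir,
        max_seg_len=config.max_seg_len)
    return sim.run()
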