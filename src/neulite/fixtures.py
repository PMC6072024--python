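"""Synthetic input generators.

Everything a test, tutorial or desk-scale experiment needs is generated
here: ball-and-stick SWC morphologies, Poisson spike-train files, a small
two-population recurrent network (excitatory passive-cable cells plus
inhibitory LIF cells exchanging all four connection classes), and the
composition of a layer-4 cortical column model — a biophysical "core"
cylinder (radius 400 μm, height 100 μm) of 10,000 cells across five types
(three excitatory Cre-line types totaling 85%, two PV inhibitory types
totaling 15%) surrounded by a "periphery" annulus (outer radius 845 μm)
of 35,000 LIF cells, so border cells see the same neighbor density as
central ones.

All generators are deterministic under a fixed seed and emit the same
standard files the main modules consume.
"""

from __future__ import annotations

import math
import os
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .config import write_config
from .netbuild import Network, create_network, distance_tapered_probability
from .netio import save_network
from .simcore import poisson_spike_train, save_spikes
from .streams import TAG_POISSON, pair_stream
from .xpotential import ElectrodeArray

__all__ = [
    "ball_and_stick_swc", "two_pop_spec", "two_pop_sim_files",
    "layer4_composition_spec", "external_population_spikes",
    "on_off_profile", "gray_then_stimulus_profile",
]

RateProfile = Union[float, List[Tuple[float, float, float]]]


# ------------------------------------------------------------- morphologies

def ball_and_stick_swc(soma_radius: float, dend_length: float,
                       n_samples: int, path: str,
                       dend_radius: float = 1.0) -> str:
    """Write a minimal SWC: one somatic point plus a straight dendrite.

    The dendrite has ``n_samples`` samples running from the soma center
    along +y over ``dend_length`` μm, so the loaded total dendritic length
    equals ``dend_length`` exactly.  Deterministic: same arguments give a
    byte-identical file.
    """
    if soma_radius <= 0 or dend_length <= 0 or dend_radius <= 0:
        raise ValueError("geometry parameters must be positive")
    if n_samples < 2:
        raise ValueError("need at least 2 dendrite samples")
    lines = ["# ball-and-stick synthetic morphology",
             f"1 1 0.0 0.0 0.0 {soma_radius:.6f} -1"]
    for j in range(n_samples):
        y = dend_length * j / (n_samples - 1)
        sid = j + 2
        parent = 1 if j == 0 else sid - 1
        lines.append(f"{sid} 3 0.0 {y:.6f} 0.0 {dend_radius:.6f} {parent}")
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path


# -------------------------------------------------------------- rate profiles

def on_off_profile(t_stop: float, period_on: float, period_off: float,
                   rate_on: float, rate_off: float,
                   ) -> List[Tuple[float, float, float]]:
    """Alternating ON/OFF piecewise-constant rate, starting ON at t=0."""
    pieces = []
    t, on = 0.0, True
    while t < t_stop:
        dur = period_on if on else period_off
        pieces.append((t, min(t + dur, t_stop),
                       rate_on if on else rate_off))
        t += dur
        on = not on
    return pieces


def gray_then_stimulus_profile(rate_gray: float, rate_stim: float,
                               t_stop: float, t_gray: float = 500.0,
                               ) -> List[Tuple[float, float, float]]:
    """A 0.5 s "gray screen" baseline followed by the stimulus period
    (timing convention only; no visual model)."""
    return [(0.0, min(t_gray, t_stop), rate_gray),
            (min(t_gray, t_stop), t_stop, rate_stim)]


def _piecewise(pieces: Sequence[Tuple[float, float, float]]
               ) -> Tuple[Callable[[float], float], float]:
    pieces = [(float(a), float(b), float(r)) for a, b, r in pieces]
    for a, b, r in pieces:
        if r < 0:
            raise ValueError(f"negative rate {r} in profile")

    def rate(t: float) -> float:
        for a, b, r in pieces:
            if a <= t < b:
                return r
        return 0.0

    rmax = max((r for _, _, r in pieces), default=0.0)
    return rate, rmax


def external_population_spikes(n_cells: int, rate_profile: RateProfile,
                               t_stop: float, seed: int, path: str) -> str:
    """Write an HDF5 spike file of ``n_cells`` independent (possibly
    inhomogeneous) Poisson trains; per-cell streams are keyed by gid."""
    if isinstance(rate_profile, (int, float)):
        profile: Optional[Callable] = None
        const_rate = float(rate_profile)
        rmax = const_rate
    else:
        profile, rmax = _piecewise(rate_profile)
        const_rate = None
    all_times, all_gids = [], []
    for gid in range(n_cells):
        rng = pair_stream(seed, TAG_POISSON, gid)
        if profile is None:
            ts = poisson_spike_train(const_rate, t_stop, rng)
        else:
            ts = poisson_spike_train(profile, t_stop, rng, rate_max=rmax)
        all_times.append(ts)
        all_gids.append(np.full(ts.size, gid, dtype=np.int64))
    save_spikes(path,
                np.concatenate(all_times) if all_times else [],
                np.concatenate(all_gids) if all_gids else [])
    return path


# ------------------------------------------------------------ network builds

def two_pop_spec(n_exc: int, n_inh: int, seed: int = 0,
                 disc_radius: float = 150.0,
                 morphology_file: str = "ball_stick.swc") -> Network:
    """Build the two-population example: excitatory (biophysical
    ball-and-stick) and inhibitory (LIF) cells in a disc, connected across
    and within the populations by a distance-tapered rule (4 edge types).
    """
    if n_exc < 1 or n_inh < 1:
        raise ValueError("n_exc and n_inh must both be >= 1")
    rng = np.random.default_rng(seed)
    net = create_network("v1")

    def disc_positions(n: int) -> np.ndarray:
        r = disc_radius * np.sqrt(rng.random(n))
        th = 2 * math.pi * rng.random(n)
        return np.column_stack([r * np.cos(th), np.zeros(n),
                                r * np.sin(th)])

    net.add_nodes(n_exc, per_node_props={"positions": disc_positions(n_exc)},
                  pop_name="exc", ei="e", model_type="biophysical",
                  model_template="passive_cable",
                  dynamics_params="exc_passive.json",
                  morphology_file=morphology_file)
    net.add_nodes(n_inh, per_node_props={"positions": disc_positions(n_inh)},
                  pop_name="inh", ei="i", model_type="intfire",
                  model_template="lif", dynamics_params="inh_lif.json")

    common = dict(connection_rule=distance_tapered_probability,
                  weight_function="identity")
    rule_params = {"p0": 0.25, "sigma": 120.0, "nsyns_range": (1, 3)}
    net.add_edges(source={"pop_name": "exc"}, target={"pop_name": "exc"},
                  connection_params=rule_params,
                  syn_weight=4e-4, delay=1.5,
                  model_template="exp2syn",
                  dynamics_params="ampa_exc_to_exc.json",
                  target_sections=["basal"], distance_range=[10.0, 1e9],
                  **common)
    net.add_edges(source={"pop_name": "exc"}, target={"pop_name": "inh"},
                  connection_params=rule_params,
                  syn_weight=0.01, delay=1.0,
                  model_template="expsyn_current",
                  dynamics_params="instanteneous_exc.json",
                  **common)
    net.add_edges(source={"pop_name": "inh"}, target={"pop_name": "exc"},
                  connection_params=rule_params,
                  syn_weight=6e-4, delay=1.0,
                  model_template="exp2syn",
                  dynamics_params="gaba_inh_to_exc.json",
                  target_sections=["somatic", "basal"],
                  distance_range=[0.0, 60.0],
                  **common)
    net.add_edges(source={"pop_name": "inh"}, target={"pop_name": "inh"},
                  connection_params=rule_params,
                  syn_weight=-0.008, delay=1.0,
                  model_template="expsyn_current",
                  dynamics_params="instanteneous_inh.json",
                  **common)
    net.build_edges(seed)
    return net


_DYNAMICS_FILES: Dict[str, Dict] = {
    "exc_passive.json": {"cm": 1.0, "g_pas": 3e-5, "e_pas": -70.0,
                         "ra": 100.0, "spike_threshold": -30.0},
    "inh_lif.json": {"tau_m": 10.0, "v_rest": -70.0, "v_thresh": -50.0,
                     "v_reset": -65.0, "r_m": 100.0, "t_ref": 2.0},
    "ampa_exc_to_exc.json": {"kind": "conductance_biexp", "tau1": 0.5,
                             "tau2": 3.0, "e_rev": 0.0},
    "gaba_inh_to_exc.json": {"kind": "conductance_biexp", "tau1": 1.0,
                             "tau2": 8.0, "e_rev": -80.0},
    "instanteneous_exc.json": {"kind": "current_exp", "tau1": 3.0},
    "instanteneous_inh.json": {"kind": "current_exp", "tau1": 5.0},
    "ampa_ext.json": {"kind": "conductance_biexp", "tau1": 0.3,
                      "tau2": 2.0, "e_rev": 0.0},
    "ext_current.json": {"kind": "current_exp", "tau1": 2.0},
}


def write_component_files(components_dir: str) -> None:
    """Emit the dynamics-parameter JSONs and the shared ball-and-stick
    morphology used by the bundled fixture networks."""
    import json

    os.makedirs(components_dir, exist_ok=True)
    for name, payload in _DYNAMICS_FILES.items():
        with open(os.path.join(components_dir, name), "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
    ball_and_stick_swc(8.0, 200.0, 21,
                       os.path.join(components_dir, "ball_stick.swc"))


def two_pop_sim_files(directory: str, n_exc: int = 20, n_inh: int = 5,
                      seed: int = 0, tstop: float = 100.0,
                      dt: float = 0.025, n_ext: int = 10,
                      ext_rate: float = 50.0, ranks: int = 1,
                      buffer_steps: int = 1000) -> str:
    """Emit a complete runnable simulation setup for the two-population
    network (network files, components, external spikes, electrode layout,
    JSON config); returns the config path."""
    net = two_pop_spec(n_exc, n_inh, seed)

    ext = create_network("ext")
    ext.add_nodes(n_ext, pop_name="ext", model_type="intfire",
                  model_template="lif", dynamics_params="inh_lif.json")

    def fan_out(source, target, fanout: int, n_targets: int) -> int:
        # each external cell drives a fixed block of targets (deterministic)
        lo = (source.node_id * fanout) % max(n_targets, 1)
        covered = {(lo + k) % n_targets for k in range(fanout)}
        return 1 if target.node_id in covered else 0

    net.add_edges(source={"pop_name": "ext"}, target={"pop_name": "exc"},
                  source_network=ext,
                  connection_rule=fan_out,
                  connection_params={"fanout": 8, "n_targets": n_exc},
                  syn_weight=1.2e-3, delay=1.0, model_template="exp2syn",
                  dynamics_params="ampa_ext.json",
                  target_sections=["basal", "somatic"],
                  distance_range=[0.0, 1e9])
    net.add_edges(source={"pop_name": "ext"}, target={"pop_name": "inh"},
                  source_network=ext,
                  connection_rule=fan_out,
                  connection_params={"fanout": 4, "n_targets": n_inh},
                  syn_weight=0.05, delay=1.0,
                  model_template="expsyn_current",
                  dynamics_params="ext_current.json")
    net.build_edges(seed)

    network_dir = os.path.join(directory, "network")
    components_dir = os.path.join(directory, "components")
    inputs_dir = os.path.join(directory, "inputs")
    os.makedirs(inputs_dir, exist_ok=True)
    save_network(net, network_dir)
    write_component_files(components_dir)
    external_population_spikes(
        n_ext, ext_rate, tstop, seed + 1,
        os.path.join(inputs_dir, "ext_spikes.h5"))
    # linear virtual probe 30 μm off the disc center, spanning the dendrites
    sites_y = np.linspace(-40.0, 160.0, 6)
    ElectrodeArray(
        ids=np.arange(6),
        positions=np.column_stack([np.full(6, 30.0), sites_y,
                                   np.zeros(6)]),
    ).to_csv(os.path.join(directory, "electrodes.csv"))

    cfg = {
        "run": {"dt": dt, "tstop": tstop, "seed": seed, "ranks": ranks},
        "network": {"name": "v1", "dir": "network"},
        "components_dir": "components",
        "inputs": [{"population": "ext",
                    "spikes_file": "inputs/ext_spikes.h5"}],
        "reports": [
            {"variable": "spikes", "file_name": "spikes.h5",
             "buffer_steps": buffer_steps},
            {"variable": "v_soma", "file_name": "v_soma.h5",
             "node_ids": "all", "buffer_steps": buffer_steps},
            {"variable": "extracellular", "file_name": "lfp.h5",
             "electrode_file": "electrodes.csv",
             "buffer_steps": buffer_steps},
        ],
        "output_dir": "output",
    }
    return write_config(os.path.join(directory, "config.json"), cfg)


# --------------------------------------------------------- layer-4 composition

# per-type counts at scale 1 (core cells sum to 10,000: 85% excitatory
# across the three Cre-line types, 15% PV; the periphery holds 35,000 LIF
# cells split evenly between one excitatory and one inhibitory type)
_CORE_COUNTS = {"Scnn1a": 3400, "Rorb": 3300, "Nr5a1": 1800,
                "PV1": 750, "PV2": 750}
_CORE_EI = {"Scnn1a": "e", "Rorb": "e", "Nr5a1": "e",
            "PV1": "i", "PV2": "i"}
_LIF_COUNTS = {"LIF_exc": 17500, "LIF_inh": 17500}
_LIF_EI = {"LIF_exc": "e", "LIF_inh": "i"}

CORE_RADIUS = 400.0       # μm
ANNULUS_OUTER_RADIUS = 845.0
LAYER_HEIGHT = 100.0


def _apportion(counts: Dict[str, int], scale: float) -> Dict[str, int]:
    """Largest-remainder apportionment so the scaled total is exact."""
    total = int(round(sum(counts.values()) * scale))
    quotas = {k: v * scale for k, v in counts.items()}
    floors = {k: int(math.floor(q)) for k, q in quotas.items()}
    short = total - sum(floors.values())
    order = sorted(counts, key=lambda k: (floors[k] - quotas[k], k))
    for k in order[:short]:
        floors[k] += 1
    return floors


def layer4_composition_spec(scale: float = 1.0, seed: int = 0,
                            with_edges: bool = False) -> Network:
    """Build the layer-4 column composition (nodes; edges optional).

    At ``scale=1``: 10,000 biophysical cells across five types uniformly
    in the core cylinder and 35,000 LIF cells in the periphery annulus.
    ``with_edges`` adds desk-scale distance-tapered recurrent rules with
    scaled-down connection probabilities (and builds them).
    """
    if not 0 < scale <= 1:
        raise ValueError(f"scale must be in (0, 1], got {scale}")
    core = _apportion(_CORE_COUNTS, scale)
    lif = _apportion(_LIF_COUNTS, scale)
    if min(core.values()) < 1 or min(lif.values()) < 1:
        raise ValueError(f"scale {scale} leaves some cell type empty")
    rng = np.random.default_rng(seed)
    net = create_network("l4")

    def cylinder(n: int, r0: float, r1: float) -> np.ndarray:
        r = np.sqrt(r0 ** 2 + (r1 ** 2 - r0 ** 2) * rng.random(n))
        th = 2 * math.pi * rng.random(n)
        y = LAYER_HEIGHT * rng.random(n)
        return np.column_stack([r * np.cos(th), y, r * np.sin(th)])

    for pop, n in core.items():
        net.add_nodes(n, per_node_props={
            "positions": cylinder(n, 0.0, CORE_RADIUS),
            "tuning_angle": 360.0 * rng.random(n)},
            pop_name=pop, ei=_CORE_EI[pop], location="core",
            model_type="biophysical", model_template="passive_cable",
            dynamics_params="exc_passive.json",
            morphology_file="ball_stick.swc")
    for pop, n in lif.items():
        net.add_nodes(n, per_node_props={
            "positions": cylinder(n, CORE_RADIUS, ANNULUS_OUTER_RADIUS)},
            pop_name=pop, ei=_LIF_EI[pop], location="periphery",
            model_type="intfire", model_template="lif",
            dynamics_params="inh_lif.json")
    if with_edges:
        for src_ei, tgt_ei, w, dp, ts, dr in [
                ("e", "e", 4e-4, "ampa_exc_to_exc.json", ["basal"],
                 [10.0, 1e9]),
                ("i", "e", 6e-4, "gaba_inh_to_exc.json",
                 ["somatic", "basal"], [0.0, 60.0])]:
            net.add_edges(
                source=lambda n, ei=src_ei: n["ei"] == ei
                and n["location"] == "core",
                target=lambda n, ei=tgt_ei: n["ei"] == ei
                and n["location"] == "core",
                connection_rule=distance_tapered_probability,
                connection_params={"p0": 0.002, "sigma": 100.0},
                syn_weight=w, delay=1.5, model_template="exp2syn",
                dynamics_params=dp, target_sections=ts, distance_range=dr,
                weight_function="gaussian_tuning_difference",
                weight_sigma=50.0)
        net.build_edges(seed)
    return net
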