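"""Simulation core: point and cable cell dynamics, partitioning, inputs.

Two built-in cell models cover the extremes of detail the builder can
request:

* ``lif`` — a leaky integrate-and-fire point neuron,
  ``tau_m dV/dt = -(V - v_rest) + r_m I_syn``, integrated by exponential
  Euler with threshold test at step end, reset and absolute refractory
  clamp.  Synaptic input is a sum of exponentially decaying currents (nA).
* ``passive_cable`` — a passive multi-compartment cell on a discretized
  morphology, ``C_n dV_n/dt = -g_pas,n (V_n - e_pas) - Σ g_syn (V_n -
  e_rev) + axial + I_inj``, integrated by backward Euler (dense solve; the
  per-cell systems are small).  Synapses are double-exponential
  conductances normalized so the peak conductance equals the weight.
  Spikes are detected as rising threshold crossings of the somatic
  voltage.  Every step returns the per-segment transmembrane current
  ``I_n`` (capacitive + ionic + synaptic, outward positive, axial
  excluded) — the source term of the extracellular forward model.  By
  construction ``Σ_n I_n`` equals the injected current at every step.

Units throughout: mV, ms, nA, μS, nF, MΩ, μm (so μS·mV = nA and
nF·mV/ms = nA).

Cells are assigned to ``M`` logical ranks round-robin (rank of a gid is
``gid mod M``); because every stochastic element draws from a stream keyed
by entity identity, all results are independent of ``M``.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import h5py
import numpy as np

from .morphology import Morphology

__all__ = [
    "LIFParams", "PassiveCellParams", "SynapseParams", "PartitionPlan",
    "LIFState", "LIFCell", "PassiveCableCell",
    "step_lif", "make_partition", "poisson_spike_train",
    "load_external_spikes", "save_spikes", "load_dynamics_params",
    "delivery_step",
]


# ----------------------------------------------------------------- parameters

@dataclass
class LIFParams:
    tau_m: float          # ms
    v_rest: float         # mV
    v_thresh: float       # mV
    v_reset: float        # mV
    r_m: float            # MΩ
    t_ref: float = 0.0    # ms

    def __post_init__(self):
        if self.tau_m <= 0 or self.r_m <= 0 or self.t_ref < 0:
            raise ValueError("require tau_m > 0, r_m > 0, t_ref >= 0")
        if self.v_thresh <= self.v_reset:
            raise ValueError("require v_thresh > v_reset")


@dataclass
class PassiveCellParams:
    cm: float                     # μF/cm²
    g_pas: float                  # S/cm²
    e_pas: float                  # mV
    ra: float                     # Ω·cm
    spike_threshold: float = -20.0  # mV, somatic detection threshold

    def __post_init__(self):
        if self.cm <= 0 or self.g_pas <= 0 or self.ra <= 0:
            raise ValueError("require cm, g_pas, ra > 0")


@dataclass
class SynapseParams:
    kind: str                     # "conductance_biexp" | "current_exp"
    tau1: float                   # ms (rise for biexp; decay for current_exp)
    tau2: float = 0.0             # ms (decay, biexp only; > tau1)
    e_rev: float = 0.0            # mV (conductance only)

    def __post_init__(self):
        if self.kind not in ("conductance_biexp", "current_exp"):
            raise ValueError(f"unknown synapse kind {self.kind!r}")
        if self.tau1 <= 0:
            raise ValueError("require tau1 > 0")
        if self.kind == "conductance_biexp" and self.tau2 <= self.tau1:
            raise ValueError("require tau2 > tau1 for conductance_biexp")


def load_dynamics_params(path: str):
    """Load a cell/synapse parameter JSON; dispatch on its keys."""
    with open(path) as fh:
        d = json.load(fh)
    if "kind" in d:
        return SynapseParams(**d)
    if "tau_m" in d:
        return LIFParams(**d)
    if "g_pas" in d:
        return PassiveCellParams(**d)
    raise ValueError(f"{path}: unrecognized dynamics_params schema "
                     f"(keys {sorted(d)})")


# ---------------------------------------------------------------- partitioning

@dataclass
class PartitionPlan:
    """Round-robin assignment of gids to M logical ranks (gid mod M)."""
    M: int
    gids: np.ndarray

    def rank_of(self, gid: int) -> int:
        return int(gid) % self.M

    def cells_on(self, rank: int) -> np.ndarray:
        return self.gids[self.gids % self.M == rank]


def make_partition(gids: Sequence[int], M: int) -> PartitionPlan:
    """Rank ``k`` hosts gids ``k, k+M, k+2M, ...`` — per-rank counts differ
    by at most one."""
    if M < 1:
        raise ValueError(f"rank count M must be >= 1, got {M}")
    return PartitionPlan(M=int(M), gids=np.sort(np.asarray(gids, dtype=int)))


def delivery_step(time_ms: float, dt: float) -> int:
    """Nearest time step of an event; half-step ties round up."""
    return int(math.floor(time_ms / dt + 0.5))


# ------------------------------------------------------------------ LIF cells

@dataclass
class LIFState:
    v: float
    refrac_steps: int = 0


def step_lif(state: LIFState, params: LIFParams, i_syn: float,
             dt: float) -> Tuple[LIFState, bool]:
    """One exponential-Euler step; returns (new state, spiked?).

    ``i_syn`` (nA) is held constant over the step.  Threshold is tested at
    step end; equality counts as a crossing.  During the refractory period
    the voltage is clamped at ``v_reset``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if state.refrac_steps > 0:
        return LIFState(v=params.v_reset,
                        refrac_steps=state.refrac_steps - 1), False
    v_inf = params.v_rest + params.r_m * i_syn
    v = v_inf + (state.v - v_inf) * math.exp(-dt / params.tau_m)
    if v >= params.v_thresh:
        return LIFState(v=params.v_reset,
                        refrac_steps=delivery_step(params.t_ref, dt)), True
    return LIFState(v=v, refrac_steps=0), False


class LIFCell:
    """Point neuron with exponential current synapses grouped by decay tau."""

    def __init__(self, params: LIFParams, dt: float):
        self.params = params
        self.dt = dt
        self.state = LIFState(v=params.v_rest)
        self._syn: Dict[float, float] = {}       # tau -> summed current state
        self._decay: Dict[float, float] = {}
        self.i_inject = 0.0                      # nA, test/stimulus hook

    def add_channel(self, tau: float) -> float:
        tau = float(tau)
        if tau not in self._syn:
            self._syn[tau] = 0.0
            self._decay[tau] = math.exp(-self.dt / tau)
        return tau

    def activate(self, channel: float, weight: float,
                 segment: Optional[int] = None) -> None:
        self._syn[channel] += weight

    @property
    def v(self) -> float:
        return self.state.v

    def step(self) -> bool:
        i_syn = sum(self._syn.values()) + self.i_inject
        self.state, spiked = step_lif(self.state, self.params, i_syn, self.dt)
        for tau in self._syn:
            self._syn[tau] *= self._decay[tau]
        return spiked


# ----------------------------------------------------------------- cable cells

class _BiexpChannel:
    """Double-exponential conductance shared by all synapses with the same
    (tau1, tau2, e_rev) on one cell; per-segment state vectors.

    g(t) = w · f · (e^{-t/τ2} - e^{-t/τ1}) with f chosen so the peak of a
    unit activation equals 1 (at t_p = τ1 τ2/(τ2-τ1) · ln(τ2/τ1)).
    """

    def __init__(self, params: SynapseParams, n_seg: int, dt: float):
        self.params = params
        t1, t2 = params.tau1, params.tau2
        tp = (t1 * t2) / (t2 - t1) * math.log(t2 / t1)
        self.factor = 1.0 / (math.exp(-tp / t2) - math.exp(-tp / t1))
        self.d1 = math.exp(-dt / t1)
        self.d2 = math.exp(-dt / t2)
        self.A = np.zeros(n_seg)
        self.B = np.zeros(n_seg)

    def activate(self, segment: int, weight: float) -> None:
        self.A[segment] += weight
        self.B[segment] += weight

    def conductance(self) -> np.ndarray:
        return self.factor * (self.B - self.A)   # μS per segment

    def decay(self) -> None:
        self.A *= self.d1
        self.B *= self.d2


class PassiveCableCell:
    """Passive multi-compartment cell, backward-Euler integration.

    Built from a discretized :class:`~neulite.morphology.Morphology`
    (world coordinates).  ``step()`` advances one ``dt`` and stores the
    per-segment transmembrane currents in ``self.i_membrane`` (nA,
    outward positive).
    """

    def __init__(self, morph: Morphology, params: PassiveCellParams,
                 dt: float):
        if not morph.segments:
            raise ValueError("morphology must be discretized")
        self.morph = morph
        self.params = params
        self.dt = dt
        n = len(morph.segments)
        self.n_seg = n
        area_cm2 = np.array([2.0 * math.pi * g.radius * g.length * 1e-8
                             for g in morph.segments])
        self.c_nF = params.cm * area_cm2 * 1e3
        self.g_pas = params.g_pas * area_cm2 * 1e6       # μS
        # axial conductances: series half-resistances between midpoints
        lap = np.zeros((n, n))
        for g in morph.segments:
            j = g.parent_index
            if j < 0:
                continue
            p = morph.segments[j]
            r_mohm = params.ra * 1e-2 * (
                g.length / (2.0 * math.pi * g.radius ** 2)
                + p.length / (2.0 * math.pi * p.radius ** 2))
            if r_mohm <= 0:
                raise ValueError("degenerate segment geometry")
            ga = 1.0 / r_mohm                            # μS
            i = g.index
            lap[i, i] += ga
            lap[j, j] += ga
            lap[i, j] -= ga
            lap[j, i] -= ga
        # a disconnected tree would make the system singular for g_pas -> 0;
        # here every segment has a path to the root by construction, but a
        # malformed parent wiring is caught at solve time
        self._lap = lap
        self.v = np.full(n, params.e_pas)
        self.i_membrane = np.zeros(n)
        self.i_inject = np.zeros(n)                      # nA per segment
        self._channels: Dict[Tuple[float, float, float], _BiexpChannel] = {}
        self._prev_v_soma = self.v[0]
        self.soma_segment = 0

    @property
    def v_soma(self) -> float:
        return float(self.v[self.soma_segment])

    def input_resistance(self) -> float:
        """Steady-state somatic input resistance (MΩ)."""
        G = np.diag(self.g_pas) + self._lap
        e = np.zeros(self.n_seg)
        e[self.soma_segment] = 1.0
        return float(np.linalg.solve(G, e)[self.soma_segment])

    def add_channel(self, params: SynapseParams) -> Tuple[float, float, float]:
        if params.kind != "conductance_biexp":
            raise ValueError(
                "passive cable cells take conductance_biexp synapses, got "
                f"{params.kind!r}")
        key = (params.tau1, params.tau2, params.e_rev)
        if key not in self._channels:
            self._channels[key] = _BiexpChannel(params, self.n_seg, self.dt)
        return key

    def activate(self, channel: Tuple[float, float, float], weight: float,
                 segment: Optional[int] = None) -> None:
        self._channels[channel].activate(segment or 0, weight)

    def step(self) -> bool:
        n = self.n_seg
        dt = self.dt
        g_syn_total = np.zeros(n)
        rhs_syn = np.zeros(n)
        for ch in self._channels.values():
            g = ch.conductance()
            g_syn_total += g
            rhs_syn += g * ch.params.e_rev
        diag = self.c_nF / dt + self.g_pas + g_syn_total
        A = self._lap + np.diag(diag)
        rhs = (self.c_nF / dt * self.v + self.g_pas * self.params.e_pas
               + rhs_syn + self.i_inject)
        v_new = np.linalg.solve(A, rhs)
        if not np.all(np.isfinite(v_new)):
            raise FloatingPointError(
                "cable solve produced non-finite voltages (singular system?)")
        self.i_membrane = (self.c_nF * (v_new - self.v) / dt
                           + self.g_pas * (v_new - self.params.e_pas))
        for ch in self._channels.values():
            self.i_membrane += ch.conductance() * (v_new - ch.params.e_rev)
            ch.decay()
        self.v = v_new
        spiked = (self._prev_v_soma < self.params.spike_threshold
                  <= self.v_soma)
        self._prev_v_soma = self.v_soma
        return bool(spiked)


# --------------------------------------------------------------- spike trains

def poisson_spike_train(rate, t_stop: float, rng: np.random.Generator,
                        rate_max: Optional[float] = None) -> np.ndarray:
    """Spike times (ms, sorted, in ``(0, t_stop]``) of a Poisson process.

    ``rate`` is either a constant rate in Hz or a callable ``rate(t_ms) ->
    Hz`` (inhomogeneous, realized by thinning against ``rate_max``).
    """
    if t_stop <= 0:
        raise ValueError("t_stop must be > 0 ms")
    if callable(rate):
        if rate_max is None or rate_max < 0:
            raise ValueError("rate_max (Hz) required for a rate function")
        if rate_max == 0:
            return np.zeros(0)
        times = _homogeneous_times(rate_max, t_stop, rng)
        if times.size == 0:
            return times
        keep = np.empty(times.size, dtype=bool)
        for i, t in enumerate(times):
            r = float(rate(t))
            if r < 0:
                raise ValueError(f"negative rate {r} at t={t} ms")
            if r > rate_max * (1 + 1e-12):
                raise ValueError(f"rate {r} at t={t} ms exceeds rate_max")
            keep[i] = rng.random() < r / rate_max
        return times[keep]
    rate = float(rate)
    if rate < 0:
        raise ValueError(f"rate must be >= 0 Hz, got {rate}")
    if rate == 0:
        return np.zeros(0)
    return _homogeneous_times(rate, t_stop, rng)


def _homogeneous_times(rate_hz: float, t_stop: float,
                       rng: np.random.Generator) -> np.ndarray:
    mean_isi = 1000.0 / rate_hz                       # ms
    expect = t_stop / mean_isi
    out = []
    t = 0.0
    block = max(16, int(expect + 4 * math.sqrt(expect) + 10))
    while True:
        gaps = rng.exponential(mean_isi, size=block)
        ts = t + np.cumsum(gaps)
        out.append(ts[ts <= t_stop])
        if ts[-1] > t_stop:
            break
        t = ts[-1]
    return np.concatenate(out)


def save_spikes(path: str, times: Sequence[float],
                gids: Sequence[int]) -> None:
    """Write a spike file: parallel datasets ``timestamps`` (ms) and
    ``gids``, sorted by (time, gid)."""
    times = np.asarray(times, dtype=float)
    gids = np.asarray(gids, dtype=np.int64)
    if times.shape != gids.shape:
        raise ValueError("times and gids must have equal length")
    order = np.lexsort((gids, times))
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("timestamps", data=times[order])
        f.create_dataset("gids", data=gids[order])


def load_external_spikes(path: str) -> Dict[int, np.ndarray]:
    """Load a spike file into ``{gid: sorted times (ms)}``.

    External populations are sources only; times must be nonnegative and
    nondecreasing per gid.
    """
    with h5py.File(path, "r") as f:
        times = np.asarray(f["timestamps"], dtype=float)
        gids = np.asarray(f["gids"], dtype=np.int64)
    trains: Dict[int, np.ndarray] = {}
    for gid in np.unique(gids):
        ts = times[gids == gid]
        if (ts < 0).any():
            raise ValueError(f"{path}: negative spike time for gid {gid}")
        if (np.diff(ts) < 0).any():
            raise ValueError(f"{path}: unsorted spike times for gid {gid}")
        trains[int(gid)] = ts
    return trains
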