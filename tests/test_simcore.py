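import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from neulite.fixtures import ball_and_stick_swc
from neulite.morphology import discretize, load_swc
from neulite.simcore import (LIFCell, LIFParams, LIFState, PassiveCableCell,
                             PassiveCellParams, SynapseParams,
                             delivery_step, load_external_spikes,
                             load_dynamics_params, make_partition,
                             poisson_spike_train, save_spikes, step_lif)
from neulite.streams import TAG_POISSON, pair_stream

LIF = LIFParams(tau_m=10.0, v_rest=-70.0, v_thresh=-50.0, v_reset=-65.0,
                r_m=100.0, t_ref=2.0)


class TestParams:
    @pytest.mark.parametrize("kw", [{"tau_m": 0}, {"r_m": -1},
                                    {"t_ref": -0.1},
                                    {"v_thresh": -80.0}])
    def test_lif_invariants(self, kw):
        base = dict(tau_m=10.0, v_rest=-70.0, v_thresh=-50.0,
                    v_reset=-65.0, r_m=100.0)
        with pytest.raises(ValueError):
            LIFParams(**{**base, **kw})

    @pytest.mark.parametrize("kw", [
        {"kind": "alpha"}, {"tau1": 0.0},
        {"kind": "conductance_biexp", "tau1": 3.0, "tau2": 2.0}])
    def test_synapse_invariants(self, kw):
        base = dict(kind="conductance_biexp", tau1=0.5, tau2=3.0)
        with pytest.raises(ValueError):
            SynapseParams(**{**base, **kw})

    def test_dynamics_params_dispatch(self, tmp_path):
        import json
        for name, payload, cls in [
                ("l.json", {"tau_m": 10, "v_rest": -70, "v_thresh": -50,
                            "v_reset": -65, "r_m": 100}, LIFParams),
                ("p.json", {"cm": 1.0, "g_pas": 3e-5, "e_pas": -70,
                            "ra": 100}, PassiveCellParams),
                ("s.json", {"kind": "current_exp", "tau1": 2.0},
                 SynapseParams)]:
            path = tmp_path / name
            path.write_text(json.dumps(payload))
            assert isinstance(load_dynamics_params(str(path)), cls)


class TestPartition:
    def test_round_robin_ten_cells_four_ranks(self):
        plan = make_partition(range(10), 4)
        assert plan.cells_on(0).tolist() == [0, 4, 8]
        assert plan.cells_on(1).tolist() == [1, 5, 9]
        assert plan.cells_on(2).tolist() == [2, 6]
        assert plan.cells_on(3).tolist() == [3, 7]

    def test_single_rank_hosts_all(self):
        plan = make_partition(range(7), 1)
        assert plan.cells_on(0).tolist() == list(range(7))

    @given(st.integers(min_value=0, max_value=200),
           st.integers(min_value=1, max_value=17))
    @settings(max_examples=60, deadline=None)
    def test_balanced_within_one(self, n, m):
        plan = make_partition(range(n), m)
        counts = [len(plan.cells_on(r)) for r in range(m)]
        assert sum(counts) == n
        assert max(counts) - min(counts) <= 1

    def test_invalid_rank_count(self):
        with pytest.raises(ValueError):
            make_partition(range(4), 0)


class TestLIF:
    @pytest.mark.parametrize("i_nA", [0.3, 0.25, 0.5])
    def test_first_spike_matches_closed_form(self, i_nA):
        dt = 0.1
        ri = LIF.r_m * i_nA
        t_exact = LIF.tau_m * math.log(ri / (ri - (LIF.v_thresh
                                                   - LIF.v_rest)))
        s, t = LIFState(v=LIF.v_rest), 0.0
        while True:
            s, spiked = step_lif(s, LIF, i_nA, dt)
            t += dt
            if spiked:
                break
            assert t < 100.0
        assert t_exact <= t <= t_exact + dt + 1e-12

    def test_rest_is_fixed_point(self):
        s = LIFState(v=LIF.v_rest)
        for _ in range(1000):
            s, spiked = step_lif(s, LIF, 0.0, 0.1)
            assert not spiked
        assert s.v == pytest.approx(LIF.v_rest)

    def test_subthreshold_drive_never_spikes(self):
        # r_m * 0.19 nA = 19 mV < 20 mV threshold distance
        s = LIFState(v=LIF.v_rest)
        for _ in range(20_000):
            s, spiked = step_lif(s, LIF, 0.19, 0.1)
            assert not spiked
        assert s.v == pytest.approx(LIF.v_rest + 19.0, abs=1e-6)

    def test_refractory_clamp(self):
        dt = 0.1
        s = LIFState(v=LIF.v_rest)
        while True:
            s, spiked = step_lif(s, LIF, 0.5, dt)
            if spiked:
                break
        n_ref = delivery_step(LIF.t_ref, dt)
        for _ in range(n_ref):
            s, spiked = step_lif(s, LIF, 0.5, dt)
            assert s.v == LIF.v_reset and not spiked

    def test_nsyns_equals_explicit_synapses(self):
        # one activation of weight 3w == three activations of weight w
        a = LIFCell(LIF, dt=0.1)
        b = LIFCell(LIF, dt=0.1)
        ch_a = a.add_channel(3.0)
        ch_b = b.add_channel(3.0)
        a.activate(ch_a, 3 * 0.02)
        for _ in range(3):
            b.activate(ch_b, 0.02)
        for _ in range(200):
            a.step()
            b.step()
            assert a.v == pytest.approx(b.v, abs=1e-12)


class TestPassiveCable:
    def _soma_cell(self, tmp_path, dt=0.025):
        p = tmp_path / "soma.swc"
        p.write_text("1 1 0 0 0 10 -1\n")
        m = discretize(load_swc(str(p)), 100.0)
        return PassiveCableCell(
            m, PassiveCellParams(cm=1.0, g_pas=5e-5, e_pas=-70.0, ra=100.0),
            dt=dt)

    def _stick_cell(self, tmp_path, dt=0.025):
        path = ball_and_stick_swc(8.0, 200.0, 21,
                                  str(tmp_path / "bs.swc"))
        m = discretize(load_swc(path), 20.0)
        return PassiveCableCell(
            m, PassiveCellParams(cm=1.0, g_pas=3e-5, e_pas=-70.0, ra=100.0),
            dt=dt)

    def test_rc_charging_closed_form(self, tmp_path):
        cell = self._soma_cell(tmp_path)
        rin = cell.input_resistance()
        tau = rin * cell.c_nF.sum()          # MOhm x nF = ms
        i = 0.1
        cell.i_inject[0] = i
        for step in range(1, 4001):
            cell.step()
            t = step * cell.dt
            v_exact = -70.0 + rin * i * (1.0 - math.exp(-t / tau))
            assert abs(cell.v[0] - v_exact) <= 0.005 * rin * i

    def test_kirchhoff_no_stimulus(self, tmp_path):
        cell = self._stick_cell(tmp_path)
        for _ in range(200):
            cell.step()
            assert abs(cell.i_membrane.sum()) <= 1e-9 * cell.n_seg

    def test_current_conservation_with_injection(self, tmp_path):
        cell = self._stick_cell(tmp_path)
        cell.i_inject[0] = 0.1
        for _ in range(400):
            cell.step()
            assert cell.i_membrane.sum() == pytest.approx(0.1, abs=1e-9)

    def test_biexp_peak_normalization_and_linearity(self, tmp_path):
        syn = SynapseParams(kind="conductance_biexp", tau1=0.5, tau2=3.0,
                            e_rev=0.0)
        peaks = []
        for w in (1e-3, 2e-3):
            cell = self._soma_cell(tmp_path)
            ch = cell.add_channel(syn)
            cell.activate(ch, w, segment=0)
            gmax = 0.0
            for _ in range(400):
                g = cell._channels[ch].conductance()[0]
                gmax = max(gmax, g)
                cell.step()
            peaks.append(gmax)
            # peak conductance equals the weight (grid resolution limits
            # how exactly the analytic peak time is hit)
            assert 0.995 * w <= gmax <= w * (1 + 1e-9)
        assert peaks[1] == pytest.approx(2 * peaks[0], rel=1e-9)

    def test_conductance_synapse_rejected_on_wrong_kind(self, tmp_path):
        cell = self._soma_cell(tmp_path)
        with pytest.raises(ValueError, match="conductance_biexp"):
            cell.add_channel(SynapseParams(kind="current_exp", tau1=2.0))


class TestDeliverySteps:
    @pytest.mark.parametrize("delay,dt,steps", [
        (2.0, 0.1, 20),          # exact division
        (0.25, 0.1, 3),          # x.5 ties round up
        (0.24, 0.1, 2),
        (0.0, 0.1, 0),
    ])
    def test_rounding(self, delay, dt, steps):
        assert delivery_step(delay, dt) == steps


class TestPoisson:
    def test_zero_rate_empty(self):
        rng = pair_stream(0, TAG_POISSON, 0)
        assert poisson_spike_train(0.0, 1000.0, rng).size == 0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            poisson_spike_train(-1.0, 100.0, pair_stream(0, TAG_POISSON, 0))

    def test_pooled_count_matches_mean(self):
        # 10 Hz x 100 s x 200 streams -> mean 1000 per stream
        total = 0
        for gid in range(200):
            total += poisson_spike_train(
                10.0, 100_000.0, pair_stream(9, TAG_POISSON, gid)).size
        mean = 200 * 1000
        assert abs(total - mean) < 3 * math.sqrt(mean)

    def test_isi_exponentiality(self):
        ts = poisson_spike_train(20.0, 600_000.0,
                                 pair_stream(4, TAG_POISSON, 1))
        isi = np.diff(ts)[:10_000]
        res = stats.kstest(isi, "expon", args=(0, 50.0))  # mean ISI 50 ms
        assert res.pvalue > 0.01

    def test_inhomogeneous_thinning_phase_rates(self):
        rate = lambda t: 20.0 if (t // 500) % 2 == 0 else 2.0
        counts_on = counts_off = 0
        t_stop = 10_000.0
        for gid in range(50):
            ts = poisson_spike_train(rate, t_stop,
                                     pair_stream(3, TAG_POISSON, gid),
                                     rate_max=20.0)
            phase = (ts // 500).astype(int) % 2
            counts_on += int((phase == 0).sum())
            counts_off += int((phase == 1).sum())
        exp_on = 50 * 20.0 * (t_stop / 2) / 1000.0
        exp_off = 50 * 2.0 * (t_stop / 2) / 1000.0
        assert abs(counts_on - exp_on) < 3 * math.sqrt(exp_on)
        assert abs(counts_off - exp_off) < 3 * math.sqrt(exp_off)


class TestSpikeFiles:
    def test_round_trip(self, tmp_path):
        path = str(tmp_path / "spk.h5")
        times = [5.0, 1.5, 3.25, 3.25]
        gids = [2, 0, 1, 0]
        save_spikes(path, times, gids)
        trains = load_external_spikes(path)
        assert trains[0].tolist() == [1.5, 3.25]
        assert trains[1].tolist() == [3.25]
        assert trains[2].tolist() == [5.0]

    def test_empty_file_valid(self, tmp_path):
        path = str(tmp_path / "spk.h5")
        save_spikes(path, [], [])
        assert load_external_spikes(path) == {}

    def test_negative_time_lists_gid(self, tmp_path):
        import h5py
        path = str(tmp_path / "bad.h5")
        with h5py.File(path, "w") as f:
            f.create_dataset("timestamps", data=[-1.0, 2.0])
            f.create_dataset("gids", data=[7, 7])
        with pytest.raises(ValueError, match="7"):
            load_external_spikes(path)

    def test_unsorted_times_rejected(self, tmp_path):
        import h5py
        path = str(tmp_path / "bad.h5")
        with h5py.File(path, "w") as f:
            f.create_dataset("timestamps", data=[5.0, 2.0])
            f.create_dataset("gids", data=[3, 3])
        with pytest.raises(ValueError, match="unsorted"):
            load_external_spikes(path)
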