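import math

import numpy as np
import pytest
from scipy.integrate import quad

from neulite.morphology import Segment, discretize, load_swc
from neulite.simcore import PassiveCableCell, PassiveCellParams
from neulite.xpotential import (ElectrodeArray, ExtracellularMedium,
                                accumulate_lfp, build_transfer_matrix,
                                line_transfer_resistance,
                                point_transfer_resistance)

SIGMA = 0.3  # S/m


def quadrature_resistance(a, b, site, sigma=SIGMA):
    """Independent oracle: numerically integrate point sources along the
    segment."""
    a, b, site = map(np.asarray, (a, b, site))
    ds = np.linalg.norm(b - a)
    f = lambda s: 1.0 / np.linalg.norm(site - (a + (b - a) * s / ds))
    val, _ = quad(f, 0.0, ds, limit=400)
    return val / (4.0 * math.pi * sigma * ds)


def seg(a, b, radius=1.0, index=0):
    a, b = np.asarray(a, float), np.asarray(b, float)
    return Segment(index=index, section_index=0, type_code=3, a=a, b=b,
                   radius=radius, length=float(np.linalg.norm(b - a)),
                   path_dist=0.0, parent_index=-1)


class TestPointSource:
    def test_unit_audit(self):
        # sigma 0.3 S/m at 10 um: 0.02653 MOhm, i.e. 26.53 uV per nA
        r = point_transfer_resistance(SIGMA, (0, 0, 0), (10, 0, 0))
        assert r == pytest.approx(1.0 / (4 * math.pi * 0.3 * 10))
        assert r * 1.0 * 1000 == pytest.approx(26.53, abs=0.01)  # uV

    def test_inverse_distance_scaling(self):
        r1 = point_transfer_resistance(SIGMA, (0, 0, 0), (25, 0, 0))
        r2 = point_transfer_resistance(SIGMA, (0, 0, 0), (50, 0, 0))
        assert r1 == pytest.approx(2 * r2)

    def test_coincident_site_is_error(self):
        with pytest.raises(ValueError):
            point_transfer_resistance(SIGMA, (1, 2, 3), (1, 2, 3))


class TestLineSource:
    def test_endpoint_swap_symmetry(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            a = rng.uniform(-100, 100, 3)
            b = a + rng.uniform(5, 50, 3)
            site = rng.uniform(-200, 200, 3)
            assert line_transfer_resistance(SIGMA, a, b, site) == \
                pytest.approx(line_transfer_resistance(SIGMA, b, a, site),
                              rel=1e-12)

    def test_agreement_with_quadrature(self):
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(1000):
            a = rng.uniform(-100, 100, 3)
            b = a + rng.uniform(-50, 50, 3)
            if np.linalg.norm(b - a) < 1.0:
                b = a + np.array([10.0, 0.0, 0.0])
            site = rng.uniform(-200, 200, 3)
            r = line_transfer_resistance(SIGMA, a, b, site)
            rq = quadrature_resistance(a, b, site)
            worst = max(worst, abs(r - rq) / rq)
        assert worst <= 1e-6

    @pytest.mark.parametrize("dist", [1500.0, 5000.0, 20000.0])
    def test_far_field_converges_to_point_source(self, dist):
        a, b = np.zeros(3), np.array([10.0, 0.0, 0.0])
        site = np.array([dist, dist * 0.4, dist * 0.2])
        r_line = line_transfer_resistance(SIGMA, a, b, site)
        r_point = point_transfer_resistance(SIGMA, site, (a + b) / 2)
        assert r_line == pytest.approx(r_point, rel=1e-3)

    def test_on_axis_site_clamped_finite(self):
        a, b = np.zeros(3), np.array([10.0, 0.0, 0.0])
        on_axis = np.array([20.0, 0.0, 0.0])
        r = line_transfer_resistance(SIGMA, a, b, on_axis, radius=1.0)
        assert np.isfinite(r) and r > 0
        # clamped value equals the value at one radius off-axis
        near = np.array([5.0, 1e-9, 0.0])
        r_in = line_transfer_resistance(SIGMA, a, b, near, radius=1.0)
        off = np.array([5.0, 1.0, 0.0])
        assert r_in == pytest.approx(
            line_transfer_resistance(SIGMA, a, b, off), rel=1e-9)

    def test_degenerate_segment_rejected(self):
        with pytest.raises(ValueError):
            line_transfer_resistance(SIGMA, (0, 0, 0), (0, 0, 0), (5, 5, 5))


class TestTransferMatrix:
    def test_single_entry_equals_line_source(self):
        s = seg((0, 0, 0), (0, 20, 0), radius=2.0)
        arr = ElectrodeArray(ids=[0], positions=[[30.0, 5.0, 0.0]])
        R = build_transfer_matrix(ExtracellularMedium(SIGMA), arr, [s])
        assert R.shape == (1, 1)
        assert R[0, 0] == pytest.approx(line_transfer_resistance(
            SIGMA, s.a, s.b, arr.positions[0], radius=2.0))

    def test_rigid_translation_invariance(self):
        shift = np.array([123.0, -45.0, 67.0])
        s1 = seg((0, 0, 0), (0, 20, 0))
        s2 = seg(shift, shift + np.array([0, 20, 0]))
        pos = np.array([[30.0, 5.0, 0.0], [0.0, 60.0, 10.0]])
        med = ExtracellularMedium(SIGMA)
        R1 = build_transfer_matrix(med, ElectrodeArray([0, 1], pos), [s1])
        R2 = build_transfer_matrix(med, ElectrodeArray([0, 1], pos + shift),
                                   [s2])
        np.testing.assert_allclose(R1, R2, rtol=1e-12)

    def test_monotone_decay_along_linear_array(self):
        s = seg((0, 0, 0), (0, 20, 0))
        pos = [[50.0 + 40.0 * k, 10.0, 0.0] for k in range(8)]
        R = build_transfer_matrix(ExtracellularMedium(SIGMA),
                                  ElectrodeArray(list(range(8)), pos), [s])
        assert (np.diff(R[:, 0]) < 0).all()


class TestAccumulateLFP:
    def test_zero_currents_zero_potential(self):
        phi = np.zeros(3)
        accumulate_lfp(phi, np.full((3, 4), 0.1), np.zeros(4))
        assert (phi == 0).all()

    def test_superposition_exact(self):
        rng = np.random.default_rng(2)
        R1, R2 = rng.random((3, 5)), rng.random((3, 7))
        I1, I2 = rng.standard_normal(5), rng.standard_normal(7)
        phi_both = np.zeros(3)
        accumulate_lfp(phi_both, R1, I1)
        accumulate_lfp(phi_both, R2, I2)
        phi_a, phi_b = np.zeros(3), np.zeros(3)
        accumulate_lfp(phi_a, R1, I1)
        accumulate_lfp(phi_b, R2, I2)
        np.testing.assert_array_equal(phi_both, phi_a + phi_b)

    def test_shape_mismatch_is_error(self):
        with pytest.raises(ValueError, match="shape"):
            accumulate_lfp(np.zeros(3), np.zeros((3, 4)), np.zeros(5))

    def test_single_compartment_closed_form(self, tmp_path):
        # a one-segment cell returns exactly the injected current through
        # its membrane, so phi(t) = R * I_inj(t)
        p = tmp_path / "soma.swc"
        p.write_text("1 1 0 0 0 10 -1\n")
        m = discretize(load_swc(str(p)), 100.0)
        cell = PassiveCableCell(
            m, PassiveCellParams(cm=1.0, g_pas=5e-5, e_pas=-70.0, ra=100.0),
            dt=0.025)
        site = np.array([500.0, 0.0, 0.0])
        med = ExtracellularMedium(SIGMA)
        R = build_transfer_matrix(
            med, ElectrodeArray([0], [site]), m.segments)[0, 0]
        for step in range(1, 2001):
            t = step * 0.025
            i = 0.2 * math.sin(2 * math.pi * t / 10.0)
            cell.i_inject[0] = i
            cell.step()
            phi = R * cell.i_membrane[0]
            assert phi == pytest.approx(R * i, abs=1e-12)

    def test_dipole_far_field_decays_faster_than_monopole(self):
        # zero net current: +I and -I on two nearby segments
        s1 = seg((0, 0, 0), (0, 10, 0), index=0)
        s2 = seg((0, 40, 0), (0, 50, 0), index=1)
        med = ExtracellularMedium(SIGMA)
        currents = np.array([1.0, -1.0])
        extent = 50.0

        def phi_at(d):
            # along the dipole axis, off the cancellation plane
            arr = ElectrodeArray([0], [[0.0, 25.0 + d, 0.0]])
            R = build_transfer_matrix(med, arr, [s1, s2])
            out = np.zeros(1)
            accumulate_lfp(out, R, currents)
            return abs(out[0])

        for d in (10 * extent, 20 * extent, 40 * extent):
            assert phi_at(2 * d) < 0.5 * phi_at(d)
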