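import numpy as np
import pytest
from scipy.linalg import expm

from truespin.engine import (LiouvilleState, ProductBasis, Simulator, Spectrum,
                             hamiltonian, peak_halfwidth, read_spectrum,
                             relaxation_rates, write_spectrum, _embed, _IZ)
from truespin.spin_system import SpinSystem, ax_benchmark


def single_spin(shift=100.0, r1=5.0, r2=5.0):
    return SpinSystem(("A",), (shift,), ((0.0,),), (r1,), (r2,))


class TestRotationConventions:
    def test_90x_maps_z_to_minus_y(self):
        sim = Simulator(single_spin())
        st = sim.hard_pulse(sim.equilibrium(), 90.0, 0.0)
        rho = st.as_matrix()
        iy = np.array([[0, -0.5j], [0.5j, 0]])
        assert np.allclose(rho, -iy, atol=1e-12)

    def test_two_180s_are_identity(self, sim_ax10):
        st = sim_ax10.hard_pulse(sim_ax10.equilibrium(), 90.0, 30.0)
        out = sim_ax10.hard_pulse(sim_ax10.hard_pulse(st, 180.0, 0.0), 180.0, 0.0)
        assert np.allclose(out.coeffs, st.coeffs, atol=1e-12)

    def test_90x_then_90minusx_is_identity(self, sim_ax10):
        st = sim_ax10.equilibrium()
        out = sim_ax10.hard_pulse(sim_ax10.hard_pulse(st, 90.0, 0.0), 90.0, 180.0)
        assert np.allclose(out.coeffs, st.coeffs, atol=1e-12)


class TestCoherentEvolution:
    def test_quarter_period_free_precession(self):
        # offset 100 Hz for 2.5 ms: phase 2*pi*100*0.0025 = pi/2
        sim = Simulator(single_spin(shift=100.0))
        st = sim.hard_pulse(sim.equilibrium(), 90.0, 0.0)
        s0 = sim.detect(st, "A")
        st = sim.evolve(st, 0.0025, relaxation=False)
        s1 = sim.detect(st, "A")
        assert abs(s1) == pytest.approx(abs(s0), rel=1e-10)
        assert np.angle(s1 / s0) == pytest.approx(np.pi / 2, abs=1e-9)

    def test_j_evolution_to_antiphase_at_half_period(self):
        # on-resonance doublet: in-phase A_x -> antiphase 2A_y X_z at 1/(2J)
        s = SpinSystem(("A", "X"), (0.0, 0.0), ((0.0, 10.0), (10.0, 0.0)),
                       (1e-6 + 1, 1), (1e-6 + 1, 1))
        # weak-coupling result needs shifted X to truncate the XX+YY term:
        s = SpinSystem(("A", "X"), (0.0, 5000.0), ((0.0, 10.0), (10.0, 0.0)),
                       (1.0, 1.0), (1.0, 1.0))
        sim = Simulator(s)
        basis = sim.basis
        ix = basis.term(("+", "e")) + basis.term(("-", "e"))  # 2*A_x
        st = sim.state_from_matrix(0.5 * ix)
        out = sim.evolve(st, 1.0 / (2 * 10.0), relaxation=False)
        # in-phase A component should be (nearly) gone
        assert abs(sim.detect(out, "A")) < 5e-3
        # antiphase 2A_yX_z present: coefficients on ('+','z')/('-','z')
        anti = abs(out.coefficient(("+", "z"))) + abs(out.coefficient(("-", "z")))
        assert anti > 0.9

    def test_equivalent_spins_show_no_j_modulation(self):
        # [I_tot, H_J] = 0 for equal shifts: transverse decay has no J wiggle
        s = SpinSystem(("A", "B"), (50.0, 50.0), ((0.0, 12.0), (12.0, 0.0)),
                       (1.0, 1.0), (1.0, 1.0))
        sim = Simulator(s)
        st = sim.hard_pulse(sim.equilibrium(), 90.0, 0.0)
        t = np.linspace(0, 0.3, 40)
        amps = []
        for dt in np.diff(np.concatenate([[0.0], t])):
            st = sim.evolve(st, dt, relaxation=False)
            amps.append(abs(sim.detect(st, ("A", "B"))))
        assert np.ptp(amps) < 1e-10


class TestRelaxationModel:
    def test_sum_rule_rates_on_basis_terms(self, ax10):
        b = ProductBasis(2)
        r = relaxation_rates(ax10, b)
        assert r[b.index[("+", "e")]] == pytest.approx(5.0)
        assert r[b.index[("+", "z")]] == pytest.approx(6.25)
        assert r[b.index[("e", "e")]] == 0.0
        assert r[b.index[("z", "z")]] == pytest.approx(6.25)

    def test_transverse_exponential_decay(self):
        sim = Simulator(single_spin(shift=0.0, r2=5.0))
        st = sim.hard_pulse(sim.equilibrium(), 90.0, 0.0)
        out = sim.evolve(st, 0.2)
        assert abs(sim.detect(out, "A")) == pytest.approx(np.exp(-1.0), rel=1e-10)

    def test_equilibrium_is_fixed_point(self, sim_ax10):
        st = sim_ax10.evolve(sim_ax10.equilibrium(), 0.37)
        assert np.allclose(st.coeffs, sim_ax10.equilibrium().coeffs, atol=1e-12)

    def test_convergence_to_equilibrium_and_monotone_deviation(self, sim_ax10):
        rng = np.random.default_rng(3)
        # random traceless Hermitian perturbation of equilibrium (the unit
        # component does not relax, so a trace offset would persist)
        h = rng.normal(size=(4, 4)) + 1j * rng.normal(size=(4, 4))
        h = h + h.conj().T
        h -= np.trace(h) / 4.0 * np.eye(4)
        rho = sim_ax10.equilibrium().as_matrix() + 0.2 * h
        st = LiouvilleState(sim_ax10.basis.to_coeffs(rho), sim_ax10)
        eq = sim_ax10.equilibrium().coeffs
        dev = [np.linalg.norm(st.coeffs - eq)]
        for _ in range(12):
            st = sim_ax10.evolve(st, 0.5)
            dev.append(np.linalg.norm(st.coeffs - eq))
        assert all(b <= a + 1e-12 for a, b in zip(dev, dev[1:]))
        # slowest relaxing mode is X longitudinal (1.25 s^-1 over 6 s)
        assert dev[-1] < 1e-3 * dev[0]

    def test_inversion_recovery_closed_form(self):
        sim = Simulator(single_spin(r1=5.0))
        st = sim.hard_pulse(sim.equilibrium(), 180.0, 0.0)
        for t in (0.05, 0.2, 0.6):
            out = sim.evolve(st, t)
            assert sim.mz(out, "A") == pytest.approx(1 - 2 * np.exp(-5 * t), rel=1e-10)


class TestStructuralInvariants:
    def test_unitarity_without_relaxation(self, sim_ax10):
        st = sim_ax10.hard_pulse(sim_ax10.equilibrium(), 90.0, 17.0)
        n0 = st.norm()
        out = sim_ax10.evolve(st, 0.123, relaxation=False)
        assert abs(out.norm() - n0) < 1e-10

    def test_hermiticity_preserved_by_all_operations(self, sim_ax10):
        rng = np.random.default_rng(11)
        h = rng.normal(size=(4, 4)) + 1j * rng.normal(size=(4, 4))
        st = LiouvilleState(sim_ax10.basis.to_coeffs(h + h.conj().T), sim_ax10)
        assert st.hermiticity_defect() < 1e-12
        ops = [
            lambda s: sim_ax10.evolve(s, 0.01),
            lambda s: sim_ax10.evolve(s, 0.02, relaxation=False),
            lambda s: sim_ax10.hard_pulse(s, 90.0, 45.0),
            lambda s: sim_ax10.selective_pulse(s, "A", 180.0, 0.0, duration=0.005),
            lambda s: sim_ax10.gradient_purge(s, "A"),
        ]
        for op in ops:
            st = op(st)
            assert st.hermiticity_defect() < 1e-10

    def test_evolve_zero_duration_is_identity(self, sim_ax10):
        st = sim_ax10.hard_pulse(sim_ax10.equilibrium(), 90.0, 0.0)
        assert np.array_equal(sim_ax10.evolve(st, 0.0).coeffs, st.coeffs)

    def test_negative_duration_rejected(self, sim_ax10):
        with pytest.raises(ValueError):
            sim_ax10.evolve(sim_ax10.equilibrium(), -1e-3)

    def test_matrix_exponential_matches_rk4_reference(self, ax10):
        """Propagation agrees with a 1 us fixed-step 4th-order integrator."""
        sim = Simulator(ax10)
        st = sim.hard_pulse(sim.equilibrium(), 90.0, 0.0)
        out = sim.evolve(st, 0.1)
        G = sim.generator(True, True)
        eq = sim.equilibrium().coeffs.reshape(-1)
        c = st.coeffs.reshape(-1) - eq
        dt = 1e-6
        half_gdt = G * dt
        # RK4 on the homogeneous deviation system dc/dt = G c
        k_cache = [half_gdt, half_gdt @ half_gdt]
        for _ in range(100000):
            k1 = G @ c
            k2 = G @ (c + 0.5 * dt * k1)
            k3 = G @ (c + 0.5 * dt * k2)
            k4 = G @ (c + dt * k3)
            c = c + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        ref = eq + c
        num = out.coeffs.reshape(-1)
        assert np.linalg.norm(num - ref) / np.linalg.norm(ref) < 1e-8


class TestSelectivePulse:
    def test_ideal_selective_inversion_leaves_partner(self, sim_ax10):
        st = sim_ax10.equilibrium()
        out = sim_ax10.selective_pulse(st, "A", 180.0, 0.0)
        assert sim_ax10.mz(out, "A") == pytest.approx(-1.0, rel=1e-12)
        assert sim_ax10.mz(out, "X") == pytest.approx(1.0, rel=1e-12)

    def test_relaxation_only_decay_during_ideal_pulse(self, sim_ax10):
        st = sim_ax10.hard_pulse(sim_ax10.equilibrium(), 90.0, 0.0)
        s0 = abs(sim_ax10.detect(st, "A"))
        out = sim_ax10.selective_pulse(st, "X", 360.0, 0.0, duration=0.0185)
        # A coherence only relaxes (r2_A = 5) - no shift/J evolution
        assert abs(sim_ax10.detect(out, "A")) == pytest.approx(
            s0 * np.exp(-5.0 * 0.0185), rel=1e-10)

    def test_shaped_constant_waveform_matches_ideal_inversion(self):
        # on-resonance target: rectangular 180 equals the ideal rotation
        s = single_spin(shift=0.0, r1=5.0, r2=5.0)
        sim = Simulator(s)
        wf = (np.ones(32), np.zeros(32))
        ideal = sim.selective_pulse(sim.equilibrium(), "A", 180.0, 0.0,
                                    duration=0.002)
        shaped = sim.selective_pulse(sim.equilibrium(), "A", 180.0, 0.0,
                                     mode="shaped", duration=0.002, waveform=wf)
        assert sim.mz(shaped, "A") == pytest.approx(sim.mz(ideal, "A"), abs=0.01)

    def test_empty_target_and_missing_waveform_rejected(self, sim_ax10):
        with pytest.raises(ValueError):
            sim_ax10.selective_pulse(sim_ax10.equilibrium(), (), 180.0, 0.0)
        with pytest.raises(ValueError):
            sim_ax10.selective_pulse(sim_ax10.equilibrium(), "A", 180.0, 0.0,
                                     mode="shaped", duration=0.01)


class TestGradientPurge:
    def test_single_quantum_filtering(self, sim_ax10):
        b = sim_ax10.basis
        rho = b.term(("+", "e")) + b.term(("e", "+"))  # A+ + X+
        st = sim_ax10.state_from_matrix(rho)
        out = sim_ax10.gradient_purge(st, "A")
        assert abs(out.coefficient(("+", "e"))) == pytest.approx(1.0)
        assert abs(out.coefficient(("e", "+"))) == 0.0

    def test_longitudinal_terms_immune(self, sim_ax10):
        st = sim_ax10.equilibrium()
        out = sim_ax10.gradient_purge(st, "A")
        assert np.allclose(out.coeffs, st.coeffs)

    def test_mixed_terms(self, sim_ax10):
        b = sim_ax10.basis
        st = sim_ax10.state_from_matrix(b.term(("+", "z")) + b.term(("z", "+")))
        out = sim_ax10.gradient_purge(st, "A")
        assert abs(out.coefficient(("+", "z"))) == pytest.approx(1.0)
        assert abs(out.coefficient(("z", "+"))) == 0.0

    def test_matches_explicit_dephasing_average_oracle(self, ax10):
        """purge-sel180-purge equals the average over 64 gradient phases of
        gradient - selective 180 - gradient (the physical pathway filter)."""
        sim = Simulator(ax10)
        rng = np.random.default_rng(5)
        h = rng.normal(size=(4, 4)) + 1j * rng.normal(size=(4, 4))
        rho0 = h + h.conj().T
        st = LiouvilleState(sim.basis.to_coeffs(rho0), sim)

        mine = sim.gradient_purge(
            sim.selective_pulse(sim.gradient_purge(st, "A"), "A", 180.0, 90.0),
            "A")

        fz = sum(_embed(2, i, _IZ) for i in range(2))
        u180 = sim._rotation_unitary(180.0, 90.0, ("A",))
        acc = np.zeros((4, 4), dtype=complex)
        for phi in 2 * np.pi * np.arange(64) / 64.0:
            g = expm(-1j * phi * fz)
            acc += g @ (u180 @ (g @ rho0 @ g.conj().T) @ u180.conj().T) @ g.conj().T
        oracle = LiouvilleState(sim.basis.to_coeffs(acc / 64.0), sim)
        assert np.allclose(mine.coeffs, oracle.coeffs, atol=1e-10)


class TestSpectra:
    def test_singlet_width_is_r2_over_pi(self):
        s = SpinSystem(("A",), (50.0,), ((0.0,),), (1.0,), (np.pi,))
        sim = Simulator(s)
        st = sim.hard_pulse(sim.equilibrium(), 90.0, 0.0)
        sp = sim.acquire_spectrum(st, dwell=1 / 1024.0, npoints=8192)
        assert peak_halfwidth(sp, 50.0, 10.0) == pytest.approx(1.0, rel=1e-3)
        # peak sits at the spin's offset
        assert sp.freq_hz[np.argmax(sp.intensity)] == pytest.approx(50.0, abs=0.05)

    def test_ax_doublets_split_by_j_centred_on_shifts(self, sim_ax10):
        st = sim_ax10.hard_pulse(sim_ax10.equilibrium(), 90.0, 0.0)
        sp = sim_ax10.acquire_spectrum(st, dwell=1 / 2048.0, npoints=8192)
        for centre in (-250.0, 250.0):
            lo = peak_halfwidth(sp, centre - 5.0, 8.0)  # raises if absent
            sel = (np.abs(sp.freq_hz - (centre - 5)) < 4)
            f_lo = sp.freq_hz[sel][np.argmax(sp.intensity[sel])]
            sel = (np.abs(sp.freq_hz - (centre + 5)) < 4)
            f_hi = sp.freq_hz[sel][np.argmax(sp.intensity[sel])]
            assert f_hi - f_lo == pytest.approx(10.0, abs=0.1)

    def test_emergent_scalar_broadening_of_a_lines(self, sim_ax10):
        """The simulated linewidth reproduces R2 + R1(partner)/2 without the
        formula being coded anywhere in the engine."""
        st = sim_ax10.hard_pulse(sim_ax10.equilibrium(), 90.0, 0.0)
        sp = sim_ax10.acquire_spectrum(st, dwell=1 / 2048.0, npoints=16384)
        w_a = 0.5 * (peak_halfwidth(sp, -255.0, 8.0) + peak_halfwidth(sp, -245.0, 8.0))
        assert w_a == pytest.approx((5.0 + 0.625) / np.pi, rel=0.02)

    def test_aliasing_guard(self, sim_ax10):
        st = sim_ax10.hard_pulse(sim_ax10.equilibrium(), 90.0, 0.0)
        with pytest.raises(ValueError, match="spectral width"):
            sim_ax10.acquire_spectrum(st, dwell=1 / 400.0, npoints=1024)

    def test_npoints_must_be_power_of_two(self, sim_ax10):
        st = sim_ax10.equilibrium()
        with pytest.raises(ValueError, match="power of two"):
            sim_ax10.acquire_spectrum(st, dwell=1 / 2048.0, npoints=3000)

    def test_line_broadening_recorded(self, sim_ax10):
        st = sim_ax10.hard_pulse(sim_ax10.equilibrium(), 90.0, 0.0)
        sp = sim_ax10.acquire_spectrum(st, dwell=1 / 2048.0, npoints=1024,
                                       line_broadening=2.0)
        assert sp.line_broadening == 2.0

    def test_spectrum_io_round_trip(self):
        sp = Spectrum(np.linspace(-5, 5, 11), np.arange(11.0), line_broadening=1.5)
        sp2 = read_spectrum(write_spectrum(sp))
        assert np.array_equal(sp2.freq_hz, sp.freq_hz)
        assert np.array_equal(sp2.intensity, sp.intensity)
        assert sp2.line_broadening == 1.5


class TestPeakHalfwidth:
    def test_synthetic_lorentzian(self):
        f = np.arange(-25, 25, 0.05)
        y = 1.0 / (1.0 + (f / 1.0) ** 2)  # FWHM 2.0
        assert peak_halfwidth(Spectrum(f, y), 0.0, 20.0) == pytest.approx(2.0, abs=0.01)

    def test_window_without_peak_raises(self):
        f = np.arange(-25, 25, 0.05)
        y = 1.0 / (1.0 + (f / 1.0) ** 2)
        with pytest.raises(ValueError):
            peak_halfwidth(Spectrum(f, y), 20.0, 4.0)

    def test_half_height_not_crossed_raises(self):
        f = np.arange(-2, 2, 0.05)
        y = 1.0 / (1.0 + (f / 10.0) ** 2)  # much wider than the window
        with pytest.raises(ValueError):
            peak_halfwidth(Spectrum(f, y), 0.0, 4.0)
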