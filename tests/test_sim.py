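import numpy as np
import pytest

import knockon as kn
from knockon.trajio import ContractViolation

from oracles import boltzmann_site_weights


def short_cfg(sitemap, **kw):
    base = dict(dt_fs=10, n_steps=20_000, seed=7, sitemap=sitemap)
    base.update(kw)
    return kn.RunConfig(**base)


class TestSimulateBasics:
    def test_zero_temperature_ion_stays_at_minimum(self, sitemap,
                                                   landscape):
        cfg = short_cfg(sitemap, temperature=1e-9)
        res = kn.simulate(cfg, landscape, n_ions=1)
        z = res.trajectory.particles[0].z
        # single ion starts at the top (S1) well centre, a minimum
        assert np.all(np.abs(z - sitemap.center("S1")) < 1e-3)

    def test_bit_identical_under_same_seed(self, sitemap, landscape):
        cfg = short_cfg(sitemap, membrane_voltage_mv=20)
        a = kn.simulate(cfg, landscape, n_ions=2, n_waters=1)
        b = kn.simulate(cfg, landscape, n_ions=2, n_waters=1)
        for pa, pb in zip(a.trajectory.particles, b.trajectory.particles):
            np.testing.assert_array_equal(pa.z, pb.z)

    def test_different_seed_differs(self, sitemap, landscape):
        a = kn.simulate(short_cfg(sitemap, seed=1), landscape, n_ions=1)
        b = kn.simulate(short_cfg(sitemap, seed=2), landscape, n_ions=1)
        assert not np.array_equal(a.trajectory.particles[0].z,
                                  b.trajectory.particles[0].z)

    def test_frame_count_contract(self, sitemap, landscape):
        cfg = short_cfg(sitemap, n_steps=1000, sample_stride=10)
        res = kn.simulate(cfg, landscape, n_ions=1)
        assert res.trajectory.n_frames == 101

    def test_unstable_step_raises(self, sitemap, landscape):
        cfg = short_cfg(sitemap, dt_fs=50_000.0, n_steps=200)
        with pytest.raises(kn.StepInstability, match="dt"):
            kn.simulate(cfg, landscape, n_ions=1)

    def test_attached_dipole_trace_shows_fingerprint(self, sitemap,
                                                     landscape):
        cfg = short_cfg(sitemap, n_steps=2000,
                        field=kn.FieldSpec(0.4, 51.87))
        osc = kn.CarbonylOscillator()
        res = kn.simulate(cfg, landscape, n_ions=1, oscillator=osc,
                          dipole_ps=20.0)
        spec = kn.ir_spectrum(res.dipole_trace)
        assert kn.find_peaks(spec)[0].f_thz == pytest.approx(51.87,
                                                             abs=0.1)

    def test_negative_counts_rejected(self, sitemap, landscape):
        with pytest.raises(ContractViolation):
            kn.simulate(short_cfg(sitemap), landscape, n_ions=-1)

    def test_single_file_order_preserved_in_filter(self, sitemap,
                                                   landscape):
        cfg = short_cfg(sitemap, n_steps=100_000, membrane_voltage_mv=30,
                        sample_stride=5)
        res = kn.simulate(cfg, landscape, n_ions=3, n_waters=2)
        sf_lo, _ = sitemap.interval("Scav")
        _, sf_hi = sitemap.interval("S0")
        zs = np.column_stack([p.z for p in res.trajectory.particles])
        for a in range(zs.shape[1]):
            for b in range(a + 1, zs.shape[1]):
                both_in = ((zs[:, a] > sf_lo) & (zs[:, a] < sf_hi)
                           & (zs[:, b] > sf_lo) & (zs[:, b] < sf_hi))
                idx = np.flatnonzero(both_in[:-1] & both_in[1:])
                sign_now = np.sign(zs[idx, a] - zs[idx, b])
                sign_next = np.sign(zs[idx + 1, a] - zs[idx + 1, b])
                assert np.all(sign_now == sign_next)


class TestEquilibrium:
    def test_boltzmann_occupancy(self, sitemap):
        # reflecting boundaries, no driving: site occupancies must match
        # the analytic Boltzmann weights of the landscape within 3 SE
        land = kn.LandscapePotential(
            well_centers=np.array([sitemap.center(s) for s in
                                   ("Scav", "S4", "S3", "S2", "S1")]),
            well_depths=np.array([1.6, 1.0, 1.3, 0.8, 1.2]),
            barriers=np.full(4, 1.2), pore_lo=sitemap.pore_lo,
            pore_hi=sitemap.pore_hi, well_halfwidth=0.05,
            well_names=("Scav", "S4", "S3", "S2", "S1"))
        cfg = kn.RunConfig(dt_fs=5, n_steps=6_000_000, seed=42,
                           boundary="reflect", sitemap=sitemap,
                           sample_stride=20)
        res = kn.simulate(cfg, land, n_ions=1)
        z = res.trajectory.particles[0].z
        idx = sitemap.region_indices(z)
        sites = ("Scav", "S4", "S3", "S2", "S1")
        expected = boltzmann_site_weights(land, sitemap, sites)
        blocks = np.array_split(idx, 20)
        for s in sites:
            j = sitemap.names.index(s)
            fr = [np.mean(b == j) for b in blocks]
            mean = np.mean(fr)
            se = np.std(fr, ddof=1) / np.sqrt(len(fr))
            assert abs(mean - expected[s]) < 3 * se + 0.01, \
                f"{s}: {mean:.3f} vs {expected[s]:.3f} (se {se:.3f})"

    def test_zero_net_flux_without_driving(self, sitemap):
        # reflecting walls: recycling would rectify equilibrium traffic
        land = kn.default_landscape(sitemap, depth=1.0, barrier=1.5,
                                    halfwidth=0.05)
        tot_out = tot_in = 0
        for seed in (1, 2, 3):
            cfg = kn.RunConfig(dt_fs=5, n_steps=4_000_000, seed=seed,
                               boundary="reflect",
                               sitemap=sitemap, sample_stride=20)
            res = kn.simulate(cfg, land, n_ions=1)
            ev = kn.detect_permeations(res.trajectory, sitemap)
            tot_out += sum(e.direction == "outward" for e in ev)
            tot_in += sum(e.direction == "inward" for e in ev)
        net = tot_out - tot_in
        se = np.sqrt(max(tot_out + tot_in, 1))
        assert abs(net) < 3 * se + 3


class TestArrhenius:
    def test_log_current_linear_in_barrier_shift(self, sitemap):
        from oracles import cycle_time_ps

        land0 = kn.default_landscape(sitemap, depth=1.0, barrier=2.0,
                                     halfwidth=0.05)
        shifts = np.array([0.0, -0.5, -1.0])
        rates, oracle = [], []
        for d in shifts:
            land = land0.with_barrier_shift(d)
            oracle.append(1e3 / cycle_time_ps(land, sitemap, tilt_mv=15))
            n = 0
            for seed in (5, 6):
                cfg = kn.RunConfig(dt_fs=5, n_steps=8_000_000, seed=seed,
                                   membrane_voltage_mv=15, sitemap=sitemap,
                                   sample_stride=25, discard_time_ns=0.5)
                res = kn.simulate(cfg, land, n_ions=1)
                ev = kn.detect_permeations(res.trajectory, sitemap)
                n += sum(e.direction == "outward" for e in ev)
            rates.append(n)
        slope = np.polyfit(shifts, np.log(rates), 1)[0]
        slope_oracle = np.polyfit(shifts, np.log(oracle), 1)[0]
        # Arrhenius behaviour: ln(current) linear in the barrier shift with
        # slope -1/kT, diluted by the diffusive part of the transit exactly
        # as the mean-first-passage-time oracle predicts
        assert slope < -0.45
        assert slope == pytest.approx(slope_oracle, abs=0.15)


class TestOscillator:
    def test_free_oscillation_decays_without_drive(self):
        osc = kn.CarbonylOscillator(x0_nm=1e-3)
        tr = kn.drive_oscillator(osc, kn.FieldSpec(0.0, 0.0), n_steps=20_000)
        assert np.abs(tr.mu[-100:]).max() < 1e-3 * np.abs(tr.mu[:100]).max()

    def test_lorentzian_amplitude_ratio_resonant_vs_96pct(self):
        osc = kn.CarbonylOscillator()
        f1 = kn.FieldSpec(0.4, osc.f0_thz)
        f2 = kn.FieldSpec(0.4, 0.96 * osc.f0_thz)
        a1 = kn.measured_amplitude(
            kn.drive_oscillator(osc, f1, n_steps=60_000), osc)
        a2 = kn.measured_amplitude(
            kn.drive_oscillator(osc, f2, n_steps=60_000), osc)
        expected = osc.steady_amplitude(f1) / osc.steady_amplitude(f2)
        assert a1 / a2 == pytest.approx(expected, rel=0.01)

    @pytest.mark.parametrize("f_thz", np.linspace(46, 58, 10).round(2))
    def test_resonance_curve_matches_lorentzian(self, f_thz):
        osc = kn.CarbonylOscillator()
        fld = kn.FieldSpec(0.4, float(f_thz))
        tr = kn.drive_oscillator(osc, fld, n_steps=60_000)
        assert kn.measured_amplitude(tr, osc) == pytest.approx(
            osc.steady_amplitude(fld), rel=0.01)

    def test_off_resonance_amplitude_strictly_smaller(self):
        osc = kn.CarbonylOscillator(f0_thz=51.87)
        on = kn.drive_oscillator(osc, kn.FieldSpec(0.4, 51.87),
                                 n_steps=40_000)
        off = kn.drive_oscillator(osc, kn.FieldSpec(0.4, 50.0),
                                  n_steps=40_000)
        assert kn.measured_amplitude(off, osc) < \
            kn.measured_amplitude(on, osc)

    def test_unresolved_dt_rejected(self):
        osc = kn.CarbonylOscillator()
        with pytest.raises(ValueError, match="dt"):
            kn.drive_oscillator(osc, kn.FieldSpec(0.4, 51.87), dt_fs=2.0)

    def test_overdamped_oscillator_rejected(self):
        with pytest.raises(ContractViolation, match="underdamped"):
            kn.CarbonylOscillator(f0_thz=0.1, gamma_per_ps=10.0)

    def test_driven_spectrum_peaks_at_drive_frequency(self):
        osc = kn.CarbonylOscillator()
        tr = kn.drive_oscillator(osc, kn.FieldSpec(0.4, osc.f0_thz),
                                 n_steps=60_000)
        spec = kn.ir_spectrum(tr)
        peak = kn.find_peaks(spec)[0]
        assert peak.f_thz == pytest.approx(osc.f0_thz, abs=0.1)

    def test_normalized_excitation_orders_frequencies(self):
        osc = kn.CarbonylOscillator()
        u_res = kn.normalized_excitation(osc, kn.FieldSpec(0.4, 51.87))
        u_53 = kn.normalized_excitation(osc, kn.FieldSpec(0.4, 53.0))
        u_50 = kn.normalized_excitation(osc, kn.FieldSpec(0.4, 50.0))
        assert u_res == pytest.approx(1.0, abs=0.02)
        assert 0.0 < u_50 < u_53 < u_res
        assert kn.normalized_excitation(osc, kn.FieldSpec(0.0, 51.87)) == 0


class TestModulatedBarrier:
    def test_zero_coupling_is_identity(self, sitemap):
        land = kn.default_landscape(sitemap, kappa=0.0)
        assert kn.modulated_barrier(land, 1.0) is land

    def test_exact_lowering(self, sitemap):
        land = kn.default_landscape(sitemap, kappa=0.5)
        out = kn.modulated_barrier(land, 1.0)
        assert out.barriers[land.s1_transition] == pytest.approx(
            land.barriers[land.s1_transition] - 0.5)
        others = np.delete(out.barriers, land.s1_transition)
        np.testing.assert_allclose(
            others, np.delete(land.barriers, land.s1_transition))

    def test_flattened_barrier_rejected(self, sitemap):
        land = kn.default_landscape(sitemap, depth=1.2, barrier=3.0,
                                    kappa=10.0)
        with pytest.raises(ContractViolation, match="barrier"):
            kn.modulated_barrier(land, 1.0)


class TestForceRatio:
    def test_reference_values(self):
        assert kn.force_ratio(299_792_458.0) == 1.0
        assert kn.force_ratio(0.0) == 0.0
        assert kn.force_ratio(300.0) == pytest.approx(1.0007e-6, rel=1e-4)

    def test_superluminal_rejected(self):
        with pytest.raises(ValueError):
            kn.force_ratio(3.1e8)
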