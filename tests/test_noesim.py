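import numpy as np
import pytest

from dnoekit import Schedule, noesim, peak_io, relax_fit
from dnoekit.noesim import (
    NoiseModel,
    evolve,
    make_spin_system,
    simulate_dnoe_curve,
    simulate_ssnoe,
)
from dnoekit.scheduler import DSAT_GRID_11

from conftest import rk4_pool_oracle


class TestMakeSpinSystem:
    def test_no_noe_means_no_cross_relaxation(self):
        assert make_spin_system(1.0, 1.4, 0.85, 0.412).sigma_nh == 0.0

    def test_cross_relaxation_implied_by_target_noe(self):
        sys_ = make_spin_system(0.805, 1.4, 0.85, 0.412)
        assert sys_.sigma_nh == pytest.approx(0.02767, abs=2e-5)
        assert sys_.sigma_nh > 0

    def test_negative_noe_implies_larger_coupling(self):
        pos = make_spin_system(0.805, 1.4, 0.85, 0.412)
        neg = make_spin_system(-0.813, 1.4, 0.85, 0.412)
        assert neg.sigma_nh > pos.sigma_nh > 0

    def test_nonphysical_coupling_warns_but_builds(self):
        with pytest.warns(UserWarning, match="coupling bound"):
            sys_ = make_spin_system(-0.9, r1n=1.0, r1h=0.01, r1w=0.4)
        assert sys_.nonphysical

    def test_relaxation_matrix_decays(self):
        sys_ = make_spin_system(-0.812, 1.1, 0.85, 0.412, k_exchange=5.0)
        eig = np.linalg.eigvals(sys_.relaxation_matrix())
        assert np.all(np.real(eig) > 0)
        assert np.allclose(np.imag(eig), 0.0)


class TestEvolve:
    def test_zero_duration_returns_initial(self):
        sys_ = make_spin_system(0.805, 1.4, 0.85, 0.412, k_exchange=5.0)
        init = np.array([0.3, 1.0, 5.0])
        np.testing.assert_array_equal(evolve(sys_, 0.0, initial=init), init)

    def test_equilibrium_is_a_fixed_point(self):
        sys_ = make_spin_system(0.805, 1.4, 0.85, 0.412, k_exchange=5.0)
        out = evolve(sys_, 7.0)
        np.testing.assert_allclose(out, sys_.eq_mags, rtol=1e-12)

    def test_long_saturation_reaches_target_noe(self):
        sys_ = make_spin_system(0.805, 1.4, 0.85, 0.412, k_exchange=5.0)
        out = evolve(sys_, 100.0 / sys_.r1n, saturate_h=True)
        assert out[0] == pytest.approx(0.805, abs=1e-9)
        assert out[1] == 0.0

    @pytest.mark.parametrize("saturate_h", [False, True])
    def test_matches_brute_force_integrator(self, saturate_h):
        sys_ = make_spin_system(-0.812, 1.1, 0.85, 0.412, k_exchange=5.0)
        fast = evolve(sys_, 1.0, saturate_h=saturate_h, initial=np.zeros(3))
        slow = rk4_pool_oracle(sys_, 1.0, 1e-4, saturate_h=saturate_h,
                               initial=np.zeros(3))
        rel = np.max(np.abs(fast - slow) / sys_.eq_mags)
        assert rel < 1e-6

    def test_reduces_to_buildup_model_without_exchange(self):
        # with water decoupled the saturated N pool follows
        # eps + (1 - eps) exp(-R1N t) exactly
        eps, r1n = 0.805, 1.4
        sys_ = make_spin_system(eps, r1n, 0.85, 0.412, k_exchange=0.0)
        for t in DSAT_GRID_11:
            mn = evolve(sys_, t, saturate_h=True)[0]
            assert mn == pytest.approx(eps + (1 - eps) * np.exp(-r1n * t), abs=1e-9)

    def test_trajectories_bounded_by_start_and_steady_state(self):
        times = np.linspace(0.0, 30.0, 40)
        # weakly coupled (positive NOE) recovery from zero stays in [0, eq];
        # strongly negative NOEs can transiently undershoot via cross
        # relaxation, so no global bound is claimed there
        mild = make_spin_system(0.805, 1.2, 0.85, 0.412, k_exchange=5.0)
        for t in times:
            m = evolve(mild, t, initial=np.zeros(3))
            assert np.all(m >= -1e-9 * mild.eq_mags)
            assert np.all(m <= mild.eq_mags * (1 + 1e-9))
        # under saturation the N pool is decoupled and monotone: within [eps, 1]
        strong = make_spin_system(-0.5, 1.2, 0.85, 0.412, k_exchange=5.0)
        for t in times:
            mn = evolve(strong, t, saturate_h=True)[0]
            assert -0.5 - 1e-9 <= mn <= 1.0 + 1e-9


class TestSimulateSsnoe:
    def test_adequate_delays_recover_true_noe(self):
        sys_ = make_spin_system(-0.812, 1.1, 0.85, 0.412, k_exchange=5.0)
        long = -np.log(1e-6)
        s = Schedule(long / 0.412, 10.0, long / 1.1, 22.3)
        assert simulate_ssnoe(sys_, s).epsilon_app == pytest.approx(-0.812, abs=1e-4)

    def test_short_saturation_biases_toward_positive(self):
        sys_ = make_spin_system(-0.812, 1.1, 0.85, 0.412, k_exchange=5.0)
        r = simulate_ssnoe(sys_, Schedule(30.0, 10.0, 1.0, 22.3))
        assert r.epsilon_app > -0.812

    def test_short_reference_delay_biases_toward_negative(self):
        sys_ = make_spin_system(-0.812, 1.1, 0.85, 0.412, k_exchange=5.0)
        r = simulate_ssnoe(sys_, Schedule(3.0, 10.0, 12.0, 22.3))
        assert r.epsilon_app < -0.812

    def test_bias_vanishes_monotonically_with_each_delay(self):
        sys_ = make_spin_system(-0.812, 1.1, 0.85, 0.412, k_exchange=5.0)
        errs_dsat = [abs(simulate_ssnoe(sys_, Schedule(30, 10, d, 22.3)).epsilon_app
                         + 0.812) for d in (0.5, 1, 2, 3, 5, 8, 12)]
        errs_rd1 = [abs(simulate_ssnoe(sys_, Schedule(rd, 10, 12, 22.3)).epsilon_app
                        + 0.812) for rd in (2, 3, 5, 8, 13, 20, 30)]
        assert all(b < a for a, b in zip(errs_dsat, errs_dsat[1:]))
        assert all(b < a for a, b in zip(errs_rd1, errs_rd1[1:]))


class TestGenerateDnoe:
    def test_noiseless_ideal_mode_is_exact(self, rng, dnoe_schedule):
        truth = noesim.draw_residue_params(3, rng)
        tables = noesim.generate_dnoe(dnoe_schedule, truth, noise=None)
        for row in truth.itertuples(index=False):
            t = tables[row.residue].delays
            expected = 100.0 * (row.epsilon_true
                                + (1 - row.epsilon_true) * np.exp(-row.r1n * t))
            np.testing.assert_array_equal(tables[row.residue].intensities, expected)

    def test_fixed_seed_reproduces_tables_bit_for_bit(self, tmp_path, dnoe_schedule):
        paths = []
        for name in ("a.tsv", "b.tsv"):
            rng = np.random.default_rng(99)
            truth = noesim.draw_residue_params(5, rng)
            tables = noesim.generate_dnoe(dnoe_schedule, truth,
                                          NoiseModel(snr=150), rng=rng)
            path = tmp_path / name
            peak_io.write_intensity_table(tables, path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_noise_rms_set_by_snr_at_peak_signal(self, rng, dnoe_schedule):
        truth = noesim.draw_residue_params(1, rng, eps_range=(0.5, 0.5))
        tables = noesim.generate_dnoe(dnoe_schedule, truth, NoiseModel(snr=200),
                                      rng=rng)
        series = next(iter(tables.values()))
        rms = series.noise_rms
        assert np.all(rms == rms[0])
        assert rms[0] == pytest.approx(100.0 / 200)

    def test_pool_mode_buildup_fits_to_true_noe(self, sample_rates):
        # slow exchange: the simulated buildup is governed by R1N and a
        # standalone fit recovers the target NOE to within 1%
        slow = peak_io.SampleRates(r1w=0.412, r1h=0.85, r1n={}, k_exchange=0.1)
        sched = Schedule(25.0, 25.0, DSAT_GRID_11, 22.3)
        truth = noesim.draw_residue_params(1, np.random.default_rng(3))
        truth.loc[0, ["epsilon_true", "r1n"]] = [0.805, 1.4]
        tables = noesim.generate_dnoe(sched, truth, noise=None, mode="pools",
                                      sample_rates=slow)
        fit = relax_fit.fit_dnoe(tables[truth.loc[0, "residue"]], "C")
        assert fit.epsilon == pytest.approx(0.805, rel=0.01)

    def test_inadequate_rd2_warns_in_pool_mode(self, sample_rates):
        sched = Schedule(13.0, 0.5, DSAT_GRID_11, 22.3)
        truth = noesim.draw_residue_params(1, np.random.default_rng(3))
        with pytest.warns(UserWarning, match="RD2"):
            noesim.generate_dnoe(sched, truth, noise=None, mode="pools",
                                 sample_rates=sample_rates)

    def test_pool_mode_curve_from_zero_rd2_carries_restart_error(self, sample_rates):
        sys_ = make_spin_system(0.805, 1.4, sample_rates.r1h, sample_rates.r1w,
                                k_exchange=sample_rates.k_exchange)
        good = simulate_dnoe_curve(sys_, Schedule(13, 40, (0.0, 1.0, 4.0), 22.3))
        bad = simulate_dnoe_curve(sys_, Schedule(13, 1.0, (0.0, 1.0, 4.0), 22.3))
        assert good[0] == pytest.approx(1.0, abs=1e-6)
        assert bad[0] < good[0]  # truncated recovery attenuates the t=0 point
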