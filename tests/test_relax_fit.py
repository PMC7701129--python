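import numpy as np
import pytest

from dnoekit import noesim, relax_fit
from dnoekit.errors import AlignmentError, IllPosedFitError, InsufficientDataError
from dnoekit.peak_io import series_from_arrays
from dnoekit.relax_fit import FitMode, dnoe_model
from dnoekit.scheduler import DSAT_GRID_11


def _r1_series(r1=1.4, a=100.0, delays=(0.0, 0.2, 0.5, 1.0, 2.0), noise_rms=None,
               rng=None):
    t = np.asarray(delays, dtype=float)
    y = a * np.exp(-r1 * t)
    if noise_rms is not None:
        y = y + rng.normal(0, noise_rms, size=t.size)
    return series_from_arrays("X1", t, y, noise_rms=noise_rms)


def _dnoe_series(s0=100.0, eps=0.805, r1=1.4, delays=DSAT_GRID_11, noise_rms=None,
                 rng=None, residue="X1"):
    t = np.asarray(delays, dtype=float)
    y = dnoe_model(t, s0, eps, r1)
    if noise_rms is not None:
        y = y + rng.normal(0, noise_rms, size=t.size)
    return series_from_arrays(residue, t, y, noise_rms=noise_rms)


class TestFitR1:
    def test_noiseless_recovery(self):
        fit = relax_fit.fit_r1(_r1_series())
        assert fit.r1 == pytest.approx(1.4, rel=1e-8)
        assert fit.amplitude == pytest.approx(100.0, rel=1e-8)
        assert not fit.non_decaying

    def test_monte_carlo_errors_match_scatter(self, rng):
        r1s, d_r1s = [], []
        for _ in range(500):
            fit = relax_fit.fit_r1(_r1_series(noise_rms=0.5, rng=rng))
            r1s.append(fit.r1)
            d_r1s.append(fit.d_r1)
        r1s, d_r1s = np.array(r1s), np.array(d_r1s)
        se = r1s.std(ddof=1) / np.sqrt(r1s.size)
        assert abs(r1s.mean() - 1.4) < 3 * se
        assert r1s.std(ddof=1) == pytest.approx(d_r1s.mean(), rel=0.20)

    def test_constant_series_flagged_non_decaying(self):
        series = series_from_arrays("X1", [0.0, 1.0, 2.0], [100.0, 100.0, 100.0])
        assert relax_fit.fit_r1(series).non_decaying

    def test_too_few_distinct_delays(self):
        series = series_from_arrays("X1", [0.0, 0.0, 1.0], [100.0, 99.0, 50.0])
        with pytest.raises(InsufficientDataError):
            relax_fit.fit_r1(series)


class TestFitDnoe:
    def test_mode_c_noiseless_recovery_on_full_grid(self):
        fit = relax_fit.fit_dnoe(_dnoe_series(), FitMode.C_STANDALONE)
        assert fit.epsilon == pytest.approx(0.805, rel=1e-8)
        assert fit.s0 == pytest.approx(100.0, rel=1e-8)
        assert fit.r1 == pytest.approx(1.4, rel=1e-8)

    def test_buildup_curve_endpoints(self):
        fit = relax_fit.fit_dnoe(_dnoe_series(eps=-0.246, r1=1.1), "C")
        at_zero = dnoe_model(0.0, fit.s0, fit.epsilon, fit.r1)
        at_inf = dnoe_model(100.0 / fit.r1, fit.s0, fit.epsilon, fit.r1)
        assert at_zero == pytest.approx(fit.s0, rel=1e-10)
        assert at_inf == pytest.approx(fit.s0 * fit.epsilon, rel=1e-10)

    def test_mode_a_and_mode_b_agree_on_noiseless_data(self):
        dnoe = _dnoe_series()
        r1_data = _r1_series()
        fit_a = relax_fit.fit_dnoe(dnoe, "A", r1_fixed=1.4)
        fit_b = relax_fit.fit_dnoe(dnoe, "B", r1_series=r1_data)
        assert fit_a.epsilon == pytest.approx(fit_b.epsilon, abs=1e-8)

    def test_mode_a_requires_r1(self):
        with pytest.raises(ValueError, match="r1_fixed"):
            relax_fit.fit_dnoe(_dnoe_series(), "A")

    def test_mode_b_requires_r1_series(self):
        with pytest.raises(ValueError, match="r1_series"):
            relax_fit.fit_dnoe(_dnoe_series(), "B")

    def test_all_delays_equal_is_ill_posed(self):
        series = series_from_arrays("X1", [1.0, 1.0, 1.0], [50.0, 51.0, 49.0])
        with pytest.raises(IllPosedFitError):
            relax_fit.fit_dnoe(series, "C")

    def test_mode_c_needs_three_distinct_delays(self):
        series = series_from_arrays("X1", [0.0, 4.0], [100.0, 80.0])
        with pytest.raises(InsufficientDataError):
            relax_fit.fit_dnoe(series, "C")

    def test_negative_noe_couples_eps_and_r1_more_strongly(self):
        # the larger intensity range of a negative NOE increases |c(eps, R1)|
        fit_pos = relax_fit.fit_dnoe(_dnoe_series(eps=0.805), "C")
        fit_neg = relax_fit.fit_dnoe(_dnoe_series(eps=-0.813), "C")
        assert abs(fit_neg.corr_eps_r1) > abs(fit_pos.corr_eps_r1)

    def test_mode_a_error_insensitive_to_r1_within_its_sd(self, rng):
        series = _dnoe_series(noise_rms=100.0 / 150, rng=rng)
        delta = relax_fit.mode_a_sensitivity(series, 1.4, 0.008)
        assert delta < 1e-5


class TestCompareModes:
    def _results(self, eps_shift=0.0):
        out = []
        for i, (eps, r1) in enumerate([(0.8, 1.3), (0.2, 1.1), (-0.5, 1.5)]):
            out.append(relax_fit.FitResult(
                residue=f"A{i+1}", mode=FitMode.C_STANDALONE,
                epsilon=eps + eps_shift, d_epsilon=0.003, s0=100.0, d_s0=0.5,
                r1=r1, d_r1=0.06, corr_eps_r1=0.01, reduced_chi2=1.0, n_points=11,
            ))
        return out

    def test_identity(self):
        cmp_ = relax_fit.compare_modes(self._results(), self._results())
        assert cmp_.pairwise_rmsd_eps == 0.0
        assert cmp_.pairwise_rmsd_r1 == 0.0
        assert cmp_.error_ratio_eps == pytest.approx(1.0)
        assert cmp_.error_ratio_r1 == pytest.approx(1.0)

    def test_uniform_shift_gives_that_rmsd(self):
        cmp_ = relax_fit.compare_modes(self._results(), self._results(eps_shift=0.01))
        assert cmp_.pairwise_rmsd_eps == pytest.approx(0.01, abs=1e-12)

    def test_residue_mismatch_lists_offenders(self):
        other = self._results()
        other[0].residue = "Z9"
        with pytest.raises(AlignmentError, match="Z9"):
            relax_fit.compare_modes(self._results(), other)

    def test_standalone_r1_less_precise_than_dedicated(self, rng, dnoe_schedule):
        # mode C extracts R1 from the buildup alone; its R1 errors exceed the
        # dedicated decay experiment's by a large factor
        truth = noesim.draw_residue_params(70, rng, eps_range=(0.2, 0.9))
        noise = noesim.NoiseModel(snr=150)
        tables = noesim.generate_dnoe(dnoe_schedule, truth, noise, rng=rng)
        r1_tables = noesim.generate_r1(truth, noise, rng=rng)
        r1_fits = {res: relax_fit.fit_r1(s) for res, s in r1_tables.items()}
        res_a = relax_fit.fit_dnoe_table(tables, "A", r1_table=r1_fits)
        res_c = relax_fit.fit_dnoe_table(tables, "C")
        cmp_ = relax_fit.compare_modes(res_a, res_c)
        assert cmp_.error_ratio_r1 > 1.0
        # while the NOE values themselves stay consistent between modes
        assert cmp_.pairwise_rmsd_eps < cmp_.mean_sigma_eps_a


class TestReducedGridReport:
    def test_full_subgrid_gives_zero_differences(self):
        series = {"X1": _dnoe_series()}
        rep = relax_fit.reduced_grid_report(series, [DSAT_GRID_11])
        assert rep["delta_eps"].abs().max() == 0.0

    def test_noiseless_data_gives_zero_differences_on_any_valid_subgrid(self):
        series = {r: _dnoe_series(eps=e, residue=r)
                  for r, e in [("X1", 0.805), ("X2", -0.246)]}
        rep = relax_fit.reduced_grid_report(series, [(0.0, 0.35, 0.79, 4.0)])
        assert rep["delta_eps"].abs().max() < 1e-9

    def test_small_subgrid_refused(self):
        with pytest.raises(ValueError, match="4 delays"):
            relax_fit.reduced_grid_report({"X1": _dnoe_series()}, [(0.0, 1.3, 4.0)])

    def test_subgrid_must_keep_endpoints(self):
        with pytest.raises(ValueError, match="maximal delay"):
            relax_fit.reduced_grid_report(
                {"X1": _dnoe_series()}, [(0.0, 0.35, 0.79, 1.3)]
            )
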