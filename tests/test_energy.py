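"""Energy-balance model: closed forms, conservation, paradigm fitting."""

import math
from dataclasses import replace

import numpy as np
import pytest

from planergy.energy import (EnergyBalanceModel, FeedingSchedule,
                             ParadigmRateModel, fit_paradigm,
                             compare_paradigms, predict_energy_per_cell,
                             assimilation_ratio, EnergyModelError,
                             PW_TO_J_PER_DAY)
from planergy.powerlaw import PowerLawResults
from planergy.rates import RatePoint


def _p3(j=2.5, p=1.0, c=0.38, e_ref=3e-6):
    return EnergyBalanceModel.allometric(j=j, p=p, c=c, e_ref=e_ref)


def _rate_points(model, ns, fed):
    """Closed-form rate points of one sign from a paradigm-2/3 model."""
    pts = []
    for i, n in enumerate(ns):
        r = 100.0 * model.growth_rate(n, fed=fed)
        pts.append(RatePoint(n, r, (0, 1), f"a{i}",
                             "growth" if fed else "degrowth",
                             history_weeks=1.0 + (i % 4)))
    return pts


class TestClosedForms:
    def test_paradigm3_with_c_zero_equals_paradigm2(self):
        m3 = EnergyBalanceModel.allometric(j=2.0, p=1.0, c=0.0, e_ref=3e-6)
        m2 = EnergyBalanceModel.isometric(j=2.0, p=1.0, epsilon=3e-6)
        for n in (1e4, 1e6, 1e8):
            assert m3.energy_of_cells(n) == pytest.approx(m2.energy_of_cells(n))

    def test_reference_size_returns_e_ref(self):
        m = _p3()
        assert m.energy_of_cells(m.n_ref) / m.n_ref == pytest.approx(m.e_ref)

    def test_reserve_doubles_at_the_predicted_size_ratio(self):
        m = _p3(c=0.38)
        n2 = m.n_ref * 2 ** (1 / 0.38)
        e1 = m.energy_of_cells(m.n_ref) / m.n_ref
        e2 = m.energy_of_cells(n2) / n2
        assert e2 / e1 == pytest.approx(2.0, rel=1e-12)

    def test_paradigm1_has_no_energy_constraint(self):
        m = EnergyBalanceModel.dynamic_reserve(j=1, p=1, k=1e4, e_set=3e-6)
        with pytest.raises(EnergyModelError):
            m.energy_of_cells(1e6)

    def test_isometric_fed_rate(self):
        m = EnergyBalanceModel.isometric(j=2.0, p=1.0, epsilon=3e-6)
        expected = 1.0 * PW_TO_J_PER_DAY / 3e-6  # (j - p) = p here
        assert m.growth_rate(1e6, fed=True) == pytest.approx(expected)
        assert m.growth_rate(1e4, fed=True) == pytest.approx(expected)

    def test_allometric_starved_rate_magnitude_decreases_with_size(self):
        m = _p3()
        rates = [abs(m.growth_rate(n, fed=False)) for n in (1e5, 1e6, 1e7)]
        assert rates[0] > rates[1] > rates[2]

    def test_allometric_rate_scales_as_n_to_minus_c(self):
        c = 0.38
        e_ref = 1.0 * PW_TO_J_PER_DAY / (0.01 * (1 + c))  # -1%/day at n_ref
        m = EnergyBalanceModel.allometric(j=0.0, p=1.0, c=c, e_ref=e_ref)
        assert m.growth_rate(m.n_ref, fed=False) == pytest.approx(-0.01)
        assert m.growth_rate(16 * m.n_ref, fed=False) == pytest.approx(
            -0.01 * 16 ** -0.38, rel=1e-12)


class TestSimulation:
    def test_isometric_matches_exponential_closed_form(self):
        m = EnergyBalanceModel.isometric(j=2.0, p=1.0, epsilon=3e-6)
        sched = FeedingSchedule(((0.0, 42.0),))
        tr = m.simulate(sched, 1e6, t_grid=np.linspace(0, 42, 43))
        closed = 1e6 * np.exp(PW_TO_J_PER_DAY / 3e-6 * tr.times)
        assert np.max(np.abs(tr.N / closed - 1)) < 1e-6

    def test_allometric_starvation_nc_decays_linearly(self):
        m = _p3()
        tr = m.simulate(FeedingSchedule.starvation(), 1e6,
                        t_grid=np.linspace(0, 42, 43))
        nc = tr.N ** m.c
        slope_truth = (-m.c * m.p * PW_TO_J_PER_DAY * m.n_ref ** m.c
                       / (m.e_ref * (1 + m.c)))
        closed = (1e6 ** m.c + slope_truth * tr.times) ** (1 / m.c)
        assert np.max(np.abs(tr.N / closed - 1)) < 1e-6
        r2 = np.corrcoef(tr.times, nc)[0, 1] ** 2
        assert r2 > 0.999

    def test_allometric_c_to_zero_converges_to_isometric(self):
        grid = np.linspace(0, 42, 43)
        sched = FeedingSchedule.weekly(6, 3.5)
        m3 = EnergyBalanceModel.allometric(j=2.5, p=1.0, c=1e-8, e_ref=3e-6)
        m2 = EnergyBalanceModel.isometric(j=2.5, p=1.0, epsilon=3e-6)
        t3 = m3.simulate(sched, 1e6, t_grid=grid)
        t2 = m2.simulate(sched, 1e6, t_grid=grid)
        assert np.max(np.abs(t3.N / t2.N - 1)) < 1e-6

    def test_dynamic_reserve_fixed_point(self):
        m = EnergyBalanceModel.dynamic_reserve(j=1.0, p=1.0, k=4630,
                                               e_set=8.64e-6)
        sched = FeedingSchedule(((0.0, 42.0),))
        tr = m.simulate(sched, 1e6, E0=8.64e-6 * 1e6,
                        t_grid=np.linspace(0, 42, 43))
        assert np.max(np.abs(tr.N / 1e6 - 1)) < 1e-9
        assert np.max(np.abs(tr.E / (8.64e-6 * 1e6) - 1)) < 1e-9

    @pytest.mark.parametrize("model,E0,sched", [
        (_p3(), None, FeedingSchedule.weekly(6, 3.5)),
        (_p3(), None, FeedingSchedule.starvation()),
        (EnergyBalanceModel.isometric(j=2.0, p=1.0, epsilon=3e-6), None,
         FeedingSchedule(((0.0, 42.0),))),
        (EnergyBalanceModel.dynamic_reserve(j=2.5, p=1.0, k=4630,
                                            e_set=8.64e-6),
         8.64e-6 * 1e6, FeedingSchedule.weekly(6, 2.0)),
    ])
    def test_energy_conservation(self, model, E0, sched):
        """|E(t) - E(0) - integral of (J-P)| <= 1e-6 max(E) throughout."""
        tr = model.simulate(sched, 1e6, E0=E0,
                            t_grid=np.linspace(0, 42, 85))
        assert tr.conservation_residual() < 1e-6

    def test_starvation_floor_truncates_with_flag(self):
        m = _p3(e_ref=1e-8)  # tiny reserves: rapid collapse
        tr = m.simulate(FeedingSchedule.starvation(), 1e4,
                        t_grid=np.linspace(0, 60, 61), n_floor=1e3)
        assert tr.truncated
        assert tr.N[-1] >= 0.99e3
        assert tr.times[-1] < 60.0

    def test_allometric_history_independence(self):
        """Starvation trajectories that meet at equal N coincide after."""
        m = _p3()
        a = m.simulate(FeedingSchedule.starvation(), 1e6,
                       t_grid=np.linspace(0, 28, 29))
        # second animal starts where the first was after 7 days
        b = m.simulate(FeedingSchedule.starvation(), a.N[7],
                       t_grid=np.linspace(0, 21, 22))
        assert np.max(np.abs(b.N / a.N[7:] - 1)) < 1e-7

    def test_dynamic_reserve_history_dependence_counterexample(self):
        """Equal N but different reserves diverge under the same starvation."""
        m = EnergyBalanceModel.dynamic_reserve(j=2.5, p=1.0, k=4630,
                                               e_set=8.64e-6)
        grid = np.linspace(0, 21, 22)
        rich = m.simulate(FeedingSchedule.starvation(), 1e6,
                          E0=8.64e-6 * 1e6, t_grid=grid)
        poor = m.simulate(FeedingSchedule.starvation(), 1e6,
                          E0=0.5 * 8.64e-6 * 1e6, t_grid=grid)
        assert abs(poor.N[-1] / rich.N[-1] - 1) > 0.01


class TestScalingPredictions:
    def test_paradigm_exponent_table(self):
        p3 = _p3().predict_scaling_exponents()
        assert (p3.e_per_n, p3.p_per_n, p3.j_per_n) == (0.38, 0.0, 0.0)
        p2 = EnergyBalanceModel.isometric(j=1, p=1, epsilon=1e-6
                                          ).predict_scaling_exponents()
        assert (p2.e_per_n, p2.p_per_n, p2.j_per_n) == (0.0, 0.0, 0.0)
        p1 = EnergyBalanceModel.dynamic_reserve(j=1, p=1, k=1, e_set=1e-6
                                                ).predict_scaling_exponents()
        assert p1.e_per_n is None and "history" in p1.note

    def test_simulated_populations_recover_c_from_reserve_scaling(self):
        m = _p3()
        ns = np.geomspace(1e5, 1e7, 12)
        e_per_n = m.energy_of_cells(ns) / ns
        from planergy.powerlaw import fit_power_law

        fit = fit_power_law(ns, e_per_n)
        assert fit.exponent == pytest.approx(m.c, abs=1e-9)


class TestParadigmFitting:
    def test_noiseless_self_consistency(self):
        m = _p3()
        ns = np.geomspace(1e5, 1e7, 25)
        gp = _rate_points(m, ns, fed=True)
        dp = _rate_points(m, ns, fed=False)
        res = fit_paradigm(gp, dp, paradigm=3)
        assert res.params["c"] == pytest.approx(0.38, abs=1e-9)
        assert res.rss == pytest.approx(0.0, abs=1e-12)
        res2 = fit_paradigm(gp, dp, paradigm=2)
        assert res2.rss > res.rss + 1.0

    def test_amplitude_ratio_identifies_influx(self):
        m = _p3(j=2.5, p=1.0)
        ns = np.geomspace(1e5, 1e7, 25)
        res = fit_paradigm(_rate_points(m, ns, fed=True),
                           _rate_points(m, ns, fed=False), paradigm=3)
        ratio = math.exp(res.params["ln_amp_growth"]
                         - res.params["ln_amp_degrowth"])
        assert ratio == pytest.approx((m.j - m.p) / m.p, rel=1e-9)
        em = res.to_energy_model(p=1.0)
        assert em.j == pytest.approx(2.5, rel=1e-9)
        assert em.e_ref == pytest.approx(m.e_ref, rel=1e-9)

    def test_noisy_recovery(self, rng):
        m = _p3()
        ns = np.exp(rng.uniform(math.log(1e5), math.log(1e7), 100))
        sigma = math.sqrt(math.log(1 + 0.25 ** 2))
        gp, dp = [], []
        for i, n in enumerate(ns):
            noise = rng.lognormal(0, sigma, 2)
            gp.append(RatePoint(n, 100 * m.growth_rate(n, fed=True) * noise[0],
                                (0, 1), f"g{i}", "growth"))
            dp.append(RatePoint(n, 100 * m.growth_rate(n, fed=False) * noise[1],
                                (0, 1), f"d{i}", "degrowth",
                                history_weeks=1.0))
        res = fit_paradigm(gp, dp, paradigm=3)
        assert res.params["c"] == pytest.approx(0.38, abs=0.05)
        ratio = math.exp(res.params["ln_amp_growth"]
                         - res.params["ln_amp_degrowth"])
        assert ratio == pytest.approx((m.j - m.p) / m.p, rel=0.20)

    def test_comparison_ranks_generating_paradigm_first(self):
        m = _p3()
        ns = np.geomspace(1e5, 1e7, 30)
        ranked = compare_paradigms(_rate_points(m, ns, fed=True),
                                   _rate_points(m, ns, fed=False))
        assert ranked[0].paradigm == 3
        assert ranked[0].rss < min(r.rss for r in ranked[1:])

    def test_degenerate_single_size_rejected(self):
        m = _p3()
        ns = np.full(5, 1e6)
        with pytest.raises(EnergyModelError, match="degenerate"):
            ParadigmRateModel(_rate_points(m, ns, True),
                              _rate_points(m, ns, False))


class TestEnergyPrediction:
    def test_closed_form_magnitude(self):
        """1 %/day at all sizes, c = 0, p = 1 pW gives 8.64 uJ/cell."""
        law = PowerLawResults(0.0, math.log(1.0), 0.0, 0.0, 0.0, 3, "ols")
        e = predict_energy_per_cell(law, c=0.0, p=1.0)
        assert e.predict(1e6) == pytest.approx(8.64e-6, rel=1e-12)

    def test_linear_in_metabolic_rate(self):
        law = PowerLawResults(-0.38, 0.5, 0.01, 0.02, 0.0, 10, "ols")
        e1 = predict_energy_per_cell(law, p=1.0)
        e2 = predict_energy_per_cell(law, p=2.0)
        for n in (1e5, 1e7):
            assert e2.predict(n) == pytest.approx(2 * e1.predict(n))

    def test_recovers_generator_reserve_law(self, noiseless_cfg):
        """e(N) from noiseless simulated degrowth matches e_ref (N/N_ref)^c
        within 1%."""
        from planergy.synth import gen_traces
        from planergy.rates import Trace, windowed_rates, fit_rate_size_law

        cfg = noiseless_cfg
        df = gen_traces(cfg, 10, "degrowth")
        pts = []
        for tr in Trace.from_frame(df):
            pts += windowed_rates(tr, n_vs_area=cfg.n_vs_area())
        law = fit_rate_size_law(pts)
        e = predict_energy_per_cell(law, p=cfg.p_pw)
        ns = np.geomspace(2e5, 1e7, 20)
        truth = cfg.e_ref * (ns / cfg.n_ref) ** cfg.c
        assert np.max(np.abs(e.predict(ns) / truth - 1)) < 0.01

    def test_zero_rate_rejected(self):
        law = PowerLawResults(-0.38, 0.0, 0.0, 0.0, 0.0, 3, "ols")
        with pytest.raises(EnergyModelError):
            predict_energy_per_cell(law, c=-1.5)


class TestAssimilationRatio:
    def _law(self, b, a):
        return PowerLawResults(b, math.log(a), 0.0, 0.0, 0.0, 3, "ols")

    def test_exact_factor_two(self):
        meas = self._law(0.38, 2e-6)
        pred = self._law(0.38, 1e-6)
        out = assimilation_ratio(meas, pred, n_range=(1e5, 1e7))
        assert out["geometric_mean"] == pytest.approx(2.0)
        assert out["range"] == pytest.approx((2.0, 2.0))

    def test_offset_only(self):
        out = assimilation_ratio(self._law(0.38, 1.8e-6),
                                 self._law(0.38, 1e-6), n_range=(1e5, 1e7))
        assert out["geometric_mean"] == pytest.approx(1.8)

    def test_degenerate_range_rejected(self):
        with pytest.raises(EnergyModelError):
            assimilation_ratio(self._law(0.38, 1e-6), self._law(0.38, 1e-6),
                               n_range=(1e7, 1e5))
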