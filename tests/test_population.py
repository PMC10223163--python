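"""Population-simulation tests: sampling laws, residual error, reproducibility,
and convergence of population summaries to typical-subject values."""
import numpy as np
import pytest

import rivddi as rd
from rivddi import constants as C


class TestDrawIndividual:
    def test_zero_cv_returns_typical(self, human_control, rng):
        var = rd.VariabilityModel()
        assert rd.draw_individual(human_control, var, rng) is human_control

    def test_lognormal_sampling_law(self, human_control, rng):
        var = rd.VariabilityModel(iiv_cv_cl=49.0, iiv_cv_vc=47.0)
        draws = np.array([rd.draw_individual(human_control, var, rng).cl_f
                          for _ in range(100_000)])
        log_ratio = np.log(draws / human_control.cl_f)
        assert np.std(log_ratio) == pytest.approx(0.49, rel=0.01)
        # the log-normal median is the typical value
        assert np.median(draws) == pytest.approx(human_control.cl_f, rel=0.01)


class TestAddResidual:
    def test_zero_sigma_is_identity(self, human_control, rng):
        prof = rd.simulate_analytic(human_control, rd.DoseRegimen(dose=20.0),
                                    np.arange(0, 24.0001, 0.5))
        out = rd.add_residual(prof, rd.VariabilityModel(), rng)
        np.testing.assert_array_equal(out.conc, prof.conc)
        assert out.is_noisy

    def test_additive_sd_at_zero_concentration(self, rng):
        prof = rd.ConcentrationProfile(times=np.arange(100_000, dtype=float),
                                       conc=np.zeros(100_000))
        var = rd.VariabilityModel(sigma_add=13.6)
        out = rd.add_residual(prof, var, rng)
        # before flooring obs ~ N(0, 13.6); the floored sample retains the
        # half-normal relationship E[obs^2] = sigma^2 / 2
        assert np.sqrt(2.0 * np.mean(out.conc ** 2)) == pytest.approx(13.6, rel=0.02)
        assert out.meta["n_floored"] == pytest.approx(50_000, rel=0.02)

    def test_error_is_mean_zero(self, rng):
        c0 = 1000.0  # large enough that flooring never triggers
        prof = rd.ConcentrationProfile(times=np.arange(100_000, dtype=float),
                                       conc=np.full(100_000, c0))
        var = rd.VariabilityModel(sigma_add=13.6, sigma_prop=23.2)
        out = rd.add_residual(prof, var, rng)
        assert np.mean(out.conc) == pytest.approx(c0, rel=5e-3)

    def test_double_noise_rejected(self, rng):
        prof = rd.ConcentrationProfile(times=np.array([0.0]), conc=np.array([1.0]))
        noisy = rd.add_residual(prof, rd.VariabilityModel(sigma_add=1.0), rng)
        with pytest.raises(rd.InvalidInputError):
            rd.add_residual(noisy, rd.VariabilityModel(sigma_add=1.0), rng)


class TestSimulatePopulation:
    def test_single_subject_zero_iiv_equals_typical(self, human_control, human_test):
        var = rd.VariabilityModel()
        reg = rd.DoseRegimen(dose=20.0, tau=24.0)
        res = rd.simulate_population(human_control, human_test, var, reg, 1, 0)
        t = res.profiles[("control", "first")][0].times
        typical = rd.simulate_analytic(human_control, rd.DoseRegimen(dose=20.0), t)
        np.testing.assert_allclose(res.profiles[("control", "first")][0].conc,
                                   typical.conc, rtol=1e-12)

    def test_paired_zero_iiv_ss_auc_ratio_is_clearance_ratio(
            self, human_control, human_test):
        # at steady state AUC = Dose/CL, so the paired per-subject ratio is
        # exactly 1 / (1 + cl_cbz)
        var = rd.VariabilityModel()
        reg = rd.DoseRegimen(dose=20.0, tau=24.0)
        res = rd.simulate_population(human_control, human_test, var, reg, 2, 0)
        df = rd.subject_metrics(res)
        ratios = (df[df.arm == "test"].auc_ss.to_numpy()
                  / df[df.arm == "control"].auc_ss.to_numpy())
        np.testing.assert_allclose(ratios, 1.0 / 3.11, rtol=1e-3)

    def test_seeded_runs_bitwise_identical(self, human_control, human_test,
                                           variability):
        reg = rd.DoseRegimen(dose=20.0, tau=24.0)
        kw = dict(var=variability, regimen=reg, n=20, seed=77)
        a = rd.simulate_population(human_control, human_test, **kw)
        b = rd.simulate_population(human_control, human_test, **kw)
        for key in a.profiles:
            for pa, pb in zip(a.profiles[key], b.profiles[key]):
                np.testing.assert_array_equal(pa.conc, pb.conc)
        sa, sb = rd.summarize(a), rd.summarize(b)
        assert sa.table.equals(sb.table)
        assert sa.relative_changes == sb.relative_changes

    def test_stronger_induction_lowers_test_arm_auc(self, human_control,
                                                    variability):
        reg = rd.DoseRegimen(dose=20.0, tau=24.0)
        means = []
        for cl_cbz in (1.0, 2.11, 4.0):
            test = rd.apply_cbz(human_control, rd.CovariateEffects(cl_cbz=cl_cbz))
            res = rd.simulate_population(human_control, test, variability, reg,
                                         50, 3)
            s = rd.summarize(res)
            t = s.table
            means.append(float(t[(t.metric == "auc_first")
                                 & (t.arm == "test")]["mean"].iloc[0]))
        assert means[0] > means[1] > means[2]

    def test_population_mean_converges_to_typical_without_iiv(
            self, human_control, human_test):
        var = rd.VariabilityModel()
        reg = rd.DoseRegimen(dose=20.0, tau=24.0)
        res = rd.simulate_population(human_control, human_test, var, reg, 5, 0)
        s = rd.summarize(res)
        t = s.table
        row = t[(t.metric == "auc_first") & (t.arm == "control")].iloc[0]
        typical = rd.simulate_analytic(human_control, rd.DoseRegimen(dose=20.0),
                                       res.profiles[("control", "first")][0].times)
        assert row["mean"] == pytest.approx(rd.auc_trapezoid(typical, 0, 24),
                                            rel=1e-9)
        assert row["mean"] == row.p5 == row.p95


class TestSummarize:
    def test_percentile_ordering(self, human_control, human_test, variability):
        reg = rd.DoseRegimen(dose=20.0, tau=24.0)
        res = rd.simulate_population(human_control, human_test, variability,
                                     reg, 200, 5)
        s = rd.summarize(res)
        df = rd.subject_metrics(res)
        for metric in ("auc_first", "auc_ss", "cmax_first", "cmax_ss"):
            for arm in ("control", "test"):
                row = s.table[(s.table.metric == metric) & (s.table.arm == arm)].iloc[0]
                med = df[df.arm == arm][metric].median()
                assert row.p5 <= med <= row.p95

    def test_ss_mean_auc_matches_lognormal_expectation(self, human_control,
                                                       human_test, variability):
        # E[AUC_ss] = 1000 D / TVCL * exp(omega^2 / 2) for log-normal CL
        reg = rd.DoseRegimen(dose=20.0, tau=24.0)
        res = rd.simulate_population(human_control, human_test, variability,
                                     reg, 2000, 11)
        s = rd.summarize(res)
        row = s.table[(s.table.metric == "auc_ss")
                      & (s.table.arm == "control")].iloc[0]
        omega = 0.49
        expected = 1000.0 * 20.0 / human_control.cl_f * np.exp(omega ** 2 / 2.0)
        # Monte-Carlo tolerance: sd of AUC_ss/mean ~ sqrt(e^{w^2}-1) ~ 0.52
        assert row["mean"] == pytest.approx(expected, rel=0.04)

    def test_empty_result_rejected(self, human_control, human_test):
        res = rd.PopulationSimResult(profiles={("control", "first"): [],
                                               ("control", "ss"): [],
                                               ("test", "first"): [],
                                               ("test", "ss"): []},
                                     n=1, seed=0, pairing="paired",
                                     regimen=rd.DoseRegimen(dose=20.0))
        with pytest.raises((rd.InvalidInputError, IndexError, ValueError)):
            rd.summarize(res)
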