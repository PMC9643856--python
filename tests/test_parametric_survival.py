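"""Survival families: closed forms, medians, ML fitting, model selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from sclcea.parametric_survival import (
    FAMILIES,
    FitResult,
    FittingError,
    IpdRecord,
    SurvivalModel,
    apply_hazard_ratio,
    fit_all_families,
    fit_ipd,
    median_survival,
    read_ipd,
    select_best,
    survival_probability,
    write_ipd,
)
from sclcea.synthetic_data import SimulationSpec, simulate_ipd

LL_OS_ADCHM = SurvivalModel("loglogistic", scale=0.06284631, shape=1.924522)
LL_OS_PLCHM = SurvivalModel("loglogistic", scale=0.07650712, shape=2.665497)
LL_PFS_PLCHM = SurvivalModel("loglogistic", scale=0.1767604, shape=3.377706)


class TestSurvivalProbability:
    def test_survival_starts_at_one(self):
        m = SurvivalModel("loglogistic", scale=0.1, shape=2.5)
        assert survival_probability(m, 0.0) == 1.0

    def test_loglogistic_median_at_reciprocal_scale_for_any_shape(self):
        for gam in (0.7, 1.0, 2.5, 6.0):
            m = SurvivalModel("loglogistic", scale=0.2, shape=gam)
            assert survival_probability(m, 1.0 / 0.2) == pytest.approx(0.5)

    def test_loglogistic_closed_form_value(self):
        # oracle: direct arithmetic (1 + (0.06284631*12)**1.924522)**-1
        assert survival_probability(LL_OS_ADCHM, 12.0) == pytest.approx(
            0.6325137863520996, rel=1e-12
        )

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            survival_probability(LL_OS_ADCHM, -0.1)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SurvivalModel("loglogistic", scale=-1.0, shape=2.0)
        with pytest.raises(ValueError):
            SurvivalModel("weibull", scale=0.1, shape=0.0)
        with pytest.raises(ValueError):
            SurvivalModel("nonsense", scale=0.1, shape=1.0)

    @hsettings(max_examples=50, derandomize=True)
    @given(
        family=st.sampled_from(FAMILIES),
        scale=st.floats(0.01, 2.0),
        shape=st.floats(0.3, 6.0),
        t=st.lists(st.floats(0.01, 100.0), min_size=2, max_size=10, unique=True),
    )
    def test_strictly_decreasing_and_in_unit_interval(self, family, scale, shape, t):
        m = SurvivalModel(family, scale=scale, shape=None if family == "exponential" else shape)
        grid = np.sort(np.asarray(t))
        s = survival_probability(m, grid)
        assert np.all(s >= 0) and np.all(s <= 1)
        assert np.all(np.diff(s) <= 0)
        # strict decrease wherever the floats have not underflowed
        alive = s > 1e-12
        assert np.all(np.diff(s[alive]) < 0)
        assert survival_probability(m, 0.0) == 1.0


class TestMedianSurvival:
    @pytest.mark.parametrize(
        "model, expected",
        [
            (LL_OS_ADCHM, 15.911833168884536),  # 1/lambda; printed trial median 15.3
            (LL_OS_PLCHM, 13.070678911975774),  # 1/lambda; printed trial median 12.8
            (SurvivalModel("exponential", scale=math.log(2.0)), 1.0),
        ],
    )
    def test_closed_form_median(self, model, expected):
        assert median_survival(model) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_median_inverts_survival(self, family):
        m = SurvivalModel(family, scale=0.13, shape=None if family == "exponential" else 1.7)
        assert survival_probability(m, median_survival(m)) == pytest.approx(0.5, abs=1e-9)


class TestFitting:
    def test_exponential_mle_matches_closed_form(self):
        # lambda_hat = events / total observed time, exact for no censoring
        times = [0.5, 1.2, 2.0, 2.5, 3.3, 4.1, 5.0, 6.2, 7.7, 9.0]
        data = [IpdRecord(t, True) for t in times]
        fit = fit_ipd(data, "exponential")
        assert fit.model.scale == pytest.approx(len(times) / sum(times), rel=1e-6)

    def test_information_criteria_identities(self):
        data = [IpdRecord(t, True) for t in np.linspace(0.5, 20, 40)]
        for fam in FAMILIES:
            f = fit_ipd(data, fam)
            assert f.aic == pytest.approx(2 * f.k_params - 2 * f.loglik)
            assert f.bic == pytest.approx(f.k_params * math.log(f.n) - 2 * f.loglik)

    def test_loglogistic_parameter_recovery_with_censoring(self):
        spec = SimulationSpec(
            model=SurvivalModel("loglogistic", scale=0.15, shape=2.0),
            n=500, censor_time_months=12.0, seed=42,
        )
        ipd = simulate_ipd(spec)
        assert 0.05 < np.mean([not r.event for r in ipd]) < 0.45
        fit = fit_ipd(ipd, "loglogistic")
        assert fit.model.scale == pytest.approx(0.15, rel=0.10)
        assert fit.model.shape == pytest.approx(2.0, rel=0.10)

    def test_model_selection_recovers_loglogistic_majority(self):
        truth = SurvivalModel("loglogistic", scale=0.15, shape=2.0)
        wins = 0
        reps = 10
        for rep in range(reps):
            ipd = simulate_ipd(SimulationSpec(model=truth, n=300,
                                              censor_time_months=18.0, seed=100 + rep))
            best = select_best(fit_all_families(ipd))
            wins += best.model.family == "loglogistic"
        assert wins > reps / 2

    def test_no_events_is_an_error(self):
        data = [IpdRecord(1.0, False)] * 10
        with pytest.raises(FittingError):
            fit_ipd(data, "weibull")


class TestSelectBest:
    def _fit(self, family, aic, bic):
        m = SurvivalModel(family, scale=0.1, shape=None if family == "exponential" else 1.0)
        return FitResult(model=m, loglik=0.0, aic=aic, bic=bic, n=10, k_params=2)

    def test_single_fit_returned(self):
        f = self._fit("weibull", 100, 105)
        assert select_best([f]) is f

    def test_min_aic_wins(self):
        a, b = self._fit("weibull", 100, 120), self._fit("lognormal", 101, 90)
        assert select_best([a, b]) is a

    def test_aic_tie_broken_by_bic_then_family_order(self):
        a, b = self._fit("lognormal", 100, 95), self._fit("weibull", 100, 90)
        assert select_best([a, b]) is b
        c, d = self._fit("loglogistic", 100, 95), self._fit("weibull", 100, 95)
        assert select_best([c, d]) is d  # weibull listed before loglogistic

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_best([])


class TestHazardRatio:
    def test_identity_at_hr_one(self):
        adj = apply_hazard_ratio(LL_OS_ADCHM, 1.0)
        t = np.linspace(0, 60, 25)
        np.testing.assert_allclose(adj(t), LL_OS_ADCHM(t))

    def test_square_root_at_hr_half(self):
        base = lambda t: np.full_like(np.asarray(t, dtype=float), 0.81)
        assert apply_hazard_ratio(base, 0.5)(1.0) == pytest.approx(0.9)

    def test_composition_with_plchm_pfs(self):
        # oracle: ((1+(0.1767604*6)**3.377706)**-1)**0.44 computed directly
        adj = apply_hazard_ratio(LL_PFS_PLCHM, 0.44)
        assert float(adj(6.0)) == pytest.approx(0.7040934638817147, rel=1e-12)

    @pytest.mark.parametrize("hr", [0.3, 0.9, 1.5, 4.0])
    def test_direction_of_adjustment(self, hr):
        t = np.linspace(0.5, 48, 30)
        base = LL_OS_PLCHM(t)
        adj = apply_hazard_ratio(LL_OS_PLCHM, hr)(t)
        if hr < 1:
            assert np.all(adj >= base)
        else:
            assert np.all(adj <= base)

    def test_nonpositive_hr_rejected(self):
        with pytest.raises(ValueError):
            apply_hazard_ratio(LL_OS_ADCHM, 0.0)


def test_ipd_roundtrip_io(tmp_path):
    records = [IpdRecord(1.25, True), IpdRecord(3.5, False), IpdRecord(0.0, False)]
    path = tmp_path / "ipd.csv"
    write_ipd(records, path)
    assert read_ipd(path) == records
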