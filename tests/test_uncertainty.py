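"""Sensitivity analyses: sampling, tornado, PSA, CEAC, price threshold."""

import numpy as np
import pytest

from sclcea.uncertainty import (
    ParamSpec,
    acceptance_probability,
    adjusted_delta_cost,
    build_param_specs,
    ceac,
    one_way_sensitivity,
    price_threshold,
    run_psa,
    sample_parameters,
)
from sclcea.workflow import override, run_base_case

PSA_N = 200  # structural checks need a cloud, not the full production run


@pytest.fixture(scope="module")
def psa(cfg):
    return run_psa(cfg, n=PSA_N, seed=7)


class TestParamSpecs:
    def test_all_table_parameters_collected(self, cfg):
        specs = build_param_specs(cfg)
        names = {s.name for s in specs}
        assert len(specs) > 30
        assert "utilities.pd" in names
        assert "survival.plchm.pfs.scale" in names
        assert "drugs.adebrelimab.price" in names
        assert any(n.startswith("adverse_events.adchm.0") for n in names)

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            ParamSpec("x", base=1.0, low=2.0, high=3.0, distribution="gamma")


class TestSampling:
    def test_fixed_parameter_never_varies(self, cfg):
        specs = build_param_specs(cfg)
        rng = np.random.default_rng(0)
        for _ in range(5):
            draw = sample_parameters(specs, rng)
            assert draw["settings.annual_discount_rate"] == 0.05

    def test_degenerate_beta_concentrates_at_base(self):
        spec = ParamSpec("u", base=0.5, low=0.4999, high=0.5001, distribution="beta")
        rng = np.random.default_rng(1)
        draws = [sample_parameters([spec], rng)["u"] for _ in range(200)]
        assert np.std(draws) < 1e-3

    def test_seeded_sequence_is_reproducible(self, cfg):
        specs = build_param_specs(cfg)
        d1 = sample_parameters(specs, np.random.default_rng(99))
        d2 = sample_parameters(specs, np.random.default_rng(99))
        assert d1 == d2

    def test_draws_respect_supports(self, cfg):
        specs = build_param_specs(cfg)
        rng = np.random.default_rng(5)
        for _ in range(50):
            draw = sample_parameters(specs, rng)
            for s in specs:
                if s.distribution == "beta":
                    assert 0.0 <= draw[s.name] <= 1.0
                if s.distribution in ("gamma", "survival_param"):
                    assert draw[s.name] > 0.0


class TestTornado:
    def test_table_matches_direct_engine_runs(self, cfg):
        specs = [s for s in build_param_specs(cfg) if s.name == "utilities.pd"]
        table = one_way_sensitivity(cfg, specs)
        row = table.iloc[0]
        lo = run_base_case(override(cfg, ("utilities", "pd"), specs[0].low))["icer"]
        hi = run_base_case(override(cfg, ("utilities", "pd"), specs[0].high))["icer"]
        assert row["low_icer"] == pytest.approx(lo.icer_per_qaly)
        assert row["high_icer"] == pytest.approx(hi.icer_per_qaly)
        assert row["width"] > 0

    def test_inert_parameter_has_zero_width(self, cfg):
        # an AE cost attached to a zero-incidence event cannot move the ICER
        import copy

        c = copy.deepcopy(cfg)
        for arm in ("adchm", "plchm"):
            c["adverse_events"][arm][0]["incidence"] = {
                "base": 0.0, "low": 0.0, "high": 0.0, "distribution": "fixed"}
        specs = [s for s in build_param_specs(c)
                 if s.name == "adverse_events.adchm.0.cost"]
        table = one_way_sensitivity(c, specs)
        assert table.iloc[0]["width"] == pytest.approx(0.0, abs=1e-9)

    def test_discount_rate_bounds_bracket_finite_icers(self, cfg):
        specs = [s for s in build_param_specs(cfg)
                 if s.name == "settings.annual_discount_rate"]
        table = one_way_sensitivity(cfg, specs)
        row = table.iloc[0]
        assert np.isfinite(row["low_icer"]) and np.isfinite(row["high_icer"])
        base = run_base_case(cfg)["icer"].icer_per_qaly
        assert min(row["low_icer"], row["high_icer"]) <= base <= max(
            row["low_icer"], row["high_icer"])


class TestPsa:
    def test_all_fixed_specs_reproduce_base_case(self, cfg):
        import copy

        frozen = copy.deepcopy(cfg)

        def freeze(node):
            if isinstance(node, dict):
                if "distribution" in node:
                    node["distribution"] = "fixed"
                for v in node.values():
                    freeze(v)
            elif isinstance(node, list):
                for v in node:
                    freeze(v)

        freeze(frozen)
        psa1 = run_psa(frozen, n=1, seed=0)
        base = run_base_case(cfg)["icer"]
        assert psa1.delta_cost[0] == pytest.approx(base.delta_cost, rel=1e-9)
        assert psa1.delta_qaly[0] == pytest.approx(base.delta_qaly, rel=1e-9)

    def test_same_seed_gives_identical_cloud(self, cfg):
        a = run_psa(cfg, n=20, seed=123)
        b = run_psa(cfg, n=20, seed=123)
        np.testing.assert_array_equal(a.delta_cost, b.delta_cost)
        np.testing.assert_array_equal(a.delta_qaly, b.delta_qaly)

    def test_price_adjustment_matches_full_rerun(self, cfg):
        # the analytic price rescaling must agree with rerunning the PSA
        # on a configuration whose price (base and range) is scaled
        import copy

        scaled = copy.deepcopy(cfg)
        for key in ("base", "low", "high"):
            scaled["drugs"]["adebrelimab"]["price"][key] *= 1.5
        a = run_psa(cfg, n=50, seed=11)
        b = run_psa(scaled, n=50, seed=11)
        np.testing.assert_allclose(adjusted_delta_cost(a, 1.5), b.delta_cost, rtol=1e-9)

    def test_invalid_iteration_count(self, cfg):
        with pytest.raises(ValueError):
            run_psa(cfg, n=0)


class TestCeacAndThreshold:
    def test_wtp_zero_counts_cost_saving_draws(self, psa):
        assert acceptance_probability(psa, 0.0) == np.mean(psa.delta_cost <= 0.0)

    def test_all_dominant_cloud_accepts_everywhere(self):
        from sclcea.uncertainty import PsaResult

        cloud = PsaResult(delta_cost=np.full(10, -1.0), delta_qaly=np.full(10, 0.1),
                          n=10, seed=0)
        curve = ceac(cloud, [0, 10_000, 50_000])
        assert (curve["probability"] == 1.0).all()

    def test_ceac_monotone_when_all_draws_gain_qalys(self, psa):
        grid = np.linspace(0, 150_000, 40)
        curve = ceac(psa, grid)
        if np.all(psa.delta_qaly > 0):
            assert np.all(np.diff(curve["probability"]) >= 0)

    def test_acceptance_monotone_in_price(self, psa):
        probs = [acceptance_probability(psa, 37653.0, m) for m in (0.5, 1.0, 2.0, 4.0, 8.0)]
        assert all(a >= b for a, b in zip(probs, probs[1:]))

    def test_threshold_crosses_target(self, cfg, psa):
        res = price_threshold(cfg, target_prob=0.5, psa=psa)
        assert res["multiplier"] > 1.0
        above = acceptance_probability(psa, res["wtp"], res["multiplier"] * 1.05)
        below = acceptance_probability(psa, res["wtp"], res["multiplier"] * 0.95)
        assert above <= 0.5 <= below

    def test_unbracketed_target_raises(self, cfg, psa):
        # a low target needs a price rise beyond the allowed search interval
        with pytest.raises(RuntimeError):
            price_threshold(cfg, target_prob=0.2, max_multiplier=1.05, psa=psa)
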