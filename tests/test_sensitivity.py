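"""Tornado one-way analysis, distribution fitting, PSA and CEAC."""

import numpy as np
import pandas as pd
import pytest

from hepacea import (
    ConfigError,
    CostUtilityModel,
    ParameterError,
    ParameterRange,
    StrategyDefinition,
    WTPSpec,
    ceac,
    fit_all,
    fit_distribution,
    one_way,
    probability_cost_effective,
    run_psa,
    tornado,
)


def constant_specs(ranges):
    return {
        pid: fit_distribution(ParameterRange(base=r.base, low=r.base, high=r.base))
        for pid, r in ranges.items()
    }


class TestFitDistribution:
    def test_symmetric_bounds_give_symmetric_beta(self):
        spec = fit_distribution(ParameterRange(base=0.5, low=0.35, high=0.65, family="beta"))
        assert spec.family == "beta"
        assert spec.dist.kwds["a"] == pytest.approx(spec.dist.kwds["b"])
        assert spec.dist.mean() == pytest.approx(0.5)

    def test_beta_recovers_mean_and_sd_on_large_sample(self, fixture):
        rng_spec = fixture.ranges["proton.u_stable"]  # 0.399, 0.279-0.519
        spec = fit_distribution(rng_spec)
        draws = spec.sample(np.random.default_rng(0), 100_000)
        se = spec.sd / np.sqrt(draws.size)
        assert abs(draws.mean() - 0.399) < 3 * se
        assert abs(draws.mean() - rng_spec.base) / rng_spec.base < 0.01
        assert np.all((draws > 0) & (draws < 1))

    def test_asymmetric_printed_range_still_centred_on_base(self, fixture):
        # the anomalous progressive-state utility bound (0.476) widens the
        # spread but moment matching keeps the mean at the base value
        spec = fit_distribution(fixture.ranges["proton.u_prog"])
        assert spec.mean == pytest.approx(0.28)
        draws = spec.sample(np.random.default_rng(1), 100_000)
        assert abs(draws.mean() - 0.28) < 3 * spec.sd / np.sqrt(draws.size)

    def test_lognormal_recovers_mean_and_sd(self, fixture):
        rng_spec = fixture.ranges["proton.c_stable"]  # 291,000
        spec = fit_distribution(rng_spec)
        assert spec.family == "lognormal"
        assert spec.dist.mean() == pytest.approx(291_000, rel=1e-9)
        assert spec.dist.std() == pytest.approx((378_300 - 203_700) / 3.92, rel=1e-9)
        draws = spec.sample(np.random.default_rng(2), 100_000)
        assert abs(draws.mean() - 291_000) < 3 * spec.sd / np.sqrt(draws.size)
        assert np.all(draws > 0)

    def test_zero_width_range_degenerates_to_point_mass(self):
        spec = fit_distribution(ParameterRange(base=291_000, low=291_000, high=291_000))
        assert spec.family == "constant"
        assert np.all(spec.sample(np.random.default_rng(0), 5) == 291_000)

    def test_beta_outside_unit_interval_rejected(self):
        with pytest.raises(ParameterError):
            fit_distribution(ParameterRange(base=0.0, low=0.0, high=0.5, family="beta"))

    def test_uniform_rule_samples_the_bounds_interval(self):
        rng_spec = ParameterRange(base=0.4, low=0.2, high=0.8, family="beta")
        spec = fit_distribution(rng_spec, rule="uniform")
        assert spec.mean == pytest.approx(0.5)
        draws = spec.sample(np.random.default_rng(3), 10_000)
        assert draws.min() >= 0.2 and draws.max() <= 0.8


class TestTornado:
    def test_zero_width_range_has_zero_spread(self, model):
        flat = ParameterRange(base=0.399, low=0.399, high=0.399, family="constant")
        entry = one_way(model, "proton.u_stable", flat)
        assert entry.spread == 0.0

    def test_one_way_equals_two_run_brute_force(self, model, fixture):
        for pid in ("proton.u_prog", "sbrt.c_prog", "sbrt.p_stable_to_dead"):
            rng_spec = fixture.ranges[pid]
            entry = one_way(model, pid, rng_spec)
            for bound, got in ((rng_spec.low, entry.outcome_low), (rng_spec.high, entry.outcome_high)):
                pinned = model.with_overrides({pid: bound}).base_case()
                assert got == pytest.approx(pinned.nmb_at_threshold, rel=1e-9)

    def test_unknown_parameter_rejected(self, model, fixture):
        with pytest.raises(ConfigError):
            one_way(model, "proton.nonexistent", fixture.ranges["proton.u_prog"])
        with pytest.raises(ConfigError):
            one_way(model, "photon.u_prog", fixture.ranges["proton.u_prog"])

    def test_report_sorted_normalised_and_complete(self, model, fixture):
        report = tornado(model, fixture.ranges)
        assert len(report) == 14
        assert report["risk_pct"].sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(report["spread"]) <= 1e-12)
        assert report["cumul_pct"].iloc[-1] == pytest.approx(1.0, abs=1e-9)

    def test_permutation_invariance(self, model, fixture):
        reordered = dict(reversed(list(fixture.ranges.items())))
        a = tornado(model, fixture.ranges)
        b = tornado(model, reordered)
        pd.testing.assert_frame_equal(a, b)

    def test_single_parameter_takes_the_whole_risk_share(self, model, fixture):
        report = tornado(model, {"proton.u_prog": fixture.ranges["proton.u_prog"]})
        assert len(report) == 1
        assert report["risk_pct"].iloc[0] == pytest.approx(1.0)

    def test_progressive_state_utility_among_most_influential(self, model, fixture):
        report = tornado(model, fixture.ranges)
        assert "proton.u_prog" in set(report["parameter"].head(3))

    def test_icer_outcome_selectable(self, model, fixture):
        report = tornado(model, fixture.ranges, outcome="icer")
        assert len(report) == 14
        assert (report["spread"] >= 0).all()


class TestPSA:
    def test_same_seed_is_bit_identical(self, model, fixture):
        specs = fit_all(fixture.ranges)
        a = run_psa(model, specs, n=50, seed=11)
        b = run_psa(model, specs, n=50, seed=11)
        pd.testing.assert_frame_equal(a.samples, b.samples)
        assert np.array_equal(a.cost_alt, b.cost_alt)
        assert np.array_equal(a.effect_ref, b.effect_ref)
        c = run_psa(model, specs, n=50, seed=12)
        assert not a.samples.equals(c.samples)

    def test_degenerate_distributions_collapse_to_base_case(self, model, fixture):
        psa = run_psa(model, constant_specs(fixture.ranges), n=8, seed=0)
        base = model.base_case()
        assert np.all(psa.cost_ref == base.reference.cost)
        assert np.all(psa.effect_ref == base.reference.effect)
        assert np.all(psa.cost_alt == base.alternative.cost)
        assert np.all(psa.effect_alt == base.alternative.effect)

    def test_sample_means_match_spec_means(self, model, fixture):
        specs = fit_all(fixture.ranges)
        psa = run_psa(model, specs, n=2000, seed=5)
        for pid, spec in specs.items():
            se = spec.sd / np.sqrt(psa.n_samples)
            assert abs(psa.samples[pid].mean() - spec.mean) < 3 * se, pid

    def test_stable_row_rejection_resamples_jointly_with_warning(self):
        risky = StrategyDefinition(
            name="risky", p_stable_to_prog=0.55, p_stable_to_dead=0.40,
            p_prog_to_dead=0.2, u_stable=0.5, u_prog=0.3, c_stable=1000, c_prog=100,
        )
        other = StrategyDefinition(
            name="other", p_stable_to_prog=0.1, p_stable_to_dead=0.1,
            p_prog_to_dead=0.1, u_stable=0.5, u_prog=0.3, c_stable=1000, c_prog=100,
        )
        model = CostUtilityModel(other, risky, WTPSpec(gdp_per_capita=719_008))
        specs = fit_all(
            {
                "risky.p_stable_to_prog": ParameterRange(
                    base=0.55, low=0.385, high=0.715, family="beta"
                ),
                "risky.p_stable_to_dead": ParameterRange(
                    base=0.40, low=0.28, high=0.52, family="beta"
                ),
            }
        )
        with pytest.warns(UserWarning, match="rejected"):
            psa = run_psa(model, specs, n=400, seed=1)
        assert psa.rejections > 0
        sums = psa.samples["risky.p_stable_to_prog"] + psa.samples["risky.p_stable_to_dead"]
        assert (sums <= 1.0).all()


class TestCEAC:
    def test_probabilities_complementary_and_bounded(self, model, fixture):
        psa = run_psa(model, fit_all(fixture.ranges), n=200, seed=2)
        grid = np.linspace(0, fixture.wtp.threshold, 11)
        curve = ceac(psa, grid)
        p_ref, p_alt = curve["p_sbrt"], curve["p_proton"]
        assert np.allclose(p_ref + p_alt, 1.0)
        assert ((p_alt >= 0) & (p_alt <= 1)).all()

    def test_degenerate_psa_steps_exactly_at_the_icer(self, model, fixture):
        psa = run_psa(model, constant_specs(fixture.ranges), n=4, seed=0)
        icer = model.base_case().comparison.icer
        curve = ceac(psa, np.array([0.0, icer * 0.99, icer * 1.01, 2 * icer]))
        assert curve["p_proton"].tolist() == [0.0, 0.0, 1.0, 1.0]
        assert np.all(np.diff(curve["p_proton"]) >= 0)  # monotone for a degenerate comparison

    def test_at_zero_wtp_probability_is_being_cheaper(self, model, fixture):
        psa = run_psa(model, fit_all(fixture.ranges), n=200, seed=9)
        curve = ceac(psa, np.array([0.0]))
        cheaper = (psa.delta_cost < 0).mean() + 0.5 * (psa.delta_cost == 0).mean()
        assert curve["p_proton"].iloc[0] == pytest.approx(cheaper)

    def test_probability_cost_effective_matches_curve(self, model, fixture):
        psa = run_psa(model, fit_all(fixture.ranges), n=100, seed=4)
        wtp = fixture.wtp.threshold
        assert probability_cost_effective(psa, wtp) == pytest.approx(
            ceac(psa, np.array([wtp]))["p_proton"].iloc[0]
        )

    def test_mean_incremental_nmb_is_affine_in_lambda(self, model, fixture):
        psa = run_psa(model, fit_all(fixture.ranges), n=100, seed=4)
        grid = np.linspace(0, 2e6, 5)
        curve = ceac(psa, grid)
        expected = psa.delta_effect.mean() * grid - psa.delta_cost.mean()
        assert curve["mean_incremental_nmb"].to_numpy() == pytest.approx(expected)
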