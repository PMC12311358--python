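"""Counterfactual means, decomposition, proportion mediated and bootstrap."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from sesmediate import mediation, prep, simulate, weights as wmod
from sesmediate.errors import EstimationError, InvalidRunError
from sesmediate.mediation import CounterfactualMeans


class TestCounterfactualMeans:
    def test_enumerated_population_matches_exhaustive_g_computation(self, toy):
        df, truth = toy
        ws = wmod.stabilized_weights(df, "x", ["c"])
        means = mediation.estimate_counterfactual_means(
            df, ws, "x", mediators=["m"], confounders=["c"],
            interaction_terms=["x:m"],
        )
        assert means.m_xx == pytest.approx(truth["m_xx"], abs=1e-8)
        assert means.m_ss == pytest.approx(truth["m_ss"], abs=1e-8)
        assert means.m_xs == pytest.approx(truth["m_xs"], abs=1e-8)

    def test_null_outcome_equalizes_means(self):
        cfg = simulate.null_config(n=30_000, seed=4)
        raw = simulate.generate_cohort(cfg)
        pt = mediation.counterfactual_point(raw)
        assert pt["m_xx"] == pytest.approx(pt["m_ss"], abs=0.02)
        assert pt["m_xs"] == pytest.approx(pt["m_xx"], abs=0.02)

    def test_cross_world_equals_factual_without_exposure_mediator_path(self):
        cfg = replace(simulate.unmediated_config(), n=50_000, seed=6, exclusion_probs={})
        raw = simulate.generate_cohort(cfg)
        pt = mediation.counterfactual_point(raw)
        assert abs(np.log(pt["nie"])) < 0.02  # m_xs == m_xx up to MC error

    def test_empty_unexposed_stratum_errors(self, toy):
        df, _ = toy
        ws = wmod.stabilized_weights(df, "x", ["c"])
        exposed_only = df[df.x == 1].reset_index(drop=True)
        with pytest.raises(EstimationError):
            mediation.estimate_counterfactual_means(
                exposed_only, wmod.WeightSet(
                    w=np.ones(len(exposed_only)), propensity=np.full(len(exposed_only), 0.5),
                    p_marginal=1.0, exposure="x", confounders=("c",),
                ), "x", mediators=["m"], confounders=["c"],
            )


class TestDecompose:
    def test_ratio_arithmetic(self):
        te, nde, nie = mediation.decompose(CounterfactualMeans(0.25, 0.10, 0.20))
        assert (te, nde, nie) == pytest.approx((2.5, 2.0, 1.25))
        assert te == pytest.approx(nde * nie, abs=1e-15)

    def test_null_direct_and_null_indirect_edges(self):
        _, nde, _ = mediation.decompose(CounterfactualMeans(0.25, 0.10, 0.10))
        assert nde == pytest.approx(1.0)
        _, _, nie = mediation.decompose(CounterfactualMeans(0.20, 0.10, 0.20))
        assert nie == pytest.approx(1.0)

    def test_zero_mean_errors(self):
        with pytest.raises(EstimationError):
            mediation.decompose(CounterfactualMeans(0.25, 0.0, 0.20))


class TestProportionMediated:
    @pytest.mark.parametrize("nie,te,expect", [
        (1.31, 1.31, 1.0),       # fully mediated
        (1.0, 1.31, 0.0),        # nothing mediated
        (1.17, 1.31, np.log(1.17) / np.log(1.31)),
    ])
    def test_log_scale_division(self, nie, te, expect):
        assert mediation.proportion_mediated(nie, te) == pytest.approx(expect)

    def test_published_style_estimate_within_rounding_tolerance(self):
        # From 2-decimal rounded inputs the log-scale share is 58.1%; the
        # unrounded-estimate value is 59.93%, within input-rounding slack.
        pm = 100 * mediation.proportion_mediated(1.17, 1.31)
        assert pm == pytest.approx(58.14, abs=0.05)
        assert abs(pm - 59.93) < 3.0

    def test_null_total_effect_gives_nan_not_crash(self):
        assert np.isnan(mediation.proportion_mediated(1.0, 1.0))

    def test_excess_relative_risk_scale(self):
        pm = mediation.proportion_mediated(1.25, 2.5, nde_rr=2.0, scale="rr_minus_one")
        assert pm == pytest.approx(2.0 * 0.25 / 1.5)


class TestBootstrap:
    def test_same_seed_reproduces_intervals(self, kept_cohort):
        sub = kept_cohort.iloc[:1500]
        kw = dict(B=20, seed=5)
        a = mediation.bootstrap_decomposition(sub, mediation.counterfactual_point, **kw)
        b = mediation.bootstrap_decomposition(sub, mediation.counterfactual_point, **kw)
        pd.testing.assert_frame_equal(a.replicates, b.replicates)
        assert a.percentile_ci("te") == b.percentile_ci("te")

    def test_constant_estimator_gives_zero_width_interval(self, kept_cohort):
        boot = mediation.bootstrap_decomposition(
            kept_cohort.iloc[:200], lambda df: {"est": 1.5}, B=30, seed=0
        )
        assert boot.percentile_ci("est") == (1.5, 1.5)

    def test_identity_holds_in_every_replicate(self, kept_cohort):
        boot = mediation.bootstrap_decomposition(
            kept_cohort.iloc[:2000], mediation.counterfactual_point, B=25, seed=3
        )
        reps = boot.replicates
        assert np.max(np.abs(reps["te"] - reps["nde"] * reps["nie"])) < 1e-12

    def test_excess_failures_invalidate_run(self, kept_cohort):
        def failing(df):
            raise EstimationError("always")
        with pytest.raises(InvalidRunError):
            mediation.bootstrap_decomposition(kept_cohort.iloc[:100], failing, B=10, seed=0)

    def test_decomposition_with_ci_bounds_bracket_points(self, kept_cohort):
        d = mediation.decomposition_with_ci(
            kept_cohort.iloc[:3000], method="counterfactual", B=40, seed=2
        )
        for point, ci in [(d.te_rr, d.te_ci), (d.nde_rr, d.nde_ci), (d.nie_rr, d.nie_ci)]:
            assert ci[0] <= ci[1]
        row = d.to_dict()
        assert row["te_lo"] <= row["te_hi"]
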