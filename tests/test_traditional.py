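"""Difference and product-of-coefficients methods and the adjusted models."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from sesmediate import mediation, prep, simulate, traditional


class TestDifferenceMethod:
    def test_enumerated_population_matches_closed_form(self, toy):
        df, truth = toy
        res = traditional.difference_fit(df, "x", mediators=["m"], confounders=["c"])
        assert res["alpha_x"] == pytest.approx(truth["alpha_x"], abs=1e-8)
        assert res["beta_x"] == pytest.approx(truth["beta_x"], abs=1e-8)

    def test_unmediated_generator_gives_null_indirect(self):
        cfg = replace(simulate.unmediated_config(), n=50_000, seed=8, exclusion_probs={})
        raw = simulate.generate_cohort(cfg)
        res = traditional.difference_point(raw)
        assert abs(np.log(res["nie"])) < 0.02

    def test_null_exposure_gives_unit_ratios(self):
        raw = simulate.generate_cohort(simulate.null_config(n=40_000, seed=2))
        res = traditional.difference_point(raw)
        for k in ("te", "nde", "nie"):
            assert abs(np.log(res[k])) < 0.05


class TestProductMethod:
    def test_mediator_additivity_is_exact(self, kept_cohort):
        adf = prep.dichotomize(kept_cohort, prep.alcohol_cutoffs(kept_cohort))
        res = traditional.product_fit(adf, "x_edu")
        parts = sum(v["indirect"] for v in res["per_mediator"].values())
        assert res["indirect_sum"] == pytest.approx(parts, abs=1e-15)
        assert res["te"] == pytest.approx(res["nde"] * res["nie"], abs=1e-12)

    def test_outcome_independent_of_mediators(self):
        # mediators vary with exposure but carry no outcome effect
        base = simulate._base_uncalibrated()
        om = replace(base.outcome_model,
                     coef={**base.outcome_model.coef,
                           **{m: 0.0 for m in simulate.MEDIATORS}})
        cfg = replace(simulate.calibrate_config(replace(base, outcome_model=om)),
                      n=50_000, seed=3, exclusion_probs={})
        raw = simulate.generate_cohort(cfg)
        res = traditional.product_point(raw)
        assert abs(np.log(res["nie"])) < 0.02
        assert res["te"] == pytest.approx(res["nde"], rel=0.02)

    def test_linear_gaussian_equivalence_with_difference_method(self):
        """Identity links everywhere: product == difference, classically."""
        rng = np.random.default_rng(0)
        n = 4000
        df = pd.DataFrame({"x": rng.integers(0, 2, n).astype(float),
                           "c": rng.normal(size=n)})
        df["m1"] = 0.5 * df.x + 0.3 * df.c + rng.normal(size=n)
        df["m2"] = -0.4 * df.x + 0.1 * df.c + rng.normal(size=n)
        df["y"] = 1.0 + 0.7 * df.x + 0.6 * df.m1 + 0.8 * df.m2 + 0.2 * df.c + rng.normal(size=n)
        diff = traditional.difference_fit(df, "x", mediators=["m1", "m2"],
                                          confounders=["c"], family="gaussian")
        prod = traditional.product_fit(df, "x", mediators=["m1", "m2"],
                                       confounders=["c"], family="gaussian",
                                       mediator_family="gaussian")
        assert prod["indirect_sum"] == pytest.approx(diff["indirect_sum"], abs=1e-10)
        assert prod["alpha_equiv"] == pytest.approx(diff["alpha_x"], abs=1e-10)

    def test_two_mediator_hand_product(self):
        """Total indirect equals the hand sum of gamma_i * mu_i."""
        rng = np.random.default_rng(4)
        n = 3000
        df = pd.DataFrame({"x": rng.integers(0, 2, n).astype(float),
                           "c": rng.normal(size=n)})
        df["m1"] = 1.0 * df.x + rng.normal(size=n)
        df["m2"] = -0.5 * df.x + rng.normal(size=n)
        df["y"] = 2.0 + 0.3 * df.x + 0.4 * df.m1 + 0.6 * df.m2 + rng.normal(size=n)
        res = traditional.product_fit(df, "x", mediators=["m1", "m2"],
                                      confounders=["c"], family="gaussian",
                                      mediator_family="gaussian")
        hand = sum(res["per_mediator"][m]["gamma_x"] * res["per_mediator"][m]["mu"]
                   for m in ("m1", "m2"))
        assert res["indirect_sum"] == pytest.approx(hand, abs=1e-12)


class TestAdjustedAssociationModels:
    def test_null_exposure_rrs_near_one(self):
        raw = simulate.generate_cohort(simulate.null_config(n=40_000, seed=5))
        t = traditional.adjusted_association_models(raw, strata=("all",))
        assert np.allclose(np.log(t["rr"]), 0.0, atol=0.06)

    def test_confounding_attenuates_from_model_one_to_two(self):
        cfg = replace(simulate.confounded_null_config(), n=60_000, seed=1,
                      exclusion_probs={})
        raw = simulate.generate_cohort(cfg)
        t = traditional.adjusted_association_models(raw, strata=("all",)).set_index("model")
        assert abs(np.log(t.loc["two", "rr"])) < abs(np.log(t.loc["one", "rr"]))

    def test_mediator_adjustment_attenuates_from_model_two_to_three(self):
        cfg = replace(simulate.default_config(), n=60_000, seed=2, exclusion_probs={})
        raw = simulate.generate_cohort(cfg)
        t = traditional.adjusted_association_models(raw, strata=("all",)).set_index("model")
        assert abs(np.log(t.loc["three", "rr"])) < abs(np.log(t.loc["two", "rr"]))

    def test_grid_covers_strata_and_models(self, kept_cohort):
        t = traditional.adjusted_association_models(kept_cohort, exposure="occupation")
        assert len(t) == 9
        assert (t.lo <= t.rr).all() and (t.rr <= t.hi).all()
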