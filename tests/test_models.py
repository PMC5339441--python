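"""Model-design tests: orthogonal polynomial coding, outcome
transformations, Wald-based stepwise reduction, and response-scale
estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from equirest import models
from equirest.models import (
    ModelSpec,
    OutcomeTransform,
    build_terms,
    default_model_specs,
    estimate_response_scale,
    fit_full_model,
    make_transform,
    poly_contrasts,
    stepwise_reduce,
)


def gram_schmidt_poly(n, order):
    """Independent oracle: Gram-Schmidt on (1, x, x^2, ...) over 0..n-1."""
    x = np.arange(n, dtype=float)
    basis = [np.ones(n) / np.sqrt(n)]
    for d in range(1, order + 1):
        v = x**d
        for b in basis:
            v = v - (v @ b) * b
        basis.append(v / np.linalg.norm(v))
    cols = np.column_stack(basis[1:])
    for k in range(cols.shape[1]):  # same sign convention: top level positive
        if cols[-1, k] < 0 or (cols[-1, k] == 0 and cols[-2, k] < 0):
            cols[:, k] = -cols[:, k]
    return cols


class TestPolyContrasts:
    def test_linear_column_for_four_levels(self):
        c = poly_contrasts(4, 1)
        assert np.allclose(c[:, 0], np.array([-3, -1, 1, 3]) / np.sqrt(20))

    def test_quadratic_column_for_four_levels(self):
        c = poly_contrasts(4, 3)
        assert c.shape == (4, 3)
        assert np.allclose(c[:, 1], np.array([1, -1, -1, 1]) / 2.0)

    @given(st.integers(3, 8), st.integers(1, 4))
    def test_matches_gram_schmidt_oracle(self, n, order):
        if order >= n:
            return
        assert np.allclose(poly_contrasts(n, order), gram_schmidt_poly(n, order))

    @given(st.integers(2, 9))
    def test_columns_orthonormal_and_centred(self, n):
        c = poly_contrasts(n, n - 1)
        assert np.allclose(c.T @ c, np.eye(n - 1), atol=1e-12)
        assert np.allclose(c.sum(axis=0), 0.0, atol=1e-12)

    def test_order_must_be_below_levels(self):
        with pytest.raises(ValueError):
            poly_contrasts(4, 4)


class TestTransforms:
    def test_logit_of_half_is_zero(self):
        assert OutcomeTransform("logit").forward(np.array([0.5]))[0] == pytest.approx(0.0)

    def test_log_with_unit_offset_maps_zero_to_zero(self):
        tf = make_transform("log", offset=1.0)
        assert tf.forward(np.array([0.0]))[0] == pytest.approx(0.0)

    def test_logit_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="proportions"):
            OutcomeTransform("logit").forward(np.array([1.2]))

    def test_round_trip_on_random_proportions(self, rng):
        p = rng.uniform(size=1000)
        p[:10] = 0.0  # boundary values go through the shrink
        p[10:20] = 1.0
        tf = make_transform("logit", p)
        assert np.max(np.abs(tf.inverse(tf.forward(p)) - p)) < 1e-9
        tf = make_transform("log")
        x = rng.exponential(30.0, size=1000)
        assert np.max(np.abs(tf.inverse(tf.forward(x)) - x)) < 1e-9


def synthetic_metrics(rng, n_groups=3, horses_per_group=6, sd=1.0, effects=None):
    """Balanced metrics-like table with controllable fixed effects."""
    effects = effects or {}
    contrasts = poly_contrasts(4, 3)
    rows = []
    for g in range(n_groups):
        for h in range(horses_per_group):
            horse = f"g{g}h{h}"
            low = 1.0 if h < horses_per_group / 2 else 0.0
            for i, t in enumerate(models.TREATMENTS):
                for day in (1, 2, 3):
                    y = 10.0 + sd * rng.normal()
                    y += effects.get("rank", 0.0) * low
                    for d in (1, 2, 3):
                        y += effects.get(f"tr{d}", 0.0) * contrasts[i, d - 1]
                        y += effects.get(f"rank_tr{d}", 0.0) * low * contrasts[i, d - 1]
                    rows.append({
                        "horse_id": horse, "group": g,
                        "rank_class": "low" if low else "high",
                        "treatment": t, "day_index": day, "outcome": y,
                    })
    return pd.DataFrame(rows)


class TestFitting:
    def test_term_structure_respects_marginality(self):
        terms = {t.name: t for t in build_terms(ModelSpec("outcome", poly_order=3))}
        assert "rank:treatment^3" in terms["rank"].blocked_by
        assert "treatment^2" in terms["treatment^1"].blocked_by
        assert terms["rank:treatment^3"].blocked_by == ()

    def test_all_significant_terms_leave_model_unchanged(self, rng):
        df = synthetic_metrics(
            rng, sd=0.5,
            effects={"tr1": 5, "tr2": 4, "tr3": 3, "rank": 2,
                     "rank_tr1": 3, "rank_tr2": 3, "rank_tr3": 3},
        )
        fit = stepwise_reduce(ModelSpec("outcome"), df)
        assert fit.path == []
        assert set(fit.retained) == {
            "treatment^1", "treatment^2", "treatment^3", "rank", "rank:treatment^3"
        }

    def test_pure_linear_effect_always_keeps_the_linear_term(self, rng):
        keeps_linear, extras = [], []
        for _ in range(15):
            df = synthetic_metrics(rng, sd=1.0, effects={"tr1": 2.5})
            fit = stepwise_reduce(ModelSpec("outcome"), df)
            keeps_linear.append("treatment^1" in fit.retained)
            extras.append(len(set(fit.retained) - {"treatment^1"}))
        assert all(keeps_linear)
        # extraneous null terms survive only at roughly the nominal 10% rate
        assert np.mean(extras) < 1.0

    def test_coding_equivalence_poly_vs_dummy(self, rng):
        # same column space -> identical OLS fitted values on any fixed data
        df = synthetic_metrics(rng, n_groups=2, horses_per_group=4,
                               effects={"tr1": 3, "rank": 1})
        level = df["treatment"].map({t: i for i, t in enumerate(models.TREATMENTS)})
        contrasts = poly_contrasts(4, 3)
        x_poly = np.column_stack(
            [np.ones(len(df))] + [contrasts[level, d] for d in range(3)]
        )
        x_dummy = np.column_stack(
            [np.ones(len(df))] + [(level == i).astype(float) for i in (1, 2, 3)]
        )
        y = df["outcome"].to_numpy()
        fitted_poly = x_poly @ np.linalg.lstsq(x_poly, y, rcond=None)[0]
        fitted_dummy = x_dummy @ np.linalg.lstsq(x_dummy, y, rcond=None)[0]
        assert np.allclose(fitted_poly, fitted_dummy)

    def test_binomial_outcome_fits_and_reduces(self, rng):
        df = synthetic_metrics(rng, effects={"tr1": 2.0})
        df["outcome"] = (df["outcome"] + rng.normal(size=len(df)) > 10.5)
        spec = ModelSpec("outcome", family="binomial", poly_order=2)
        fit = stepwise_reduce(spec, df)
        assert all(s.df_den is None for s in fit.stats)
        assert "treatment^1" in fit.retained

    def test_default_specs_cover_the_outcome_list(self):
        specs = {s.outcome: s for s in default_model_specs()}
        assert len(specs) == 13
        assert specs["duration_min_total"].poly_order == 3
        assert specs["duration_min_litter"].poly_order == 2
        assert specs["duration_min_rubber_mats"].transformation == "log"
        assert specs["pct_lateral"].transformation == "logit"
        assert specs["under_30min"].family == "binomial"


class TestResponseScale:
    def test_identity_estimates_equal_cell_means_structure(self, rng):
        df = synthetic_metrics(rng, sd=0.2, effects={"tr1": 4.0})
        fit = stepwise_reduce(ModelSpec("outcome"), df)
        est = estimate_response_scale(fit)
        assert len(est) == 8
        assert (est["ci_low"] <= est["estimate"]).all()
        assert (est["estimate"] <= est["ci_high"]).all()
        # linear effect: estimates increase along the treatment ladder
        for rank_class in ("low", "high"):
            vals = est[est.rank_class == rank_class]["estimate"].to_numpy()
            assert (np.diff(vals) > 0).all()

    def test_logit_fit_recovers_known_proportions(self, rng):
        truth_logit = {t: lo for t, lo in zip(models.TREATMENTS, (-2.0, -1.5, -1.0, -0.5))}
        rows = []
        for g in range(3):
            for h in range(8):
                for t in models.TREATMENTS:
                    for day in (1, 2, 3):
                        eta = truth_logit[t] + 0.15 * rng.normal()
                        p = 1 / (1 + np.exp(-eta))
                        rows.append({"horse_id": f"g{g}h{h}", "group": g,
                                     "rank_class": "low" if h < 4 else "high",
                                     "treatment": t, "day_index": day,
                                     "pct_lateral": 100 * p})
        df = pd.DataFrame(rows)
        fit = stepwise_reduce(ModelSpec("pct_lateral", transformation="logit"), df)
        est = estimate_response_scale(fit)
        assert (est["scale"] == "median").all()
        for t, lo in truth_logit.items():
            target = 100 / (1 + np.exp(-lo))
            got = est[est.treatment == t]["estimate"].mean()
            assert got == pytest.approx(target, rel=0.15)

    def test_monotone_back_transform_preserves_ci_ordering(self, rng):
        df = synthetic_metrics(rng, effects={"tr1": 1.0})
        df["outcome"] = np.abs(df["outcome"])
        fit = stepwise_reduce(ModelSpec("outcome", transformation="log"), df)
        est = estimate_response_scale(fit)
        assert (est["ci_low"] < est["ci_high"]).all()
        assert (est["estimate"] > 0).all()
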