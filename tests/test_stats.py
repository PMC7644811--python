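"""Tests of the scalar repeated-measures ANOVA and permutation SPM."""

import numpy as np
import pandas as pd
import pytest

from synlab import stats


def _long_table(y):
    rows = []
    for i in range(y.shape[0]):
        for e, env in enumerate(["O", "T"]):
            for t, typ in enumerate(["R", "W"]):
                rows.append(
                    {"participant": i, "environment": env, "type": typ, "value": y[i, e, t]}
                )
    return pd.DataFrame(rows)


class TestScalarAnova:
    def test_identical_conditions_give_null_result(self, rng):
        base = rng.standard_normal(12)
        y = np.repeat(base[:, None, None], 2, axis=1).repeat(2, axis=2)
        res = stats.scalar_anova(_long_table(y))
        for eff in res.effects.values():
            assert eff.F == pytest.approx(0.0, abs=1e-20)
            assert eff.p == pytest.approx(1.0)

    def test_matches_statsmodels_reference(self, rng):
        from statsmodels.stats.anova import AnovaRM

        y = rng.standard_normal((30, 2, 2))
        y[:, 1, :] += 1.0  # environment effect of d ~ 1
        df = _long_table(y)
        res = stats.scalar_anova(df)
        ref = AnovaRM(
            df, "value", "participant", within=["environment", "type"]
        ).fit().anova_table
        assert res.method == "parametric"
        assert res.effects["environment"].F == pytest.approx(
            ref.loc["environment", "F Value"], abs=1e-8
        )
        assert res.effects["type"].F == pytest.approx(ref.loc["type", "F Value"], abs=1e-8)
        assert res.effects["interaction"].F == pytest.approx(
            ref.loc["environment:type", "F Value"], abs=1e-8
        )

    def test_skewed_residuals_route_to_rank_path(self, rng):
        y = rng.exponential(1.0, size=(25, 2, 2)) ** 3
        res = stats.scalar_anova(_long_table(y))
        assert res.method == "rank_based"
        for eff in res.effects.values():
            assert 0.0 <= eff.p <= 1.0

    def test_fdr_adjustment_is_monotone(self, rng):
        y = rng.standard_normal((15, 2, 2))
        res = stats.scalar_anova(_long_table(y))
        assert np.all(res.posthoc["p_adj"] >= res.posthoc["p_raw"] - 1e-15)

    def test_too_few_participants_rejected(self, rng):
        y = rng.standard_normal((2, 2, 2))
        with pytest.raises(ValueError):
            stats.scalar_anova(_long_table(y))

    def test_incomplete_participants_dropped(self, rng):
        y = rng.standard_normal((10, 2, 2))
        df = _long_table(y)
        df = df.drop(df[(df.participant == 0) & (df.environment == "T")].index)
        res = stats.scalar_anova(df)
        assert res.n_participants == 9


class TestSpm:
    def test_exact_null_has_no_significant_clusters(self, rng):
        curves = np.repeat(rng.standard_normal((15, 1, 6, 200)), 2, axis=1)
        curves += 1e-9 * rng.standard_normal(curves.shape)  # break exact ties
        res = stats.spm_rm_anova(curves, n_resamples=300, seed=0)
        assert stats.significant_clusters(res) == []

    def test_injected_offset_detected_in_window(self, rng):
        curves = rng.standard_normal((20, 2, 6, 200))
        curves[:, 0, :, 30:51] += 3.0 * curves.std()
        res = stats.spm_rm_anova(curves, n_resamples=500, seed=1)
        sig = stats.significant_clusters(res)
        assert sig, "expected a significant cluster"
        spans = [(c.start, c.end) for c in sig]
        assert any(s <= 50 and e >= 30 for s, e in spans)

    def test_participant_order_invariance(self, rng):
        curves = rng.standard_normal((12, 2, 4, 200))
        res1 = stats.spm_rm_anova(curves, n_resamples=200, seed=3)
        res2 = stats.spm_rm_anova(curves[::-1], n_resamples=200, seed=3)
        np.testing.assert_allclose(res1.f_curve, res2.f_curve, atol=1e-10)

    def test_permutation_p_values_valid_under_null(self, rng):
        """P(cluster p <= alpha) under label exchange stays near or
        below alpha (Monte-Carlo error allowed)."""
        hits = 0
        reps = 60
        for k in range(reps):
            curves = rng.standard_normal((12, 2, 3, 200))
            res = stats.spm_rm_anova(curves, n_resamples=200, seed=k)
            hits += bool(stats.significant_clusters(res))
        assert hits / reps <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_rejects_malformed_input(self, rng):
        with pytest.raises(ValueError):
            stats.spm_rm_anova(rng.standard_normal((10, 3, 4, 200)))
        with pytest.raises(ValueError):
            stats.spm_rm_anova(rng.standard_normal((1, 2, 4, 200)))
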