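"""Fit statistics, misfit flags, separation reliability."""

import numpy as np
import pandas as pd
import pytest

import riskrasch as rr


def _zstd_oracle(ms, q2):
    q = np.sqrt(q2)
    return (ms ** (1 / 3) - 1.0) * (3.0 / q) + q / 3.0


class TestStandardizedResiduals:
    def test_unit_residual_at_half_probability(self):
        # x=1 at P=0.5 -> z = 0.5/0.5 = 1; x=0 -> z = -1
        X = np.array([[1, 0], [0, 1], [1, 1], [0, 0]], float)
        m = rr.ResponseMatrix(X, list("abcd"), ["i", "j"])
        fit = rr.fit_jmle(m)  # symmetric: all parameters 0
        res = rr.standardized_residuals(fit, m)
        np.testing.assert_allclose(np.abs(res.standardized[0]), [1, 1], atol=1e-4)
        assert res.standardized[0, 0] > 0 and res.standardized[0, 1] < 0

    def test_identity_z_times_sqrtw_is_raw(self, study_cohort, study_fit):
        res = rr.standardized_residuals(study_fit, study_cohort.matrix)
        obs = res.observed
        np.testing.assert_allclose(
            (res.standardized * np.sqrt(res.variance))[obs], res.raw[obs],
            atol=1e-12,
        )
        assert (np.abs(res.raw[obs]) < 1).all()

    def test_mean_squared_residual_near_one_under_model(self):
        """At the generating parameters the standardized residuals have
        unit mean square."""
        sim = rr.simulate_responses(rr.PopulationSpec(n_persons=1000, seed=2))
        res = rr.standardized_residuals(sim.generating_fit(), sim.matrix)
        z2 = res.standardized[res.estimation] ** 2
        assert 0.9 < z2.mean() < 1.1

    def test_dimension_mismatch_rejected(self, study_fit):
        other = rr.simulate_responses(rr.PopulationSpec(n_persons=10, seed=0))
        with pytest.raises(ValueError):
            rr.standardized_residuals(study_fit, other.matrix)


class TestFitStatistics:
    def test_guttman_matrix_overfits(self):
        """Perfectly ordered (deterministic Guttman) data shows less
        variation than the stochastic model expects: evaluated at
        moderate person/item parameters, infit < 1 for every item."""
        from riskrasch.engine import ItemCalibration, PersonMeasure, RaschFit

        theta = np.linspace(-2, 2, 10)
        delta = np.array([-1.0, 0.0, 1.0])
        X = (theta[:, None] > delta[None, :]).astype(float)
        m = rr.ResponseMatrix(X, [f"p{n}" for n in range(10)], ["a", "b", "c"])
        fit = RaschFit(
            items=[ItemCalibration(l, float(d), 0.3, int(X[:, i].sum()), 10)
                   for i, (l, d) in enumerate(zip("abc", delta))],
            persons=[PersonMeasure(f"p{n}", float(X[n].sum()), float(t), 0.5)
                     for n, t in enumerate(theta)],
            iterations=0, max_logit_change=0.0, converged=True,
        )
        res = rr.standardized_residuals(fit, m)
        stats = rr.fit_statistics(res, "items")
        assert (stats["infit_ms"] < 1).all()

    def test_random_item_misfits(self):
        """An item replaced by coin flips independent of ability is caught
        by outfit."""
        sim = rr.simulate_responses(rr.PopulationSpec(n_persons=1000, seed=5))
        X = sim.matrix.scores.copy()
        X[:, 5] = (np.random.default_rng(5).random(1000) < 0.5).astype(float)
        m = rr.ResponseMatrix(X, sim.matrix.person_ids, sim.matrix.item_labels)
        fit = rr.fit_jmle(m)
        stats = rr.fit_statistics(rr.standardized_residuals(fit, m), "items")
        row = stats.iloc[5]
        assert row["outfit_ms"] > 1
        assert row["outfit_zstd"] > 2

    def test_outfit_more_sensitive_to_outlier_than_infit(self):
        """One wildly unexpected response (a very able person failing a
        very easy item) moves outfit more than infit."""
        sim = rr.simulate_responses(
            rr.PopulationSpec(n_persons=400, ability_mean=0.0, ability_sd=1.5,
                              seed=8)
        )
        fit = rr.fit_jmle(sim.matrix)
        res = rr.standardized_residuals(fit, sim.matrix)
        base = rr.fit_statistics(res, "items")
        # flip the easiest item for the highest-ability person
        easiest = int(np.argmin(fit.difficulties))
        top = int(np.argmax(np.where(~fit.person_extreme, fit.measures, -np.inf)))
        X = sim.matrix.scores.copy()
        assert X[top, easiest] == 1.0
        X[top, easiest] = 0.0
        m2 = rr.ResponseMatrix(X, sim.matrix.person_ids, sim.matrix.item_labels)
        res2 = rr.standardized_residuals(fit, m2)
        pert = rr.fit_statistics(res2, "items")
        d_out = pert.loc[easiest, "outfit_ms"] - base.loc[easiest, "outfit_ms"]
        d_in = pert.loc[easiest, "infit_ms"] - base.loc[easiest, "infit_ms"]
        assert d_out > d_in > 0

    def test_zstd_formula_matches_oracle(self, study_cohort, study_fit):
        """Recompute the Wilson–Hilferty standardization from the raw
        residual arrays and compare."""
        res = rr.standardized_residuals(study_fit, study_cohort.matrix)
        stats = rr.fit_statistics(res, "items")
        i = 1
        mask = res.estimation[:, i]
        W = res.variance[mask, i]
        raw = res.raw[mask, i]
        z2 = (raw**2 / W)
        n = mask.sum()
        C = W * (1 - 3 * W)
        infit = (raw**2).sum() / W.sum()
        outfit = z2.mean()
        q2_in = (C - W**2).sum() / W.sum() ** 2
        q2_out = (C / W**2).sum() / n**2 - 1 / n
        assert stats.loc[i, "infit_ms"] == pytest.approx(infit)
        assert stats.loc[i, "outfit_ms"] == pytest.approx(outfit)
        assert stats.loc[i, "infit_zstd"] == pytest.approx(
            _zstd_oracle(infit, q2_in))
        assert stats.loc[i, "outfit_zstd"] == pytest.approx(
            _zstd_oracle(outfit, q2_out))

    def test_zstd_near_zero_at_unit_mean_square(self, study_cohort, study_fit):
        """At ms = 1 the transform reduces to q/3, within ±0.2 of zero for
        cohorts of a few hundred."""
        res = rr.standardized_residuals(study_fit, study_cohort.matrix)
        i = 1
        mask = res.estimation[:, i]
        W = res.variance[mask, i]
        C = W * (1 - 3 * W)
        q2_in = (C - W**2).sum() / W.sum() ** 2
        assert abs(_zstd_oracle(1.0, q2_in)) < 0.2

    def test_undefined_for_sparse_units(self):
        X = np.array([[1, 0, 1], [0, 1, 0], [1, 1, np.nan], [0, 0, 1]])
        X2 = X.copy()
        X2[0, 2] = np.nan
        X2[3, 2] = np.nan  # item 3 observed once only
        m = rr.ResponseMatrix(X2, list("abcd"), ["i", "j", "k"])
        fit = rr.fit_jmle(m)
        stats = rr.fit_statistics(rr.standardized_residuals(fit, m), "items")
        assert np.isnan(stats.loc[2, "infit_ms"])


class TestFlagMisfit:
    @pytest.mark.parametrize(
        "zstd,flagged,review",
        [(2.40, True, False), (-2.5, True, False), (1.9, False, False),
         (3.2, True, True)],
    )
    def test_thresholds(self, zstd, flagged, review):
        stats = pd.DataFrame(
            {
                "unit_id": ["u"],
                "infit_ms": [1.1],
                "outfit_ms": [1.0],
                "infit_zstd": [zstd],
                "outfit_zstd": [0.0],
            }
        )
        out = rr.flag_misfit(stats)
        assert bool(out.loc[0, "flagged"]) is flagged
        assert bool(out.loc[0, "review"]) is review

    def test_infit_precedence_in_ordering(self):
        stats = pd.DataFrame(
            {
                "unit_id": ["a", "b"],
                "infit_ms": [1, 1],
                "outfit_ms": [1, 1],
                "infit_zstd": [0.5, 2.2],
                "outfit_zstd": [3.0, 0.0],
            }
        )
        out = rr.flag_misfit(stats)
        assert out.loc[0, "unit_id"] == "b"


class TestReliability:
    def test_published_item_reliability(self, published_difficulties,
                                        published_ses):
        rep = rr.separation_reliability(published_difficulties, published_ses)
        assert round(rep.reliability, 2) == 0.99

    def test_limits(self):
        rep = rr.separation_reliability([-2, 0, 2], [1e-6, 1e-6, 1e-6])
        assert rep.reliability == pytest.approx(1.0, abs=1e-9)
        # observed variance equal to mean error variance -> reliability 0
        m = np.array([-1.0, 1.0])
        rep0 = rr.separation_reliability(m, [1.0, 1.0])
        assert rep0.reliability == pytest.approx(0.0)

    def test_scale_shift_invariance(self, published_difficulties,
                                    published_ses):
        a = rr.separation_reliability(published_difficulties, published_ses)
        b = rr.separation_reliability(published_difficulties + 5.0,
                                      published_ses)
        assert a.reliability == pytest.approx(b.reliability)

    def test_validation(self):
        with pytest.raises(ValueError):
            rr.separation_reliability([1.0], [0.5])
        with pytest.raises(ValueError):
            rr.separation_reliability([1.0, 2.0], [0.5, -0.5])
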