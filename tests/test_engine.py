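"""Rasch calibration: probabilities, PROX, JMLE, score conversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import riskrasch as rr
from riskrasch.engine import EstimationConfig, person_measure_for_score

from conftest import PUBLISHED_SCORE_TABLE, bisect_measure


class TestRaschProbability:
    def test_symmetry_point(self):
        assert rr.rasch_probability(0.0, 0.0) == pytest.approx(0.5)

    def test_closed_form(self):
        assert rr.rasch_probability(1.1, 0.1) == pytest.approx(0.7311, abs=1e-4)

    def test_saturation_no_overflow(self):
        assert rr.rasch_probability(-30.0, 30.0) == pytest.approx(0.0, abs=1e-20)
        assert rr.rasch_probability(30.0, -30.0) == pytest.approx(1.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            rr.rasch_probability(np.nan, 0.0)

    @settings(max_examples=50, derandomize=True)
    @given(
        st.floats(-10, 10),
        st.floats(-10, 10),
        st.floats(0.01, 5),
    )
    def test_monotone_in_theta_and_delta(self, theta, delta, eps):
        p = rr.rasch_probability(theta, delta)
        assert rr.rasch_probability(theta + eps, delta) > p
        assert rr.rasch_probability(theta, delta + eps) < p


class TestProx:
    def test_equal_margins_give_zero_difficulties(self):
        X = np.array([[1, 0], [0, 1], [1, 1], [0, 0], [1, 0], [0, 1]], float)
        m = rr.ResponseMatrix(X, [f"p{i}" for i in range(6)], ["a", "b"])
        d, b, p_ext, i_ext = rr.prox_initialize(m)
        np.testing.assert_allclose(d[~i_ext], [0.0, 0.0], atol=1e-12)

    def test_monotone_in_margin(self):
        rng = np.random.default_rng(0)
        X = (rng.random((200, 4)) < [0.8, 0.6, 0.4, 0.2]).astype(float)
        m = rr.ResponseMatrix(X, [f"p{i}" for i in range(200)], list("abcd"))
        d, *_ = rr.prox_initialize(m)
        assert (np.diff(d) > 0).all()  # rarer endorsement = harder item


class TestJMLE:
    def test_symmetric_two_items(self):
        # each item endorsed by exactly half the (non-extreme) persons
        X = np.array([[1, 0], [0, 1], [1, 0], [0, 1]], float)
        m = rr.ResponseMatrix(X, list("abcd"), ["i1", "i2"])
        fit = rr.fit_jmle(m)
        np.testing.assert_allclose(fit.difficulties, [0.0, 0.0], atol=1e-6)

    def test_centering_invariant(self, study_fit):
        core = ~study_fit.item_extreme
        assert abs(study_fit.difficulties[core].sum()) < 1e-6

    def test_parameter_recovery_correlation(self, published_difficulties):
        """Recovered difficulties correlate > 0.99 with generating values
        at N=2000 even though JMLE expands the scale."""
        sim = rr.simulate_responses(
            rr.PopulationSpec(
                n_persons=2000, ability_mean=-2.2, ability_sd=1.5, seed=1
            )
        )
        fit = rr.fit_jmle(sim.matrix)
        r = np.corrcoef(fit.difficulties, published_difficulties)[0, 1]
        assert r > 0.99

    def test_recovery_with_bias_correction_well_targeted(self):
        """With the (L-1)/L correction and a well-targeted instrument the
        generating difficulties are recovered closely."""
        d_true = np.linspace(-2, 2, 9)
        d_true -= d_true.mean()
        sim = rr.simulate_responses(
            rr.PopulationSpec(
                n_persons=2000, ability_mean=0.0, ability_sd=1.5,
                difficulties=tuple(d_true), seed=1,
            )
        )
        fit = rr.fit_jmle(sim.matrix, EstimationConfig(bias_correction=True))
        rmse = float(np.sqrt(((fit.difficulties - d_true) ** 2).mean()))
        assert rmse < 0.12

    def test_sufficiency_margins_determine_fit(self):
        """Two matrices with identical row and column margins yield the
        same calibration (a tetrad swap preserves both)."""
        sim = rr.simulate_responses(rr.PopulationSpec(n_persons=80, seed=4))
        X1 = sim.matrix.scores.copy()
        # find a tetrad: persons a,b and items i,j with pattern 1,0 / 0,1
        found = False
        for a in range(80):
            for b in range(a + 1, 80):
                dcols = np.flatnonzero((X1[a] == 1) & (X1[b] == 0))
                ecols = np.flatnonzero((X1[a] == 0) & (X1[b] == 1))
                if dcols.size and ecols.size:
                    i, j = dcols[0], ecols[0]
                    X2 = X1.copy()
                    X2[a, i], X2[a, j] = 0, 1
                    X2[b, i], X2[b, j] = 1, 0
                    found = True
                    break
            if found:
                break
        assert found
        m1 = sim.matrix
        m2 = rr.ResponseMatrix(X2, m1.person_ids, m1.item_labels)
        f1, f2 = rr.fit_jmle(m1), rr.fit_jmle(m2)
        np.testing.assert_allclose(f1.difficulties, f2.difficulties, atol=1e-9)
        np.testing.assert_allclose(
            np.sort(f1.measures), np.sort(f2.measures), atol=1e-9
        )

    def test_translation_invariance_of_difficulties(self):
        """Shifting all generating abilities by a constant leaves fitted
        (centered) difficulties unchanged up to sampling noise."""
        d = np.linspace(-2, 2, 9)
        d -= d.mean()
        rng = np.random.default_rng(12)
        theta = rng.normal(0.0, 1.5, 3000)
        U = rng.random((3000, 9))
        fits = []
        for c in (0.0, 0.7):
            P = 1 / (1 + np.exp(-((theta + c)[:, None] - d[None, :])))
            X = (U < P).astype(float)
            m = rr.ResponseMatrix(X, [f"p{i}" for i in range(3000)],
                                  [f"i{i}" for i in range(9)])
            fits.append(rr.fit_jmle(m).difficulties)
        assert np.abs(fits[0] - fits[1]).max() < 0.3

    def test_extreme_persons_get_boundary_measures(self):
        X = np.array(
            [[0, 0, 0], [1, 1, 1], [1, 0, 0], [1, 1, 0], [0, 1, 0], [1, 0, 1]],
            float,
        )
        m = rr.ResponseMatrix(X, list("abcdef"), ["i1", "i2", "i3"])
        fit = rr.fit_jmle(m)
        per = {p.person_id: p for p in fit.persons}
        assert per["a"].extreme_flag and per["b"].extreme_flag
        assert per["a"].measure < min(p.measure for p in fit.persons
                                      if not p.extreme_flag)
        assert per["b"].measure > max(p.measure for p in fit.persons
                                      if not p.extreme_flag)

    def test_nonconvergence_flagged_not_raised(self, study_cohort):
        with pytest.warns(RuntimeWarning):
            fit = rr.fit_jmle(study_cohort.matrix, EstimationConfig(max_iter=2))
        assert not fit.converged
        assert fit.iterations == 2

    def test_missing_cells_use_observed_sums_only(self):
        """Blanking cells changes only what is summed, not the contract:
        the fit still reproduces each person's observed raw score."""
        sim = rr.simulate_responses(rr.PopulationSpec(n_persons=120, seed=6))
        X = sim.matrix.scores.copy()
        rng = np.random.default_rng(0)
        holes = rng.random(X.shape) < 0.1
        X[holes] = np.nan
        m = rr.ResponseMatrix(X, sim.matrix.person_ids, sim.matrix.item_labels)
        fit = rr.fit_jmle(m)
        assert fit.converged
        raw = np.nansum(np.where(np.isnan(X), 0, X), axis=1)
        for p, r in zip(fit.persons, raw):
            assert p.raw_score == pytest.approx(r)


class TestScoreConversion:
    def test_published_table_reproduced(self, published_difficulties):
        rows = rr.score_conversion_table(published_difficulties, adjust=0.3)
        for row in rows:
            m_ref, se_ref = PUBLISHED_SCORE_TABLE[row.raw_score]
            assert row.measure == pytest.approx(m_ref, abs=0.02)
            assert row.se == pytest.approx(se_ref, abs=0.02)

    def test_closed_form_equal_difficulties(self):
        m, _ = person_measure_for_score(np.zeros(2), 1.0)
        assert m == pytest.approx(0.0, abs=1e-8)
        rows = rr.score_conversion_table(np.zeros(9))
        assert rows[5].measure == pytest.approx(np.log(5 / 4), abs=1e-8)

    def test_monotone_measures(self, published_difficulties):
        rows = rr.score_conversion_table(published_difficulties)
        measures = [r.measure for r in rows]
        assert (np.diff(measures) > 0).all()

    def test_se_u_shape(self, published_difficulties):
        rows = rr.score_conversion_table(published_difficulties)
        mid = rows[len(rows) // 2].se
        assert rows[0].se > mid and rows[-1].se > mid

    def test_out_of_range_score_rejected(self, published_difficulties):
        with pytest.raises(ValueError):
            person_measure_for_score(published_difficulties, 9.5)
        with pytest.raises(ValueError):
            person_measure_for_score(published_difficulties, -0.1)

    @settings(max_examples=40, derandomize=True)
    @given(
        st.lists(st.floats(-4, 4), min_size=3, max_size=8),
        st.integers(1, 7),
    )
    def test_newton_matches_bisection(self, difficulties, raw):
        d = np.asarray(difficulties)
        raw = min(raw, len(d) - 1)
        m, _ = person_measure_for_score(d, float(raw))
        assert m == pytest.approx(bisect_measure(d, raw), abs=1e-6)
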