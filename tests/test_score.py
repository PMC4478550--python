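"""Scoring layer: LOC-scores, abundance, z-LOC, mixture cutoffs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ensloc import score as S
from ensloc.ensemble import AssignmentVector
from ensloc.phantom import CLASSES
from ensloc.segment import CellRegion


def assignment(classes=(), qc="pass"):
    m = np.zeros(16, dtype=bool)
    for c in classes:
        m[CLASSES.index(c)] = True
    return AssignmentVector((0,), qc, "unbudded", m if qc == "pass" else np.zeros(16, bool))


def cell(integrated, area, object_id=1):
    mask = np.ones((area, 1), dtype=bool)
    return CellRegion(
        object_id=object_id,
        mask=mask,
        bbox=(0, 0, area, 1),
        centroid=(0.0, area / 2 - 0.5),
        area=area,
        integrated_intensity={"GFP": float(integrated)},
    )


class TestLocProfile:
    def test_exclusive_assignment_sums_to_one(self):
        asg = [assignment(["nucleus"]) for _ in range(100)]
        prof = S.loc_profile(asg)
        assert prof.loc_scores[CLASSES.index("nucleus")] == 1.0
        assert prof.loc_scores.sum() == 1.0
        assert prof.n_classifiable == 100

    def test_multi_localization_sums_above_one(self):
        asg = [assignment(["nucleus"]) for _ in range(50)] + [
            assignment(["nucleus", "nucleolus"]) for _ in range(50)
        ]
        prof = S.loc_profile(asg)
        assert prof.loc_scores[CLASSES.index("nucleus")] == 1.0
        assert prof.loc_scores[CLASSES.index("nucleolus")] == 0.5
        assert prof.loc_scores.sum() == pytest.approx(1.5)

    def test_dead_ghost_and_unclassified_excluded_from_denominator(self):
        asg = (
            [assignment(["ER"]) for _ in range(30)]
            + [assignment(qc="dead") for _ in range(10)]
            + [assignment(qc="ghost") for _ in range(5)]
            + [assignment([]) for _ in range(15)]  # unclassifiable
        )
        prof = S.loc_profile(asg)
        assert prof.n_cells_total == 60
        assert prof.n_classifiable == 30
        assert prof.loc_scores[CLASSES.index("ER")] == 1.0

    def test_matches_column_count_oracle(self):
        rng = np.random.default_rng(3)
        table = rng.random((200, 16)) < 0.15
        asg = [
            AssignmentVector((i,), "pass", "unbudded", row) for i, row in enumerate(table)
        ]
        prof = S.loc_profile(asg)
        classifiable = table.any(axis=1)
        oracle = table[classifiable].sum(axis=0) / classifiable.sum()
        np.testing.assert_allclose(prof.loc_scores, oracle)

    def test_zero_classifiable_is_unquantifiable(self):
        prof = S.loc_profile([assignment([]) for _ in range(5)])
        assert not prof.quantifiable
        assert np.isnan(prof.loc_scores).all()

    def test_low_confidence_flag(self):
        prof = S.loc_profile([assignment(["ER"]) for _ in range(10)])
        assert prof.low_confidence


class TestAbundance:
    def test_single_cell_ratio(self):
        rec = S.abundance_ig([cell(500.0, 100)])
        assert rec.ig == pytest.approx(5.0)

    def test_homogeneity_under_intensity_scaling(self):
        cells = [cell(100.0 * (i + 1), 50, i + 1) for i in range(10)]
        scaled = [cell(300.0 * (i + 1), 50, i + 1) for i in range(10)]
        assert S.abundance_ig(scaled).ig == pytest.approx(3 * S.abundance_ig(cells).ig)

    def test_empty_list_unquantifiable(self):
        rec = S.abundance_ig([])
        assert not rec.quantifiable

    def test_excludes_dead_cells_when_assignments_given(self):
        cells = [cell(100.0, 10, 1), cell(9000.0, 10, 2)]
        asg = [assignment(["ER"]), assignment(qc="dead")]
        rec = S.abundance_ig(cells, assignments=asg)
        assert rec.ig == pytest.approx(10.0)


class TestDeltaPL:
    def test_fold_change(self):
        a = S.AbundanceRecord("p", "cond", 10.0, 5)
        b = S.AbundanceRecord("p", "ctrl", 5.0, 5)
        assert S.delta_pl(a, b) == pytest.approx(2.0)
        assert S.delta_pl(a, a) == 1.0

    def test_zero_control_flagged(self):
        a = S.AbundanceRecord("p", "cond", 1.0, 5)
        z = S.AbundanceRecord("p", "ctrl", 0.0, 5)
        with pytest.raises(ZeroDivisionError):
            S.delta_pl(a, z)

    def test_transitivity_at_fixed_control(self):
        rng = np.random.default_rng(0)
        igs = rng.uniform(1, 10, 3)
        recs = [S.AbundanceRecord("p", s, ig, 5) for s, ig in zip("ABC", igs)]
        lhs = S.delta_pl(recs[0], recs[2]) / S.delta_pl(recs[1], recs[2])
        assert lhs == pytest.approx(igs[0] / igs[1], abs=1e-12)


class TestZloc:
    def test_equal_proportions_give_zero(self):
        assert S.zloc(50, 100, 50, 100) == 0.0

    def test_closed_form_example(self):
        # pooled p = 0.625, se = sqrt(0.625*0.375*0.02)
        assert S.zloc(75, 100, 50, 100) == pytest.approx(3.6515, abs=1e-4)

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.proportion import proportions_ztest

        rng = np.random.default_rng(11)
        for _ in range(300):
            n1, n2 = rng.integers(10, 500, 2)
            k1, k2 = rng.integers(1, n1), rng.integers(1, n2)
            mine = S.zloc(int(k1), int(n1), int(k2), int(n2))
            oracle, _ = proportions_ztest([k1, k2], [n1, n2])
            assert mine == pytest.approx(oracle, rel=1e-9)

    def test_degenerate_pooled_proportion_gives_zero(self):
        assert S.zloc(0, 50, 0, 80) == 0.0
        assert S.zloc(50, 50, 80, 80) == 0.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            S.zloc(5, 4, 1, 10)
        with pytest.raises(ValueError):
            S.zloc(1, 0, 1, 10)

    @settings(max_examples=200, deadline=None)
    @given(
        n1=st.integers(1, 300),
        n2=st.integers(1, 300),
        data=st.data(),
    )
    def test_antisymmetry(self, n1, n2, data):
        k1 = data.draw(st.integers(0, n1))
        k2 = data.draw(st.integers(0, n2))
        assert S.zloc(k1, n1, k2, n2) == pytest.approx(-S.zloc(k2, n2, k1, n1))

    def test_type_one_error_under_null(self):
        # 10^4 replicate null comparisons at p=0.3, n=1000 per arm
        rng = np.random.default_rng(29)
        n = 1000
        k1 = rng.binomial(n, 0.3, size=10_000)
        k2 = rng.binomial(n, 0.3, size=10_000)
        z = np.array([S.zloc(int(a), n, int(b), n) for a, b in zip(k1, k2)])
        rate = np.mean(np.abs(z) > 1.96)
        assert rate == pytest.approx(0.05, abs=0.01)


class TestMixture:
    def test_pure_normal_has_negligible_outlier_weight(self):
        rng = np.random.default_rng(1)
        fit = S.fit_mixture(rng.normal(0, 1, 10_000))
        assert fit.converged
        assert fit.outlier_weight < 0.01

    def test_recovers_planted_mixture(self):
        rng = np.random.default_rng(2)
        z = np.concatenate([rng.normal(0, 1, 9500), rng.uniform(-10, 10, 500)])
        fit = S.fit_mixture(z)
        assert fit.converged
        assert fit.outlier_weight == pytest.approx(0.05, abs=0.02)
        assert fit.background[0] == pytest.approx(0.0, abs=0.05)
        assert fit.background[1] == pytest.approx(1.0, abs=0.05)
        lo, hi = fit.cutoffs
        assert lo < 0 < hi

    def test_loglik_nondecreasing_every_iteration(self):
        rng = np.random.default_rng(3)
        z = np.concatenate([rng.normal(0, 1, 2000), rng.uniform(-8, 8, 100)])
        fit = S.fit_mixture(z)
        assert np.all(np.diff(fit.loglik_trajectory) >= -1e-7)

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError, match="degenerate|identical"):
            S.fit_mixture(np.zeros(100))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="50"):
            S.fit_mixture(np.random.default_rng(0).normal(size=20))


class TestCallChanges:
    def _fit(self):
        rng = np.random.default_rng(5)
        z = np.concatenate([rng.normal(0, 1, 9000), rng.uniform(-10, 10, 400)])
        return S.fit_mixture(z)

    def test_all_zero_z_makes_no_calls(self):
        rec = S.ComparisonRecord("p", "c", "w", None, np.zeros(16))
        out = S.call_changes(rec, self._fit())
        assert not out.significant.any()

    def test_extreme_z_called_with_direction(self):
        z = np.zeros(16)
        z[CLASSES.index("vacuole/vacuolar membrane")] = 8.0
        z[CLASSES.index("cell periphery")] = -7.0
        rec = S.ComparisonRecord("p", "c", "w", None, z)
        out = S.call_changes(rec, self._fit())
        vac = CLASSES.index("vacuole/vacuolar membrane")
        per = CLASSES.index("cell periphery")
        assert out.significant[vac] and out.direction[vac] == "toward"
        assert out.significant[per] and out.direction[per] == "away"
        assert out.significant.sum() == 2

    def test_unconverged_fit_rejected(self):
        fit = self._fit()
        fit.converged = False
        rec = S.ComparisonRecord("p", "c", "w", None, np.zeros(16))
        with pytest.raises(ValueError, match="converge"):
            S.call_changes(rec, fit)


class TestCompareProfiles:
    def test_zloc_vector_and_dpl(self):
        counts_a = np.zeros(16, dtype=int)
        counts_a[0] = 75
        counts_b = np.zeros(16, dtype=int)
        counts_b[0] = 50
        pa = S.LocalizationProfile("p", "A", counts_a / 100, 100, 100, counts_a)
        pb = S.LocalizationProfile("p", "B", counts_b / 100, 100, 100, counts_b)
        ia = S.AbundanceRecord("p", "A", 10.0, 100)
        ib = S.AbundanceRecord("p", "B", 5.0, 100)
        rec = S.compare_profiles(pa, pb, ia, ib)
        assert rec.dpl == pytest.approx(2.0)
        assert rec.zloc[0] == pytest.approx(3.6515, abs=1e-4)
        assert np.all(rec.zloc[1:] == 0.0)
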