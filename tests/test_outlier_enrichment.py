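"""Studentized-residual outliers and hypergeometric location enrichment."""

import itertools
import math

import numpy as np
import pytest

from menzerath.binning_stats import make_bins
from menzerath.mal_models import fit_nwls
from menzerath.outlier_enrichment import (
    OutlierRecord,
    OutlierReport,
    bonferroni,
    detect_outliers,
    enrich_categories,
    hat_diagonal,
    hypergeom_tail,
    internally_studentized,
    studentized_residuals,
)
from menzerath.synthetic_data import SyntheticConfig, generate_dataset, truth_report
from .conftest import protein


class TestStudentization:
    def test_matches_textbook_ols_internally_studentized(self):
        """On a plain linear regression, the generic machinery must equal the
        closed-form internally studentized residuals (statsmodels oracle)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(12)
        x = np.linspace(0.0, 4.0, 9)
        y = 2.0 + 0.7 * x + rng.normal(0, 0.5, x.size)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        e = y - X @ beta
        h = hat_diagonal(X, np.ones_like(x))
        ours = internally_studentized(e, h, df=x.size - 2)

        model = sm.OLS(y, X).fit()
        oracle = model.get_influence().resid_studentized_internal
        np.testing.assert_allclose(ours, oracle, atol=1e-10)

    def test_protein_on_curve_scores_zero(self):
        prots = [protein(f"P{i}", [8] * x) for i, x in enumerate([1, 2, 3, 4, 5, 6], 1)]
        prots.append(protein("OUT", [40, 40]))
        fit = fit_nwls(4, make_bins(prots), seed=0)
        report = studentized_residuals(fit, prots)
        by_acc = {r.accession: r for r in report.records}
        # the constant-length proteins sit almost exactly on the fitted curve
        assert abs(by_acc["P3"].studentized) < 1.0
        assert by_acc["OUT"].studentized > by_acc["P3"].studentized

    def test_planted_inflated_proteins_are_flagged_above(self):
        flagged_fracs = []
        for seed in range(5):
            cfg = SyntheticConfig(n_proteins=2000, outlier_fraction=0.01,
                                  outlier_inflation=3.0, seed=seed)
            prots = generate_dataset(cfg)
            truth = truth_report(cfg)
            fit = fit_nwls(4, make_bins(prots), seed=seed)
            report = studentized_residuals(fit, prots)
            above = {r.accession for r in report.above}
            planted = set(truth.planted_outliers)
            if planted:
                flagged_fracs.append(len(planted & above) / len(planted))
        assert np.mean(flagged_fracs) >= 0.8

    def test_unconverged_fit_rejected(self):
        prots = [protein(f"P{i}", [8] * x) for i, x in enumerate([1, 2, 3, 4], 1)]
        fit = fit_nwls(4, make_bins(prots), seed=0)
        fit.converged = False
        with pytest.raises(ValueError):
            studentized_residuals(fit, prots)


def _report(values):
    records = tuple(
        OutlierRecord(f"P{i}", 3, 10.0, 9.0, 1.0, v, "none") for i, v in enumerate(values)
    )
    return OutlierReport(records=records, upper=3.0, lower=-2.0, sigma_hat=1.0, model_id=4)


class TestDetectOutliers:
    def test_asymmetric_thresholds(self):
        above, below = detect_outliers(_report([3.5, 2.9, -1.9, -2.5]))
        assert [r.studentized for r in above] == [3.5]
        assert [r.studentized for r in below] == [-2.5]

    def test_symmetric_thresholds_drop_below_group(self):
        above, below = detect_outliers(_report([3.5, 2.9, -1.9, -2.5]), lower=-3.0)
        assert [r.studentized for r in above] == [3.5]
        assert below == []

    def test_empty_report(self):
        above, below = detect_outliers(_report([]))
        assert above == [] and below == []

    def test_raising_upper_threshold_is_monotone(self):
        values = list(np.random.default_rng(5).normal(0, 2, 50))
        report = _report(values)
        prev = {r.accession for r in detect_outliers(report, upper=1.0)[0]}
        for upper in (1.5, 2.0, 3.0, 4.0):
            cur = {r.accession for r in detect_outliers(report, upper=upper)[0]}
            assert cur <= prev
            prev = cur

    def test_ordering_by_magnitude(self):
        above, _ = detect_outliers(_report([3.2, 5.0, 4.1]))
        assert [r.studentized for r in above] == [5.0, 4.1, 3.2]


def exact_tail(x, n, M, N):
    """Upper-tail hypergeometric probability by exact integer enumeration."""
    total = math.comb(N, n)
    hits = sum(math.comb(M, k) * math.comb(N - M, n - k)
               for k in range(x, min(n, M) + 1))
    return hits / total


class TestHypergeomTail:
    def test_full_support_at_zero(self):
        assert hypergeom_tail(0, 3, 4, 10) == 1.0
        assert hypergeom_tail(0, 0, 0, 5) == 1.0

    def test_small_worked_case(self):
        # (C(4,2)·C(6,1) + C(4,3)·C(6,0)) / C(10,3) = 40/120
        assert hypergeom_tail(2, 3, 4, 10) == pytest.approx(1 / 3)

    def test_matches_exhaustive_enumeration_for_all_small_instances(self):
        for N in range(1, 13):
            for M in range(N + 1):
                for n in range(N + 1):
                    for x in range(n + 2):
                        assert hypergeom_tail(x, n, M, N) == pytest.approx(
                            exact_tail(x, n, M, N), abs=1e-12
                        ), (x, n, M, N)

    def test_non_increasing_in_x(self):
        vals = [hypergeom_tail(x, 50, 30, 200) for x in range(51)]
        assert all(a >= b - 1e-15 for a, b in zip(vals, vals[1:]))

    def test_infeasible_counts(self):
        assert hypergeom_tail(5, 4, 10, 20) == 0.0
        assert hypergeom_tail(5, 10, 4, 20) == 0.0
        with pytest.raises(ValueError):
            hypergeom_tail(1, 5, 30, 20)


class TestBonferroni:
    def test_published_threshold(self):
        assert f"{bonferroni(0.05, 211):.10f}" == "0.0002369668"

    @pytest.mark.parametrize("alpha,c,expected", [(0.05, 1, 0.05), (1.0, 4, 0.25)])
    def test_simple_cases(self, alpha, c, expected):
        assert bonferroni(alpha, c) == pytest.approx(expected)

    @pytest.mark.parametrize("alpha,c", [(0.0, 3), (1.5, 3), (0.05, 0), (0.05, 2.5)])
    def test_invalid_inputs(self, alpha, c):
        with pytest.raises(ValueError):
            bonferroni(alpha, c)


class TestEnrichment:
    def _dataset(self):
        prots = []
        for i in range(40):
            locs = {"common"} if i % 2 == 0 else {"rare"} if i < 8 else {"other"}
            prots.append(protein(f"P{i}", (5, 5), locations=locs))
        return prots

    def test_absent_category_never_significant(self):
        dataset = self._dataset()
        outliers = [p for p in dataset if "common" in p.locations][:5]
        results = enrich_categories(outliers, dataset)
        absent = next(r for r in results if r.x == 0)
        assert absent.p_value == 1.0 and not absent.significant

    def test_outliers_must_be_subset_of_dataset(self):
        dataset = self._dataset()
        with pytest.raises(ValueError):
            enrich_categories([protein("STRANGER", (3,))], dataset)

    def test_empty_outliers_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert enrich_categories([], self._dataset()) == []

    def test_planted_enrichment_detected(self):
        rng = np.random.default_rng(77)
        dataset = []
        for i in range(2000):
            locs = set()
            if rng.random() < 0.05:
                locs.add("planted")
            locs.add(f"bg_{rng.integers(0, 20)}")
            dataset.append(protein(f"P{i}", (5, 5), locations=locs))
        with_planted = [p for p in dataset if "planted" in p.locations]
        without = [p for p in dataset if "planted" not in p.locations]
        outliers = with_planted[:25] + without[:75]  # 25% planted among outliers
        results = enrich_categories(outliers, dataset)
        top = results[0]
        assert top.category == "planted"
        assert top.significant and top.direction == "over"

    def test_results_sorted_by_p(self):
        dataset = self._dataset()
        outliers = dataset[:6]
        results = enrich_categories(outliers, dataset)
        ps = [r.p_value for r in results]
        assert ps == sorted(ps)
        for r in results:
            assert r.x <= min(r.n, r.M)
            assert r.significant == (r.p_value < r.alpha_corrected)
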