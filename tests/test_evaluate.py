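"""Held-out evaluation harness, model comparison and cohort summaries."""

import numpy as np
import pytest

import ognmf as og
from ognmf.cohort_io import ColumnScaling, FeatureMatrix
from ognmf.evaluate import HeldOut
from ognmf.solver import Factorization, SolverConfig, TraceLog

from conftest import make_lowrank_fm


def exact_factorization(fm):
    """A factorization whose reconstruction equals fm.X exactly."""
    n = fm.X.shape[0]
    trace = TraceLog(objective=[0.0], step=[0.0])
    return Factorization(U=np.eye(n), V=fm.X.copy(), k=n, trace=trace,
                         converged=True)


class TestHoldout:
    def test_fraction_of_observed_cells(self, encoded):
        j = encoded.column_index("chol_hdl")
        n_obs = int(encoded.M[:, j].sum())
        fm_train, held = og.holdout_chol_hdl(encoded, 0.2, seed=0)
        assert len(held) == round(0.2 * n_obs)

    def test_masking_contract(self, encoded):
        fm_train, held = og.holdout_chol_hdl(encoded, 0.2, seed=1)
        j = encoded.column_index("chol_hdl")
        assert np.all(encoded.M[held.rows, j] == 1)
        assert np.all(fm_train.M[held.rows, j] == 0)
        # held-out cells carry the placeholder, not the true value
        remaining = fm_train.M[:, j] == 1
        placeholder = fm_train.X[remaining, j].mean()
        assert np.allclose(fm_train.X[held.rows, j], placeholder)

    def test_disjoint_seeds_overlap_near_hypergeometric_mean(self, encoded):
        j = encoded.column_index("chol_hdl")
        n_obs = int(encoded.M[:, j].sum())
        m = round(0.2 * n_obs)
        expected = m * m / n_obs  # hypergeometric mean overlap
        overlaps = []
        for s in range(10):
            _, h1 = og.holdout_chol_hdl(encoded, 0.2, seed=2 * s)
            _, h2 = og.holdout_chol_hdl(encoded, 0.2, seed=2 * s + 1)
            overlaps.append(len(np.intersect1d(h1.rows, h2.rows)))
        assert np.mean(overlaps) == pytest.approx(expected, abs=4.0)

    def test_degenerate_fractions_rejected(self, encoded):
        with pytest.raises(ValueError):
            og.holdout_chol_hdl(encoded, 0.0)
        with pytest.raises(ValueError):
            og.holdout_chol_hdl(encoded, 1.0)
        with pytest.raises(ValueError):
            og.holdout_chol_hdl(encoded, 1e-6)  # zero cells held out


class TestRiskAccuracy:
    def test_perfect_reconstruction_scores_one(self):
        fm, sex = make_lowrank_fm(n=40, k=2, seed=0)
        _, held = og.holdout_chol_hdl(fm, 0.2, seed=0)
        result = og.risk_accuracy(exact_factorization(fm), fm, held, sex)
        assert result.accuracy == 1.0
        assert np.trace(result.confusion) == result.confusion.sum() == len(held)

    def test_one_level_shift_scores_zero_off_diagonal(self):
        # true ratios at the male level-2 centre; reconstruction at level 3
        lo, hi = 1.8, 11.5
        sc = ColumnScaling("continuous", lo=lo, hi=hi)
        true_ratio, shifted_ratio = 5.8, 9.45
        n = 8
        X = np.full((n, 2), sc.encode(true_ratio))
        fm = FeatureMatrix(X=X, M=np.ones_like(X), columns=["f0", "chol_hdl"],
                           scaling={"f0": sc, "chol_hdl": sc})
        held = HeldOut("chol_hdl", np.arange(n),
                       np.full(n, true_ratio), X[:, 1].copy())
        fact = exact_factorization(fm)
        fact.V = np.full((n, 2), sc.encode(shifted_ratio))
        result = og.risk_accuracy(fact, fm, held, ["M"] * n)
        assert result.accuracy == 0.0
        assert result.confusion[1, 2] == n  # all mass on the 2 -> 3 cell

    def test_noiseless_lowrank_cohort_accuracy_high(self):
        """With true rank-k structure the imputed ratios band correctly."""
        fm, sex = make_lowrank_fm(n=100, k=3, seed=1)
        fm_train, held = og.holdout_chol_hdl(fm, 0.1, seed=1)
        fact = og.fit_ognmf(fm_train.X, fm_train.M,
                            SolverConfig(k=3, epsilon=1e-10, max_iter=3000,
                                         ortho_weight=0.0, seed=1))
        result = og.risk_accuracy(fact, fm, held, sex)
        assert result.accuracy >= 0.9

    def test_missing_sex_for_heldout_row_rejected(self):
        fm, sex = make_lowrank_fm(n=20, k=2, seed=2)
        _, held = og.holdout_chol_hdl(fm, 0.2, seed=2)
        sex = list(sex)
        sex[int(held.rows[0])] = None
        with pytest.raises(ValueError, match="sex"):
            og.risk_accuracy(exact_factorization(fm), fm, held, sex)

    def test_accuracy_series_tracks_snapshots(self):
        fm, sex = make_lowrank_fm(n=40, k=2, seed=3)
        fm_train, held = og.holdout_chol_hdl(fm, 0.2, seed=3)
        fact = og.fit_ognmf(fm_train.X, fm_train.M,
                            SolverConfig(k=2, seed=3, store_factors=True))
        result = og.risk_accuracy(fact, fm, held, sex)
        assert len(result.accuracy_series) == fact.trace.n_iter
        assert len(result.step_series) == fact.trace.n_iter
        assert result.membership_series.shape == (fact.trace.n_iter, 4)
        assert result.accuracy_series[-1] == pytest.approx(result.accuracy)


class TestBaselines:
    def test_ognmf_beats_mean_baseline_on_lowrank_cohorts(self):
        """Paired comparison over 20 seeds on noiseless rank-3 cohorts."""
        wins = 0
        for seed in range(20):
            fm, sex = make_lowrank_fm(n=60, k=3, seed=seed)
            fm_train, held = og.holdout_chol_hdl(fm, 0.2, seed=seed)
            fact = og.fit_ognmf(fm_train.X, fm_train.M,
                                SolverConfig(k=3, epsilon=1e-9, max_iter=2000,
                                             ortho_weight=0.0, seed=seed))
            a = og.risk_accuracy(fact, fm, held, sex).accuracy
            b = og.column_mean_accuracy(fm_train, held, sex)
            wins += a > b
        assert wins >= 16

    def test_mlr_baseline_beats_mean_on_default_cohort(self, default_cohort, encoded):
        cohort, _ = default_cohort
        fm_train, held = og.holdout_chol_hdl(encoded, 0.2, seed=5)
        sex = cohort.column("gender")
        mlr = og.mlr_holdout_accuracy(encoded, fm_train, held, sex)
        mean = og.column_mean_accuracy(fm_train, held, sex)
        assert mlr > mean


class TestCompareModels:
    @pytest.mark.parametrize(
        "a, b, expected",
        [(0.6759, 0.6159, 9.7), (0.5, 0.5, 0.0), (0.5, 0.25, 100.0)],
    )
    def test_relative_difference_percent(self, a, b, expected):
        assert og.compare_models(a, b) == expected

    def test_invalid_accuracies_rejected(self):
        with pytest.raises(ValueError):
            og.compare_models(0.0, 0.5)
        with pytest.raises(ValueError):
            og.compare_models(0.5, 1.5)


class TestCohortSummary:
    def test_identical_groups_yield_null_tests(self):
        recs = []
        for ssn in ("SSN-", "SSN+"):
            for v in (180.0, 200.0, 220.0, 240.0):
                recs.append(og.PatientRecord(
                    ssn_status=ssn, chol=v, tg=v / 2, age=50.0 + v / 100,
                    hbsab="pos" if v > 200 else "neg", hbsag="neg",
                ))
        summary = og.cohort_summary(og.CohortTable(recs))
        t_rows = summary.tests[summary.tests["test"] == "t"]
        assert np.allclose(t_rows["stat_primary"], 0.0)
        assert np.allclose(t_rows["p_primary"], 1.0)
        prop = summary.tests[summary.tests["test"] == "two-proportion"]
        assert np.allclose(prop["p_secondary"], 1.0)

    def test_two_proportion_from_printed_counts(self):
        # 104/199 vs 39/101 positive: 52% vs 39%, significant without correction
        recs = []
        for n, pos, ssn in ((199, 104, "SSN-"), (101, 39, "SSN+")):
            for i in range(n):
                recs.append(og.PatientRecord(
                    ssn_status=ssn, hbsab="pos" if i < pos else "neg",
                    hbsag="neg", chol=200.0 + i % 3, age=50.0, tg=150.0,
                ))
        summary = og.cohort_summary(og.CohortTable(recs))
        pct = summary.binary.loc[("hbsab", "SSN-"), "percent"]
        assert round(pct) == 52
        assert round(summary.binary.loc[("hbsab", "SSN+"), "percent"]) == 39
        row = summary.tests.loc["hbsab"]
        assert row["p_secondary"] < 0.05  # uncorrected chi-square

    def test_default_cohort_reproduces_group_means(self, default_cohort):
        cohort, _ = default_cohort
        summary = og.cohort_summary(cohort)
        for group, target, sd, n in (("SSN-", 219.6, 41.1, 199),
                                     ("SSN+", 208.9, 39.0, 101)):
            mean = summary.continuous.loc[("chol", group), "mean"]
            assert abs(mean - target) < 3 * sd / np.sqrt(n)

    def test_group_difference_directions(self):
        """SSN- runs higher on CHOL, TG and age in nearly every draw."""
        hits = 0
        for seed in range(10):
            cohort, _ = og.generate_cohort(seed=100 + seed)
            s = og.cohort_summary(cohort).continuous
            ok = all(
                s.loc[(v, "SSN-"), "mean"] > s.loc[(v, "SSN+"), "mean"]
                for v in ("chol", "tg", "age")
            )
            hits += ok
        assert hits >= 9

    def test_single_group_rejected(self):
        recs = [og.PatientRecord(ssn_status="SSN-", chol=200.0)] * 4
        with pytest.raises(ValueError):
            og.cohort_summary(og.CohortTable(recs))


class TestExportFigures:
    def test_writes_plots_and_deterministic_data(self, tmp_path):
        fm, sex = make_lowrank_fm(n=40, k=2, seed=4)
        fm_train, held = og.holdout_chol_hdl(fm, 0.2, seed=4)
        fact = og.fit_ognmf(fm_train.X, fm_train.M,
                            SolverConfig(k=2, seed=4, store_factors=True))
        result = og.risk_accuracy(fact, fm, held, sex)
        out1, out2 = tmp_path / "a", tmp_path / "b"
        files = og.export_figures(result, fact.trace, out1)
        og.export_figures(result, fact.trace, out2)
        names = {f.name for f in files}
        assert {"membership_bands.png", "step_error.png", "accuracy.png",
                "step_error.csv"} <= names
        for csv in ("membership_bands.csv", "step_error.csv", "accuracy.csv"):
            assert (out1 / csv).read_bytes() == (out2 / csv).read_bytes()

    def test_empty_result_rejected(self, tmp_path):
        fm, sex = make_lowrank_fm(n=20, k=2, seed=5)
        _, held = og.holdout_chol_hdl(fm, 0.2, seed=5)
        result = og.risk_accuracy(exact_factorization(fm), fm, held, sex)
        empty_trace = TraceLog()
        with pytest.raises(ValueError):
            og.export_figures(result, empty_trace, tmp_path / "c")
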