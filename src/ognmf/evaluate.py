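"""Experiment harness: held-out imputation of the CHOL/HDL ratio, risk
accuracy, solver trajectories, model comparison, and cohort summaries.

The central experiment masks a random fraction of the observed CHOL/HDL
cells, refits the masked factorization, imputes the held-out ratios from the
reconstruction, bands them into the four risk levels and scores exact-match
accuracy against the risk levels implied by the true ratios.  A
column-mean-imputation baseline and a multiclass logistic regression
baseline provide the comparison points, and per-iteration factor snapshots
yield accuracy- and step-error-versus-iteration trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import CohortTable, FeatureMatrix
from .risk import RiskThresholds, classify_ratio, soft_assign
from .solver import Factorization, impute

__all__ = [
    "HeldOut",
    "EvalResult",
    "holdout_chol_hdl",
    "risk_accuracy",
    "column_mean_accuracy",
    "mlr_holdout_accuracy",
    "compare_models",
    "CohortSummary",
    "cohort_summary",
    "export_figures",
]

RATIO_COLUMN = "chol_hdl"


@dataclass
class HeldOut:
    """Cells masked for evaluation, with their true values."""

    column: str
    rows: np.ndarray
    true_values: np.ndarray  # clinical units
    true_scaled: np.ndarray

    def cells(self, fm: FeatureMatrix) -> list[tuple[int, str]]:
        return [(int(i), self.column) for i in self.rows]

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class EvalResult:
    """Held-out risk-prediction outcome.

    ``accuracy_series`` / ``membership_series`` are per solver iteration
    (empty unless the fit stored factor snapshots); ``step_series`` mirrors
    the solver trace.
    """

    accuracy: float
    confusion: np.ndarray
    heldout: HeldOut
    predicted_values: np.ndarray
    predicted_levels: np.ndarray
    true_levels: np.ndarray
    accuracy_series: np.ndarray = field(default_factory=lambda: np.empty(0))
    step_series: np.ndarray = field(default_factory=lambda: np.empty(0))
    membership_series: np.ndarray = field(default_factory=lambda: np.empty((0, 4)))


def holdout_chol_hdl(
    fm: FeatureMatrix, fraction: float = 0.2, seed: int = 0
) -> tuple[FeatureMatrix, HeldOut]:
    """Mask a seeded random fraction of observed CHOL/HDL cells.

    The held-out cells get mask 0 and, like every unobserved cell, the
    placeholder value (mean of the cells still observed) in the training
    copy; their true scaled and clinical values are recorded for scoring.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"holdout fraction must lie in (0, 1), got {fraction}")
    j = fm.column_index(RATIO_COLUMN)
    observed = np.flatnonzero(fm.M[:, j] == 1)
    n_held = int(round(fraction * len(observed)))
    if n_held == 0:
        raise ValueError(
            f"fraction {fraction} of {len(observed)} observed cells leaves "
            "zero held-out cells"
        )
    rng = np.random.default_rng(seed)
    held = np.sort(rng.choice(observed, size=n_held, replace=False))

    fm_train = fm.copy()
    fm_train.M[held, j] = 0
    remaining = np.flatnonzero(fm_train.M[:, j] == 1)
    if len(remaining) == 0:
        raise ValueError("holdout would leave the ratio column empty")
    placeholder = float(fm_train.X[remaining, j].mean())
    true_scaled = fm.X[held, j].copy()
    fm_train.X[held, j] = placeholder

    sc = fm.scaling[RATIO_COLUMN]
    true_values = np.asarray(sc.decode(true_scaled), dtype=float)
    return fm_train, HeldOut(
        column=RATIO_COLUMN,
        rows=held,
        true_values=true_values,
        true_scaled=true_scaled,
    )


def _classify_many(sex, values, thresholds) -> np.ndarray:
    return np.array(
        [int(classify_ratio(s, v, thresholds)) for s, v in zip(sex, values)]
    )


def risk_accuracy(
    fact: Factorization,
    fm: FeatureMatrix,
    heldout: HeldOut,
    sex,
    thresholds: RiskThresholds | None = None,
) -> EvalResult:
    """Score held-out risk-level prediction from the fitted factorization.

    ``sex`` gives 'M'/'F' per cohort row (a missing entry for a held-out row
    is an error, since the risk bands are sex-specific).  If the fit stored
    per-iteration snapshots, the accuracy and mean soft-membership
    trajectories are evaluated at every iteration.
    """
    thresholds = thresholds or RiskThresholds()
    if len(heldout) == 0:
        raise ValueError("held-out set is empty")
    sex = list(sex)
    held_sex = []
    for i in heldout.rows:
        s = sex[int(i)]
        if s not in ("M", "F"):
            raise ValueError(f"missing or invalid sex for held-out row {i}: {s!r}")
        held_sex.append(s)

    cells = heldout.cells(fm)
    pred_values = impute(fact, fm, cells)
    pred_levels = _classify_many(held_sex, np.maximum(pred_values, 1e-9), thresholds)
    true_levels = _classify_many(held_sex, heldout.true_values, thresholds)

    confusion = np.zeros((4, 4), dtype=int)
    for t, p in zip(true_levels, pred_levels):
        confusion[t - 1, p - 1] += 1
    accuracy = float(np.trace(confusion) / confusion.sum())

    acc_series, mem_series = [], []
    if fact.trace.snapshots is not None:
        for U, V in fact.trace.snapshots:
            snap = Factorization(U=U, V=V, k=fact.k, trace=fact.trace, converged=True)
            vals = impute(snap, fm, cells)
            levels = _classify_many(held_sex, np.maximum(vals, 1e-9), thresholds)
            acc_series.append(float(np.mean(levels == true_levels)))
            weights = np.array([
                soft_assign(s, max(v, 1e-9), thresholds).weights
                for s, v in zip(held_sex, vals)
            ])
            mem_series.append(weights.mean(axis=0))

    return EvalResult(
        accuracy=accuracy,
        confusion=confusion,
        heldout=heldout,
        predicted_values=pred_values,
        predicted_levels=pred_levels,
        true_levels=true_levels,
        accuracy_series=np.array(acc_series),
        step_series=np.array(fact.trace.step),
        membership_series=(
            np.array(mem_series) if mem_series else np.empty((0, 4))
        ),
    )


def column_mean_accuracy(
    fm_train: FeatureMatrix,
    heldout: HeldOut,
    sex,
    thresholds: RiskThresholds | None = None,
) -> float:
    """Accuracy of the trivial baseline that imputes every held-out ratio
    with the training-observed column mean."""
    thresholds = thresholds or RiskThresholds()
    j = fm_train.column_index(heldout.column)
    observed = fm_train.M[:, j] == 1
    sc = fm_train.scaling[heldout.column]
    mean_value = float(sc.decode(fm_train.X[observed, j].mean()))
    sex = list(sex)
    held_sex = [sex[int(i)] for i in heldout.rows]
    pred = _classify_many(held_sex, np.full(len(heldout), mean_value), thresholds)
    true = _classify_many(held_sex, heldout.true_values, thresholds)
    return float(np.mean(pred == true))


def compare_models(acc_a: float, acc_b: float) -> float:
    """Relative accuracy difference ``100 (a - b) / b`` in percent, to one
    decimal (positive when model A is more accurate)."""
    if not (0 < acc_a <= 1 and 0 < acc_b <= 1):
        raise ValueError("accuracies must lie in (0, 1]")
    return round(100.0 * (acc_a - acc_b) / acc_b, 1)


def mlr_holdout_accuracy(
    fm: FeatureMatrix,
    fm_train: FeatureMatrix,
    heldout: HeldOut,
    sex,
    thresholds: RiskThresholds | None = None,
    lam: float = 1e-3,
    seed: int = 0,
) -> float:
    """Held-out risk accuracy of the multiclass logistic regression baseline.

    The MLR predicts the risk level from every encoded feature except the
    ratio column itself (unobserved features become NaN and are mean-imputed
    by the fit); it trains on the rows whose ratio stayed observed after the
    holdout and is scored on the held-out rows, so it sees exactly the same
    information as the factorization.
    """
    from .baseline import fit_mlr, predict_mlr

    thresholds = thresholds or RiskThresholds()
    j = fm.column_index(heldout.column)
    keep = [c for c in range(fm.X.shape[1]) if c != j]
    F = fm_train.X[:, keep].copy()
    F[fm_train.M[:, keep] == 0] = np.nan

    sex = list(sex)
    sc = fm.scaling[heldout.column]
    train_rows = np.flatnonzero(fm_train.M[:, j] == 1)
    train_rows = np.array([i for i in train_rows if sex[i] in ("M", "F")])
    labels = _classify_many(
        [sex[i] for i in train_rows],
        np.asarray(sc.decode(fm.X[train_rows, j]), dtype=float),
        thresholds,
    )
    model = fit_mlr(F[train_rows], labels, lam=lam, seed=seed)
    pred, _ = predict_mlr(model, F[heldout.rows])
    true = _classify_many(
        [sex[int(i)] for i in heldout.rows], heldout.true_values, thresholds
    )
    return float(np.mean(pred == true))


# ---------------------------------------------------------------------------
# Cohort summaries


@dataclass
class CohortSummary:
    """Per-group descriptive statistics with two-group tests."""

    continuous: pd.DataFrame  # index (variable, group): n, mean, sd, min, max
    binary: pd.DataFrame  # index (variable, group): n_pos, n, percent
    tests: pd.DataFrame  # per variable: statistic and p-values


_SUMMARY_CONTINUOUS = ("age", "glu", "chol", "tg", "chol_hdl", "ldl", "tsh", "psa")
_SUMMARY_BINARY = {"hbsab": "pos", "hbsag": "pos"}


def cohort_summary(
    cohort: CohortTable, group_by: str = "ssn_status"
) -> CohortSummary:
    """Group-stratified summary of a cohort with between-group tests.

    Continuous variables get per-group n/mean/SD/min/max plus Welch and
    pooled two-sample t-tests; binary variables get positive counts and
    percentages plus a two-proportion chi-square test, reported both with
    and without Yates continuity correction.  A variable with fewer than two
    observations in a group has its test skipped (statistics are still
    reported).
    """
    groups = sorted({r.get(group_by) for r in cohort.records if r.get(group_by)})
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups by {group_by!r}, found {groups}")

    cont_rows, bin_rows, test_rows = [], [], []
    by_group = {
        g: [r for r in cohort.records if r.get(group_by) == g] for g in groups
    }
    if any(len(v) == 0 for v in by_group.values()):
        raise ValueError("both groups must be non-empty")

    for var in _SUMMARY_CONTINUOUS:
        samples = {}
        for g in groups:
            vals = np.array(
                [r.get(var) for r in by_group[g] if r.get(var) is not None],
                dtype=float,
            )
            samples[g] = vals
            if len(vals):
                cont_rows.append({
                    "variable": var, "group": g, "n": len(vals),
                    "mean": vals.mean(), "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                    "min": vals.min(), "max": vals.max(),
                })
        a, b = samples[groups[0]], samples[groups[1]]
        if len(a) < 2 or len(b) < 2:
            import warnings

            warnings.warn(f"too few observations to test {var!r}; skipped")
            continue
        t_w, p_w = stats.ttest_ind(a, b, equal_var=False)
        t_p, p_p = stats.ttest_ind(a, b, equal_var=True)
        test_rows.append({
            "variable": var, "test": "t",
            "stat_welch": float(t_w), "p_welch": float(p_w),
            "stat_pooled": float(t_p), "p_pooled": float(p_p),
        })

    for var, pos_level in _SUMMARY_BINARY.items():
        counts = {}
        for g in groups:
            vals = [r.get(var) for r in by_group[g] if r.get(var) is not None]
            n_pos = sum(v == pos_level for v in vals)
            counts[g] = (n_pos, len(vals))
            bin_rows.append({
                "variable": var, "group": g, "n_pos": n_pos, "n": len(vals),
                "percent": 100.0 * n_pos / len(vals) if vals else np.nan,
            })
        (a_pos, a_n), (b_pos, b_n) = counts[groups[0]], counts[groups[1]]
        if min(a_n, b_n) < 2:
            continue
        table = np.array([[a_pos, a_n - a_pos], [b_pos, b_n - b_pos]])
        if (table.sum(axis=0) == 0).any():
            # a degenerate margin (all-positive or all-negative cohort-wide):
            # no association is testable
            p_corr = p_unc = 1.0
            s_corr = s_unc = 0.0
        else:
            s_corr, p_corr = stats.chi2_contingency(table, correction=True)[:2]
            s_unc, p_unc = stats.chi2_contingency(table, correction=False)[:2]
        test_rows.append({
            "variable": var, "test": "two-proportion",
            "stat_welch": float(s_corr), "p_welch": float(p_corr),
            "stat_pooled": float(s_unc), "p_pooled": float(p_unc),
        })

    tests = pd.DataFrame(test_rows).set_index("variable") if test_rows else pd.DataFrame()
    if not tests.empty:
        tests = tests.rename(columns={
            "stat_welch": "stat_primary", "p_welch": "p_primary",
            "stat_pooled": "stat_secondary", "p_pooled": "p_secondary",
        })
    return CohortSummary(
        continuous=pd.DataFrame(cont_rows).set_index(["variable", "group"]),
        binary=pd.DataFrame(bin_rows).set_index(["variable", "group"]),
        tests=tests,
    )


# ---------------------------------------------------------------------------
# Figures


def export_figures(result: EvalResult, trace, outdir) -> list:
    """Write the three diagnostic figures and their backing CSV data.

    band plot — mean soft-membership weight per risk level per iteration
    (band widths); step-error curve; accuracy curve.  The CSV files backing
    the plots are byte-deterministic for identical inputs.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if len(result.heldout) == 0 or trace.n_iter == 0:
        raise ValueError("empty evaluation result; nothing to plot")

    written = []
    iters = np.arange(1, trace.n_iter + 1)

    if result.membership_series.size:
        mem = result.membership_series
        df = pd.DataFrame(
            mem, columns=[f"level_{j}" for j in range(1, 5)],
        )
        df.insert(0, "iteration", np.arange(1, len(mem) + 1))
        csv = outdir / "membership_bands.csv"
        df.to_csv(csv, index=False)
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.stackplot(
            df["iteration"], mem.T,
            labels=[f"level {j}" for j in range(1, 5)], alpha=0.8,
        )
        ax.set_xlabel("iteration")
        ax.set_ylabel("mean membership weight")
        ax.set_title("Soft-assignment band widths by risk level")
        ax.legend(loc="upper right", fontsize=8)
        fig.savefig(outdir / "membership_bands.png", dpi=120)
        plt.close(fig)
        written += [csv, outdir / "membership_bands.png"]

    df = pd.DataFrame({"iteration": iters, "step_error": trace.step})
    csv = outdir / "step_error.csv"
    df.to_csv(csv, index=False)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.semilogy(iters, trace.step)
    ax.set_xlabel("iteration")
    ax.set_ylabel("step error (relative objective change)")
    ax.set_title("Convergence of the masked factorization")
    fig.savefig(outdir / "step_error.png", dpi=120)
    plt.close(fig)
    written += [csv, outdir / "step_error.png"]

    if result.accuracy_series.size:
        df = pd.DataFrame({
            "iteration": np.arange(1, len(result.accuracy_series) + 1),
            "accuracy": result.accuracy_series,
        })
        csv = outdir / "accuracy.csv"
        df.to_csv(csv, index=False)
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(df["iteration"], 100 * df["accuracy"])
        ax.set_xlabel("iteration")
        ax.set_ylabel("held-out risk accuracy (%)")
        ax.set_title("Predictive accuracy per iteration")
        fig.savefig(outdir / "accuracy.png", dpi=120)
        plt.close(fig)
        written += [csv, outdir / "accuracy.png"]

    return written
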