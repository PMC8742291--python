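"""Synthetic screening-cohort generator.

Emulates a community hepatitis-B screening cohort stratified by social
security number status (SSN−, the operational proxy for undocumented
immigrants, versus SSN+): per-group truncated-normal laboratory marginals,
Bernoulli serology, demographic proportions, subset-tested PSA and optional
missing-completely-at-random (MCAR) masking.  Defaults reproduce the
published group-stratified summary statistics of the study population
(n = 199 SSN−, 101 SSN+).

Because truncating a normal at the printed min/max shifts its mean and
shrinks its SD (by up to ~20 mg/dL for the right-skewed triglycerides), the
generator *moment-matches*: it solves for the underlying (mu, sigma) whose
truncated distribution has exactly the requested mean and SD, so simulated
sample moments are unbiased for the requested values at any n.

The module also provides a plain low-rank testbed (``generate_lowrank``)
with known factors for validating the masked factorization solver.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort_io import CohortTable, PatientRecord, default_codebook

__all__ = [
    "Marginal",
    "GroupSpec",
    "CohortSpec",
    "GroundTruth",
    "truncated_normal_params",
    "generate_cohort",
    "generate_lowrank",
    "apply_missingness",
]


@dataclass(frozen=True)
class Marginal:
    """Target mean/SD and truncation bounds of one continuous variable."""

    mean: float
    sd: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"SD must be > 0, got {self.sd}")
        if not self.min < self.max:
            raise ValueError(f"need min < max, got [{self.min}, {self.max}]")


@dataclass(frozen=True)
class GroupSpec:
    """Generative parameters for one SSN stratum."""

    n: int
    continuous: dict[str, Marginal]
    hbsab_pos_rate: float
    hbsag_pos_rate: float
    male_prop: float
    race_props: dict[str, float]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size n must be >= 1")
        for name, rate in (
            ("hbsab_pos_rate", self.hbsab_pos_rate),
            ("hbsag_pos_rate", self.hbsag_pos_rate),
            ("male_prop", self.male_prop),
        ):
            if not 0 <= rate <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {rate}")
        total = sum(self.race_props.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"race_props must sum to 1, got {total}")


def _default_groups() -> dict[str, GroupSpec]:
    # Published group-stratified marginals of the 2004 screening cohort.
    ssn_neg = GroupSpec(
        n=199,
        continuous={
            "age": Marginal(53.9, 14.2, 16, 93),
            "glu": Marginal(93.2, 24.5, 47, 226),
            "chol": Marginal(219.6, 41.1, 140, 354),
            "tg": Marginal(173.2, 91.8, 46, 663),
            "chol_hdl": Marginal(3.9, 1.1, 1.8, 8.6),
            "ldl": Marginal(126.8, 33.3, 55, 238),
            "tsh": Marginal(2.1, 1.2, 0.1, 6.37),
            "psa": Marginal(1.1, 0.7, 0.02, 4.2),
        },
        hbsab_pos_rate=104 / 199,
        hbsag_pos_rate=18 / 199,
        male_prop=106 / 199,
        race_props={
            "chinese_american": 132 / 199,
            "other_asian_american": 52 / 199,
            "other": 15 / 199,
        },
    )
    ssn_pos = GroupSpec(
        n=101,
        continuous={
            "age": Marginal(48.7, 12.0, 20, 75),
            "glu": Marginal(88.2, 18.3, 58, 194),
            "chol": Marginal(208.9, 39.0, 129, 341),
            "tg": Marginal(148.4, 104.2, 14, 801),
            "chol_hdl": Marginal(3.8, 1.5, 1.9, 12.7),
            "ldl": Marginal(120.1, 37.0, 0.9, 214),
            "tsh": Marginal(2.3, 1.5, 0.3, 12.8),
            "psa": Marginal(1.1, 0.7, 0.02, 4.2),
        },
        hbsab_pos_rate=39 / 101,
        hbsag_pos_rate=8 / 101,
        male_prop=58 / 101,
        race_props={
            "chinese_american": 76 / 101,
            "other_asian_american": 12 / 101,
            "other": 13 / 101,
        },
    )
    return {"SSN-": ssn_neg, "SSN+": ssn_pos}


@dataclass(frozen=True)
class CohortSpec:
    """Full generative specification of a synthetic screening cohort.

    ``psa_tested`` restricts the PSA column to that many rows cohort-wide
    (subset-tested missingness); ``missing_rates`` adds MCAR missingness per
    feature on top.  ``copula_rho`` optionally couples the continuous labs
    within each group through an exchangeable Gaussian copula (defaults to
    independence — the published tables carry no covariance information).
    HDL is derived as CHOL divided by the drawn ratio, kept within
    ``hdl_bounds`` by redrawing the ratio, so ``chol_hdl`` is exactly
    CHOL/HDL by construction.
    """

    groups: dict[str, GroupSpec] = field(default_factory=_default_groups)
    psa_tested: int | None = 43
    missing_rates: dict[str, float] = field(default_factory=dict)
    hdl_bounds: tuple[float, float] = (15.0, 150.0)
    copula_rho: float | None = None
    calibrate: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for feat, rate in self.missing_rates.items():
            if not 0 <= rate < 1:
                raise ValueError(
                    f"missing rate for {feat!r} must lie in [0, 1), got {rate}"
                )
        n_total = sum(g.n for g in self.groups.values())
        if self.psa_tested is not None and not 0 < self.psa_tested <= n_total:
            raise ValueError(f"psa_tested must lie in (0, {n_total}]")
        if self.copula_rho is not None and not -0.2 <= self.copula_rho < 1:
            raise ValueError("copula_rho must lie in [-0.2, 1)")

    def with_sizes(self, n_ssn_neg: int, n_ssn_pos: int) -> "CohortSpec":
        groups = {
            "SSN-": replace(self.groups["SSN-"], n=n_ssn_neg),
            "SSN+": replace(self.groups["SSN+"], n=n_ssn_pos),
        }
        return replace(self, groups=groups)


@dataclass
class GroundTruth:
    """Everything the generator knew: complete pre-missingness values,
    group labels, calibrated truncated-normal parameters, and (for the
    low-rank testbed) the true factors and clean matrix."""

    frame: pd.DataFrame | None = None
    params: dict | None = None
    U: np.ndarray | None = None
    V: np.ndarray | None = None
    X_clean: np.ndarray | None = None


@functools.lru_cache(maxsize=256)
def truncated_normal_params(
    mean: float, sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """Underlying (mu, sigma) whose [lo, hi]-truncated normal has the given
    mean and SD (two-dimensional moment match, solved numerically)."""

    def resid(p):
        mu, log_sigma = p
        sigma = np.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        d = stats.truncnorm(a, b, loc=mu, scale=sigma)
        return [d.mean() - mean, d.std() - sd]

    sol = optimize.least_squares(resid, [mean, np.log(sd)], method="lm")
    mu, sigma = float(sol.x[0]), float(np.exp(sol.x[1]))
    if max(abs(r) for r in resid(sol.x)) > 1e-6 * sd:
        warnings.warn(
            f"moment match failed for mean={mean}, sd={sd} on [{lo}, {hi}]; "
            "falling back to nominal parameters",
            stacklevel=2,
        )
        return mean, sd
    return mu, sigma


def _sample_truncnorm(marg: Marginal, size: int, rng, calibrate: bool,
                      uniforms: np.ndarray | None = None) -> np.ndarray:
    mu, sigma = (
        truncated_normal_params(marg.mean, marg.sd, marg.min, marg.max)
        if calibrate
        else (marg.mean, marg.sd)
    )
    a, b = (marg.min - mu) / sigma, (marg.max - mu) / sigma
    dist = stats.truncnorm(a, b, loc=mu, scale=sigma)
    u = rng.uniform(size=size) if uniforms is None else uniforms
    return dist.ppf(u)


def _copula_uniforms(rng, size: int, d: int, rho: float) -> np.ndarray:
    """Exchangeable Gaussian-copula uniforms, shape (size, d)."""
    cov = np.full((d, d), rho)
    np.fill_diagonal(cov, 1.0)
    Z = rng.multivariate_normal(np.zeros(d), cov, size=size, method="cholesky")
    return stats.norm.cdf(Z)


_CONTINUOUS_ORDER = ("age", "glu", "chol", "tg", "chol_hdl", "ldl", "tsh", "psa")


def generate_cohort(
    spec: CohortSpec | None = None, seed: int | None = None
) -> tuple[CohortTable, GroundTruth]:
    """Draw a synthetic cohort and its ground truth.

    Continuous labs are truncated normals per group (moment-matched to the
    spec's mean/SD); serology and sex are Bernoulli, race categorical; HDL
    is CHOL over the drawn ratio; PSA is restricted to ``spec.psa_tested``
    rows and MCAR missingness applied per ``spec.missing_rates``.  Fully
    deterministic given the seed (``seed`` overrides ``spec.seed``).
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    rows: list[dict] = []
    params: dict = {}
    for group_name, g in spec.groups.items():
        uniforms = None
        if spec.copula_rho is not None:
            uniforms = _copula_uniforms(
                rng, g.n, len(_CONTINUOUS_ORDER), spec.copula_rho
            )
        draws: dict[str, np.ndarray] = {}
        for j, var in enumerate(_CONTINUOUS_ORDER):
            marg = g.continuous[var]
            u = None if uniforms is None else uniforms[:, j]
            draws[var] = _sample_truncnorm(marg, g.n, rng, spec.calibrate, u)
            params[(group_name, var)] = truncated_normal_params(
                marg.mean, marg.sd, marg.min, marg.max
            ) if spec.calibrate else (marg.mean, marg.sd)

        # HDL = CHOL / ratio; redraw the ratio where HDL lands outside
        # plausible bounds (rare: needs an extreme CHOL/ratio combination).
        lo_hdl, hi_hdl = spec.hdl_bounds
        ratio = draws["chol_hdl"]
        marg_r = g.continuous["chol_hdl"]
        for _ in range(100):
            hdl = draws["chol"] / ratio
            bad = (hdl < lo_hdl) | (hdl > hi_hdl)
            if not bad.any():
                break
            ratio = ratio.copy()
            ratio[bad] = _sample_truncnorm(marg_r, int(bad.sum()), rng, spec.calibrate)
        else:
            raise RuntimeError("could not keep derived HDL within bounds")
        draws["chol_hdl"] = ratio
        hdl = draws["chol"] / ratio

        male = rng.uniform(size=g.n) < g.male_prop
        hbsab = rng.uniform(size=g.n) < g.hbsab_pos_rate
        hbsag = rng.uniform(size=g.n) < g.hbsag_pos_rate
        race_levels = list(g.race_props)
        race = rng.choice(race_levels, size=g.n, p=[g.race_props[r] for r in race_levels])

        for i in range(g.n):
            rows.append({
                "ssn_status": group_name,
                "gender": "M" if male[i] else "F",
                "race": str(race[i]),
                "hbsab": "pos" if hbsab[i] else "neg",
                "hbsag": "pos" if hbsag[i] else "neg",
                "hdl": float(hdl[i]),
                **{var: float(draws[var][i]) for var in _CONTINUOUS_ORDER},
            })

    order = rng.permutation(len(rows))
    rows = [rows[i] for i in order]
    for i, row in enumerate(rows):
        row["account_number"] = f"A{i + 1:04d}"
    truth = GroundTruth(frame=pd.DataFrame(rows), params=params)

    # Missingness: subset-tested PSA, then MCAR per feature.
    n = len(rows)
    observed = {feat: np.ones(n, dtype=bool) for feat in rows[0]}
    if spec.psa_tested is not None:
        tested = rng.choice(n, size=spec.psa_tested, replace=False)
        observed["psa"] = np.zeros(n, dtype=bool)
        observed["psa"][tested] = True
    for feat, rate in spec.missing_rates.items():
        if feat not in observed:
            raise ValueError(f"missing rate given for unknown feature {feat!r}")
        keep = rng.uniform(size=n) >= rate
        observed[feat] &= keep

    records = []
    for i, row in enumerate(rows):
        rec = PatientRecord()
        for feat, value in row.items():
            if observed[feat][i]:
                setattr(rec, feat, value)
        records.append(rec)
    return CohortTable(records, default_codebook()), truth


def generate_lowrank(
    n: int,
    p: int,
    k: int,
    noise_sd: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Non-negative rank-k testbed: ``X = clip(U* V* + noise, 0)`` with an
    MCAR mask guaranteed to keep >= 1 observed cell per row and column."""
    if k > min(n, p):
        raise ValueError(f"rank k={k} exceeds min(n, p)={min(n, p)}")
    if not 0 <= missing_rate < 1:
        raise ValueError(f"missing_rate must lie in [0, 1), got {missing_rate}")
    rng = np.random.default_rng(seed)
    U = np.abs(rng.standard_normal((n, k)))
    V = np.abs(rng.standard_normal((k, p)))
    X_clean = U @ V
    X = X_clean.copy()
    if noise_sd > 0:
        X = np.maximum(X + noise_sd * rng.standard_normal((n, p)), 0.0)
    for _ in range(100):
        M = (rng.uniform(size=(n, p)) >= missing_rate).astype(float)
        if M.sum(axis=1).min() >= 1 and M.sum(axis=0).min() >= 1:
            break
    else:
        raise RuntimeError(
            "could not draw a mask keeping every row and column observed"
        )
    return X, M, GroundTruth(U=U, V=V, X_clean=X_clean)


def apply_missingness(
    M: np.ndarray,
    pattern: float | tuple[str, int, int],
    seed: int = 0,
) -> np.ndarray:
    """Apply a missingness pattern to an observation mask.

    ``pattern`` is either an MCAR rate in ``[0, 1)`` (each observed cell is
    dropped i.i.d.) or ``("subset", column, n_observed)`` marking a column
    observed for exactly ``n_observed`` of its currently observed rows
    (subset-tested labs such as PSA).
    """
    M = np.asarray(M, dtype=float)
    rng = np.random.default_rng(seed)
    out = M.copy()
    if isinstance(pattern, (int, float)):
        rate = float(pattern)
        if not 0 <= rate < 1:
            raise ValueError(f"MCAR rate must lie in [0, 1), got {rate}")
        drop = rng.uniform(size=M.shape) < rate
        out[drop] = 0.0
        return out
    kind, col, n_obs = pattern
    if kind != "subset":
        raise ValueError(f"unknown missingness pattern {kind!r}")
    candidates = np.flatnonzero(out[:, col] == 1)
    if len(candidates) < n_obs:
        raise ValueError(
            f"column {col} has only {len(candidates)} observed rows, "
            f"cannot keep {n_obs}"
        )
    keep = rng.choice(candidates, size=n_obs, replace=False)
    out[:, col] = 0.0
    out[keep, col] = 1.0
    return out
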