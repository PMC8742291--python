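"""Four-level cardiovascular risk banding from HDL%% and the CHOL/HDL ratio.

The total-cholesterol-to-HDL ratio is a standard lipid risk index.  Screening
practice bands it, with sex-specific cutpoints, into four ordinal levels:

====  ============================  ===========  ===========  =========
code  level                         male ratio   female ratio  HDL (%)
====  ============================  ===========  ===========  =========
1     below-average risk            < 4.2        < 3.9        > 25
2     average risk                  4.2 - 7.4    3.9 - 5.8    15 - 25
3     above-average risk (moderate) 7.4 - 11.5   5.8 - 9.0    9 - 15
4     above-average risk (high)     > 11.5       > 9.0        < 9
====  ============================  ===========  ===========  =========

The published bands leave printed gaps and overlaps at the cutpoints; here
they are resolved into contiguous half-open intervals so that every positive
ratio classifies to exactly one level: the two lower cutpoints belong to the
higher-risk side, the top ratio cutpoint to the moderate band, and shared
HDL%% cutpoints to the lower-risk band.

Besides the hard assignment, :func:`soft_assign` produces a fuzzy membership
vector over the four levels, reflecting how close a ratio sits to the band
cutoffs (used for the band-width diagnostics of the risk clustering).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RiskCategory",
    "RiskThresholds",
    "SoftMembership",
    "classify_ratio",
    "classify_hdl_percent",
    "soft_assign",
]


class RiskCategory(enum.IntEnum):
    """Ordinal risk level; larger means higher cardiovascular risk."""

    BELOW_AVERAGE = 1
    AVERAGE = 2
    ABOVE_AVERAGE_MODERATE = 3
    ABOVE_AVERAGE_HIGH = 4


@dataclass(frozen=True)
class RiskThresholds:
    """Sex-specific ratio cutpoints and the HDL%% cutpoints.

    ``male``/``female`` are the three ascending CHOL/HDL cutpoints between
    consecutive levels; ``hdl_pct`` the three descending HDL%% cutpoints.
    """

    male: tuple[float, float, float] = (4.2, 7.4, 11.5)
    female: tuple[float, float, float] = (3.9, 5.8, 9.0)
    hdl_pct: tuple[float, float, float] = (25.0, 15.0, 9.0)

    def __post_init__(self) -> None:
        for name in ("male", "female"):
            c = getattr(self, name)
            if not (c[0] < c[1] < c[2]):
                raise ValueError(f"{name} ratio cutpoints must strictly increase: {c}")
        h = self.hdl_pct
        if not (h[0] > h[1] > h[2] > 0):
            raise ValueError(f"HDL%% cutpoints must strictly decrease: {h}")

    def for_sex(self, sex: str) -> tuple[float, float, float]:
        if sex == "M":
            return self.male
        if sex == "F":
            return self.female
        raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")


@dataclass(frozen=True)
class SoftMembership:
    """Probability-like weights over the four risk levels (sum to 1)."""

    weights: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.shape != (4,):
            raise ValueError("membership must be a 4-vector")
        if np.any(w < 0) or not math.isclose(w.sum(), 1.0, abs_tol=1e-12):
            raise ValueError("membership weights must be non-negative and sum to 1")

    @property
    def argmax(self) -> RiskCategory:
        return RiskCategory(int(np.argmax(self.weights)) + 1)


def _check_ratio(ratio: float) -> float:
    ratio = float(ratio)
    if not math.isfinite(ratio) or ratio <= 0:
        raise ValueError(f"CHOL/HDL ratio must be finite and positive, got {ratio}")
    return ratio


def classify_ratio(
    sex: str, ratio: float, thresholds: RiskThresholds | None = None
) -> RiskCategory:
    """Hard risk level for a CHOL/HDL ratio.

    Intervals (male shown; female analogous): ``[0, 4.2) -> 1``,
    ``[4.2, 7.4) -> 2``, ``[7.4, 11.5] -> 3``, ``(11.5, inf) -> 4``.
    """
    thresholds = thresholds or RiskThresholds()
    ratio = _check_ratio(ratio)
    c1, c2, c3 = thresholds.for_sex(sex)
    if ratio < c1:
        return RiskCategory.BELOW_AVERAGE
    if ratio < c2:
        return RiskCategory.AVERAGE
    if ratio <= c3:
        return RiskCategory.ABOVE_AVERAGE_MODERATE
    return RiskCategory.ABOVE_AVERAGE_HIGH


def classify_hdl_percent(
    hdl_pct: float, thresholds: RiskThresholds | None = None
) -> RiskCategory:
    """Hard risk level for HDL as a percentage of total cholesterol.

    Intervals: ``(25, 100] -> 1``, ``[15, 25] -> 2``, ``[9, 15) -> 3``,
    ``(0, 9) -> 4``; risk is non-increasing in HDL%%.
    """
    thresholds = thresholds or RiskThresholds()
    hdl_pct = float(hdl_pct)
    if not math.isfinite(hdl_pct) or not (0 < hdl_pct <= 100):
        raise ValueError(f"HDL%% must lie in (0, 100], got {hdl_pct}")
    h1, h2, h3 = thresholds.hdl_pct
    if hdl_pct > h1:
        return RiskCategory.BELOW_AVERAGE
    if hdl_pct >= h2:
        return RiskCategory.AVERAGE
    if hdl_pct >= h3:
        return RiskCategory.ABOVE_AVERAGE_MODERATE
    return RiskCategory.ABOVE_AVERAGE_HIGH


def default_bandwidth(sex: str, thresholds: RiskThresholds | None = None) -> float:
    """Half the narrowest interior band width for the given sex."""
    c1, c2, c3 = (thresholds or RiskThresholds()).for_sex(sex)
    return 0.5 * min(c2 - c1, c3 - c2)


def _category_coordinate(
    ratio: float, cuts: tuple[float, float, float], bandwidth: float
) -> float:
    """Map a ratio to a piecewise-linear category coordinate ``t in [1, 4]``.

    ``t = j`` at the midpoint of band ``j`` (outer bands: cutpoint -/+
    bandwidth stands in for the midpoint) and ``t = j + 0.5`` exactly at the
    cutpoint between bands ``j`` and ``j+1``.  Triangular kernels in ``t``
    then peak at band centres, split 50/50 at every cutpoint, and hand over
    the argmax precisely where the hard classification switches, regardless
    of how unequal the band widths are.
    """
    c1, c2, c3 = cuts
    anchors_r = [c1 - bandwidth, c1, 0.5 * (c1 + c2), c2, 0.5 * (c2 + c3), c3, c3 + bandwidth]
    anchors_t = [1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0]
    return float(np.interp(ratio, anchors_r, anchors_t))


def soft_assign(
    sex: str,
    ratio: float,
    thresholds: RiskThresholds | None = None,
    bandwidth: float | None = None,
) -> SoftMembership:
    """Fuzzy membership of a CHOL/HDL ratio over the four risk levels.

    Triangular kernels centred at each band's midpoint (outer bands use
    cutpoint -/+ ``bandwidth`` as the centre) evaluated in a warped category
    coordinate and normalized to sum to 1.  Far from all cutpoints the hard
    band's weight tends to 1; exactly at a cutpoint the two adjacent bands
    split the weight equally.

    ``bandwidth`` defaults to half the narrowest interior band width for the
    given sex.
    """
    thresholds = thresholds or RiskThresholds()
    ratio = _check_ratio(ratio)
    if bandwidth is None:
        bandwidth = default_bandwidth(sex, thresholds)
    bandwidth = float(bandwidth)
    if not math.isfinite(bandwidth) or bandwidth <= 0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth}")
    t = _category_coordinate(ratio, thresholds.for_sex(sex), bandwidth)
    weights = np.maximum(0.0, 1.0 - np.abs(t - np.arange(1, 5)))
    return SoftMembership(weights / weights.sum())
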