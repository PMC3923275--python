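"""Replicate-SD calibration, three-sigma change calling, protein rollup.

Significance is calibrated empirically: a 1:1 heavy/light standard mixture is
measured repeatedly, the sample SD of the recovered ratios estimates the
method's dispersion at unit ratio, and a ratio is called a significant change
when it departs from 1.0 by more than 3 SD (≈99% confidence under
normality), a minor change between 1 and 3 SD.  Downward thresholds are the
reciprocals of the upward ones, so the bands are symmetric on the ratio
scale.  Protein-level ratios are the median of their quantifiable peptide
ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sstats

__all__ = [
    "ReplicateSeries",
    "SignificanceThresholds",
    "SignificanceCall",
    "replicate_sd",
    "thresholds_from_sd",
    "classify_change",
    "protein_ratio",
    "linearity_r2",
]

Classification = Literal[
    "significant-up", "minor-up", "unchanged", "minor-down", "significant-down"
]


@dataclass(frozen=True)
class ReplicateSeries:
    """Repeated ratio measurements of one entity at nominal 1:1 mixing."""

    entity: str
    ratios: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.ratios):
            raise ValueError("ratios must be > 0")

    @property
    def n(self) -> int:
        return len(self.ratios)


def _round2(x: float) -> float:
    """Round half up to two decimals (the convention of the printed bounds)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SignificanceThresholds:
    """The four band edges of the three-sigma scheme, already rounded.

    Bands (ratio scale):
      (0, lower_significant)          significant-down
      [lower_significant, lower_minor_high)   minor-down
      [lower_minor_high, upper_minor_low]     unchanged
      (upper_minor_low, upper_significant]    minor-up
      (upper_significant, inf)        significant-up
    Boundary values always fall in the less extreme band.
    """

    level: Literal["peptide", "protein"]
    sd: float
    upper_significant: float
    upper_minor_low: float
    lower_minor_high: float
    lower_significant: float

    def __post_init__(self) -> None:
        if self.sd > 0 and not (
            self.lower_significant
            <= self.lower_minor_high
            <= 1.0
            <= self.upper_minor_low
            <= self.upper_significant
        ):
            raise ValueError("threshold ordering violated")


@dataclass(frozen=True)
class SignificanceCall:
    ratio: float
    classification: Classification
    thresholds: SignificanceThresholds


def replicate_sd(series: ReplicateSeries) -> float:
    """Sample standard deviation (n−1 denominator) of the replicate ratios."""
    if series.n < 2:
        raise ValueError("need at least 2 replicates to estimate SD")
    return float(np.std(series.ratios, ddof=1))


def thresholds_from_sd(
    sd: float, level: Literal["peptide", "protein"] = "peptide"
) -> SignificanceThresholds:
    """Three-sigma band edges from a replicate SD, rounded half-up at 2 dp.

    Upper edges are round(1 + 3·sd) and round(1 + sd); lower edges are the
    rounded reciprocals of the *unrounded* upper expressions, keeping the
    bands reciprocal-symmetric before rounding.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    return SignificanceThresholds(
        level=level,
        sd=sd,
        upper_significant=_round2(1 + 3 * sd),
        upper_minor_low=_round2(1 + sd),
        lower_minor_high=_round2(1 / (1 + sd)),
        lower_significant=_round2(1 / (1 + 3 * sd)),
    )


def classify_change(
    ratio: float, thresholds: SignificanceThresholds
) -> SignificanceCall:
    """Band membership by direct comparison; ties go to the milder band."""
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    t = thresholds
    if ratio > t.upper_significant:
        c: Classification = "significant-up"
    elif ratio > t.upper_minor_low:
        c = "minor-up"
    elif ratio >= t.lower_minor_high:
        c = "unchanged"
    elif ratio >= t.lower_significant:
        c = "minor-down"
    else:
        c = "significant-down"
    return SignificanceCall(ratio, c, t)


def protein_ratio(peptide_ratios: Sequence[float]) -> tuple[float, bool]:
    """Median of the quantifiable peptide ratios; flags single-peptide support.

    Returns ``(median, low_support)`` where low_support is True when fewer
    than two peptides contribute.  Even counts average the two central
    values.
    """
    if len(peptide_ratios) == 0:
        raise ValueError("no quantifiable peptide ratios")
    return float(np.median(peptide_ratios)), len(peptide_ratios) < 2


def linearity_r2(expected: Sequence[float], observed: Sequence[float]) -> float:
    """Squared Pearson correlation of an OLS fit of observed on expected."""
    if len(expected) != len(observed):
        raise ValueError("length mismatch")
    if len(expected) < 3:
        raise ValueError("need at least 3 points")
    if np.std(expected) == 0 or np.std(observed) == 0:
        raise ValueError("zero variance")
    fit = sstats.linregress(expected, observed)
    return float(fit.rvalue**2)
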