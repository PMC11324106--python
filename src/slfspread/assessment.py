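"""Scoring ensemble forecasts against observed infestation status.

Two protocols are provided.  The aggregate protocol classifies each county
by strict majority rule — model-infested in a year iff more than half of
the ensemble runs infest it by then — and counts matches, false positives
(model infested, data not) and false negatives against the observed
status.  The county-level protocol reports, per county and year, the
percentage of runs that predicted the correct status: ``100 * p_{i,t}``
where the county was observed infested and ``100 * (1 - p_{i,t})`` where
it was not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .region_data import ObservedStatus
from .simulator import EnsembleSummary

__all__ = [
    "AccuracyReport",
    "CountyAccuracy",
    "classify_majority",
    "aggregate_accuracy",
    "county_accuracy_over_time",
]


@dataclass(frozen=True)
class AccuracyReport:
    """Aggregate confusion counts for one assessment year."""

    year: int
    n_counties: int
    n_correct: int
    n_incorrect: int
    n_false_positive: int
    n_false_negative: int

    def __post_init__(self) -> None:
        if self.n_correct + self.n_incorrect != self.n_counties:
            raise ValueError("correct + incorrect must equal n_counties")
        if self.n_false_positive + self.n_false_negative != self.n_incorrect:
            raise ValueError("FP + FN must equal n_incorrect")

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * self.n_correct / self.n_counties


@dataclass(frozen=True)
class CountyAccuracy:
    """Per-county, per-year correctness percentages (county x year)."""

    fips_codes: tuple[str, ...]
    years: tuple[int, ...]
    pct: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.pct < 0) or np.any(self.pct > 100):
            raise ValueError("accuracy percentages must lie in [0, 100]")


def classify_majority(summary: EnsembleSummary, year: int) -> np.ndarray:
    """Majority-rule classification: infested iff strictly > half the runs.

    A county exactly at one half (possible with an even ensemble size) is
    classified NOT infested — the rule is "more than half".
    """
    if year not in summary.years:
        raise ValueError(f"year {year} not in ensemble range {summary.years}")
    return summary.p_at(year) > 0.5


def aggregate_accuracy(pred: np.ndarray, obs: np.ndarray, year: int) -> AccuracyReport:
    """Confusion counts of a predicted vs observed boolean status vector."""
    pred = np.asarray(pred, dtype=bool)
    obs = np.asarray(obs, dtype=bool)
    if pred.shape != obs.shape:
        raise ValueError(f"prediction length {pred.shape} != observation length {obs.shape}")
    fp = int(np.sum(pred & ~obs))
    fn = int(np.sum(~pred & obs))
    n = pred.size
    return AccuracyReport(
        year=year,
        n_counties=n,
        n_correct=n - fp - fn,
        n_incorrect=fp + fn,
        n_false_positive=fp,
        n_false_negative=fn,
    )


def county_accuracy_over_time(
    summary: EnsembleSummary, status: ObservedStatus
) -> CountyAccuracy:
    """Percent of runs predicting each county's correct status each year.

    Years present in both the ensemble and the observed record are scored;
    counties must match.  Raises if the year ranges are disjoint.
    """
    if summary.fips_codes != status.fips_codes:
        raise ValueError("ensemble and observed status cover different counties")
    common = [y for y in summary.years if y in status.years]
    if not common:
        raise ValueError("ensemble and observed status share no years")
    p = np.column_stack([summary.p_at(y) for y in common])
    q = np.column_stack([status.at_year(y) for y in common])
    pct = 100.0 * np.where(q, p, 1.0 - p)
    return CountyAccuracy(fips_codes=summary.fips_codes, years=tuple(common), pct=pct)
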