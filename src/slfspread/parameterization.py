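"""Estimation of the adjacency spread probability and establishment vectors.

The per-neighbor annual spread probability ``p`` is not set by hand: it is
derived from year-over-year county transitions.  For every county that is
uninfested at year t we count its infested border neighbors ``N`` and
record whether it became infested by t+1.  Pooling over consecutive year
pairs gives, for each distinct ``N``, an empirical colonization proportion
``p_I(N)``.  The saturating-exponential independence model

    p_I(N) = 1 - exp(-a N)

is then fit to those proportions by unweighted nonlinear least squares,
and the per-neighbor probability follows as ``p = 1 - exp(-a)``.

Long-distance (highway) spread uses establishment vectors: each county's
share of a human-activity factor (garden centers, population) over the
region total, so each vector sums to one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

from .region_data import ObservedStatus, Region

__all__ = [
    "TransitionTable",
    "SpreadParameters",
    "FitError",
    "transition_table",
    "transition_points",
    "fit_colonization_rate",
    "fit_colonization_rate_points",
    "derive_p",
    "establishment_vector",
    "estimate_spread_parameters",
    "colonization_curve",
]


@dataclass(frozen=True)
class TransitionTable:
    """Pooled year-over-year colonization counts, one row per distinct N.

    ``N``: number of infested border neighbors at year t (at-risk counties
    only).  ``n_at_risk``: uninfested counties with that N, pooled over all
    year pairs.  ``n_infected_next``: how many became infested by t+1.
    ``p_I = n_infected_next / n_at_risk``.
    """

    N: np.ndarray
    n_at_risk: np.ndarray
    n_infected_next: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.n_infected_next > self.n_at_risk):
            raise ValueError("n_infected_next exceeds n_at_risk")
        if np.any(self.N < 0) or np.any(self.n_at_risk < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def p_I(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(self.n_at_risk > 0, self.n_infected_next / self.n_at_risk, np.nan)


@dataclass(frozen=True)
class SpreadParameters:
    """Fitted model parameters for one region.

    ``a``: colonization rate; ``a_ci``: its 95% confidence interval;
    ``p = 1 - exp(-a)``: per-infested-neighbor annual spread probability;
    ``s_g``, ``s_p``: establishment vectors (county shares of garden
    centers and population), each summing to one over the region.
    """

    a: float
    a_ci: tuple[float, float]
    p: float
    s_g: np.ndarray
    s_p: np.ndarray

    def __post_init__(self) -> None:
        for label, s in (("s_g", self.s_g), ("s_p", self.s_p)):
            if np.any(s < 0) or np.any(s > 1):
                raise ValueError(f"{label} entries must lie in [0, 1]")
            if not math.isclose(float(s.sum()), 1.0, rel_tol=0, abs_tol=1e-9):
                raise ValueError(f"{label} must sum to 1")
        if not math.isclose(self.p, 1.0 - math.exp(-self.a), rel_tol=0, abs_tol=1e-12):
            raise ValueError("p must equal 1 - exp(-a)")


class FitError(RuntimeError):
    """Nonlinear least squares failed to converge."""


def colonization_curve(N: np.ndarray | float, a: float) -> np.ndarray | float:
    """Saturating-exponential colonization probability ``1 - exp(-a N)``."""
    return 1.0 - np.exp(-a * np.asarray(N, dtype=float))


def transition_table(
    region: Region,
    status: ObservedStatus,
    year_pairs: Sequence[tuple[int, int]],
    include_zero: bool = True,
) -> TransitionTable:
    """Pool at-risk counties over year pairs into colonization counts by N.

    Counties already infested at year t are excluded; counts are pooled
    across all pairs before proportions are formed.  ``include_zero=False``
    drops the N = 0 bin (counties with no infested border neighbor, whose
    colonizations are highway-mediated jumps).
    """
    counts: dict[int, list[int]] = {}
    any_at_risk = False
    for t, t1 in year_pairs:
        q_t = status.at_year(t)
        q_t1 = status.at_year(t1)
        at_risk = ~q_t
        if not at_risk.any():
            continue
        any_at_risk = True
        n_infested_neighbors = region.A @ q_t.astype(np.int64)
        for i in np.flatnonzero(at_risk):
            N = int(n_infested_neighbors[i])
            bucket = counts.setdefault(N, [0, 0])
            bucket[0] += 1
            bucket[1] += int(q_t1[i])
    if not any_at_risk:
        raise ValueError("no at-risk counties in any year pair (region fully infested)")
    if not include_zero:
        counts.pop(0, None)
    Ns = sorted(counts)
    return TransitionTable(
        N=np.array(Ns, dtype=np.int64),
        n_at_risk=np.array([counts[n][0] for n in Ns], dtype=np.int64),
        n_infected_next=np.array([counts[n][1] for n in Ns], dtype=np.int64),
    )


def transition_points(
    region: Region,
    status: ObservedStatus,
    year_pairs: Sequence[tuple[int, int]],
    include_zero: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-year-pair (N, p_I) points — the unpooled alternative.

    One proportion per (year pair, distinct N) instead of pooling counts
    across pairs first; year pairs with no at-risk counties are skipped.
    """
    Ns: list[float] = []
    ps: list[float] = []
    for pair in year_pairs:
        try:
            t = transition_table(region, status, [pair], include_zero=include_zero)
        except ValueError:
            continue
        mask = t.n_at_risk > 0
        Ns.extend(t.N[mask].tolist())
        ps.extend(t.p_I[mask].tolist())
    if not Ns:
        raise ValueError("no at-risk counties in any year pair (region fully infested)")
    return np.array(Ns, dtype=float), np.array(ps, dtype=float)


def _fit_points(
    N: np.ndarray, p_I: np.ndarray, a0: float
) -> tuple[float, tuple[float, float]]:
    if len(N) < 2:
        raise ValueError("need at least 2 distinct N values with counties at risk")
    if np.allclose(p_I, 0.0):
        warnings.warn("all colonization proportions are zero; a = 0", stacklevel=2)
        return 0.0, (0.0, 0.0)
    try:
        popt, pcov = optimize.curve_fit(colonization_curve, N, p_I, p0=[a0])
    except RuntimeError as exc:  # pragma: no cover - pathological tables
        raise FitError(f"colonization-rate fit did not converge: {exc}") from exc
    a = float(popt[0])
    se = float(np.sqrt(pcov[0, 0]))
    dof = max(len(N) - 1, 1)
    half = stats.t.ppf(0.975, dof) * se
    return a, (a - half, a + half)


def fit_colonization_rate(
    table: TransitionTable, a0: float = 0.1
) -> tuple[float, tuple[float, float]]:
    """Fit the rate ``a`` in ``p_I = 1 - exp(-a N)`` by least squares.

    Unweighted NLS on the (N, p_I) rows, one point per distinct N, with a
    95% confidence interval from the asymptotic covariance using the
    t-distribution on n-1 degrees of freedom (matching standard
    curve-fitting toolboxes).  A table with all-zero proportions returns
    a = 0 with a degenerate interval and a warning.
    """
    mask = table.n_at_risk > 0
    return _fit_points(table.N[mask].astype(float), table.p_I[mask], a0)


def fit_colonization_rate_points(
    N: np.ndarray, p_I: np.ndarray, a0: float = 0.1
) -> tuple[float, tuple[float, float]]:
    """Least-squares fit on raw (N, p_I) points (per-year-pair variant)."""
    return _fit_points(np.asarray(N, float), np.asarray(p_I, float), a0)


def derive_p(a: float) -> float:
    """Per-infested-neighbor annual spread probability ``p = 1 - exp(-a)``."""
    if a < 0:
        raise ValueError(f"rate a must be nonnegative, got {a}")
    return 1.0 - math.exp(-a)


def establishment_vector(
    region: Region, factor: Literal["garden_centers", "population"]
) -> np.ndarray:
    """County shares of a human-activity factor over the region total.

    Entry i is county i's count divided by the region total, so the vector
    sums to one and is invariant to rescaling all counts.
    """
    if factor == "garden_centers":
        counts = np.array([c.garden_centers for c in region.counties], dtype=float)
    elif factor == "population":
        counts = np.array([c.population for c in region.counties], dtype=float)
    else:
        raise ValueError(f"unknown factor {factor!r}")
    total = counts.sum()
    if total <= 0:
        raise ValueError(f"region total of {factor} is zero; establishment vector undefined")
    return counts / total


def estimate_spread_parameters(
    region: Region,
    status: ObservedStatus,
    year_pairs: Sequence[tuple[int, int]] | None = None,
    include_zero: bool = True,
    pooling: Literal["pooled", "per_year"] = "pooled",
) -> SpreadParameters:
    """Full parameterization: transition table -> a -> p, plus s vectors.

    ``year_pairs`` defaults to all consecutive pairs in the status years.
    ``pooling`` chooses between counts pooled across year pairs before the
    proportions are formed (default) and one proportion per year pair.
    """
    if year_pairs is None:
        year_pairs = list(zip(status.years, status.years[1:]))
    if pooling == "pooled":
        table = transition_table(region, status, year_pairs, include_zero=include_zero)
        a, a_ci = fit_colonization_rate(table)
    elif pooling == "per_year":
        N, p_I = transition_points(region, status, year_pairs, include_zero=include_zero)
        a, a_ci = fit_colonization_rate_points(N, p_I)
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    a = max(a, 0.0)
    return SpreadParameters(
        a=a,
        a_ci=a_ci,
        p=derive_p(a),
        s_g=establishment_vector(region, "garden_centers"),
        s_p=establishment_vector(region, "population"),
    )
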