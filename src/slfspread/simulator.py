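"""Discrete-time stochastic spread process on the two county networks.

Each year every uninfested county is exposed to three sequential Bernoulli
colonization sub-steps, applied in a fixed order:

1. **adjacency** — probability ``1 - (1-p)^(sum_j A_ij q_j)``: each
   infested border neighbor is an independent chance of colonization;
2. **garden centers** — probability ``c * (1 - (1-s_g,i)^(sum_j H_ij q_j))``
   over the highway network, where ``s_g,i`` is the county's share of the
   region's garden centers;
3. **population** — the same form with the population share ``s_p,i``.

``c`` is a 1/2 prefactor applied to both highway channels by default
(``half_factor=True``), matching the published simulation code; the
equation-literal variant (``c = 1``) is available as a switch.  Sub-steps
cascade: counties infested by an earlier sub-step of the same year count
as sources for the later sub-steps (in-place update semantics).  A
``synchronous`` switch instead evaluates all three channels against the
start-of-year state.  Infestation is absorbing: a county never reverts.

Randomness contract: exactly one uniform draw per county per sub-step
(three per county-year), consumed in (channel, county-index ascending)
order, so a run is bit-reproducible given its seed.  Ensembles give each
run an independent child stream spawned from the ensemble seed, so run k
is reproducible regardless of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .parameterization import SpreadParameters
from .region_data import Region

__all__ = [
    "SimulationConfig",
    "InfestationHistory",
    "EnsembleSummary",
    "step",
    "simulate_run",
    "simulate_ensemble",
]

#: Fixed sub-step order within a year.
CHANNEL_ORDER = ("adjacency", "garden_centers", "population")


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of one simulation or ensemble.

    ``seed_fips`` is the single initially infested county; ``horizon`` is
    the number of annual steps T (so a run covers start_year ..
    start_year+T); ``half_factor`` applies the 1/2 prefactor to both
    highway channels; ``synchronous`` disables within-year cascading.
    """

    seed_fips: str
    start_year: int = 2014
    horizon: int = 7
    n_runs: int = 1000
    rng_seed: int = 0
    half_factor: bool = True
    synchronous: bool = False

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(range(self.start_year, self.start_year + self.horizon + 1))


@dataclass(frozen=True)
class InfestationHistory:
    """Boolean infestation matrix Q of one run: county x year.

    Column 0 is the seed state (exactly one infested county); each row is
    monotone nondecreasing in time.
    """

    fips_codes: tuple[str, ...]
    years: tuple[int, ...]
    Q: np.ndarray  # bool, county x (T+1)


@dataclass(frozen=True)
class EnsembleSummary:
    """Proportion-infested matrix P of a Monte-Carlo ensemble.

    ``P[i, k]`` is the fraction of runs in which county i was infested at
    ``years[k]``; entries lie in [0, 1], rows are monotone in time, and
    the seed county's row is identically 1.
    """

    fips_codes: tuple[str, ...]
    years: tuple[int, ...]
    P: np.ndarray  # float, county x (T+1)
    n_runs: int

    def p_at(self, year: int) -> np.ndarray:
        return self.P[:, self.years.index(year)].copy()


def _check_dimensions(q: np.ndarray, region: Region, params: SpreadParameters) -> None:
    n = region.n_counties
    if q.shape != (n,):
        raise ValueError(f"state vector has shape {q.shape}, expected ({n},)")
    if params.s_g.shape != (n,) or params.s_p.shape != (n,):
        raise ValueError("establishment vectors do not match the region size")


def _substep_probability(
    channel: str, q: np.ndarray, region: Region, params: SpreadParameters, c: float
) -> np.ndarray:
    """Colonization probability of every county for one sub-step.

    ``(1-x)^k`` is evaluated with the integer exposure count ``k`` from the
    current state; infested counties get probability 1 by convention (they
    remain infested regardless of the draw).
    """
    qi = q.astype(np.int64)
    if channel == "adjacency":
        exposure = region.A @ qi
        prob = 1.0 - (1.0 - params.p) ** exposure
    elif channel == "garden_centers":
        exposure = region.H @ qi
        prob = c * (1.0 - (1.0 - params.s_g) ** exposure)
    elif channel == "population":
        exposure = region.H @ qi
        prob = c * (1.0 - (1.0 - params.s_p) ** exposure)
    else:  # pragma: no cover
        raise ValueError(f"unknown channel {channel!r}")
    return prob


def step(
    q: np.ndarray,
    region: Region,
    params: SpreadParameters,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Advance the infestation state by one year.

    Consumes exactly ``3 * n_counties`` uniforms: one per county per
    sub-step, counties in index order within each sub-step.
    """
    _check_dimensions(q, region, params)
    c = 0.5 if config.half_factor else 1.0
    q = q.astype(bool).copy()
    if config.synchronous:
        base = q.copy()
        for channel in CHANNEL_ORDER:
            ch_c = c if channel != "adjacency" else 1.0
            prob = _substep_probability(channel, base, region, params, ch_c)
            u = rng.random(region.n_counties)
            q |= prob > u
    else:
        for channel in CHANNEL_ORDER:
            ch_c = c if channel != "adjacency" else 1.0
            prob = _substep_probability(channel, q, region, params, ch_c)
            u = rng.random(region.n_counties)
            q |= prob > u
    return q


def _initial_state(region: Region, seed_fips: str) -> np.ndarray:
    if seed_fips not in region.index_of:
        raise ValueError(f"seed county {seed_fips} is not in the region")
    q0 = np.zeros(region.n_counties, dtype=bool)
    q0[region.index_of[seed_fips]] = True
    return q0


def simulate_run(
    region: Region,
    params: SpreadParameters,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> InfestationHistory:
    """One realization: T annual steps from the single seed county."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    q = _initial_state(region, config.seed_fips)
    Q = np.empty((region.n_counties, config.horizon + 1), dtype=bool)
    Q[:, 0] = q
    for t in range(1, config.horizon + 1):
        q = step(q, region, params, config, rng)
        Q[:, t] = q
    return InfestationHistory(fips_codes=region.fips_codes, years=config.years, Q=Q)


def _run_streams(rng_seed: int, n_runs: int) -> Iterable[np.random.Generator]:
    for child in np.random.SeedSequence(rng_seed).spawn(n_runs):
        yield np.random.Generator(np.random.PCG64(child))


def simulate_ensemble(
    region: Region, params: SpreadParameters, config: SimulationConfig
) -> EnsembleSummary:
    """Monte-Carlo ensemble: mean of ``n_runs`` independent run matrices.

    Per-run streams are spawned deterministically from ``config.rng_seed``,
    so the ensemble is bit-reproducible and independent of execution order.
    """
    total = np.zeros((region.n_counties, config.horizon + 1), dtype=np.int64)
    for rng in _run_streams(config.rng_seed, config.n_runs):
        total += simulate_run(region, params, config, rng).Q
    return EnsembleSummary(
        fips_codes=region.fips_codes,
        years=config.years,
        P=total / config.n_runs,
        n_runs=config.n_runs,
    )
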