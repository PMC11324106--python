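"""Synthetic regions and infestation histories for download-free testing.

The generator emulates the statistical structure the analysis assumes
rather than US geography: a connected planar-style county adjacency graph
(a rectangular grid), a sparse highway overlay laid as chains of counties
so highway hops are long-range relative to border adjacency, nonnegative
integer garden-center counts (Poisson), heavy-tailed populations
(log-normal), and infestation histories generated by the spread model
itself from known parameters — which makes parameter-recovery experiments
possible with no external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameterization import SpreadParameters, derive_p, establishment_vector
from .region_data import CountyRecord, ObservedStatus, Region, build_region
from .simulator import SimulationConfig, simulate_run

__all__ = ["SyntheticSpec", "generate_region", "generate_history", "synthetic_parameters"]

# Plausible two-digit primary interstate IDs for synthetic routes.
_ROUTE_IDS = (70, 76, 78, 80, 81, 83, 84, 86, 88, 90, 95, 99, 64, 66, 68, 71, 74, 77, 79, 85)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic region.

    ``grid_shape``: rows x columns of the county lattice (adjacency is the
    4-neighbor grid, always connected).  ``n_highways`` routes of
    ``highway_length`` consecutive counties are laid along distinct rows,
    each assigning one interstate ID.  ``gc_mean``: Poisson mean of
    garden-center counts (must be > 0 so the establishment vector exists).
    ``pop_log_mean``/``pop_log_sigma``: log-normal population parameters
    (defaults give a median around 50k persons, spanning roughly 5k-500k —
    the county-size range the model is used on).
    """

    grid_shape: tuple[int, int] = (6, 6)
    n_highways: int = 2
    highway_length: int = 4
    gc_mean: float = 8.0
    pop_log_mean: float = 10.8
    pop_log_sigma: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows * cols < 2:
            raise ValueError("need at least 2 counties")
        if self.gc_mean <= 0:
            raise ValueError("gc_mean must be > 0 (establishment vector undefined otherwise)")
        if self.n_highways > rows:
            raise ValueError("at most one highway route per grid row")
        if self.n_highways > 0 and self.highway_length > cols:
            raise ValueError("highway_length cannot exceed the number of columns")
        if self.n_highways > len(_ROUTE_IDS):
            raise ValueError(f"at most {len(_ROUTE_IDS)} highway routes supported")


def _grid_pairs(rows: int, cols: int, fips: list[str]) -> list[tuple[str, str]]:
    import networkx as nx

    g = nx.grid_2d_graph(rows, cols)
    pos = {(r, c): r * cols + c for r in range(rows) for c in range(cols)}
    return [(fips[pos[u]], fips[pos[v]]) for u, v in g.edges()]


def generate_region(spec: SyntheticSpec) -> Region:
    """Deterministically generate a connected synthetic region.

    Counties are numbered row-major with synthetic FIPS codes 90000+k
    (state code "ZZ").  Highway route h runs along row
    ``h * rows // n_highways``, starting at a column drawn at random, and
    tags its counties with one ID from a fixed pool.
    """
    rng = np.random.default_rng(spec.rng_seed)
    rows, cols = spec.grid_shape
    n = rows * cols
    fips = [f"{90000 + k:05d}" for k in range(n)]

    highway_ids: list[set[int]] = [set() for _ in range(n)]
    for h in range(spec.n_highways):
        row = h * rows // spec.n_highways
        start = int(rng.integers(0, cols - spec.highway_length + 1))
        for c in range(start, start + spec.highway_length):
            highway_ids[row * cols + c].add(_ROUTE_IDS[h])

    gc = rng.poisson(spec.gc_mean, size=n)
    if gc.sum() == 0:  # Poisson at small mean*n can produce an all-zero draw
        gc[int(rng.integers(0, n))] = 1
    pop = np.maximum(
        rng.lognormal(spec.pop_log_mean, spec.pop_log_sigma, size=n).astype(np.int64), 1
    )

    records = [
        CountyRecord(
            fips=fips[k],
            name=f"Synth{k:03d}",
            state="ZZ",
            year_infested=None,
            garden_centers=int(gc[k]),
            population=int(pop[k]),
            highway_ids=frozenset(highway_ids[k]),
        )
        for k in range(n)
    ]
    return build_region(records, _grid_pairs(rows, cols, fips))


def synthetic_parameters(region: Region, a: float) -> SpreadParameters:
    """Spread parameters with a known rate ``a`` and the region's s vectors."""
    return SpreadParameters(
        a=a,
        a_ci=(a, a),
        p=derive_p(a),
        s_g=establishment_vector(region, "garden_centers"),
        s_p=establishment_vector(region, "population"),
    )


def generate_history(
    region: Region,
    params: SpreadParameters,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> ObservedStatus:
    """One model-generated history as an observed-status record.

    Runs the simulator once and labels each county with the first year its
    state switched on, exactly as real infestation-year designations are
    recorded.  Used for parameter-recovery experiments where the true rate
    is known by construction.
    """
    history = simulate_run(region, params, config, rng=rng)
    return ObservedStatus(
        fips_codes=history.fips_codes, years=history.years, q=history.Q.copy()
    )
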