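"""Stochastic spread process: sub-step kernels, runs, and ensembles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from slfspread import (
    SimulationConfig,
    SpreadParameters,
    SyntheticSpec,
    derive_p,
    generate_region,
    simulate_ensemble,
    simulate_run,
    step,
    synthetic_parameters,
)

from conftest import make_record
from slfspread.region_data import build_region


def params_with(region, p, s_g=None, s_p=None):
    """SpreadParameters with explicit p and optional explicit s vectors."""
    n = region.n_counties
    a = -np.log(1.0 - p) if p < 1 else 50.0
    base = synthetic_parameters(region, max(a, 0.0)) if p < 1 else None
    s_g = np.asarray(s_g, dtype=float) if s_g is not None else (
        base.s_g if base is not None else np.full(n, 1.0 / n)
    )
    s_p = np.asarray(s_p, dtype=float) if s_p is not None else (
        base.s_p if base is not None else np.full(n, 1.0 / n)
    )
    return SpreadParameters(a=a, a_ci=(a, a), p=derive_p(a), s_g=s_g, s_p=s_p)


def concentrated(n, at=0):
    """Establishment vector with all mass on one county."""
    v = np.zeros(n)
    v[at] = 1.0
    return v


# --------------------------------------------------------------------------
# Independent one-step oracle: exact enumeration over the 2^n state lattice,
# conditioning on the cascading sub-step order.  Formulas are written out
# here directly so the oracle shares no code with the implementation.


def exact_one_step_marginals(q0, A, H, p, s_g, s_p, half_factor=True):
    n = len(q0)
    c = 0.5 if half_factor else 1.0
    dist = {tuple(int(x) for x in q0): 1.0}

    def substep(dist, prob_of):
        out = {}
        for state, pr in dist.items():
            q = np.array(state)
            probs = prob_of(q)
            free = [i for i in range(n) if q[i] == 0]
            for mask in range(2 ** len(free)):
                new = list(state)
                w = pr
                for b, i in enumerate(free):
                    if (mask >> b) & 1:
                        new[i] = 1
                        w *= probs[i]
                    else:
                        w *= 1.0 - probs[i]
                if w > 0:
                    key = tuple(new)
                    out[key] = out.get(key, 0.0) + w
        return out

    dist = substep(dist, lambda q: 1.0 - (1.0 - p) ** (A @ q))
    dist = substep(dist, lambda q: c * (1.0 - (1.0 - s_g) ** (H @ q)))
    dist = substep(dist, lambda q: c * (1.0 - (1.0 - s_p) ** (H @ q)))
    marg = np.zeros(n)
    for state, pr in dist.items():
        marg += pr * np.array(state)
    return marg


class TestStepKernel:
    def test_adjacency_probability_two_infested_neighbors(self):
        """1 - (1-p)^2 for a county with two infested border neighbors."""
        p = 0.2519
        records = [
            make_record("10001", year=2014),
            make_record("10002"),
            make_record("10003", year=2014),
        ]
        region = build_region(records, [("10001", "10002"), ("10002", "10003")])
        params = params_with(region, p)
        q = np.array([True, False, True])
        expected = 1.0 - (1.0 - params.p) ** 2
        assert expected == pytest.approx(0.4403, abs=5e-4)

        # Monte-Carlo check of the realized sub-step probability
        config = SimulationConfig(seed_fips="10001", horizon=1, half_factor=True)
        rng = np.random.default_rng(0)
        hits = sum(
            step(q, region, params, config, rng)[1] for _ in range(20000)
        )
        se = np.sqrt(expected * (1 - expected) / 20000)
        assert hits / 20000 == pytest.approx(expected, abs=4 * se)

    def test_garden_substep_half_prefactor(self):
        """One infested highway neighbor, s_g = 0.1: probability c * 0.1."""
        records = [
            make_record("20001", year=2014, gc=9, highways={80}),
            make_record("20002", gc=1, highways={80}),
        ]
        region = build_region(records, [("20001", "20002")])
        # adjacency inert (p = 0), population channel inert (mass on seed)
        params = params_with(
            region, 0.0, s_g=[0.9, 0.1], s_p=concentrated(2, at=0)
        )
        q = np.array([True, False])
        for half, expected in [(True, 0.05), (False, 0.10)]:
            config = SimulationConfig(seed_fips="20001", horizon=1, half_factor=half)
            rng = np.random.default_rng(1)
            hits = sum(step(q, region, params, config, rng)[1] for _ in range(20000))
            se = np.sqrt(expected * (1 - expected) / 20000)
            assert hits / 20000 == pytest.approx(expected, abs=4 * se)

    def test_infested_counties_are_absorbing(self, grid_region, grid_params):
        config = SimulationConfig(seed_fips=grid_region.fips_codes[0], horizon=1)
        q = np.ones(grid_region.n_counties, dtype=bool)
        rng = np.random.default_rng(2)
        assert step(q, grid_region, grid_params, config, rng).all()

    def test_no_highway_row_gets_zero_highway_probability(self):
        """A county with no interstate can only be reached via its border."""
        records = [
            make_record("20001", year=2014, highways={80}),
            make_record("20002", highways={80}),
            make_record("20003"),  # off the highway, not adjacent to the seed
        ]
        region = build_region(records, [("20001", "20002"), ("20002", "20003")])
        params = params_with(region, 0.0, s_g=[0.0, 0.5, 0.5], s_p=[0.0, 0.5, 0.5])
        q = np.array([True, False, False])
        config = SimulationConfig(seed_fips="20001", horizon=1)
        rng = np.random.default_rng(3)
        for _ in range(2000):
            assert not step(q, region, params, config, rng)[2]

    def test_draw_budget_three_uniforms_per_county(self, grid_region, grid_params):
        config = SimulationConfig(seed_fips=grid_region.fips_codes[0], horizon=1)
        q = np.zeros(grid_region.n_counties, dtype=bool)
        q[0] = True

        class CountingRNG:
            def __init__(self):
                self.rng = np.random.default_rng(4)
                self.n = 0

            def random(self, size):
                self.n += size
                return self.rng.random(size)

        counter = CountingRNG()
        step(q, grid_region, grid_params, config, counter)
        assert counter.n == 3 * grid_region.n_counties


class TestSimulateRun:
    def test_no_spread_with_inert_channels(self, path3_region):
        params = params_with(path3_region, 0.0, s_g=concentrated(3), s_p=concentrated(3))
        config = SimulationConfig(seed_fips="10001", horizon=6)
        hist = simulate_run(path3_region, params, config)
        assert hist.Q[0].all()
        assert not hist.Q[1:].any()

    def test_deterministic_front_at_p_one(self):
        """p = 1, no highways: infection is exactly graph distance from seed."""
        records = [make_record(f"4000{i}") for i in range(1, 6)]
        pairs = [(records[i].fips, records[i + 1].fips) for i in range(4)]
        region = build_region(records, pairs)
        params = params_with(region, 1.0, s_g=concentrated(5), s_p=concentrated(5))
        config = SimulationConfig(seed_fips="40001", horizon=4)
        hist = simulate_run(region, params, config)
        for t in range(5):
            assert hist.Q[:, t].tolist() == [d <= t for d in range(5)]

    def test_rows_monotone_and_seed_column(self, grid_region, grid_params, quick_config):
        hist = simulate_run(grid_region, grid_params, quick_config)
        assert hist.Q[:, 0].sum() == 1
        assert hist.Q[grid_region.index_of[quick_config.seed_fips], 0]
        assert (np.diff(hist.Q.astype(int), axis=1) >= 0).all()

    def test_unknown_seed_rejected(self, grid_region, grid_params):
        config = SimulationConfig(seed_fips="00000", horizon=2)
        with pytest.raises(ValueError, match="seed county"):
            simulate_run(grid_region, grid_params, config)

    def test_byte_identical_given_same_seed(self, grid_region, grid_params, quick_config):
        h1 = simulate_run(grid_region, grid_params, quick_config)
        h2 = simulate_run(grid_region, grid_params, quick_config)
        assert h1.Q.tobytes() == h2.Q.tobytes()


class TestEnsemble:
    def test_single_run_ensemble_equals_that_run(self, grid_region, grid_params):
        config = SimulationConfig(
            seed_fips=grid_region.fips_codes[0], horizon=3, n_runs=1, rng_seed=9
        )
        summary = simulate_ensemble(grid_region, grid_params, config)
        assert np.isin(summary.P, (0.0, 1.0)).all()

    def test_seed_row_identically_one(self, grid_region, grid_params, quick_config):
        summary = simulate_ensemble(grid_region, grid_params, quick_config)
        i = grid_region.index_of[quick_config.seed_fips]
        assert (summary.P[i] == 1.0).all()

    def test_proportions_monotone_and_bounded(self, grid_region, grid_params, quick_config):
        summary = simulate_ensemble(grid_region, grid_params, quick_config)
        assert ((summary.P >= 0) & (summary.P <= 1)).all()
        assert (np.diff(summary.P, axis=1) >= -1e-12).all()

    def test_path_neighbor_infested_half_the_time(self, path3_region):
        """One step at p = 0.5 infects the seed's neighbor in ~50% of runs."""
        params = params_with(path3_region, 0.5, s_g=concentrated(3), s_p=concentrated(3))
        config = SimulationConfig(
            seed_fips="10001", horizon=1, n_runs=20000, rng_seed=12
        )
        summary = simulate_ensemble(path3_region, params, config)
        se = np.sqrt(0.25 / 20000)
        assert summary.P[1, 1] == pytest.approx(0.5, abs=4 * se)
        assert summary.P[2, 1] == 0.0  # distance 2: unreachable in one step

    @pytest.mark.parametrize("half_factor", [True, False])
    def test_one_step_marginals_match_enumeration_oracle(self, half_factor):
        """Ensemble frequencies agree with exact 2^n enumeration (4 counties)."""
        records = [
            make_record("50001", year=2014, gc=6, pop=30_000, highways={95}),
            make_record("50002", gc=2, pop=10_000),
            make_record("50003", gc=1, pop=40_000, highways={95}),
            make_record("50004", gc=1, pop=20_000, highways={95}),
        ]
        pairs = [("50001", "50002"), ("50002", "50003"), ("50003", "50004")]
        region = build_region(records, pairs)
        params = params_with(region, 0.3)
        q0 = np.array([1, 0, 0, 0], dtype=bool)
        exact = exact_one_step_marginals(
            q0, region.A, region.H, params.p, params.s_g, params.s_p, half_factor
        )
        n_runs = 20000
        config = SimulationConfig(
            seed_fips="50001", horizon=1, n_runs=n_runs, rng_seed=21,
            half_factor=half_factor,
        )
        summary = simulate_ensemble(region, params, config)
        observed = summary.P[:, 1]
        se = np.sqrt(np.maximum(exact * (1 - exact), 1e-12) / n_runs)
        assert np.all(np.abs(observed - exact) <= 4 * se + 1e-9)

    def test_ensemble_byte_identical_given_same_seed(
        self, grid_region, grid_params, quick_config
    ):
        s1 = simulate_ensemble(grid_region, grid_params, quick_config)
        s2 = simulate_ensemble(grid_region, grid_params, quick_config)
        assert s1.P.tobytes() == s2.P.tobytes()


@given(seed=st.integers(0, 2**31 - 1))
def test_monotone_absorbing_for_any_stream(seed):
    """No county ever reverts, whatever the random stream."""
    region = generate_region(
        SyntheticSpec(grid_shape=(3, 3), n_highways=1, highway_length=3, rng_seed=1)
    )
    params = synthetic_parameters(region, 0.5)
    config = SimulationConfig(seed_fips=region.fips_codes[4], horizon=5, rng_seed=seed)
    hist = simulate_run(region, params, config, rng=np.random.default_rng(seed))
    assert (np.diff(hist.Q.astype(int), axis=1) >= 0).all()
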