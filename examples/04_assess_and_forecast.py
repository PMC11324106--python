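"""Score a forecast against observations, then forecast a larger region.

The assessment protocol fits the rate on 2014-2020 transitions, runs a
1000-run ensemble from the seed county, and scores the 2021 forecast by
strict majority rule (a county is model-infested iff more than half the
runs infest it).  The fitted rate is then carried to a larger region —
establishment vectors are recomputed from the larger region's own garden
center and population totals, but the rate is not refit.
"""

import numpy as np

from slfspread import (
    SimulationConfig,
    SyntheticSpec,
    generate_history,
    generate_region,
    run_assessment_protocol,
    run_forecast,
    synthetic_parameters,
)

region = generate_region(SyntheticSpec(grid_shape=(10, 10), n_highways=3,
                                       highway_length=8, rng_seed=2))
seed_fips = region.fips_codes[55]

# the "observed" record: one history generated by the model at a known rate
truth = synthetic_parameters(region, 0.2902)
status = generate_history(region, truth,
                          SimulationConfig(seed_fips=seed_fips, horizon=7),
                          rng=np.random.default_rng(2))

result = run_assessment_protocol(region, seed_fips=seed_fips, n_runs=1000,
                                 rng_seed=0, observed=status)
r = result.report
print(f"refit a = {result.params.a:.4f}, p = {result.params.p:.4f}")
print(f"2021 assessment: {r.n_correct}/{r.n_counties} correct "
      f"({r.accuracy_pct:.1f}%), {r.n_false_positive} false positives, "
      f"{r.n_false_negative} false negatives")

larger = generate_region(SyntheticSpec(grid_shape=(14, 14), n_highways=4,
                                       highway_length=10, rng_seed=3))
forecast = run_forecast(larger, result.params, seed_fips=larger.fips_codes[98],
                        start_year=2014, end_year=2025, n_runs=1000, rng_seed=0)
at_2025 = forecast.p_at(2025)
print(f"\nforecast region: {larger.n_counties} counties through 2025")
print(f"counties with >50% infestation risk in 2025: {int((at_2025 > 0.5).sum())}")
print(f"mean 2025 infestation risk: {at_2025.mean():.2f}")
# False positives are counties the model infests that the record does not;
# with a self-generated record they reflect pure Monte-Carlo spread
# variability rather than missing drivers.
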