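# slfspread

A county-level stochastic network model of spotted lanternfly (*Lycorma
delicatula*) spread, driven by human-activity factors.  The spotted
lanternfly has been expanding from its 2014 introduction point in Berks
County, PA, and its long-distance jumps track human transport rather than
its own flight range.  `slfspread` is for ecologists and invasion
modelers who want a minimal, fully parameterized, testable model of that
spread: it builds the county networks, fits the local spread probability
from year-over-year infestation records, runs Monte-Carlo ensemble
forecasts, and scores them against observed county infestation status.

## The model

Counties are nodes on two interconnected networks:

* the **border-adjacency network** `A` (`a_ij = 1` iff counties i and j
  share a border) — the short-distance channel;
* the **primary-interstate network** `H` (`h_ij = 1` iff the counties are
  transected by a common two-digit interstate) — the long-distance
  channel.

The infestation state is a boolean vector `q_t` updated annually by three
sequential Bernoulli colonization sub-steps for each uninfested county i:

1. adjacency: `Pr = 1 − (1−p)^(Σ_j a_ij q_j)`, each infested border
   neighbor an independent colonization chance;
2. garden centers: `Pr = ½ (1 − (1−s_g,i)^(Σ_j h_ij q_j))` on the highway
   network, where `s_g,i` is county i's share of the region's garden
   centers;
3. population: the same form with the population share `s_p,i`.

Sub-steps cascade within a year, infestation is absorbing, and the ½
prefactor on the highway channels is switchable.  The per-neighbor
probability is not a free knob: the rate `a` in the saturating-exponential
colonization curve `p_I(N) = 1 − e^(−aN)` is fit by nonlinear least
squares to observed year-over-year transition proportions, and
`p = 1 − e^(−a)`.  On the observed 2014–2020 record this procedure yields
`a = 0.2902`, hence `p = 0.2519`.

Forecasts are ensembles (1000 runs by default): the summary matrix `P`
holds the proportion of runs infesting each county by each year, a county
is model-classified infested iff strictly more than half the runs infest
it, and forecasts are scored by confusion counts and by per-county
accuracy `100·p_i,t` (observed infested) or `100·(1−p_i,t)` (not).

## Worked example

Every stage runs without external data: the synthetic-region generator
produces grid-county regions with interstate routes, Poisson garden-center
counts and log-normal populations, and the model itself generates
infestation histories with known parameters.  From
`examples/02_fit_colonization_rate.py`:

```
N (infested neighbors), at-risk counties, colonized next year, proportion:
  N=0: 1/999 = 0.001
  N=1: 20/71 = 0.282
  N=2: 11/23 = 0.478
  N=3: 3/5 = 0.600

true rate a = 0.2902
refit rate a = 0.3172  (95% CI 0.2970, 0.3375)
spread probability p = 1 - exp(-a) = 0.2719
```

A history simulated at `a = 0.2902` on a 168-county synthetic region is
refit from its own pooled year-over-year transitions; the recovered rate
brackets the truth within single-history binomial noise.  The other
examples build regions (`01`), run ensemble forecasts (`03`), and chain
fit → ensemble → majority-rule assessment → larger-region forecast (`04`).

The same stages are available from the shell:

```
slfspread synth --rows 6 --cols 6 --out-dir synthetic/
slfspread protocol --region synthetic/region.csv --adjacency synthetic/adjacency.csv
slfspread forecast --region big/region.csv --adjacency big/adjacency.csv \
    --params protocol_out/params.json --end-year 2025
```

## Real county data

Loaders accept county tables as CSV (`fips,name,state,year_infested,
garden_centers,population,highway_ids`, interstates semicolon-separated)
or as the published supplementary-workbook layout (XLSX, one sheet per
region), plus census-style county border pairs as two-column CSV.  The
real 166-/581-county tables are third-party data and are not
redistributed here; place transcriptions at `data/s1_166_region.csv` and
`data/s1_166_adjacency.csv` and the observed-data checks in
`tests/test_acceptance.py` and `scripts/acceptance.py` pick them up
automatically.

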