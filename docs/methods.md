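# Methods

## Model

The unit of space is the county and the unit of time is one year.  The
state is a boolean infestation vector `q_t`; infestation is absorbing (no
US county designated infested has ever been de-designated, and the model
encodes that as a hard invariant).  Spread operates on two fixed networks
over the same node set:

* **Border adjacency `A`** — symmetric, binary, zero-diagonal; the graph
  must be connected.  Short-distance spread follows the independence
  model: with `N_i = Σ_j a_ij q_j` infested neighbors, an uninfested
  county escapes each independently, so its annual colonization
  probability is `1 − (1−p)^{N_i}`.
* **Primary-interstate co-membership `H`** — `h_ij = 1` iff counties i
  and j are transected by at least one common two-digit interstate.  The
  definition "share a highway" is implemented literally as a clique per
  interstate, regardless of distance along the route; a `chain` topology
  (edges only between consecutive counties along a route, requiring an
  explicit route ordering) is available behind a switch because the
  printed definition does not distinguish the two.  Long-distance spread
  along `H` uses per-county establishment probabilities: `s_x,i` is
  county i's share of the region total of factor x (garden centers
  `s_g`, population `s_p`), so each vector sums to one and is invariant
  to rescaling the counts.

Each year applies three Bernoulli colonization sub-steps in the fixed
order adjacency → garden centers → population.  The highway sub-steps use
probability `c·(1 − (1−s_x,i)^{Σ_j h_ij q_j})` with `c = ½` by default.
Two deliberate fidelity choices:

* **The ½ prefactor** appears in the published simulation code but not in
  the printed channel equations.  The code is taken as ground truth
  (`half_factor=True` default) because the reported results were produced
  with it; `half_factor=False` gives the equation-literal variant.
* **Cascading sub-steps**: each channel sees infections created by
  earlier channels of the same year (in-place update semantics, matching
  the reference implementation).  A `synchronous` switch evaluates all
  three channels against the start-of-year state, for sensitivity
  analysis only.

## Parameterization

The adjacency probability `p` is estimated from observed year-over-year
transitions.  For each consecutive year pair (t, t+1) in the fitting
window (2014–2020 by default), every county uninfested at t contributes
one observation: its infested-neighbor count `N` and whether it was
infested by t+1.  Counts are pooled across year pairs before proportions
are formed (`pooling="per_year"` keeps one proportion per pair instead),
and the `N = 0` bin is included by default (`fit_include_zero`) — counties
colonized by highway jumps with no infested border neighbor land there and
legitimately pull the fit, since the transition record does not label the
channel.  The curve `p_I(N) = 1 − e^{−aN}` is fit by unweighted nonlinear
least squares (`scipy.optimize.curve_fit`, initial guess `a₀ = 0.1`, one
point per distinct N), mirroring default toolbox behavior; the 95% CI uses
the asymptotic standard error with a t quantile on n−1 degrees of freedom.
Degenerate inputs are explicit: an all-zero proportion table returns
`a = 0` with a warning, fewer than two populated bins is an error, and a
fully infested region (empty at-risk set) is an error.

`p = 1 − e^{−a}` maps the rate to a probability; on the observed
2014–2020 record the published procedure gives `a = 0.2902` (95% CI
0.2048–0.3756) and `p = 0.2519`.  Establishment vectors are always
renormalized over whichever region is being simulated: a rate fitted on
the assessment region transfers to a larger forecast region unchanged,
but `s_g` and `s_p` are recomputed from that region's own totals
(`transfer_parameters`).  The rate is deliberately not refit on the
larger region — no infestation data exists outside the assessment region
at fit time.

## Simulation and randomness

A run starts from exactly one infested seed county (Berks County, FIPS
42011, in the real configuration) and applies T annual steps; the default
assessment run is 2014 → 2021 (T = 7) and the extended forecast 2014 →
2025 (T = 11).  Each sub-step draws exactly one uniform per county, in
county-index order, three per county-year; a county is colonized iff its
sub-step probability strictly exceeds its draw.  Ensembles (1000 runs by
default) give each run its own PCG64 stream spawned via
`numpy.random.SeedSequence(rng_seed).spawn`, so results are bit-reproducible
for a given seed and independent of execution order.  The ensemble
summary `P` is the plain mean of the run matrices.

## Assessment

The aggregate protocol classifies a county model-infested in a year iff
strictly more than half of the runs infest it by then — a county at
exactly one half (possible with an even ensemble size) is classified NOT
infested, following the strict "more than half" rule — and reports
correct/incorrect counts, false positives (model infested, record not)
and false negatives.  The county-level protocol reports `100·p_i,t` where
the record says infested and `100·(1−p_i,t)` where it does not, per
county and year.  Assessment is restricted to the counties of the region
being scored.

## Synthetic data

The generator emulates the structural assumptions, not US geography: a
rectangular grid of counties (connected, planar, hand-checkable edge
counts) with interstate routes laid as chains of consecutive counties
along rows — so highway hops are long-range relative to border adjacency,
as in the real system — Poisson garden-center counts (mean 8 per county)
and log-normal populations (log-mean 10.8, log-sd 1.0: median ≈ 49k
persons, bulk roughly 7k–360k, matching the county-size range the model
is used on).  Infestation histories are generated by the model itself
from known parameters, which is what makes parameter-recovery experiments
possible without any download.  What synthetic tests do not show: real
county shapes and covariate spatial correlation, non-uniform surveillance
effort, or any spread channel the model lacks (rail, air, waterways);
passing them validates the machinery and its statistics, not the model's
ecological adequacy.

## Problem sizes and numerical choices

Test and acceptance runs use grids of 9–400 counties with ensembles of
50–20 000 runs, sized so every stochastic check has a stated error bound:
one-step marginals are compared against exact 2^n enumeration on ≤ 5
counties within 4 binomial standard errors at 20 000 runs, and parameter
recovery asserts the median refit rate over 50 histories at a generating
rate of 0.3 lies in [0.2, 0.4] — an interval, not a point, because
single-history transition proportions are binomial draws.  The
full-protocol quantities in `scripts/acceptance.py` use a 12×14-county
synthetic region (168 counties, comparable to the 166-county assessment
region) with 1000-run ensembles.

## Known limitations

* The real 166-/581-county tables are third-party data and are not
  bundled; observed-data checks activate only when a transcription is
  supplied under `data/`.
* The supplementary-workbook reader matches column headers by alias and
  is validated against a synthetic workbook, not the original file.
* The fit treats each distinct-N proportion as one unweighted point;
  weighted or binomial-likelihood variants are out of scope.
* No within-year dynamics, distance weighting, or channels beyond border
  adjacency and the primary-interstate overlay.
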