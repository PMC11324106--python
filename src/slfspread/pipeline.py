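"""End-to-end protocols: fit -> simulate -> assess -> forecast.

Two reference workflows are provided.  The assessment protocol fits the
colonization rate on year-over-year transitions within a region, runs a
Monte-Carlo ensemble from the single 2014 seed county, and scores the
final-year forecast against the observed status.  The forecast protocol
reuses a previously fitted rate on a (typically larger) region — the rate
is NOT refit, since no infestation data exists outside the fitting region
at fit time — while the establishment vectors are recomputed from the
forecast region's own covariate totals.

All tabular outputs carry a ``#`` metadata header (package version, rng
seed, config hash) sufficient to re-run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .assessment import (
    AccuracyReport,
    CountyAccuracy,
    aggregate_accuracy,
    classify_majority,
    county_accuracy_over_time,
)
from .parameterization import (
    SpreadParameters,
    establishment_vector,
    estimate_spread_parameters,
)
from .region_data import BERKS_FIPS, ObservedStatus, Region, observed_status
from .simulator import EnsembleSummary, SimulationConfig, simulate_ensemble

logger = logging.getLogger(__name__)

__all__ = [
    "ProtocolResult",
    "run_assessment_protocol",
    "run_forecast",
    "transfer_parameters",
    "write_parameters",
    "read_parameters",
    "write_ensemble_csv",
    "read_ensemble_csv",
    "write_accuracy_report",
    "write_county_accuracy_csv",
]


@dataclass(frozen=True)
class ProtocolResult:
    """Everything the assessment protocol produces."""

    params: SpreadParameters
    ensemble: EnsembleSummary
    report: AccuracyReport
    county_accuracy: CountyAccuracy
    observed: ObservedStatus


def run_assessment_protocol(
    region: Region,
    seed_fips: str = BERKS_FIPS,
    start_year: int = 2014,
    assess_year: int = 2021,
    fit_through: int = 2020,
    n_runs: int = 1000,
    rng_seed: int = 0,
    half_factor: bool = True,
    fit_include_zero: bool = True,
    observed: ObservedStatus | None = None,
) -> ProtocolResult:
    """Fit, simulate and assess within one region.

    The rate is fit on pooled consecutive transitions ``start_year ..
    fit_through``; the ensemble runs ``assess_year - start_year`` annual
    steps from the single seed county and is scored against the observed
    ``assess_year`` status by strict majority rule.  ``observed`` defaults
    to the status implied by the region's recorded infestation years.
    """
    if observed is None:
        observed = observed_status(region, range(start_year, assess_year + 1))
    fit_pairs = [(t, t + 1) for t in range(start_year, fit_through)]
    params = estimate_spread_parameters(
        region, observed, year_pairs=fit_pairs, include_zero=fit_include_zero
    )
    logger.info("fitted a=%.4f (95%% CI %.4f-%.4f), p=%.4f", params.a, *params.a_ci, params.p)
    config = SimulationConfig(
        seed_fips=seed_fips,
        start_year=start_year,
        horizon=assess_year - start_year,
        n_runs=n_runs,
        rng_seed=rng_seed,
        half_factor=half_factor,
    )
    ensemble = simulate_ensemble(region, params, config)
    pred = classify_majority(ensemble, assess_year)
    report = aggregate_accuracy(pred, observed.at_year(assess_year), year=assess_year)
    county_acc = county_accuracy_over_time(ensemble, observed)
    logger.info(
        "%d/%d counties correct (%.1f%%), %d FP, %d FN",
        report.n_correct,
        report.n_counties,
        report.accuracy_pct,
        report.n_false_positive,
        report.n_false_negative,
    )
    return ProtocolResult(params, ensemble, report, county_acc, observed)


def transfer_parameters(params: SpreadParameters, region: Region) -> SpreadParameters:
    """Carry a fitted rate to another region, recomputing the s vectors.

    Establishment vectors are shares of region totals, so they must be
    renormalized over whichever region is simulated.
    """
    return SpreadParameters(
        a=params.a,
        a_ci=params.a_ci,
        p=params.p,
        s_g=establishment_vector(region, "garden_centers"),
        s_p=establishment_vector(region, "population"),
    )


def run_forecast(
    region: Region,
    fitted: SpreadParameters,
    seed_fips: str = BERKS_FIPS,
    start_year: int = 2014,
    end_year: int = 2025,
    n_runs: int = 1000,
    rng_seed: int = 0,
    half_factor: bool = True,
) -> EnsembleSummary:
    """Forecast ensemble on a region using an externally fitted rate."""
    params = transfer_parameters(fitted, region)
    config = SimulationConfig(
        seed_fips=seed_fips,
        start_year=start_year,
        horizon=end_year - start_year,
        n_runs=n_runs,
        rng_seed=rng_seed,
        half_factor=half_factor,
    )
    return simulate_ensemble(region, params, config)


# --------------------------------------------------------------------------
# Artifact I/O with reproducibility metadata


def _config_hash(meta: dict) -> str:
    payload = json.dumps(meta, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _metadata(rng_seed: int | None, extra: dict | None = None) -> dict:
    meta = {"package": f"slfspread {__version__}"}
    if rng_seed is not None:
        meta["rng_seed"] = rng_seed
    if extra:
        meta.update(extra)
    meta["config_hash"] = _config_hash(meta)
    return meta


def _header_lines(meta: dict) -> str:
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def write_parameters(
    params: SpreadParameters, fips_codes: Sequence[str], path: str | Path,
    rng_seed: int | None = None,
) -> None:
    """Write fitted parameters as JSON: a, CI, p, and s vectors by FIPS."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "metadata": _metadata(rng_seed),
        "a": params.a,
        "a_ci": list(params.a_ci),
        "p": params.p,
        "s_g": dict(zip(fips_codes, params.s_g.tolist())),
        "s_p": dict(zip(fips_codes, params.s_p.tolist())),
    }
    path.write_text(json.dumps(payload, indent=2))


def read_parameters(path: str | Path) -> tuple[SpreadParameters, tuple[str, ...]]:
    payload = json.loads(Path(path).read_text())
    fips = tuple(payload["s_g"])
    params = SpreadParameters(
        a=payload["a"],
        a_ci=tuple(payload["a_ci"]),
        p=payload["p"],
        s_g=np.array([payload["s_g"][f] for f in fips]),
        s_p=np.array([payload["s_p"][f] for f in fips]),
    )
    return params, fips


def write_ensemble_csv(
    summary: EnsembleSummary, path: str | Path, rng_seed: int | None = None
) -> None:
    """Proportion-infested matrix as CSV: rows FIPS, columns years."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(summary.P, index=list(summary.fips_codes), columns=list(summary.years))
    df.index.name = "fips"
    meta = _metadata(rng_seed, {"n_runs": summary.n_runs})
    with path.open("w", encoding="utf-8") as fh:
        fh.write(_header_lines(meta))
        df.to_csv(fh)


def read_ensemble_csv(path: str | Path) -> EnsembleSummary:
    n_runs = 0
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("# n_runs:"):
                n_runs = int(line.split(":")[1])
            if not line.startswith("#"):
                break
    df = pd.read_csv(path, comment="#", dtype={"fips": str}).set_index("fips")
    return EnsembleSummary(
        fips_codes=tuple(df.index),
        years=tuple(int(c) for c in df.columns),
        P=df.to_numpy(),
        n_runs=n_runs or 1,
    )


def write_accuracy_report(report: AccuracyReport, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "metadata": _metadata(None),
        "year": report.year,
        "n_counties": report.n_counties,
        "n_correct": report.n_correct,
        "n_incorrect": report.n_incorrect,
        "n_false_positive": report.n_false_positive,
        "n_false_negative": report.n_false_negative,
        "accuracy_pct": report.accuracy_pct,
    }
    path.write_text(json.dumps(payload, indent=2))


def write_county_accuracy_csv(acc: CountyAccuracy, path: str | Path) -> None:
    """Per-county accuracy-over-time percentages: rows FIPS, columns years."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(acc.pct, index=list(acc.fips_codes), columns=list(acc.years))
    df.index.name = "fips"
    with path.open("w", encoding="utf-8") as fh:
        fh.write(_header_lines(_metadata(None)))
        df.to_csv(fh)
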