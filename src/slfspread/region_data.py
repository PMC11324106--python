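"""County regions and their two interconnected networks.

A modeled region is a set of counties carrying covariates (garden-center
counts, population, the primary two-digit interstates that transect them)
and an observed infestation year, together with two symmetric binary
county-by-county matrices:

* ``A`` — border adjacency (``A[i, j] = 1`` iff counties i and j share a
  border), the channel for short-distance spread;
* ``H`` — highway co-membership (``H[i, j] = 1`` iff the counties are
  transected by at least one common primary interstate), the channel for
  long-distance, human-activity-mediated spread.

Counties are identified by 5-digit FIPS codes throughout; positional
indices are an internal detail of the matrices.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "CountyRecord",
    "Region",
    "ObservedStatus",
    "SchemaError",
    "ValidationError",
    "load_county_table",
    "build_adjacency_matrix",
    "build_highway_matrix",
    "build_region",
    "load_adjacency_pairs",
    "observed_status",
    "write_county_table",
    "write_adjacency_pairs",
]

#: First year of the observed US infestation record used for fitting.
FIRST_OBSERVED_YEAR = 2014

#: FIPS code of Berks County, PA — the 2014 introduction point.
BERKS_FIPS = "42011"

REQUIRED_COLUMNS = (
    "fips",
    "name",
    "state",
    "year_infested",
    "garden_centers",
    "population",
    "highway_ids",
)

#: Delimiter separating interstate IDs inside the ``highway_ids`` CSV field.
HIGHWAY_DELIMITER = ";"


class SchemaError(ValueError):
    """An input table is missing a required column."""


class ValidationError(ValueError):
    """An input table has structurally valid but inconsistent content."""


@dataclass(frozen=True)
class CountyRecord:
    """One county: identifiers, covariates, and observed infestation year.

    Parameters
    ----------
    fips:
        5-digit county FIPS code (string, preserving leading zeros).
    name, state:
        County name and 2-letter state code.
    year_infested:
        Year the county was designated infested, or ``None`` if never.
    garden_centers:
        Number of garden-center businesses in the county (>= 0).
    population:
        County population (> 0).
    highway_ids:
        Primary (two-digit) interstate IDs transecting the county; may be
        empty.
    """

    fips: str
    name: str
    state: str
    year_infested: int | None
    garden_centers: int
    population: int
    highway_ids: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(self.fips) != 5 or not self.fips.isdigit():
            raise ValidationError(f"FIPS must be a 5-digit string, got {self.fips!r}")
        if self.population <= 0:
            raise ValidationError(f"county {self.fips}: population must be positive")
        if self.garden_centers < 0:
            raise ValidationError(f"county {self.fips}: garden_centers must be >= 0")
        if self.year_infested is not None and self.year_infested < FIRST_OBSERVED_YEAR:
            raise ValidationError(
                f"county {self.fips}: year_infested {self.year_infested} predates "
                f"{FIRST_OBSERVED_YEAR}"
            )


@dataclass(frozen=True)
class Region:
    """An ordered county list with its adjacency and highway matrices."""

    counties: tuple[CountyRecord, ...]
    A: np.ndarray
    H: np.ndarray
    index_of: dict[str, int]

    def __post_init__(self) -> None:
        n = len(self.counties)
        for label, M in (("A", self.A), ("H", self.H)):
            if M.shape != (n, n):
                raise ValidationError(f"{label} has shape {M.shape}, expected {(n, n)}")
            if not np.array_equal(M, M.T):
                raise ValidationError(f"{label} is not symmetric")
            if np.any(np.diag(M) != 0):
                raise ValidationError(f"{label} has a nonzero diagonal")
            if not np.isin(M, (0, 1)).all():
                raise ValidationError(f"{label} is not binary")

    @property
    def n_counties(self) -> int:
        return len(self.counties)

    @property
    def fips_codes(self) -> tuple[str, ...]:
        return tuple(c.fips for c in self.counties)

    def is_connected(self) -> bool:
        """True iff the border-adjacency graph is connected."""
        import networkx as nx

        g = nx.from_numpy_array(self.A)
        return nx.is_connected(g)


@dataclass(frozen=True)
class ObservedStatus:
    """Observed boolean infestation status per county and year.

    ``q[i, k] = 1`` iff county i was designated infested in or before
    ``years[k]``.  Rows are monotone nondecreasing: no county reverts.
    """

    fips_codes: tuple[str, ...]
    years: tuple[int, ...]
    q: np.ndarray  # bool, county x year

    def __post_init__(self) -> None:
        if self.q.shape != (len(self.fips_codes), len(self.years)):
            raise ValidationError("status matrix shape does not match labels")
        if np.any(np.diff(self.q.astype(np.int8), axis=1) < 0):
            raise ValidationError("observed status must be monotone in time")

    def at_year(self, year: int) -> np.ndarray:
        return self.q[:, self.years.index(year)].copy()


def _parse_highway_ids(raw: str) -> frozenset[int]:
    raw = raw.strip()
    if not raw:
        return frozenset()
    return frozenset(int(tok) for tok in raw.split(HIGHWAY_DELIMITER) if tok.strip())


def _parse_year(raw) -> int | None:
    if raw is None:
        return None
    text = str(raw).strip()
    if not text or text.lower() in {"na", "nan", "none"}:
        return None
    return int(float(text))


def _record_from_mapping(row: dict) -> CountyRecord:
    return CountyRecord(
        fips=str(row["fips"]).strip().zfill(5),
        name=str(row["name"]).strip(),
        state=str(row["state"]).strip(),
        year_infested=_parse_year(row["year_infested"]),
        garden_centers=int(float(row["garden_centers"])),
        population=int(float(row["population"])),
        highway_ids=_parse_highway_ids(str(row["highway_ids"] or "")),
    )


def _check_duplicates(records: Sequence[CountyRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.fips in seen:
            raise ValidationError(f"duplicate FIPS {rec.fips} in county table")
        seen.add(rec.fips)


def load_county_table(
    path: str | Path,
    dialect: Literal["csv", "s1_xlsx"] = "csv",
    sheet: str | None = None,
) -> list[CountyRecord]:
    """Load and validate a county table.

    Parameters
    ----------
    path:
        CSV file (UTF-8, header row, ``#`` comment lines allowed) or an
        XLSX workbook laid out like the published supplementary data
        (one sheet per region).
    dialect:
        ``"csv"`` (default) or ``"s1_xlsx"``.
    sheet:
        Sheet name for the XLSX dialect (e.g. ``"166 Region Data"``).

    Returns
    -------
    list of validated :class:`CountyRecord`, in file order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"county table not found: {path}")
    if dialect == "csv":
        rows = _read_csv_rows(path)
    elif dialect == "s1_xlsx":
        rows = _read_s1_xlsx_rows(path, sheet)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    records = [_record_from_mapping(row) for row in rows]
    if not records:
        raise ValidationError(f"county table {path} is empty")
    _check_duplicates(records)
    logger.info("loaded %d counties from %s", len(records), path)
    return records


def _read_csv_rows(path: Path) -> list[dict]:
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(line for line in fh if not line.startswith("#"))
        header = reader.fieldnames or []
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"county table {path} missing column(s): {', '.join(missing)}")
        return list(reader)


# Header aliases for the supplementary-workbook dialect; matching is
# case-insensitive on alphanumerics only.
_S1_ALIASES: dict[str, tuple[str, ...]] = {
    "fips": ("fips", "fipscode"),
    "name": ("name", "county", "countyname"),
    "state": ("state", "st"),
    "year_infested": ("yearinfested", "yeardesignatedinfested", "infestedyear", "year"),
    "garden_centers": ("gardencenters", "numbergardencenters", "gardencentercount"),
    "population": ("population", "pop", "population2019"),
    "highway_ids": ("highwayids", "interstates", "primaryinterstates", "interstatenumbers", "highways"),
}


def _normalize_header(text: str) -> str:
    return "".join(ch for ch in str(text).lower() if ch.isalnum())


def _read_s1_xlsx_rows(path: Path, sheet: str | None) -> list[dict]:
    from openpyxl import load_workbook

    wb = load_workbook(path, read_only=True, data_only=True)
    ws = wb[sheet] if sheet else wb.worksheets[0]
    rows = ws.iter_rows(values_only=True)
    header = next(rows)
    colmap: dict[str, int] = {}
    for idx, cell in enumerate(header):
        norm = _normalize_header(cell or "")
        for canon, aliases in _S1_ALIASES.items():
            if norm in aliases and canon not in colmap:
                colmap[canon] = idx
    missing = [c for c in REQUIRED_COLUMNS if c not in colmap]
    if missing:
        raise SchemaError(f"sheet {ws.title!r} missing column(s): {', '.join(missing)}")
    out = []
    for raw in rows:
        if raw is None or all(v is None for v in raw):
            continue
        row = {canon: raw[idx] for canon, idx in colmap.items()}
        # interstates may be stored numerically or delimited by , ; or /
        hw = row["highway_ids"]
        if hw is not None:
            row["highway_ids"] = (
                str(hw).replace(",", HIGHWAY_DELIMITER).replace("/", HIGHWAY_DELIMITER)
            )
        out.append(row)
    wb.close()
    return out


def load_adjacency_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column CSV of FIPS pairs (census county-adjacency style)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"adjacency pair file not found: {path}")
    pairs = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(line for line in fh if not line.startswith("#"))
        for row in reader:
            if not row or row[0].lower() in {"fips1", "fips_a", "fips"}:
                continue
            pairs.append((row[0].strip().zfill(5), row[1].strip().zfill(5)))
    return pairs


def build_adjacency_matrix(
    records: Sequence[CountyRecord], pairs: Iterable[tuple[str, str]]
) -> np.ndarray:
    """Symmetric binary border-adjacency matrix from FIPS pairs.

    Pairs mentioning a FIPS outside the region are dropped (census
    adjacency lists cross region borders); self-pairs are ignored.
    """
    index = {rec.fips: i for i, rec in enumerate(records)}
    n = len(records)
    A = np.zeros((n, n), dtype=np.uint8)
    dropped = 0
    for a, b in pairs:
        if a == b:
            continue
        if a not in index or b not in index:
            dropped += 1
            continue
        i, j = index[a], index[b]
        A[i, j] = A[j, i] = 1
    if dropped:
        logger.info("dropped %d adjacency pairs outside the region", dropped)
    return A


def build_highway_matrix(
    records: Sequence[CountyRecord],
    topology: Literal["clique", "chain"] = "clique",
    route_order: dict[int, Sequence[str]] | None = None,
) -> np.ndarray:
    """Symmetric binary highway matrix: counties sharing an interstate.

    With the default ``clique`` topology every pair of counties transected
    by a common primary interstate is linked, regardless of distance along
    the route (the literal reading of "share a highway").  The ``chain``
    alternative links only consecutive counties along each route and
    requires ``route_order``: interstate ID -> ordered FIPS list.
    """
    index = {rec.fips: i for i, rec in enumerate(records)}
    n = len(records)
    H = np.zeros((n, n), dtype=np.uint8)
    if topology == "clique":
        by_highway: dict[int, list[int]] = {}
        for i, rec in enumerate(records):
            for hid in rec.highway_ids:
                by_highway.setdefault(hid, []).append(i)
        for members in by_highway.values():
            for a_pos, i in enumerate(members):
                for j in members[a_pos + 1 :]:
                    H[i, j] = H[j, i] = 1
    elif topology == "chain":
        if route_order is None:
            raise ValueError("chain topology requires route_order (interstate -> ordered FIPS)")
        for hid, route in route_order.items():
            route_idx = [index[f] for f in route if f in index]
            for i, j in zip(route_idx, route_idx[1:]):
                H[i, j] = H[j, i] = 1
    else:
        raise ValueError(f"unknown highway topology {topology!r}")
    return H


def build_region(
    records: Sequence[CountyRecord],
    pairs: Iterable[tuple[str, str]],
    highway_topology: Literal["clique", "chain"] = "clique",
    route_order: dict[int, Sequence[str]] | None = None,
    require_connected: bool = True,
) -> Region:
    """Assemble a validated :class:`Region` from records and border pairs."""
    _check_duplicates(records)
    A = build_adjacency_matrix(records, pairs)
    H = build_highway_matrix(records, topology=highway_topology, route_order=route_order)
    region = Region(
        counties=tuple(records),
        A=A,
        H=H,
        index_of={rec.fips: i for i, rec in enumerate(records)},
    )
    if require_connected and region.n_counties > 1 and not region.is_connected():
        raise ValidationError("border-adjacency graph is not connected")
    logger.info(
        "region: %d counties, %d border edges, %d highway edges",
        region.n_counties,
        int(A.sum()) // 2,
        int(H.sum()) // 2,
    )
    return region


def observed_status(region: Region, years: Sequence[int]) -> ObservedStatus:
    """Observed boolean status matrix q over ``years`` from infestation years."""
    years = tuple(int(y) for y in years)
    if not years:
        raise ValueError("years must be nonempty")
    if any(y2 <= y1 for y1, y2 in zip(years, years[1:])):
        raise ValueError("years must be strictly increasing")
    if years[0] < FIRST_OBSERVED_YEAR:
        raise ValueError(f"observed record starts in {FIRST_OBSERVED_YEAR}")
    q = np.zeros((region.n_counties, len(years)), dtype=bool)
    for i, rec in enumerate(region.counties):
        if rec.year_infested is not None:
            q[i] = np.array(years) >= rec.year_infested
    return ObservedStatus(fips_codes=region.fips_codes, years=years, q=q)


def write_county_table(
    records: Sequence[CountyRecord], path: str | Path, header_comment: str | None = None
) -> None:
    """Write records in the CSV dialect :func:`load_county_table` reads."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        writer = csv.writer(fh)
        writer.writerow(REQUIRED_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.fips,
                    rec.name,
                    rec.state,
                    rec.year_infested if rec.year_infested is not None else "",
                    rec.garden_centers,
                    rec.population,
                    HIGHWAY_DELIMITER.join(str(h) for h in sorted(rec.highway_ids)),
                ]
            )


def write_adjacency_pairs(
    pairs: Iterable[tuple[str, str]], path: str | Path, header_comment: str | None = None
) -> None:
    """Write FIPS border pairs as the two-column CSV the loader reads."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        writer = csv.writer(fh)
        writer.writerow(["fips1", "fips2"])
        for a, b in pairs:
            writer.writerow([a, b])
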