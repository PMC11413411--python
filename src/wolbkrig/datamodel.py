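"""Population tables: domain types, CSV I/O, duplicate-location filtering, pooling.

The unit of observation is a sampled *Rhagoletis cerasi* population: a
location, a sampling year, the number of individuals genotyped for the
wCer2 *Wolbachia* strain (``n``), and the number found infected (``k``).
Optionally each individual carries a mitochondrial COI haplotype call
(HT1/HT2).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PopulationSample",
    "PopulationTable",
    "PoolingResult",
    "SchemaError",
    "ValidationError",
    "read_population_table",
    "write_population_table",
    "filter_duplicate_locations",
    "pool_groups",
    "load_survey_table",
]

REQUIRED_COLUMNS = ("id", "lat", "lon", "year", "n", "k")
OPTIONAL_COLUMNS = ("haplotypes", "range_label")
HAPLOTYPE_LABELS = frozenset({"HT1", "HT2", "unknown"})
RANGE_LABELS = frozenset({"native", "introduced"})


class SchemaError(ValueError):
    """The input table lacks required columns."""


class ValidationError(ValueError):
    """One or more rows violate the domain invariants."""


@dataclass(frozen=True)
class PopulationSample:
    """A single sampled population with infection counts.

    ``k`` of ``n`` genotyped individuals carry wCer2, so ``k / n`` is the
    field estimate of the local infection frequency.
    """

    id: str
    lat: float
    lon: float
    year: int
    n: int
    k: int
    haplotypes: tuple[str, ...] | None = None
    range_label: str = "native"

    def __post_init__(self) -> None:
        problems = sample_problems(self)
        if problems:
            raise ValidationError(f"invalid sample {self.id!r}: " + "; ".join(problems))

    @property
    def p_hat(self) -> float:
        return self.k / self.n


def sample_problems(s: PopulationSample) -> list[str]:
    """Return a list of invariant violations (empty when valid)."""
    out: list[str] = []
    if not -90.0 <= s.lat <= 90.0:
        out.append(f"lat {s.lat} outside [-90, 90]")
    if not -180.0 <= s.lon <= 180.0:
        out.append(f"lon {s.lon} outside [-180, 180]")
    if s.n < 1:
        out.append(f"n={s.n} < 1")
    if not 0 <= s.k <= s.n:
        out.append(f"k={s.k} outside [0, n={s.n}]")
    if s.haplotypes is not None:
        if len(s.haplotypes) > s.n:
            out.append(f"{len(s.haplotypes)} haplotype calls for n={s.n} individuals")
        bad = sorted(set(s.haplotypes) - HAPLOTYPE_LABELS)
        if bad:
            out.append(f"unknown haplotype labels {bad}")
    if s.range_label not in RANGE_LABELS:
        out.append(f"range_label {s.range_label!r} not in {sorted(RANGE_LABELS)}")
    return out


@dataclass
class PopulationTable:
    """An ordered collection of :class:`PopulationSample` with unique ids."""

    samples: list[PopulationSample] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate population ids: {dupes}")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def __getitem__(self, key: str) -> PopulationSample:
        for s in self.samples:
            if s.id == key:
                return s
        raise KeyError(key)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.samples]

    def coordinates(self) -> np.ndarray:
        """(n, 2) array of (lat, lon)."""
        return np.array([(s.lat, s.lon) for s in self.samples], dtype=float).reshape(-1, 2)

    def frequencies(self) -> np.ndarray:
        return np.array([s.p_hat for s in self.samples], dtype=float)

    def subset(self, range_label: str) -> "PopulationTable":
        return PopulationTable([s for s in self.samples if s.range_label == range_label])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            rows.append(
                {
                    "id": s.id,
                    "lat": s.lat,
                    "lon": s.lon,
                    "year": s.year,
                    "n": s.n,
                    "k": s.k,
                    "haplotypes": ";".join(s.haplotypes) if s.haplotypes is not None else "",
                    "range_label": s.range_label,
                }
            )
        return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS))


@dataclass(frozen=True)
class PoolingResult:
    """Counts summed over a group of populations."""

    group_label: str
    n_total: int
    k_total: int

    def __post_init__(self) -> None:
        if not 0 <= self.k_total <= self.n_total:
            raise ValidationError(
                f"pooled k={self.k_total} outside [0, n={self.n_total}] for {self.group_label!r}"
            )

    @property
    def n(self) -> int:  # duck-compatible with PopulationSample for tests
        return self.n_total

    @property
    def k(self) -> int:
        return self.k_total

    @property
    def p_hat(self) -> float:
        return self.k_total / self.n_total


def _row_to_sample(row: pd.Series) -> PopulationSample:
    hap_raw = row.get("haplotypes", "")
    haplotypes: tuple[str, ...] | None
    if hap_raw is None or (isinstance(hap_raw, float) and np.isnan(hap_raw)) or str(hap_raw) == "":
        haplotypes = None
    else:
        haplotypes = tuple(h.strip() for h in str(hap_raw).split(";") if h.strip())
    range_label = row.get("range_label", "native")
    if range_label is None or (isinstance(range_label, float) and np.isnan(range_label)) or str(range_label) == "":
        range_label = "native"
    return PopulationSample(
        id=str(row["id"]),
        lat=float(row["lat"]),
        lon=float(row["lon"]),
        year=int(row["year"]),
        n=int(row["n"]),
        k=int(row["k"]),
        haplotypes=haplotypes,
        range_label=str(range_label),
    )


def table_from_frame(df: pd.DataFrame) -> PopulationTable:
    """Validate a DataFrame row-by-row into a :class:`PopulationTable`.

    Raises :class:`ValidationError` naming every offending row (0-based
    position in the frame) so a user can fix the file in one pass.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    samples: list[PopulationSample] = []
    errors: list[str] = []
    for idx, (_, row) in enumerate(df.iterrows()):
        try:
            samples.append(_row_to_sample(row))
        except (ValidationError, ValueError, TypeError) as exc:
            errors.append(f"row {idx}: {exc}")
    if errors:
        raise ValidationError("invalid rows:\n" + "\n".join(errors))
    return PopulationTable(samples)


def read_population_table(
    path: str | Path | io.TextIOBase, dialect: dict[str, str] | None = None
) -> PopulationTable:
    """Read a population CSV (UTF-8, header row) into a validated table.

    Parameters
    ----------
    path
        CSV file with columns ``id, lat, lon, year, n, k`` and optional
        ``haplotypes`` (semicolon-joined labels) and ``range_label``.
    dialect
        Optional map from the file's column names to the canonical names,
        e.g. ``{"latitude": "lat"}``.
    """
    df = pd.read_csv(path, encoding="utf-8")
    if dialect:
        df = df.rename(columns=dialect)
    return table_from_frame(df)


def write_population_table(table: PopulationTable, path: str | Path) -> None:
    """Write a table in the same CSV dialect :func:`read_population_table` reads."""
    df = table.to_frame()
    # fixed float formatting keeps identical inputs byte-identical on disk
    df.to_csv(path, index=False, float_format="%.6f", encoding="utf-8", lineterminator="\n")


def filter_duplicate_locations(
    table: PopulationTable, seed: int, tol_deg: float = 1e-3
) -> PopulationTable:
    """Keep one population per distinct location, chosen at random.

    Spatial variance estimation requires independent observations, so
    locations sampled more than once are thinned to a single population.
    Two samples share a location when their coordinates agree within
    ``tol_deg`` (~100 m at 1e-3 degrees) in *both* axes; groups are the
    connected components of that relation. Exactly one member of each
    group survives, drawn uniformly with ``seed``; output preserves
    input order. Deterministic given (table, seed, tol_deg).
    """
    if tol_deg < 0:
        raise ValueError("tol_deg must be >= 0")
    n = len(table)
    coords = table.coordinates()
    # union-find over the "within tolerance in both axes" relation
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        close = np.flatnonzero(
            (np.abs(coords[:, 0] - coords[i, 0]) <= tol_deg)
            & (np.abs(coords[:, 1] - coords[i, 1]) <= tol_deg)
        )
        ri = find(i)
        for j in close:
            rj = find(int(j))
            if ri != rj:
                parent[rj] = ri
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    rng = np.random.default_rng(seed)
    keep: set[int] = set()
    # iterate groups in order of first appearance for determinism
    for root in sorted(groups, key=lambda r: groups[r][0]):
        members = groups[root]
        keep.add(members[int(rng.integers(len(members)))])
    return PopulationTable([s for i, s in enumerate(table.samples) if i in keep])


def pool_groups(
    table: PopulationTable, grouping: dict[str, str]
) -> list[PoolingResult]:
    """Sum (n, k) over populations sharing a group label.

    ``grouping`` maps population id -> group label; every id must exist in
    the table. Results are ordered by first appearance of each label.
    """
    unknown = [pid for pid in grouping if pid not in set(table.ids)]
    if unknown:
        raise KeyError(f"ids not in table: {sorted(unknown)}")
    totals: dict[str, list[int]] = {}
    order: list[str] = []
    for s in table.samples:
        if s.id not in grouping:
            continue
        label = grouping[s.id]
        if label not in totals:
            totals[label] = [0, 0]
            order.append(label)
        totals[label][0] += s.n
        totals[label][1] += s.k
    return [PoolingResult(label, *totals[label]) for label in order]


def load_survey_table() -> PopulationTable:
    """Load the packaged 2018–2022 wCer2 field survey (15 populations).

    Fourteen native-range populations plus the introduced Niagara County
    (USA) population, with published per-population sample sizes, infected
    counts and haplotype calls. Latitude/longitude are approximate
    representative locations for each named region (synthetic stand-ins;
    the published dataset does not print coordinates in-table), adequate
    for exercising the spatial stages but not for reanalysis of real
    geography.
    """
    here = Path(__file__).parent / "data" / "survey_2018_2022.csv"
    return read_population_table(here)
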