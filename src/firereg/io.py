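"""Domain data model and file I/O for fire-history datasets.

Sites, trees and fire scars are plain dataclasses. Fire-scar chronologies
are exchanged in a minimal FHX2 dialect (the community standard for
fire-scar data); trees and site metadata travel as delimited tables
(comma or tab, sniffed from the header row).

The FHX dialect recognised here uses one character per tree-year:

    ``D``   scar, dormant season
    ``U``   scar, season unknown (other season letters are normalised to U)
    ``|``   recorder year (open catface, no scar)
    ``.``   non-recorder year (tree alive, not recording)
    space   null (outside the series span)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "SiteMeta",
    "TreeRecord",
    "FireScarRecord",
    "ValidationReport",
    "FhxParseError",
    "read_fhx",
    "write_fhx",
    "read_tree_table",
    "read_site_table",
    "validate_dataset",
    "dedupe_scars",
]

SPECIES = {"PIPO", "PSME", "PICO", "POTR", "PIFL", "other"}
COVER_TYPES = {
    "ponderosa", "douglas_fir", "lodgepole", "aspen", "limber",
    "mixed_conifer", "grass_shrub", "other",
}
YEAR_MIN, YEAR_MAX = 1400, 2100

# Elevation bounds of the montane study zone; violations are flagged,
# not rejected.
STUDY_ZONE_ELEV_M = (1800.0, 3000.0)


@dataclass
class SiteMeta:
    """Metadata for one sampled site (stand- or plot-level)."""

    site_id: str
    site_type: str = "stand"          # {stand, plot}
    area_ha: float = 100.0
    elevation_m: float = 2200.0
    slope_deg: float = 10.0
    aspect_deg: float = 180.0
    cover_type: str = "ponderosa"
    dist_grassland_m: float | None = None
    dist_ravine_m: float | None = None
    x: float = 0.0
    y: float = 0.0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.site_type not in {"stand", "plot"}:
            raise ValueError(f"unknown site_type {self.site_type!r}")
        if self.area_ha <= 0:
            raise ValueError("area_ha must be positive")
        if not 0.0 <= self.slope_deg <= 90.0:
            raise ValueError("slope_deg must be in [0, 90]")
        if not 0.0 <= self.aspect_deg < 360.0:
            raise ValueError("aspect_deg must be in [0, 360)")
        if self.cover_type not in COVER_TYPES:
            raise ValueError(f"unknown cover_type {self.cover_type!r}")
        lo, hi = STUDY_ZONE_ELEV_M
        if not lo <= self.elevation_m <= hi:
            warnings.warn(
                f"site {self.site_id}: elevation {self.elevation_m} m outside "
                f"the montane study zone [{lo}, {hi}] m",
                stacklevel=2,
            )


@dataclass
class TreeRecord:
    """One dated tree: raw core data plus the derived establishment year."""

    site_id: str
    tree_id: str
    species: str = "PIPO"
    inner_ring_year: int | None = None
    pith_offset_yr: int = 0
    coring_height_offset_yr: int = 0
    establishment_year: int | None = None
    status: str = "live"              # {live, dead}
    dbh_cm: float | None = None
    excluded: bool = False
    exclusion_reason: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.pith_offset_yr < 0 or self.coring_height_offset_yr < 0:
            raise ValueError("pith/coring offsets must be >= 0")
        if (
            self.establishment_year is not None
            and self.inner_ring_year is not None
            and self.establishment_year > self.inner_ring_year
        ):
            raise ValueError("establishment_year must not exceed inner_ring_year")


@dataclass(frozen=True)
class FireScarRecord:
    """A dated cambial fire injury on one tree.

    ``scar_year_end`` differs from ``scar_year_start`` by at most one year,
    for dormant-season scars whose calendar year is ambiguous (1859-60 style).
    """

    site_id: str
    tree_id: str
    scar_year_start: int
    scar_year_end: int | None = None
    season: str = "unknown"           # {dormant, growing, unknown}

    def __post_init__(self) -> None:
        if self.scar_year_end is None:
            object.__setattr__(self, "scar_year_end", self.scar_year_start)
        if self.scar_year_end < self.scar_year_start:
            raise ValueError("scar_year_end < scar_year_start")
        if self.scar_year_end - self.scar_year_start > 1:
            raise ValueError("scar year ranges may span at most one year")
        if self.season not in {"dormant", "growing", "unknown"}:
            raise ValueError(f"unknown season {self.season!r}")

    @property
    def ambiguous(self) -> bool:
        return self.scar_year_end != self.scar_year_start


# ---------------------------------------------------------------------------
# FHX chronology files
# ---------------------------------------------------------------------------

class FhxParseError(ValueError):
    pass


_SCAR_CODES = {"D": "dormant", "U": "unknown"}
# Season letters of the full FHX vocabulary; everything but dormant is
# normalised to unknown.
_SEASON_ALIASES = {"E": "U", "M": "U", "L": "U", "A": "U"}
RECORDER, NONRECORDER, NULL = "|", ".", " "


def read_fhx(path: str | Path) -> tuple[list[FireScarRecord], pd.DataFrame]:
    """Parse an FHX2 chronology file.

    Returns the scar records and a per-year recorder table: a DataFrame
    indexed by calendar year with one column per series, holding the
    non-scar state of each tree-year as ``"recorder"``, ``"nonrecorder"``
    or ``"null"`` (scar years count as recorder years).
    """
    lines = Path(path).read_text(encoding="ascii").splitlines()
    if not lines or not lines[0].strip().upper().startswith("FHX2"):
        raise FhxParseError("line 1: missing 'FHX2 FORMAT' header")
    try:
        first_year, n_series, id_length = (int(t) for t in lines[1].split())
    except (IndexError, ValueError) as exc:
        raise FhxParseError(
            "line 2: expected '<first_year> <n_series> <id_length>'"
        ) from exc

    id_rows = lines[2 : 2 + id_length]
    if len(id_rows) < id_length:
        raise FhxParseError("truncated series-id block")
    series_ids = []
    for j in range(n_series):
        chars = [row[j] if j < len(row) else " " for row in id_rows]
        sid = "".join(chars).strip()
        if not sid:
            raise FhxParseError(f"series {j + 1}: empty series id")
        series_ids.append(sid)

    data_lines = [ln for ln in lines[2 + id_length :] if ln.strip() != ""]
    records: list[FireScarRecord] = []
    states: dict[int, list[str]] = {}
    for i, raw in enumerate(data_lines):
        year = first_year + i
        row = raw[:n_series].ljust(n_series)
        if len(raw.rstrip()) > n_series and not raw[n_series].isspace():
            raise FhxParseError(
                f"series length mismatch at year {year}: row wider than the "
                f"{n_series} declared series"
            )
        year_states = []
        for j, ch in enumerate(row):
            ch = _SEASON_ALIASES.get(ch, ch)
            if ch in _SCAR_CODES:
                records.append(
                    FireScarRecord(
                        site_id="", tree_id=series_ids[j],
                        scar_year_start=year, season=_SCAR_CODES[ch],
                    )
                )
                year_states.append("recorder")
            elif ch == RECORDER:
                year_states.append("recorder")
            elif ch == NONRECORDER:
                year_states.append("nonrecorder")
            elif ch == NULL:
                year_states.append("null")
            else:
                raise FhxParseError(
                    f"series {series_ids[j]!r}, year {year}: unknown code {ch!r}"
                )
        states[year] = year_states

    table = pd.DataFrame.from_dict(
        states, orient="index", columns=series_ids
    ).sort_index()
    table.index.name = "year"
    return records, table


def write_fhx(
    records: Iterable[FireScarRecord],
    recorder_table: pd.DataFrame,
    path: str | Path,
) -> None:
    """Write scar records and a per-year recorder table as FHX2 text.

    ``read_fhx(write_fhx(...))`` is an identity on the record set; the code
    matrix round-trips byte-for-byte modulo trailing whitespace.
    """
    records = list(records)
    series_ids = list(recorder_table.columns)
    years = list(recorder_table.index)
    if years != list(range(min(years), max(years) + 1)):
        raise ValueError("recorder table must cover a contiguous year span")

    matrix = {}
    for year in years:
        row = []
        for sid in series_ids:
            state = recorder_table.loc[year, sid]
            row.append({"recorder": RECORDER, "nonrecorder": NONRECORDER,
                        "null": NULL}[state])
        matrix[year] = row
    seen: set[tuple[str, int]] = set()
    for rec in records:
        if rec.tree_id not in series_ids:
            raise ValueError(f"scar series {rec.tree_id!r} not in recorder table")
        year = rec.scar_year_start
        if year not in matrix:
            raise ValueError(f"scar year {year} outside the table span")
        j = series_ids.index(rec.tree_id)
        if matrix[year][j] == NULL:
            raise ValueError(
                f"contradictory codes: scar at null year {year} of {rec.tree_id!r}"
            )
        if (rec.tree_id, year) in seen:
            raise ValueError(f"duplicate scar for {rec.tree_id!r} in {year}")
        seen.add((rec.tree_id, year))
        matrix[year][j] = "D" if rec.season == "dormant" else "U"

    id_length = max(len(s) for s in series_ids)
    padded = [s.ljust(id_length) for s in series_ids]
    lines = ["FHX2 FORMAT", f"{min(years)} {len(series_ids)} {id_length}"]
    for k in range(id_length):
        lines.append("".join(p[k] for p in padded).rstrip())
    lines.append("")
    for year in years:
        lines.append(("".join(matrix[year]) + f" {year}").rstrip())
    Path(path).write_text("\n".join(lines) + "\n", encoding="ascii")


# ---------------------------------------------------------------------------
# Delimited tables
# ---------------------------------------------------------------------------

def _read_delimited(path: str | Path) -> pd.DataFrame:
    head = Path(path).read_text().splitlines()[0]
    sep = "\t" if "\t" in head else ","
    return pd.read_csv(path, sep=sep)


_TREE_REQUIRED = ["site_id", "tree_id", "species", "inner_ring_year"]
_SITE_REQUIRED = ["site_id", "site_type", "area_ha", "elevation_m",
                  "slope_deg", "aspect_deg", "cover_type"]


def _check_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table missing required columns: {missing}")


def read_tree_table(path: str | Path) -> list[TreeRecord]:
    """Read a delimited tree table into :class:`TreeRecord` objects.

    Blank numeric cells become missing values (``None``), never zero.
    Unknown columns are preserved in each record's ``extra`` dict.
    """
    df = _read_delimited(path)
    _check_columns(df, _TREE_REQUIRED, "tree")
    known = set(_TREE_REQUIRED) | {
        "pith_offset_yr", "coring_height_offset_yr", "establishment_year",
        "status", "dbh_cm", "excluded",
    }
    records = []
    for i, row in df.iterrows():
        try:
            inner = int(row["inner_ring_year"])
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"row {i + 1}: unparseable inner_ring_year "
                f"{row['inner_ring_year']!r}"
            ) from exc
        est = row.get("establishment_year")
        dbh = row.get("dbh_cm")

        def _int_or(key: str, default: int = 0) -> int:
            val = row.get(key, default)
            return default if val is None or pd.isna(val) else int(val)

        records.append(
            TreeRecord(
                site_id=str(row["site_id"]),
                tree_id=str(row["tree_id"]),
                species=str(row["species"]),
                inner_ring_year=inner,
                pith_offset_yr=_int_or("pith_offset_yr"),
                coring_height_offset_yr=_int_or("coring_height_offset_yr"),
                establishment_year=None if pd.isna(est) else int(est),
                status=str(row.get("status", "live")),
                dbh_cm=None if dbh is None or pd.isna(dbh) else float(dbh),
                excluded=bool(row.get("excluded", False))
                and not pd.isna(row.get("excluded", False)),
                extra={c: row[c] for c in df.columns if c not in known},
            )
        )
    return records


def read_site_table(path: str | Path) -> list[SiteMeta]:
    """Read a delimited site-metadata table into :class:`SiteMeta` objects."""
    df = _read_delimited(path)
    _check_columns(df, _SITE_REQUIRED, "site")
    known = set(_SITE_REQUIRED) | {"dist_grassland_m", "dist_ravine_m", "x", "y"}
    sites = []
    for _, row in df.iterrows():
        dg, dr = row.get("dist_grassland_m"), row.get("dist_ravine_m")
        sites.append(
            SiteMeta(
                site_id=str(row["site_id"]),
                site_type=str(row["site_type"]),
                area_ha=float(row["area_ha"]),
                elevation_m=float(row["elevation_m"]),
                slope_deg=float(row["slope_deg"]),
                aspect_deg=float(row["aspect_deg"]),
                cover_type=str(row["cover_type"]),
                dist_grassland_m=None if dg is None or pd.isna(dg) else float(dg),
                dist_ravine_m=None if dr is None or pd.isna(dr) else float(dr),
                x=float(row.get("x", 0.0) or 0.0),
                y=float(row.get("y", 0.0) or 0.0),
                extra={c: row[c] for c in df.columns if c not in known},
            )
        )
    return sites


# ---------------------------------------------------------------------------
# Dataset validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Report-only consistency check; the dataset is never modified."""

    orphan_site_ids: list[str] = field(default_factory=list)
    orphan_tree_ids: list[str] = field(default_factory=list)
    year_violations: list[str] = field(default_factory=list)
    duplicate_scars: list[tuple[str, int]] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not (
            self.orphan_site_ids or self.orphan_tree_ids
            or self.year_violations or self.duplicate_scars
        )


def validate_dataset(
    sites: Sequence[SiteMeta],
    trees: Sequence[TreeRecord],
    scars: Sequence[FireScarRecord],
) -> ValidationReport:
    """Cross-check referential integrity, year ranges and duplicate scars."""
    report = ValidationReport()
    site_ids = {s.site_id for s in sites}
    tree_ids = {(t.site_id, t.tree_id) for t in trees}

    for t in trees:
        if t.site_id not in site_ids:
            report.orphan_site_ids.append(t.site_id)
        for label, year in (
            ("inner_ring_year", t.inner_ring_year),
            ("establishment_year", t.establishment_year),
        ):
            if year is not None and not YEAR_MIN <= year <= YEAR_MAX:
                report.year_violations.append(
                    f"tree {t.tree_id}: {label} {year} outside "
                    f"[{YEAR_MIN}, {YEAR_MAX}]"
                )
    seen: set[tuple[str, str, int]] = set()
    for s in scars:
        if (s.site_id, s.tree_id) not in tree_ids:
            report.orphan_tree_ids.append(s.tree_id)
        if not YEAR_MIN <= s.scar_year_start <= YEAR_MAX:
            report.year_violations.append(
                f"scar {s.tree_id}@{s.scar_year_start}: year outside range"
            )
        key = (s.site_id, s.tree_id, s.scar_year_start)
        if key in seen:
            report.duplicate_scars.append((s.tree_id, s.scar_year_start))
        seen.add(key)
    return report


def dedupe_scars(scars: Sequence[FireScarRecord]) -> list[FireScarRecord]:
    """Collapse duplicate scars for one tree-year to a single record.

    A tree can record a given fire at most once; duplicates trigger a
    warning, not an error.
    """
    out: dict[tuple[str, str, int], FireScarRecord] = {}
    for s in scars:
        key = (s.site_id, s.tree_id, s.scar_year_start)
        if key in out:
            warnings.warn(
                f"duplicate scar for tree {s.tree_id} in {s.scar_year_start}; "
                "collapsed to one record",
                stacklevel=2,
            )
        else:
            out[key] = s
    return list(out.values())
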