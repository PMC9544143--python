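"""Observation records, CSV ingest/egress, series assembly and coverage filtering.

One :class:`ObservationRecord` is a single radiometer reading of a subplot on
one day; a :class:`SeasonSeries` collects all NDVI observations of one subplot
in one year and is the unit passed to spline fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import pandas as pd

CANONICAL_COLUMNS = [
    "plot_id", "subplot_id", "richness", "treatment",
    "year", "doy", "red", "nir", "ndvi",
]
_REQUIRED = ["plot_id", "subplot_id", "richness", "treatment", "year", "doy"]


@dataclass
class ObservationRecord:
    """One radiometer reading; carries reflectances and/or a precomputed NDVI."""

    plot_id: str
    subplot_id: str
    richness: int
    treatment: str
    year: int
    doy: int
    red: float | None = None
    nir: float | None = None
    ndvi: float | None = None

    def validate(self) -> list[str]:
        """Return reason codes for every violated range constraint."""
        reasons = []
        if not 1 <= self.doy <= 366:
            reasons.append("doy-out-of-range")
        for name in ("red", "nir"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                reasons.append(f"{name}-out-of-range")
        if self.ndvi is not None and not -1.0 <= self.ndvi <= 1.0:
            reasons.append("ndvi-out-of-range")
        has_refl = self.red is not None and self.nir is not None
        if not has_refl and self.ndvi is None:
            reasons.append("no-response")
        return reasons


@dataclass
class SeasonSeries:
    """All NDVI observations of one subplot in one calendar year.

    ``doy`` is strictly increasing; same-day replicate readings are averaged
    on assembly. At least 4 observations are required for spline eligibility.
    """

    subplot_id: str
    year: int
    doy: list[int]
    ndvi: list[float]
    plot_id: str = ""
    richness: int | None = None
    treatment: str = ""

    @property
    def key(self) -> tuple[str, int]:
        return (self.subplot_id, self.year)

    def __len__(self) -> int:
        return len(self.doy)

    def __post_init__(self) -> None:
        if len(self.doy) != len(self.ndvi):
            raise ValueError("doy and ndvi lengths differ")
        if any(b <= a for a, b in zip(self.doy, self.doy[1:])):
            raise ValueError("doy must be strictly increasing")


@dataclass
class ValidationReport:
    """Rows rejected during ingest, with machine-readable reason codes."""

    rejected: list[tuple[int, str]] = field(default_factory=list)  # (row index, reason)

    def add(self, row_index: int, reason: str) -> None:
        self.rejected.append((row_index, reason))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rejected, columns=["row", "reason"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _get_float(row, col):
    v = row.get(col)
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def read_observations(
    path: str | Path,
    dialect: dict[str, str] | None = None,
) -> tuple[list[ObservationRecord], ValidationReport]:
    """Read long-format observations from a delimited text file.

    Parameters
    ----------
    dialect
        Maps canonical column names to the file's header names, e.g.
        ``{"doy": "julian_day"}``. Unmapped names are taken as-is.

    Returns
    -------
    (records, report)
        Validated records, and a report listing rejected rows with reason
        codes. Rows that fail validation are excluded from ``records`` but
        never silently dropped.
    """
    dialect = dialect or {}
    raw = pd.read_csv(path)
    colmap = {c: dialect.get(c, c) for c in CANONICAL_COLUMNS}
    missing = [colmap[c] for c in _REQUIRED if colmap[c] not in raw.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")

    report = ValidationReport()
    records: list[ObservationRecord] = []
    for i, row in enumerate(raw.to_dict("records")):
        try:
            rec = ObservationRecord(
                plot_id=str(row[colmap["plot_id"]]),
                subplot_id=str(row[colmap["subplot_id"]]),
                richness=int(row[colmap["richness"]]),
                treatment=str(row[colmap["treatment"]]),
                year=int(row[colmap["year"]]),
                doy=int(row[colmap["doy"]]),
                red=_get_float(row, colmap["red"]),
                nir=_get_float(row, colmap["nir"]),
                ndvi=_get_float(row, colmap["ndvi"]),
            )
        except (ValueError, TypeError, KeyError) as exc:
            report.add(i, f"unparseable: {exc}")
            continue
        reasons = rec.validate()
        if reasons:
            for r in reasons:
                report.add(i, r)
        else:
            records.append(rec)
    return records, report


def write_observations(records: list[ObservationRecord], path: str | Path) -> None:
    """Write records to canonical-column CSV (UTF-8, header row)."""
    rows = [{f.name: getattr(r, f.name) for f in dc_fields(ObservationRecord)}
            for r in records]
    pd.DataFrame(rows, columns=CANONICAL_COLUMNS).to_csv(path, index=False)


def observations_frame(records: list[ObservationRecord]) -> pd.DataFrame:
    rows = [{f.name: getattr(r, f.name) for f in dc_fields(ObservationRecord)}
            for r in records]
    return pd.DataFrame(rows, columns=CANONICAL_COLUMNS)


def assemble_series(records: list[ObservationRecord]) -> list[SeasonSeries]:
    """Group records into one :class:`SeasonSeries` per (subplot, year).

    Records must already carry NDVI (apply :func:`~greenwave.phenology.compute_ndvi`
    first otherwise). Same-day duplicates are averaged; days sorted ascending.
    """
    for r in records:
        if r.ndvi is None:
            raise ValueError(
                f"record {r.subplot_id} year {r.year} doy {r.doy} lacks ndvi; "
                "run compute_ndvi first"
            )
    groups: dict[tuple[str, int], list[ObservationRecord]] = {}
    for r in records:
        groups.setdefault((r.subplot_id, r.year), []).append(r)

    out: list[SeasonSeries] = []
    for (sid, year), recs in sorted(groups.items()):
        by_day: dict[int, list[float]] = {}
        for r in recs:
            by_day.setdefault(r.doy, []).append(r.ndvi)  # type: ignore[arg-type]
        days = sorted(by_day)
        meta = recs[0]
        out.append(SeasonSeries(
            subplot_id=sid, year=year,
            doy=days,
            ndvi=[sum(by_day[d]) / len(by_day[d]) for d in days],
            plot_id=meta.plot_id, richness=meta.richness, treatment=meta.treatment,
        ))
    return out


# reason codes emitted by coverage_filter
EARLY_UNDERSAMPLED = "early-season undersampled"
LATE_UNDERSAMPLED = "late-season undersampled"
TOO_FEW_TOTAL = "fewer than 4 observations"


def coverage_filter(
    series: list[SeasonSeries],
    min_per_half: int = 2,
    boundary_doy: int | dict[int, float] | None = None,
) -> tuple[list[SeasonSeries], list[tuple[SeasonSeries, str]]]:
    """Drop subplot-year series that do not cover both halves of the season.

    A series is retained iff it has at least ``min_per_half`` observations on
    each side of ``boundary_doy`` and at least 4 in total; everything else is
    returned with a reason code. ``boundary_doy`` may be a single day, a
    per-year mapping, or None, in which case the per-year median observed day
    across all subplots is used.
    """
    if min_per_half < 1:
        raise ValueError("min_per_half must be >= 1")

    if boundary_doy is None:
        per_year: dict[int, list[int]] = {}
        for s in series:
            per_year.setdefault(s.year, []).extend(s.doy)
        boundary = {y: float(pd.Series(d).median()) for y, d in per_year.items()}
    elif isinstance(boundary_doy, dict):
        boundary = {y: float(b) for y, b in boundary_doy.items()}
    else:
        boundary = {s.year: float(boundary_doy) for s in series}

    retained: list[SeasonSeries] = []
    excluded: list[tuple[SeasonSeries, str]] = []
    for s in series:
        b = boundary[s.year]
        n_early = sum(1 for d in s.doy if d <= b)
        n_late = sum(1 for d in s.doy if d > b)
        if len(s) < 4:
            excluded.append((s, TOO_FEW_TOTAL))
        elif n_early < min_per_half:
            excluded.append((s, EARLY_UNDERSAMPLED))
        elif n_late < min_per_half:
            excluded.append((s, LATE_UNDERSAMPLED))
        else:
            retained.append(s)
    return retained, excluded
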