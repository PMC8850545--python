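"""Weekly relative-search-volume series I/O and panel assembly.

Google Trends reports, per query term, the weekly share of all searches in a
geography, max-normalised to a 0–100 scale; sub-threshold cells are exported
as the literal ``"<1"``, which this pipeline censors to 0 at parse time (and
counts, so the sub-threshold prevalence of any input is auditable).

Two CSV dialects are read: ``trends_export`` — a leading category line, a
blank line, then a ``Week,<term>: (<geo>)`` header — and ``plain`` — a bare
``week,value`` header. Weeks are identified by their start date and must be
strictly increasing at exact 7-day spacing.
"""

from __future__ import annotations

import csv
import datetime as dt
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WeeklySeries",
    "TrendsPanel",
    "CovariateSeries",
    "TrendsIOError",
    "read_trends_csv",
    "assemble_panel",
    "write_panel_csv",
    "read_panel_csv",
    "write_covariates_csv",
    "read_covariates_csv",
]

logger = logging.getLogger(__name__)

WEEK = dt.timedelta(days=7)


class TrendsIOError(ValueError):
    """Malformed search-volume input or invalid panel operation."""


def _check_week_axis(weeks: Sequence[dt.date], context: str = "") -> tuple[dt.date, ...]:
    weeks = tuple(weeks)
    if not weeks:
        raise TrendsIOError(f"{context}: empty week axis")
    for i in range(1, len(weeks)):
        gap = weeks[i] - weeks[i - 1]
        if gap != WEEK:
            raise TrendsIOError(
                f"{context}: week axis breaks 7-day spacing at row {i + 1} "
                f"({weeks[i - 1].isoformat()} -> {weeks[i].isoformat()}, "
                f"gap {gap.days} days)"
            )
    return weeks


@dataclass(frozen=True)
class WeeklySeries:
    """One query term's weekly relative search volume (0–100 scale).

    ``censored`` counts cells that were reported sub-threshold ("<1") and
    rounded down to 0 during parsing or generation.
    """

    term: str
    geo: str
    week_start: tuple[dt.date, ...]
    values: np.ndarray
    censored: int = 0

    def __post_init__(self) -> None:
        weeks = _check_week_axis(self.week_start, f"series {self.term!r}")
        object.__setattr__(self, "week_start", weeks)
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or len(vals) != len(weeks):
            raise TrendsIOError(
                f"series {self.term!r}: {len(vals)} values for {len(weeks)} weeks"
            )
        if np.any(~np.isfinite(vals)) or vals.min() < 0 or vals.max() > 100:
            raise TrendsIOError(
                f"series {self.term!r}: values outside the [0, 100] scale"
            )
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.week_start)


@dataclass(frozen=True)
class TrendsPanel:
    """Aligned collection of weekly series (terms x weeks) for one geo.

    Backed by a DataFrame with the week-start axis as index and one column
    per term; term order is preserved. ``role`` tags the panel's lexicon
    (absolutist | control | symptom) and ``censored`` maps term -> number of
    censored cells carried over from its member series.
    """

    frame: pd.DataFrame
    geo: str
    role: str = "absolutist"
    censored: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame.empty:
            raise TrendsIOError("panel has no data")
        _check_week_axis(list(self.frame.index), "panel")
        terms = list(self.frame.columns)
        if len(set(terms)) != len(terms):
            raise TrendsIOError("duplicate terms in panel")

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)

    @property
    def week_start(self) -> tuple[dt.date, ...]:
        return tuple(self.frame.index)

    @property
    def values(self) -> np.ndarray:
        """terms x weeks matrix."""
        return self.frame.to_numpy().T

    @property
    def n_terms(self) -> int:
        return self.frame.shape[1]

    @property
    def n_weeks(self) -> int:
        return self.frame.shape[0]

    def series(self, term: str) -> WeeklySeries:
        if term not in self.frame.columns:
            raise TrendsIOError(f"term {term!r} not in panel")
        return WeeklySeries(
            term=term,
            geo=self.geo,
            week_start=self.week_start,
            values=self.frame[term].to_numpy(),
            censored=self.censored.get(term, 0),
        )


@dataclass(frozen=True)
class CovariateSeries:
    """Weekly epidemic covariates: new cases and deaths per million."""

    geo: str
    week_start: tuple[dt.date, ...]
    new_cases_per_million: np.ndarray
    new_deaths_per_million: np.ndarray

    def __post_init__(self) -> None:
        weeks = _check_week_axis(self.week_start, f"covariates {self.geo!r}")
        object.__setattr__(self, "week_start", weeks)
        for name in ("new_cases_per_million", "new_deaths_per_million"):
            vals = np.asarray(getattr(self, name), dtype=float)
            if len(vals) != len(weeks):
                raise TrendsIOError(f"covariate {name} length mismatch")
            if np.any(~np.isfinite(vals)) or vals.min() < 0:
                raise TrendsIOError(f"covariate {name} must be finite and >= 0")
            vals.setflags(write=False)
            object.__setattr__(self, name, vals)

    def __len__(self) -> int:
        return len(self.week_start)


# ---------------------------------------------------------------------------
# parsing


def _parse_date(cell: str, row_no: int, path) -> dt.date:
    try:
        return dt.date.fromisoformat(cell.strip())
    except ValueError:
        raise TrendsIOError(
            f"{path}: row {row_no}: cannot parse week start {cell!r}"
        ) from None


def _parse_value(cell: str, row_no: int, path) -> tuple[float, bool]:
    """Return (value, was_censored). The literal '<1' rounds down to 0."""
    cell = cell.strip()
    if cell in ("<1", "< 1"):
        return 0.0, True
    try:
        val = float(cell)
    except ValueError:
        raise TrendsIOError(f"{path}: row {row_no}: cannot parse value {cell!r}") from None
    if not 0.0 <= val <= 100.0:
        raise TrendsIOError(
            f"{path}: row {row_no}: value {val} outside the [0, 100] scale"
        )
    return val, False


def read_trends_csv(
    path: str | Path,
    dialect: str = "plain",
    term: str | None = None,
    geo: str = "",
) -> WeeklySeries:
    """Read one weekly series from a CSV file.

    ``dialect='trends_export'`` expects the Google Trends download layout
    (category line, blank line, ``Week,<term>: (<geo>)`` header);
    ``dialect='plain'`` expects a ``week,value`` header. ``"<1"`` cells parse
    to 0 and increment the series' censoring counter.
    """
    path = Path(path)
    if dialect not in ("plain", "trends_export"):
        raise TrendsIOError(f"unknown dialect {dialect!r}")
    text = path.read_text(encoding="utf-8-sig")
    lines = text.splitlines()
    start = 0
    if dialect == "trends_export":
        if len(lines) < 3:
            raise TrendsIOError(f"{path}: too short for a Trends export")
        # category line, blank line, then the header
        start = 2
        header = next(csv.reader([lines[2]]))
        if len(header) != 2 or header[0].strip().lower() != "week":
            raise TrendsIOError(f"{path}: malformed Trends export header {lines[2]!r}")
        label = header[1]
        if term is None:
            term = label.split(":", 1)[0].strip()
        if "(" in label and label.rstrip().endswith(")"):
            geo = geo or label[label.rfind("(") + 1: label.rstrip().rfind(")")].strip()
        start = 3
    else:
        header = next(csv.reader([lines[0]]))
        if len(header) != 2 or header[0].strip().lower() != "week":
            raise TrendsIOError(f"{path}: expected 'week,value' header, got {lines[0]!r}")
        if term is None:
            term = header[1].strip() if header[1].strip().lower() != "value" else path.stem
        start = 1

    weeks: list[dt.date] = []
    values: list[float] = []
    censored = 0
    for offset, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        row = next(csv.reader([line]))
        if len(row) != 2:
            raise TrendsIOError(f"{path}: row {offset}: expected 2 cells, got {len(row)}")
        weeks.append(_parse_date(row[0], offset, path))
        val, was_censored = _parse_value(row[1], offset, path)
        values.append(val)
        censored += was_censored
    if not weeks:
        raise TrendsIOError(f"{path}: no data rows")
    for i in range(1, len(weeks)):
        if weeks[i] - weeks[i - 1] != WEEK:
            raise TrendsIOError(
                f"{path}: row {start + 1 + i}: week {weeks[i].isoformat()} is "
                f"{(weeks[i] - weeks[i - 1]).days} days after the previous row "
                f"(weeks must be 7 days apart)"
            )
    return WeeklySeries(term=term, geo=geo, week_start=tuple(weeks),
                        values=np.array(values), censored=censored)


# ---------------------------------------------------------------------------
# panels


def assemble_panel(
    series_list: Sequence[WeeklySeries],
    role: str = "absolutist",
) -> TrendsPanel:
    """Align weekly series into a terms x weeks panel.

    Axes may differ only by truncation at either end; the panel covers their
    intersection and the number of dropped leading/trailing weeks is logged.
    Interior mismatches, duplicate terms and an empty intersection are errors.
    """
    if not series_list:
        raise TrendsIOError("no series to assemble")
    geos = {s.geo for s in series_list}
    if len(geos) > 1:
        raise TrendsIOError(f"series span multiple geos: {sorted(geos)}")
    terms = [s.term for s in series_list]
    if len(set(terms)) != len(terms):
        dupes = sorted({t for t in terms if terms.count(t) > 1})
        raise TrendsIOError(f"duplicate terms: {dupes}")

    start = max(s.week_start[0] for s in series_list)
    end = min(s.week_start[-1] for s in series_list)
    if end < start:
        raise TrendsIOError("series week axes have an empty intersection")
    if (end - start).days % 7 != 0:
        raise TrendsIOError("series week axes are offset (not aligned to the same weekday)")

    n_weeks = (end - start).days // 7 + 1
    axis = tuple(start + i * WEEK for i in range(n_weeks))
    data = {}
    dropped = 0
    for s in series_list:
        lead = (start - s.week_start[0]).days // 7
        data[s.term] = s.values[lead: lead + n_weeks]
        dropped += (len(s) - n_weeks)
    if dropped:
        logger.warning(
            "assemble_panel: dropped %d leading/trailing week cells to align "
            "%d series on a common %d-week axis", dropped, len(series_list), n_weeks
        )
    frame = pd.DataFrame(data, index=list(axis))
    return TrendsPanel(
        frame=frame,
        geo=series_list[0].geo,
        role=role,
        censored={s.term: s.censored for s in series_list},
    )


def write_panel_csv(panel: TrendsPanel, path: str | Path) -> None:
    """Write a panel as ``week`` plus one column per term.

    Values are written with full ``repr`` precision so a read/assemble round
    trip reproduces the panel bit-for-bit; censoring applies only at parse
    time, never at write time.
    """
    path = Path(path)
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["week", *panel.terms])
    mat = panel.frame.to_numpy()
    for i, week in enumerate(panel.week_start):
        writer.writerow([week.isoformat(), *(repr(float(v)) for v in mat[i])])
    path.write_text(buf.getvalue(), encoding="utf-8")


def read_panel_csv(path: str | Path, geo: str = "", role: str = "absolutist") -> TrendsPanel:
    """Read a multi-term panel CSV (inverse of :func:`write_panel_csv`)."""
    path = Path(path)
    with path.open(encoding="utf-8-sig", newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or rows[0][0].strip().lower() != "week":
        raise TrendsIOError(f"{path}: expected a 'week,...' header")
    terms = [c.strip() for c in rows[0][1:]]
    weeks: list[dt.date] = []
    censored = {t: 0 for t in terms}
    values = []
    for row_no, row in enumerate(rows[1:], start=2):
        if not any(cell.strip() for cell in row):
            continue
        if len(row) != len(terms) + 1:
            raise TrendsIOError(f"{path}: row {row_no}: ragged row")
        weeks.append(_parse_date(row[0], row_no, path))
        vals = []
        for term, cell in zip(terms, row[1:]):
            val, was_censored = _parse_value(cell, row_no, path)
            censored[term] += was_censored
            vals.append(val)
        values.append(vals)
    series = [
        WeeklySeries(term=t, geo=geo, week_start=tuple(weeks),
                     values=np.array([r[j] for r in values]), censored=censored[t])
        for j, t in enumerate(terms)
    ]
    return assemble_panel(series, role=role)


# ---------------------------------------------------------------------------
# covariates


def write_covariates_csv(cov: CovariateSeries, path: str | Path) -> None:
    path = Path(path)
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["week", "new_cases_per_million", "new_deaths_per_million"])
    for week, c, d in zip(cov.week_start, cov.new_cases_per_million,
                          cov.new_deaths_per_million):
        writer.writerow([week.isoformat(), repr(float(c)), repr(float(d))])
    path.write_text(buf.getvalue(), encoding="utf-8")


def read_covariates_csv(path: str | Path, geo: str = "") -> CovariateSeries:
    path = Path(path)
    frame = pd.read_csv(path)
    expected = ["week", "new_cases_per_million", "new_deaths_per_million"]
    if list(frame.columns) != expected:
        raise TrendsIOError(f"{path}: expected columns {expected}")
    weeks = tuple(dt.date.fromisoformat(str(w)) for w in frame["week"])
    return CovariateSeries(
        geo=geo,
        week_start=weeks,
        new_cases_per_million=frame["new_cases_per_million"].to_numpy(float),
        new_deaths_per_million=frame["new_deaths_per_million"].to_numpy(float),
    )
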