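"""Input-dataset schema: column dictionary, parsing, validation, templates.

A dataset is tidy and rectangular: one row per effect size to compute, with
columns drawn from the fixed snake_case dictionary in :data:`COLUMNS`.  Any
recognized subset of columns may be present; blank cells are missing values
(0 is a value, never missing).  Unknown columns are ignored with a logged
warning; duplicate column names are fatal.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, fields, make_dataclass
from pathlib import Path
from typing import Any, Iterable, Mapping

import pandas as pd

from .estimate import EsConvertError, InputError

log = logging.getLogger("esconvert")

DIRECTIONS = ("positive", "negative", "unspecified")

# kind -> (parser/validator family)
#   text      free text
#   direction one of DIRECTIONS
#   count     non-negative integer
#   real      any finite real
#   pos       strictly positive real
#   nonneg    real >= 0
#   prob      real in [0, 1]
#   corr      real in (-1, 1)
#   pvalue    real in (0, 1]
#   eta       real in [0, 1)
COLUMNS: list[tuple[str, str, str]] = [
    ("study_id", "text", "Study label; cluster key for aggregation and diffing"),
    ("es_direction", "direction",
     "Sign to apply when the input carries none (F, p, eta2): "
     "positive / negative / unspecified"),
    ("n1", "count", "Sample size, group 1 (exposed/treated)"),
    ("n2", "count", "Sample size, group 2 (control)"),
    ("n_total", "count", "Total sample size when per-group sizes are unknown"),
    ("n_cases", "count", "Number of cases (case-control designs)"),
    ("n_controls", "count", "Number of controls (case-control designs)"),
    ("m1", "real", "Mean of group 1 (outcome units)"),
    ("m2", "real", "Mean of group 2"),
    ("sd1", "pos", "Standard deviation of group 1"),
    ("sd2", "pos", "Standard deviation of group 2"),
    ("se1", "pos", "Standard error of the mean, group 1"),
    ("se2", "pos", "Standard error of the mean, group 2"),
    ("m1_ci_lo", "real", "95% CI lower bound of the group-1 mean"),
    ("m1_ci_up", "real", "95% CI upper bound of the group-1 mean"),
    ("m2_ci_lo", "real", "95% CI lower bound of the group-2 mean"),
    ("m2_ci_up", "real", "95% CI upper bound of the group-2 mean"),
    ("med1", "real", "Median of group 1"),
    ("med2", "real", "Median of group 2"),
    ("q1_1", "real", "First quartile, group 1"),
    ("q3_1", "real", "Third quartile, group 1"),
    ("q1_2", "real", "First quartile, group 2"),
    ("q3_2", "real", "Third quartile, group 2"),
    ("min1", "real", "Minimum, group 1"),
    ("max1", "real", "Maximum, group 1"),
    ("min2", "real", "Minimum, group 2"),
    ("max2", "real", "Maximum, group 2"),
    ("t_value", "real", "Student t statistic (two independent groups)"),
    ("f_value", "nonneg", "One-way ANOVA F statistic (two groups)"),
    ("p_value", "pvalue", "Two-tailed p-value of the group comparison"),
    ("eta_sq", "eta", "Eta-squared (two groups)"),
    ("md_value", "real", "Reported mean difference (group 1 minus group 2)"),
    ("md_se", "pos", "Standard error of the reported mean difference"),
    ("md_ci_lo", "real", "95% CI lower bound of the mean difference"),
    ("md_ci_up", "real", "95% CI upper bound of the mean difference"),
    ("pre_m1", "real", "Pre-test mean, group 1 (change-score route)"),
    ("pre_m2", "real", "Pre-test mean, group 2"),
    ("pre_sd1", "pos", "Pre-test SD, group 1"),
    ("pre_sd2", "pos", "Pre-test SD, group 2"),
    ("r_prepost", "corr", "Pre-post correlation (must be supplied explicitly)"),
    ("adj_m1", "real", "Covariate-adjusted mean, group 1 (ANCOVA route)"),
    ("adj_m2", "real", "Covariate-adjusted mean, group 2"),
    ("adj_sd_pooled", "pos",
     "Pooled SD on the unadjusted scale accompanying the adjusted means"),
    ("a", "count", "2x2 cell: group-1 events"),
    ("b", "count", "2x2 cell: group-1 non-events"),
    ("c", "count", "2x2 cell: group-2 events"),
    ("d_cell", "count", "2x2 cell: group-2 non-events"),
    ("p_event1", "prob", "Event proportion, group 1"),
    ("p_event2", "prob", "Event proportion, group 2"),
    ("or_value", "pos", "Reported odds ratio"),
    ("or_ci_lo", "pos", "OR 95% CI lower bound"),
    ("or_ci_up", "pos", "OR 95% CI upper bound"),
    ("logor_value", "real", "Reported log odds ratio"),
    ("logor_se", "pos", "Standard error of the log odds ratio"),
    ("rr_value", "pos", "Reported risk ratio"),
    ("rr_ci_lo", "pos", "RR 95% CI lower bound"),
    ("rr_ci_up", "pos", "RR 95% CI upper bound"),
    ("irr_value", "pos", "Reported incidence rate ratio"),
    ("irr_ci_lo", "pos", "IRR 95% CI lower bound"),
    ("irr_ci_up", "pos", "IRR 95% CI upper bound"),
    ("e1", "count", "Event count, group 1 (person-time route)"),
    ("time1", "pos", "Person-time at risk, group 1"),
    ("e2", "count", "Event count, group 2"),
    ("time2", "pos", "Person-time at risk, group 2"),
    ("r_value", "corr", "Correlation coefficient"),
    ("n_r", "count", "Sample size the correlation is based on"),
    ("baseline_risk", "prob",
     "Control-group event probability (OR->RR, NNT conversions)"),
]

COLUMN_NAMES = tuple(name for name, _, _ in COLUMNS)
COLUMN_KINDS = {name: kind for name, kind, _ in COLUMNS}
COLUMN_DESCRIPTIONS = {name: desc for name, _, desc in COLUMNS}

#: Accepted input aliases, applied at read time (documented contract).
ALIASES = {
    "d": "d_cell",
    "mean1": "m1",
    "mean2": "m2",
    "p": "p_value",
    "t": "t_value",
    "f": "f_value",
    "or": "or_value",
    "rr": "rr_value",
    "irr": "irr_value",
}

_NA_TOKENS = {"", "na", "n/a", "nan", "none", "null", "."}

StudyRow = make_dataclass(
    "StudyRow",
    [(name, Any, field(default=None)) for name in COLUMN_NAMES],
    frozen=False,
)
StudyRow.__doc__ = (
    "One row of the input schema: every recognized input statistic for a "
    "single estimand; unreported statistics are None."
)


@dataclass(frozen=True)
class Violation:
    """One invariant violation found in a row (data, not an exception)."""

    field: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}: {self.message}"


@dataclass(frozen=True)
class DatasetTemplate:
    """An empty extraction sheet for a set of target measures."""

    measure_set: tuple[str, ...]
    columns: tuple[str, ...]
    descriptions: tuple[str, ...]


class DatasetError(EsConvertError):
    """Fatal problem with an input dataset (parse failures, duplicate
    columns, invariant violations)."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__(
            "invalid dataset:\n" + "\n".join(f"  - {p}" for p in self.problems)
        )


# ---------------------------------------------------------------------------
# parsing


def _parse_cell(name: str, raw: Any):
    """Parse one raw cell for column ``name``; raise ValueError if malformed."""
    kind = COLUMN_KINDS[name]
    if raw is None:
        return None
    if isinstance(raw, str):
        stripped = raw.strip()
        if stripped.lower() in _NA_TOKENS:
            return None
        if kind == "text":
            return stripped
        if kind == "direction":
            low = stripped.lower()
            if low not in DIRECTIONS:
                raise ValueError(
                    f"expected one of {DIRECTIONS}, got {stripped!r}"
                )
            return low
        return float(stripped)  # ValueError on malformed numerics
    # already numeric (e.g. coming from a DataFrame)
    if isinstance(raw, float) and math.isnan(raw):
        return None
    if kind == "text":
        return str(raw)
    if kind == "direction":
        raise ValueError(f"expected one of {DIRECTIONS}, got {raw!r}")
    return float(raw)


def row_from_mapping(mapping: Mapping[str, Any]):
    """Build a StudyRow from a name->raw-cell mapping (aliases applied).

    Returns ``(row, errors)`` where ``errors`` is a list of
    ``(column, message)`` pairs for malformed cells.
    """
    values: dict[str, Any] = {}
    errors: list[tuple[str, str]] = []
    for key, raw in mapping.items():
        name = ALIASES.get(str(key).strip().lower(), str(key).strip())
        if name not in COLUMN_KINDS:
            continue
        try:
            values[name] = _parse_cell(name, raw)
        except (ValueError, TypeError) as exc:
            errors.append((name, str(exc) or f"could not parse {raw!r}"))
    return StudyRow(**values), errors


# ---------------------------------------------------------------------------
# validation

_CI_PAIRS = [
    ("m1_ci_lo", "m1_ci_up"),
    ("m2_ci_lo", "m2_ci_up"),
    ("md_ci_lo", "md_ci_up"),
    ("or_ci_lo", "or_ci_up"),
    ("rr_ci_lo", "rr_ci_up"),
    ("irr_ci_lo", "irr_ci_up"),
]

_QUANTILE_CHAINS = [
    ("min1", "q1_1", "med1", "q3_1", "max1"),
    ("min2", "q1_2", "med2", "q3_2", "max2"),
]


def validate_row(row) -> list[Violation]:
    """Return every invariant violation in ``row`` (empty when clean).

    Pure and order-independent over fields; a fully blank row is clean
    (emptiness is handled downstream by route detection).
    """
    out: list[Violation] = []
    for name in COLUMN_NAMES:
        val = getattr(row, name)
        if val is None:
            continue
        kind = COLUMN_KINDS[name]
        if kind in ("text", "direction"):
            continue
        if not math.isfinite(val):
            out.append(Violation(name, "must be finite"))
            continue
        if kind == "count" and (val < 0 or val != int(val)):
            out.append(Violation(name, "must be a non-negative integer"))
        elif kind == "pos" and val <= 0:
            out.append(Violation(name, "must be strictly positive"))
        elif kind == "nonneg" and val < 0:
            out.append(Violation(name, "must be non-negative"))
        elif kind == "prob" and not 0 <= val <= 1:
            out.append(Violation(name, "must lie in [0, 1]"))
        elif kind == "corr" and not -1 < val < 1:
            out.append(Violation(name, "must lie in (-1, 1)"))
        elif kind == "pvalue" and not 0 < val <= 1:
            out.append(Violation(name, "must lie in (0, 1]"))
        elif kind == "eta" and not 0 <= val < 1:
            out.append(Violation(name, "must lie in [0, 1)"))
    for lo, up in _CI_PAIRS:
        lo_v, up_v = getattr(row, lo), getattr(row, up)
        if lo_v is not None and up_v is not None and not lo_v < up_v:
            out.append(Violation(lo, f"CI bounds must satisfy {lo} < {up}"))
    for chain in _QUANTILE_CHAINS:
        present = [(n, getattr(row, n)) for n in chain if getattr(row, n) is not None]
        for (n_a, v_a), (n_b, v_b) in zip(present, present[1:]):
            if v_a > v_b:
                out.append(Violation(n_b, f"ordering violated: {n_a} > {n_b}"))
    if all(getattr(row, n) is not None for n in ("a", "b", "n1")):
        if row.a + row.b != row.n1:
            out.append(Violation("a", "a + b must equal n1"))
    if all(getattr(row, n) is not None for n in ("c", "d_cell", "n2")):
        if row.c + row.d_cell != row.n2:
            out.append(Violation("c", "c + d_cell must equal n2"))
    return out


# ---------------------------------------------------------------------------
# file IO

_DIALECT_SUFFIX = {".csv": "csv", ".tsv": "tsv", ".txt": "tsv", ".xlsx": "xlsx"}
_SEP = {"csv": ",", "tsv": "\t"}


def _infer_dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("csv", "tsv", "xlsx"):
            raise InputError(f"unknown dialect {dialect!r}")
        return dialect
    try:
        return _DIALECT_SUFFIX[path.suffix.lower()]
    except KeyError:
        raise InputError(f"cannot infer dialect from suffix {path.suffix!r}")


def _read_raw_table(path: Path, dialect: str) -> tuple[list[str], list[list[Any]]]:
    """Header + raw string/cell rows, with duplicate-header detection."""
    if dialect == "xlsx":
        from openpyxl import load_workbook

        wb = load_workbook(path, read_only=True, data_only=True)
        ws = wb.worksheets[0]
        rows = [list(r) for r in ws.iter_rows(values_only=True)]
        wb.close()
        if not rows:
            raise DatasetError(["file has no header row"])
        header = ["" if c is None else str(c).strip() for c in rows[0]]
        body = rows[1:]
    else:
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh, delimiter=_SEP[dialect])
            rows = list(reader)
        if not rows:
            raise DatasetError(["file has no header row"])
        header = [c.strip() for c in rows[0]]
        body = rows[1:]
    seen: set[str] = set()
    dupes = sorted({h for h in header if h in seen or seen.add(h)})
    if dupes:
        raise DatasetError([f"duplicate column name(s): {', '.join(dupes)}"])
    return header, body


def read_dataset(path, dialect: str | None = None, validate: bool = True):
    """Read a dataset file into a list of validated StudyRows.

    Unknown columns are ignored with a logged warning.  Malformed numeric
    cells and (when ``validate``) invariant violations are collected into a
    single :class:`DatasetError` naming each offending row and column.
    """
    path = Path(path)
    dialect = _infer_dialect(path, dialect)
    header, body = _read_raw_table(path, dialect)
    canon = [ALIASES.get(h.lower(), h) for h in header]
    unknown = [h for h, c in zip(header, canon) if c not in COLUMN_KINDS and h]
    if unknown:
        log.warning("ignoring unrecognized column(s): %s", ", ".join(unknown))
    rows: list[Any] = []
    problems: list[str] = []
    for i, raw in enumerate(body, start=1):
        mapping = dict(zip(header, raw))
        if all(
            v is None or (isinstance(v, str) and not v.strip()) for v in mapping.values()
        ):
            continue  # fully blank line
        row, errors = row_from_mapping(mapping)
        for col, msg in errors:
            problems.append(f"row {i}, column {col!r}: {msg}")
        if validate:
            for v in validate_row(row):
                problems.append(f"row {i}, column {v.field!r}: {v.message}")
        rows.append(row)
    if problems:
        raise DatasetError(problems)
    return rows


def rows_from_frame(frame: pd.DataFrame, validate: bool = True):
    """Convert a DataFrame with schema columns into StudyRows."""
    canon = [ALIASES.get(str(c).lower(), str(c)) for c in frame.columns]
    dupes = sorted({c for c in canon if canon.count(c) > 1 and c in COLUMN_KINDS})
    if dupes:
        raise DatasetError([f"duplicate column name(s): {', '.join(dupes)}"])
    unknown = [c for c in canon if c not in COLUMN_KINDS]
    if unknown:
        log.warning("ignoring unrecognized column(s): %s", ", ".join(unknown))
    rows, problems = [], []
    for i, (_, rec) in enumerate(frame.iterrows(), start=1):
        row, errors = row_from_mapping(rec.to_dict())
        for col, msg in errors:
            problems.append(f"row {i}, column {col!r}: {msg}")
        if validate:
            for v in validate_row(row):
                problems.append(f"row {i}, column {v.field!r}: {v.message}")
        rows.append(row)
    if problems:
        raise DatasetError(problems)
    return rows


def to_frame(rows: Iterable[Any]) -> pd.DataFrame:
    """StudyRows -> DataFrame in canonical column order (NaN for missing)."""
    records = [{n: getattr(r, n) for n in COLUMN_NAMES} for r in rows]
    frame = pd.DataFrame.from_records(records, columns=list(COLUMN_NAMES))
    return frame


def write_dataset(data, path, dialect: str | None = None) -> None:
    """Write StudyRows or a DataFrame to CSV/TSV/XLSX (UTF-8, RFC-4180)."""
    path = Path(path)
    dialect = _infer_dialect(path, dialect)
    frame = data if isinstance(data, pd.DataFrame) else to_frame(data)
    if dialect == "xlsx":
        frame.to_excel(path, index=False)
    else:
        frame.to_csv(path, index=False, sep=_SEP[dialect])


# ---------------------------------------------------------------------------
# templates


def make_template(
    measures: Iterable[str], path=None, dialect: str = "csv"
) -> DatasetTemplate:
    """Build (and optionally write) an empty extraction sheet.

    The sheet's header is the union of the columns needed by every input
    route that can produce any requested measure, in canonical order; the
    second row carries one description line per column.
    """
    from . import registry  # local import: registry depends on this module

    measures = tuple(dict.fromkeys(measures))
    if not measures:
        raise InputError("at least one measure code is required")
    unknown = [m for m in measures if m not in registry.measures()]
    if unknown:
        raise InputError(
            f"unknown measure code(s) {unknown}; valid codes: "
            f"{', '.join(registry.measures())}"
        )
    needed: set[str] = {"study_id", "es_direction"}
    for m in measures:
        for f in registry.formulas_for(m):
            needed.update(f.requires)
            if f.needs_direction:
                needed.add("es_direction")
    columns = tuple(n for n in COLUMN_NAMES if n in needed)
    template = DatasetTemplate(
        measure_set=measures,
        columns=columns,
        descriptions=tuple(COLUMN_DESCRIPTIONS[c] for c in columns),
    )
    if path is not None:
        frame = pd.DataFrame([template.descriptions], columns=list(columns))
        path = Path(path)
        dialect = _infer_dialect(path, dialect)
        if dialect == "xlsx":
            frame.to_excel(path, index=False)
        else:
            frame.to_csv(path, index=False, sep=_SEP[dialect])
    return template
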