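"""Cell-level diffing of double-extracted datasets.

Two independent data extractors produce two spreadsheets describing the
same studies; :func:`compare_datasets` realigns their rows on a key-column
tuple (so row order and row count may differ), compares every shared cell,
and reports only the differences.  Numeric cells are compared after
parsing ("2.0" equals "2"), with an optional absolute tolerance for float
columns; text cells are compared exactly after whitespace trimming.
"""

from __future__ import annotations

import html as _html
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .estimate import EsConvertError, InputError


class CompareError(EsConvertError):
    pass


@dataclass(frozen=True)
class DiffReport:
    """Differences between two key-aligned datasets.

    ``differences`` has one row per differing cell: the key columns, the
    column name, and the two values.  ``only_in_a``/``only_in_b`` list
    rows whose key exists in one dataset only.
    """

    key_cols: tuple[str, ...]
    differences: pd.DataFrame
    only_in_a: pd.DataFrame
    only_in_b: pd.DataFrame
    compared_columns: tuple[str, ...]
    n_common_rows: int

    @property
    def n_diff_cells(self) -> int:
        return len(self.differences)

    @property
    def n_diff_rows(self) -> int:
        if self.differences.empty:
            return 0
        return self.differences.groupby(list(self.key_cols)).ngroups

    @property
    def is_empty(self) -> bool:
        return (
            self.differences.empty
            and self.only_in_a.empty
            and self.only_in_b.empty
        )

    def summary(self) -> dict[str, int]:
        return {
            "common_rows": self.n_common_rows,
            "differing_cells": self.n_diff_cells,
            "differing_rows": self.n_diff_rows,
            "rows_only_in_a": len(self.only_in_a),
            "rows_only_in_b": len(self.only_in_b),
        }


def _cells_equal(x, y, tol: float) -> bool:
    xs = "" if x is None else str(x).strip()
    ys = "" if y is None else str(y).strip()
    if xs.lower() in ("", "nan") and ys.lower() in ("", "nan"):
        return True
    try:
        xf, yf = float(xs), float(ys)
    except ValueError:
        return xs == ys
    if math.isnan(xf) and math.isnan(yf):
        return True
    return abs(xf - yf) <= tol


def _load(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table.reset_index(drop=True)
    path = Path(table)
    if path.suffix.lower() == ".xlsx":
        return pd.read_excel(path, dtype=str)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(path, dtype=str, sep=sep, keep_default_na=False)


def compare_datasets(a, b, key_cols, tol: float = 0.0) -> DiffReport:
    """Diff two datasets after key-based row realignment.

    ``key_cols`` must exist in both tables and their value tuples must be
    unique within each table (duplicates are a fatal error naming the
    offending keys).  Columns are compared on the intersection, with a
    warning when the column sets differ.
    """
    import logging

    log = logging.getLogger("esconvert")
    fa, fb = _load(a), _load(b)
    key_cols = tuple(key_cols)
    if not key_cols:
        raise InputError("at least one key column is required")
    for name, frame in (("A", fa), ("B", fb)):
        missing = [k for k in key_cols if k not in frame.columns]
        if missing:
            raise CompareError(
                f"key column(s) {missing} missing from dataset {name}"
            )
    cols_a = [c for c in fa.columns if c not in key_cols]
    cols_b = [c for c in fb.columns if c not in key_cols]
    shared = [c for c in cols_a if c in set(cols_b)]
    if set(cols_a) != set(cols_b):
        log.warning(
            "datasets have different column sets; comparing on the "
            "intersection (%d column(s))", len(shared),
        )

    def keyed(frame, name):
        keys = [tuple(str(frame.at[i, k]).strip() for k in key_cols)
                for i in frame.index]
        seen, dupes = set(), []
        for k in keys:
            if k in seen:
                dupes.append(k)
            seen.add(k)
        if dupes:
            raise CompareError(
                f"duplicate key(s) in dataset {name}: {sorted(set(dupes))}"
            )
        return dict(zip(keys, frame.index)), keys

    index_a, keys_a = keyed(fa, "A")
    index_b, keys_b = keyed(fb, "B")
    common = [k for k in keys_a if k in index_b]
    only_a = [k for k in keys_a if k not in index_b]
    only_b = [k for k in keys_b if k not in index_a]

    diff_records = []
    for key in common:
        ia, ib = index_a[key], index_b[key]
        for col in shared:
            va, vb = fa.at[ia, col], fb.at[ib, col]
            if not _cells_equal(va, vb, tol):
                rec = dict(zip(key_cols, key))
                rec.update(column=col, value_a=va, value_b=vb)
                diff_records.append(rec)
    diff_frame = pd.DataFrame.from_records(
        diff_records,
        columns=list(key_cols) + ["column", "value_a", "value_b"],
    )
    return DiffReport(
        key_cols=key_cols,
        differences=diff_frame,
        only_in_a=fa.loc[[index_a[k] for k in only_a]].reset_index(drop=True),
        only_in_b=fb.loc[[index_b[k] for k in only_b]].reset_index(drop=True),
        compared_columns=tuple(shared),
        n_common_rows=len(common),
    )


def write_report(report: DiffReport, path, fmt: str | None = None) -> None:
    """Write a diff report as csv, txt, xlsx or html."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        report.differences.to_csv(path, index=False)
    elif fmt == "txt":
        with open(path, "w", encoding="utf-8") as fh:
            for k, v in report.summary().items():
                fh.write(f"{k}: {v}\n")
            fh.write("\n")
            fh.write(report.differences.to_string(index=False))
            fh.write("\n")
    elif fmt == "xlsx":
        with pd.ExcelWriter(path) as writer:
            report.differences.to_excel(
                writer, sheet_name="differences", index=False)
            report.only_in_a.to_excel(
                writer, sheet_name="only_in_a", index=False)
            report.only_in_b.to_excel(
                writer, sheet_name="only_in_b", index=False)
    elif fmt == "html":
        _write_html(report, path)
    else:
        raise InputError(f"unknown report format {fmt!r}")


def _write_html(report: DiffReport, path) -> None:
    """Minimal colour-coded rendering: grey for consistent context cells,
    highlighted cells where the two extractions disagree."""
    esc = _html.escape
    rows = []
    for _, rec in report.differences.iterrows():
        key = " / ".join(esc(str(rec[k])) for k in report.key_cols)
        rows.append(
            f"<tr><td class='ctx'>{key}</td>"
            f"<td class='ctx'>{esc(str(rec['column']))}</td>"
            f"<td class='diff'>{esc(str(rec['value_a']))}</td>"
            f"<td class='diff'>{esc(str(rec['value_b']))}</td></tr>"
        )
    summary = " | ".join(f"{k}: {v}" for k, v in report.summary().items())
    doc = (
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        "<style>table{border-collapse:collapse}"
        "td,th{border:1px solid #999;padding:4px 8px}"
        ".ctx{color:#777}.diff{background:#ffd7d7;color:#a00}</style>"
        "</head><body>"
        f"<p>{esc(summary)}</p>"
        "<table><tr><th>key</th><th>column</th>"
        "<th>dataset A</th><th>dataset B</th></tr>"
        + "".join(rows)
        + "</table></body></html>"
    )
    Path(path).write_text(doc, encoding="utf-8")
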