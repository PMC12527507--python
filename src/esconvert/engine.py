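"""Per-row route detection, candidate computation, selection, conversion.

``convert_df`` is the workhorse: given a dataset and a target measure it
computes, for every row, one candidate estimate per applicable input
route, selects a single main estimate, and appends the consistency
indicators whenever two or more routes overlap.  Processing is strictly
row-independent, order-preserving and deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import consistency as _consistency
from . import registry, schema
from .estimate import EffectEstimate, EsConvertError, InputError

log = logging.getLogger("esconvert")

#: The three approaches to selecting a main effect size, and the concrete
#: strategies each one admits.
SELECTION_APPROACHES = {
    "custom_hierarchy": ("hierarchy",),
    "predefined_hierarchy": ("auto",),
    "extreme_value": ("smallest", "largest"),
}

STRATEGIES = tuple(s for ss in SELECTION_APPROACHES.values() for s in ss)


def comparison_scale_name(measure: str) -> str:
    """Human-readable name of a measure's comparison scale."""
    from .estimate import LOG_MEASURES

    if measure in LOG_MEASURES:
        return "log"
    if measure == "R":
        return "fisher_z"
    if measure == "NNT":
        return "risk_diff"
    return "identity"


@dataclass(frozen=True)
class Hierarchy:
    """Ordered route preference, highest priority first."""

    routes: tuple[str, ...]
    source: str = "user"

    def __post_init__(self):
        if len(set(self.routes)) != len(self.routes):
            raise InputError("hierarchy contains duplicate routes")
        registered = set(registry.routes())
        unknown = [r for r in self.routes if r not in registered]
        if unknown:
            raise InputError(
                f"hierarchy names unregistered route(s): {unknown}"
            )

    @classmethod
    def parse(cls, spec, source: str = "user") -> "Hierarchy":
        """From a 'means_sd>t>p' string or an iterable of route ids."""
        if isinstance(spec, str):
            routes = tuple(p.strip() for p in spec.split(">") if p.strip())
        else:
            routes = tuple(spec)
        if not routes:
            raise InputError("hierarchy is empty")
        return cls(routes=routes, source=source)

    @classmethod
    def predefined(cls, measure: str) -> "Hierarchy":
        return cls(routes=registry.predefined_routes(measure),
                   source="predefined")


@dataclass(frozen=True)
class CandidateSet:
    """All estimates computable for one row, plus the selected main one."""

    row: object
    measure: str
    candidates: tuple[EffectEstimate, ...]
    notes: tuple[tuple[str, str], ...] = ()  # (route, message)
    selected: EffectEstimate | None = None
    selection_strategy: str | None = None

    @property
    def routes_available(self) -> tuple[str, ...]:
        return tuple(c.route for c in self.candidates)

    @property
    def route_used(self) -> str | None:
        return self.selected.route if self.selected is not None else None


def enumerate_candidates(row, measure: str) -> CandidateSet:
    """One candidate per applicable registered route, in registry order.

    Per-route formula failures never abort the row: they are recorded as
    (route, message) notes.  A row with no applicable route yields an
    empty set with an explanatory note.
    """
    cands: list[EffectEstimate] = []
    notes: list[tuple[str, str]] = []
    for f in registry.formulas_for(measure):
        if not f.applicable(row):
            continue
        if not f.direction_ok(row):
            notes.append(
                (f.route,
                 "direction required: set es_direction to 'positive' or "
                 "'negative' for signless statistics")
            )
            continue
        try:
            cands.append(f.fn(row))
        except EsConvertError as exc:
            notes.append((f.route, str(exc)))
    if not cands and not notes:
        notes.append(("", "no applicable input data"))
    return CandidateSet(
        row=row, measure=measure, candidates=tuple(cands), notes=tuple(notes)
    )


def select_main(
    cs: CandidateSet,
    strategy: str = "auto",
    hierarchy: Hierarchy | None = None,
) -> CandidateSet:
    """Pick the main estimate; a pure function of its arguments.

    hierarchy: first candidate whose route appears earliest in the given
    hierarchy (falls back to 'auto' with a warning when the hierarchy
    covers none of the available routes).  auto: the shipped pre-defined
    hierarchy for the measure.  smallest/largest: the candidate with the
    min/max absolute effect on the comparison scale, ties broken by
    registry order.
    """
    if strategy not in STRATEGIES:
        raise InputError(f"unknown strategy {strategy!r}; valid: {STRATEGIES}")
    if not cs.candidates:
        return replace(cs, selected=None, selection_strategy=strategy)
    if strategy == "hierarchy":
        if hierarchy is None:
            raise InputError("strategy 'hierarchy' requires a Hierarchy")
        available = cs.routes_available
        for route in hierarchy.routes:
            if route in available:
                pick = cs.candidates[available.index(route)]
                return replace(cs, selected=pick, selection_strategy=strategy)
        log.warning(
            "hierarchy %s covers none of the available routes %s; "
            "falling back to the pre-defined hierarchy",
            hierarchy.routes, available,
        )
        strategy = "auto"
    if strategy == "auto":
        order = registry.predefined_routes(cs.measure)
        rank = {r: i for i, r in enumerate(order)}
        pick = min(
            range(len(cs.candidates)),
            key=lambda i: (rank.get(cs.candidates[i].route, len(rank)), i),
        )
        return replace(cs, selected=cs.candidates[pick],
                       selection_strategy="auto")
    sign = 1 if strategy == "smallest" else -1
    pick = min(
        range(len(cs.candidates)),
        key=lambda i: (sign * abs(cs.candidates[i].comparison_value), i),
    )
    return replace(cs, selected=cs.candidates[pick],
                   selection_strategy=strategy)


_OUTPUT_COLUMNS = [
    "study_id", "measure", "n_candidates", "routes_available", "route_used",
    "es_value", "es_se", "es_ci_lo", "es_ci_up", "es_scale",
    "es_min", "es_max", "es_diff", "es_sd", "ci_overlap_pct",
    "consistency_scale", "flags", "note",
]


def convert_df(
    data,
    measure: str,
    es_selected: str = "auto",
    hierarchy: Hierarchy | str | Sequence[str] | None = None,
    sign_tol: float = 0.01,
    overlap_threshold: float = 25.0,
    diff_threshold: float | None = None,
    overlap_denominator: str = "shorter",
) -> pd.DataFrame:
    """Compute one main effect size per row of a dataset.

    ``data`` may be a file path, a DataFrame with schema columns, or an
    iterable of StudyRows.  The output has one row per input row: the
    main estimate (value, SE, 95% CI, route used), all available routes,
    and — whenever at least two routes overlap — the five consistency
    indicators plus discrepancy flags.  Rows without any applicable input
    yield blanks and a note; a summary is logged.
    """
    rows = _as_rows(data)
    if hierarchy is not None and not isinstance(hierarchy, Hierarchy):
        hierarchy = Hierarchy.parse(hierarchy)
    records = []
    n_missing = 0
    for row in rows:
        cs = select_main(
            enumerate_candidates(row, measure), es_selected, hierarchy
        )
        rec = dict.fromkeys(_OUTPUT_COLUMNS, math.nan)
        rec["study_id"] = row.study_id
        rec["measure"] = measure
        rec["n_candidates"] = len(cs.candidates)
        rec["routes_available"] = ";".join(cs.routes_available)
        rec["flags"] = ""
        note_parts = [f"{r}: {m}" if r else m for r, m in cs.notes]
        if cs.selected is not None:
            sel = cs.selected
            rec.update(
                route_used=sel.route, es_value=sel.value, es_se=sel.se,
                es_ci_lo=sel.ci_lo, es_ci_up=sel.ci_up, es_scale=sel.scale,
            )
            if sel.note:
                note_parts.append(sel.note)
        else:
            rec["route_used"] = ""
            n_missing += 1
        report = _consistency.consistency_indicators(
            cs, denominator=overlap_denominator
        )
        if report is not None:
            rec.update(
                es_min=report.es_min, es_max=report.es_max,
                es_diff=report.es_diff, es_sd=report.es_sd,
                ci_overlap_pct=report.ci_overlap_pct,
                consistency_scale=report.scale,
            )
            flags = _consistency.flag_discrepancies(
                cs, report, sign_tol=sign_tol,
                overlap_threshold=overlap_threshold,
                diff_threshold=diff_threshold,
            )
            rec["flags"] = ";".join(flags)
        else:
            rec["consistency_scale"] = ""
        rec["note"] = "; ".join(note_parts)
        records.append(rec)
    if n_missing:
        log.info(
            "%d of %d row(s) had no applicable input data for measure %s",
            n_missing, len(records), measure,
        )
    return pd.DataFrame.from_records(records, columns=_OUTPUT_COLUMNS)


def _as_rows(data):
    if isinstance(data, (str, Path)):
        return schema.read_dataset(data)
    if isinstance(data, pd.DataFrame):
        return schema.rows_from_frame(data)
    return list(data)
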