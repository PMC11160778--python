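"""Trial-level data model for urgent oddball-search sessions.

The canonical in-memory container is a :class:`pandas.DataFrame` with one row
per trial and the columns listed in :data:`CANONICAL_COLUMNS`.  Timing columns
are in milliseconds.  ``pt_ms`` (processing time) is the interval during which
the color cue can inform the choice, ``rt_ms - gap_ms``; it may be negative on
trials where the saccade was launched before cue onset.

Task constants: the go signal precedes the cue by a Gap of 0-225 ms, and a
response must land within 450 ms of the go signal to count.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_COLUMNS",
    "COLORS",
    "QUADRANTS",
    "GAP_MAX_MS",
    "RT_MAX_MS",
    "LoadReport",
    "compute_pt",
    "assign_quadrant",
    "load_trials",
    "write_trials",
    "filter_valid",
    "shift_rts",
    "validate_trials",
]

COLORS = ("red", "green")
QUADRANTS = ("right", "up", "left", "down")

GAP_MAX_MS = 225.0
RT_MAX_MS = 450.0

#: Canonical column order of a trial table.  ``target_x_deg``/``target_y_deg``
#: are optional; ``pt_ms``, ``target_quadrant`` and ``correct`` are derived
#: when absent.
CANONICAL_COLUMNS = (
    "subject_id",
    "session_id",
    "trial_index",
    "gap_ms",
    "rt_ms",
    "pt_ms",
    "target_color",
    "target_quadrant",
    "choice_quadrant",
    "correct",
    "target_x_deg",
    "target_y_deg",
)

_REQUIRED = ("subject_id", "session_id", "trial_index", "gap_ms", "rt_ms",
             "target_color", "choice_quadrant")


@dataclass
class LoadReport:
    """Accounting of a :func:`load_trials` call."""

    n_parsed: int = 0
    n_rejected: int = 0
    derived_columns: list[str] = field(default_factory=list)
    rejected_rows: list[tuple[int, str]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_parsed": self.n_parsed,
                "n_rejected": self.n_rejected,
                "derived_columns": self.derived_columns,
                "rejected_rows": self.rejected_rows,
            },
            indent=2,
        )


def compute_pt(rt_ms: float, gap_ms: float) -> float:
    """Processing time: reaction time minus the go-to-cue gap.

    Negative values are legitimate (the saccade left before the cue appeared;
    such choices are necessarily uninformed).
    """
    if not (math.isfinite(rt_ms) and math.isfinite(gap_ms)):
        raise ValueError("rt_ms and gap_ms must be finite")
    return rt_ms - gap_ms


def assign_quadrant(x_deg: float, y_deg: float) -> str:
    """Map a target position (degrees of visual angle) to its quadrant label.

    Half-open 90-degree sectors anchored counter-clockwise on the axes:
    ``right`` covers polar angle [0, 90), so the positive x axis is ``right``,
    the positive y axis ``up``, the negative x axis ``left`` and the negative
    y axis ``down``.  The origin has no defined quadrant.
    """
    if x_deg == 0.0 and y_deg == 0.0:
        raise ValueError("quadrant undefined at the origin")
    theta = math.atan2(y_deg, x_deg) % (2.0 * math.pi)
    sector = int(theta // (math.pi / 2.0)) % 4
    return QUADRANTS[sector]


def _coerce_row(row: Mapping[str, object]) -> dict:
    out = dict(row)
    out["trial_index"] = int(out["trial_index"])
    for c in ("gap_ms", "rt_ms", "pt_ms", "target_x_deg", "target_y_deg"):
        if c in out and out[c] is not None and out[c] == out[c]:
            out[c] = float(out[c])
    return out


def load_trials(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    strict: bool = True,
) -> tuple[pd.DataFrame, LoadReport]:
    """Read a delimited trial table and return (trials, load report).

    Parameters
    ----------
    path
        CSV file with a header row naming the canonical columns (snake_case).
    column_map
        Optional mapping ``{file column -> canonical column}`` for tables
        using a different schema.
    strict
        If True, a provided ``correct`` column disagreeing with the
        quadrant comparison is a hard error (it flags mis-coded inputs);
        if False such rows are rejected with a warning entry instead.

    Missing ``pt_ms`` is derived as ``rt_ms - gap_ms``; a missing
    ``target_quadrant`` is derived from ``target_x_deg``/``target_y_deg``;
    a missing ``correct`` is derived from the quadrant comparison.
    Unparseable rows are skipped and logged in the report.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    missing = [c for c in _REQUIRED if c not in raw.columns]
    has_xy = {"target_x_deg", "target_y_deg"} <= set(raw.columns)
    if "target_quadrant" not in raw.columns and not has_xy:
        missing.append("target_quadrant (or target_x_deg/target_y_deg)")
    if missing:
        raise ValueError(f"missing required columns: {missing}")

    report = LoadReport()
    records: list[dict] = []
    seen_keys: set[tuple] = set()
    for i, row in enumerate(raw.to_dict("records")):
        try:
            rec = _parse_row(row, has_xy, report, strict=strict)
        except _RowError as e:
            report.n_rejected += 1
            report.rejected_rows.append((i, str(e)))
            continue
        key = (rec["subject_id"], rec["session_id"], rec["trial_index"])
        if key in seen_keys:
            raise ValueError(f"duplicate (subject, session, trial_index): {key}")
        seen_keys.add(key)
        records.append(rec)
        report.n_parsed += 1

    trials = pd.DataFrame.from_records(records, columns=CANONICAL_COLUMNS)
    trials = trials.sort_values(
        ["subject_id", "session_id", "trial_index"], kind="stable"
    ).reset_index(drop=True)
    trials = trials.astype(
        {"trial_index": int, "gap_ms": float, "rt_ms": float, "pt_ms": float,
         "correct": bool, "target_x_deg": float, "target_y_deg": float}
    )
    report.derived_columns = sorted(set(report.derived_columns))
    return trials, report


class _RowError(ValueError):
    pass


def _parse_row(row: Mapping[str, str], has_xy: bool, report: LoadReport,
               strict: bool) -> dict:
    rec: dict = {}
    for c in ("subject_id", "session_id"):
        rec[c] = str(row[c])
    try:
        rec["trial_index"] = int(row["trial_index"])
        rec["gap_ms"] = float(row["gap_ms"])
        rec["rt_ms"] = float(row["rt_ms"])
    except (TypeError, ValueError) as e:
        raise _RowError(f"unparseable numeric field: {e}") from e
    if rec["trial_index"] < 0:
        raise _RowError("trial_index must be >= 0")
    if not (math.isfinite(rec["gap_ms"]) and math.isfinite(rec["rt_ms"])):
        raise _RowError("non-finite gap or rt")

    color = str(row["target_color"]).strip().lower()
    if color not in COLORS:
        raise _RowError(f"unknown target_color {color!r}")
    rec["target_color"] = color

    for xy in ("target_x_deg", "target_y_deg"):
        v = row.get(xy, "")
        rec[xy] = float(v) if str(v).strip() not in ("", "NA", "nan") else math.nan

    tq = str(row.get("target_quadrant", "")).strip().lower()
    if tq:
        if tq not in QUADRANTS:
            raise _RowError(f"unknown target_quadrant {tq!r}")
        rec["target_quadrant"] = tq
    elif has_xy and math.isfinite(rec["target_x_deg"]):
        rec["target_quadrant"] = assign_quadrant(rec["target_x_deg"],
                                                 rec["target_y_deg"])
        report.derived_columns.append("target_quadrant")
    else:
        raise _RowError("no target quadrant and no usable target position")

    cq = str(row["choice_quadrant"]).strip().lower()
    if cq not in QUADRANTS:
        raise _RowError(f"unknown choice_quadrant {cq!r}")
    rec["choice_quadrant"] = cq

    derived_correct = rec["choice_quadrant"] == rec["target_quadrant"]
    given = str(row.get("correct", "")).strip().lower()
    if given:
        given_correct = given in ("1", "true", "t", "yes")
        if given_correct != derived_correct:
            msg = (f"correct column ({given_correct}) contradicts quadrant "
                   f"comparison ({derived_correct})")
            if strict:
                raise ValueError(msg)
            raise _RowError(msg)
    else:
        report.derived_columns.append("correct")
    rec["correct"] = derived_correct

    pt = str(row.get("pt_ms", "")).strip()
    if pt:
        rec["pt_ms"] = float(pt)
        if abs(rec["pt_ms"] - (rec["rt_ms"] - rec["gap_ms"])) > 1e-9:
            raise _RowError("pt_ms != rt_ms - gap_ms")
    else:
        rec["pt_ms"] = compute_pt(rec["rt_ms"], rec["gap_ms"])
        report.derived_columns.append("pt_ms")
    return rec


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table in the canonical CSV schema."""
    cols = [c for c in CANONICAL_COLUMNS if c in trials.columns]
    trials.to_csv(path, index=False, columns=cols)


def validate_trials(trials: pd.DataFrame) -> None:
    """Raise if the trial-table invariants are violated.

    Checks: pt = rt - gap exactly; correct == (choice quadrant == target
    quadrant); gap within the task's 0-225 ms range; enum values.
    """
    if not np.allclose(trials["pt_ms"], trials["rt_ms"] - trials["gap_ms"],
                       rtol=0.0, atol=1e-9):
        raise ValueError("pt_ms != rt_ms - gap_ms")
    eq = trials["choice_quadrant"].to_numpy() == trials["target_quadrant"].to_numpy()
    if not (trials["correct"].to_numpy() == eq).all():
        raise ValueError("correct flag inconsistent with quadrants")
    gap = trials["gap_ms"].to_numpy()
    if ((gap < 0.0) | (gap > GAP_MAX_MS)).any():
        raise ValueError(f"gap_ms outside [0, {GAP_MAX_MS}]")
    for col, allowed in (("target_color", COLORS),
                         ("target_quadrant", QUADRANTS),
                         ("choice_quadrant", QUADRANTS)):
        if not trials[col].isin(allowed).all():
            raise ValueError(f"invalid values in {col}")


def filter_valid(trials: pd.DataFrame) -> pd.DataFrame:
    """Keep trials with a finite RT no later than 450 ms after the go signal.

    Order is preserved; the number of removed trials is available as
    ``len(before) - len(after)``.
    """
    rt = trials["rt_ms"].to_numpy(dtype=float)
    keep = np.isfinite(rt) & (rt <= RT_MAX_MS)
    return trials.loc[keep].reset_index(drop=True)


def shift_rts(trials: pd.DataFrame, delta_ms: float,
              subjects: Iterable[str] | None = None) -> pd.DataFrame:
    """Subtract ``delta_ms`` from every RT (optionally only for ``subjects``).

    PTs move by the same amount; all other fields are untouched.  Used to
    align one subject's response times to another's before pooling.
    """
    out = trials.copy()
    if subjects is None:
        mask = np.ones(len(out), dtype=bool)
    else:
        mask = out["subject_id"].isin(list(subjects)).to_numpy()
    out.loc[mask, "rt_ms"] = out.loc[mask, "rt_ms"] - delta_ms
    out.loc[mask, "pt_ms"] = out.loc[mask, "rt_ms"] - out.loc[mask, "gap_ms"]
    return out
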