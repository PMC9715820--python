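"""Patient event timelines and delimited-text cohort I/O.

A cohort file is plain CSV with one baseline row per patient followed by one
row per dated event, so it can be inspected, filtered and version-controlled
with ordinary tools. The common study end date travels in a ``# study_end_date=``
comment on the first line.
"""

from __future__ import annotations

import datetime as _dt
import io
import os
from dataclasses import dataclass, field, replace

import pandas as pd

EVENT_KINDS = ("clinic_visit", "hf_hospitalization", "death")
SEXES = ("male", "female")

_COLUMNS = [
    "patient_id",
    "row_type",
    "date",
    "event_kind",
    "age_years",
    "sex",
    "lvef_percent",
    "ntprobnp_ng_per_l",
]


class CohortParseError(ValueError):
    """Malformed cohort file; message names the offending line number."""


@dataclass(frozen=True)
class PatientTimeline:
    """One patient's dated events, baseline covariates and administrative window.

    The baseline assessment itself counts as a clinic contact; ``events`` holds
    only post-baseline dated events, sorted by date, with at most one death
    event which must come last. All event dates lie inside
    ``[baseline_date, study_end_date]``.
    """

    patient_id: str
    baseline_date: _dt.date
    study_end_date: _dt.date
    events: tuple[tuple[_dt.date, str], ...] = ()
    age_years: float | None = None
    sex: str | None = None
    lvef_percent: float | None = None
    ntprobnp_ng_per_l: float | None = None

    def __post_init__(self) -> None:
        if self.study_end_date < self.baseline_date:
            raise ValueError(f"patient {self.patient_id}: study end precedes baseline")
        if self.sex is not None and self.sex not in SEXES:
            raise ValueError(f"patient {self.patient_id}: sex must be one of {SEXES}")
        dates = [d for d, _ in self.events]
        if dates != sorted(dates):
            raise ValueError(f"patient {self.patient_id}: events not sorted by date")
        deaths = [i for i, (_, k) in enumerate(self.events) if k == "death"]
        if len(deaths) > 1:
            raise ValueError(f"patient {self.patient_id}: more than one death event")
        if deaths and deaths[0] != len(self.events) - 1:
            raise ValueError(f"patient {self.patient_id}: death is not the last event")
        for d, kind in self.events:
            if kind not in EVENT_KINDS:
                raise ValueError(f"patient {self.patient_id}: unknown event kind {kind!r}")
            if d < self.baseline_date:
                raise ValueError(
                    f"patient {self.patient_id}: event {kind} on {d} precedes baseline "
                    f"{self.baseline_date}"
                )
            if d > self.study_end_date:
                raise ValueError(
                    f"patient {self.patient_id}: event {kind} on {d} after study end "
                    f"{self.study_end_date}"
                )

    @property
    def death_date(self) -> _dt.date | None:
        for d, kind in self.events:
            if kind == "death":
                return d
        return None

    def events_of_kind(self, kind: str) -> list[_dt.date]:
        return [d for d, k in self.events if k == kind]


def write_cohort(cohort: list[PatientTimeline], path: str | os.PathLike) -> None:
    """Write a cohort to CSV; lossless round trip with :func:`read_cohort`.

    The study end date (shared across the cohort) is stored as a header
    comment. An empty cohort yields a header-only file.
    """
    rows: list[dict] = []
    study_end = None
    for p in cohort:
        if study_end is None:
            study_end = p.study_end_date
        elif p.study_end_date != study_end:
            raise ValueError("write_cohort requires a common study_end_date across patients")
        rows.append(
            {
                "patient_id": p.patient_id,
                "row_type": "baseline",
                "date": p.baseline_date.isoformat(),
                "event_kind": "",
                "age_years": p.age_years,
                "sex": p.sex or "",
                "lvef_percent": p.lvef_percent,
                "ntprobnp_ng_per_l": p.ntprobnp_ng_per_l,
            }
        )
        for d, kind in p.events:
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "row_type": "event",
                    "date": d.isoformat(),
                    "event_kind": kind,
                    "age_years": None,
                    "sex": "",
                    "lvef_percent": None,
                    "ntprobnp_ng_per_l": None,
                }
            )
    frame = pd.DataFrame(rows, columns=_COLUMNS)
    with open(path, "w", newline="") as fh:
        if study_end is not None:
            fh.write(f"# study_end_date={study_end.isoformat()}\n")
        frame.to_csv(fh, index=False)


def _parse_date(value: str, line_no: int, what: str) -> _dt.date:
    try:
        return _dt.date.fromisoformat(value)
    except ValueError:
        raise CohortParseError(f"line {line_no}: invalid {what} date {value!r}") from None


def _opt_float(value, line_no: int, what: str) -> float | None:
    if value is None or value == "" or pd.isna(value):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise CohortParseError(f"line {line_no}: invalid {what} {value!r}") from None


def read_cohort(path: str | os.PathLike) -> list[PatientTimeline]:
    """Read a cohort CSV written by :func:`write_cohort`.

    Raises :class:`CohortParseError` naming the 1-based file line of any
    malformed or invariant-violating row (e.g. a death dated before baseline).
    """
    with open(path) as fh:
        first = fh.readline()
        study_end: _dt.date | None = None
        offset = 1  # header line of the CSV proper
        if first.startswith("#"):
            offset = 2
            key, _, value = first.lstrip("# ").rstrip().partition("=")
            if key != "study_end_date":
                raise CohortParseError(f"line 1: unrecognised header comment {first.rstrip()!r}")
            study_end = _parse_date(value, 1, "study_end_date")
            body = fh.read()
        else:
            body = first + fh.read()
    frame = pd.read_csv(io.StringIO(body), dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise CohortParseError(f"missing columns: {missing}")

    baselines: dict[str, dict] = {}
    events: dict[str, list[tuple[_dt.date, str]]] = {}
    order: list[str] = []
    for idx, row in frame.iterrows():
        line_no = int(idx) + offset + 1
        pid = row["patient_id"]
        if not pid:
            raise CohortParseError(f"line {line_no}: empty patient_id")
        if row["row_type"] == "baseline":
            if pid in baselines:
                raise CohortParseError(f"line {line_no}: duplicate baseline for patient {pid}")
            baselines[pid] = {
                "line": line_no,
                "baseline_date": _parse_date(row["date"], line_no, "baseline"),
                "age_years": _opt_float(row["age_years"], line_no, "age_years"),
                "sex": row["sex"] or None,
                "lvef_percent": _opt_float(row["lvef_percent"], line_no, "lvef_percent"),
                "ntprobnp_ng_per_l": _opt_float(row["ntprobnp_ng_per_l"], line_no, "ntprobnp_ng_per_l"),
            }
            order.append(pid)
        elif row["row_type"] == "event":
            kind = row["event_kind"]
            if kind not in EVENT_KINDS:
                raise CohortParseError(f"line {line_no}: unknown event_kind {kind!r}")
            events.setdefault(pid, []).append((_parse_date(row["date"], line_no, "event"), kind))
        else:
            raise CohortParseError(f"line {line_no}: unknown row_type {row['row_type']!r}")

    orphans = set(events) - set(baselines)
    if orphans:
        raise CohortParseError(f"events for patients with no baseline row: {sorted(orphans)}")

    cohort: list[PatientTimeline] = []
    for pid in order:
        info = baselines[pid]
        if study_end is None:
            raise CohortParseError("no study_end_date header comment in file")
        try:
            cohort.append(
                PatientTimeline(
                    patient_id=pid,
                    baseline_date=info["baseline_date"],
                    study_end_date=study_end,
                    events=tuple(events.get(pid, [])),
                    age_years=info["age_years"],
                    sex=info["sex"],
                    lvef_percent=info["lvef_percent"],
                    ntprobnp_ng_per_l=info["ntprobnp_ng_per_l"],
                )
            )
        except ValueError as exc:
            raise CohortParseError(f"line {info['line']}: {exc}") from None
    return cohort
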