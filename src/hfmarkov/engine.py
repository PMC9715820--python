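"""Assign cycle-indexed health states to patient timelines.

The study window is cut into consecutive half-open 4-calendar-month cycles
from the baseline date: cycle ``k`` covers ``[baseline + 4(k-1) months,
baseline + 4k months)``, so an event on a boundary date belongs to the later
cycle and no event can be counted twice.

State assignment within a cycle follows the precedence Dead > Hosp > OPD:

* ``D`` if the death date falls in or before the cycle window (and for every
  later cycle — death is absorbing);
* else ``H`` if at least one heart-failure hospitalization admission date
  falls in the window (with or without a clinic visit);
* else ``O`` if at least one clinic visit falls in the window;
* else ``N`` if any event of any kind (including death) occurs in a later
  window — a service-free gap followed by a subsequent event;
* else ``L``: no event from this cycle through the study end without dying —
  the patient left the service. ``L`` is backdated to the first fully
  event-free cycle and is absorbing.

Cycles whose window extends past the study end date are administratively
censored: they are excluded from ``n_complete_cycles`` and contribute no
transitions, except that a known absorbing state (a dated death, or
disengagement established within the window) is carried forward.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd

from ._utils import add_months
from .cohort import PatientTimeline
from .states import StateSequence

__all__ = ["assign_states", "assign_cohort_states", "sequences_to_frame", "frame_to_sequences"]


def assign_states(
    timeline: PatientTimeline,
    cycle_length_months: int = 4,
    horizon: int | None = None,
) -> StateSequence:
    """Convert one patient timeline into a cycle-indexed state sequence.

    Parameters
    ----------
    timeline
        Validated patient record (events sorted, death last, dates in window).
    cycle_length_months
        Cycle length; 4 calendar months by default.
    horizon
        Number of cycles to emit. Defaults to the number of complete cycles
        inside the administrative window. A longer horizon extends only
        absorbing states; transient patients are censored at the last
        complete cycle.

    Returns
    -------
    StateSequence
        States for cycles ``1..K`` with ``n_complete_cycles`` recording how
        many cycle windows closed on or before the study end date.
    """
    base = timeline.baseline_date
    end = timeline.study_end_date
    death = timeline.death_date
    if death is not None and death < base:
        raise ValueError(f"patient {timeline.patient_id}: death before baseline")

    # number of complete cycles: largest k with window end <= study end
    n_complete = 0
    while add_months(base, cycle_length_months * (n_complete + 1)) <= end:
        n_complete += 1
    if horizon is None:
        horizon = n_complete

    hosp_dates = timeline.events_of_kind("hf_hospitalization")
    visit_dates = timeline.events_of_kind("clinic_visit")
    all_dates = [d for d, _ in timeline.events]

    states: list[str] = []
    absorbed: str | None = None
    for k in range(1, horizon + 1):
        if absorbed is not None:
            states.append(absorbed)
            continue
        w_start = add_months(base, cycle_length_months * (k - 1))
        w_end = add_months(base, cycle_length_months * k)
        if death is not None and death < w_end:
            absorbed = "D"
            states.append("D")
            continue
        if k > n_complete:
            break  # administratively censored: no state assignable
        if any(w_start <= d < w_end for d in hosp_dates):
            states.append("H")
        elif any(w_start <= d < w_end for d in visit_dates):
            states.append("O")
        elif any(d >= w_end for d in all_dates):
            states.append("N")
        else:
            absorbed = "L"
            states.append("L")
    return StateSequence(
        patient_id=timeline.patient_id,
        states=tuple(states),
        n_complete_cycles=n_complete,
    )


def assign_cohort_states(
    cohort: Iterable[PatientTimeline],
    cycle_length_months: int = 4,
    horizon: int | None = None,
) -> list[StateSequence]:
    """Vector version of :func:`assign_states` over a cohort."""
    return [assign_states(p, cycle_length_months, horizon) for p in cohort]


def sequences_to_frame(sequences: Iterable[StateSequence]) -> pd.DataFrame:
    """Long-format table: patient_id, cycle_index (1-based), state, censored.

    ``censored`` flags cycles past the administrative window whose state is
    known only because it is absorbing and carried forward.
    """
    rows = []
    for seq in sequences:
        for k, s in enumerate(seq.states, start=1):
            rows.append(
                {
                    "patient_id": seq.patient_id,
                    "cycle_index": k,
                    "state": s,
                    "censored": k > seq.n_complete_cycles,
                }
            )
    return pd.DataFrame(rows, columns=["patient_id", "cycle_index", "state", "censored"])


def frame_to_sequences(frame: pd.DataFrame) -> list[StateSequence]:
    """Inverse of :func:`sequences_to_frame`."""
    out: list[StateSequence] = []
    for pid, grp in frame.groupby("patient_id", sort=False):
        grp = grp.sort_values("cycle_index")
        if list(grp["cycle_index"]) != list(range(1, len(grp) + 1)):
            raise ValueError(f"patient {pid}: cycle indices not contiguous from 1")
        n_complete = int((~grp["censored"].astype(bool)).sum())
        out.append(
            StateSequence(
                patient_id=str(pid),
                states=tuple(grp["state"]),
                n_complete_cycles=n_complete,
            )
        )
    return out


def write_states(sequences: Iterable[StateSequence], path: str | os.PathLike) -> None:
    sequences_to_frame(sequences).to_csv(path, index=False)


def read_states(path: str | os.PathLike) -> list[StateSequence]:
    return frame_to_sequences(pd.read_csv(path, dtype={"patient_id": str}))
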