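"""Five-state health-state taxonomy for cycle-based heart-failure follow-up.

The disease course is discretised into consecutive 4-month cycles after a
baseline clinic assessment. Within each cycle a patient occupies exactly one
of five mutually exclusive states:

``D`` (Dead)
    Death from any cause. Absorbing.
``L`` (Left)
    The patient had no further interaction with the heart-failure service for
    the remainder of the study, without dying — service disengagement, not
    administrative censoring. Absorbing.
``H`` (Hosp)
    At least one heart-failure hospitalization during the cycle, with or
    without a clinic visit.
``O`` (OPD)
    At least one out-patient clinic visit during the cycle, without admission
    or death.
``N`` (NoEvent)
    A service-free cycle that is followed by at least one later event; this
    distinguishes temporary non-attendance from ``L``.

The canonical state order is fixed as (D, L, H, O, N): absorbing states
precede transient ones, so the 5x5 transition matrix partitions into the
blocks [[I, 0], [R, Q]].
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

#: Canonical state order: absorbing (D, L) before transient (H, O, N).
STATE_LABELS: tuple[str, ...] = ("D", "L", "H", "O", "N")
STATE_NAMES: dict[str, str] = {
    "D": "Dead",
    "L": "Left",
    "H": "Hosp",
    "O": "OPD",
    "N": "NoEvent",
}
ABSORBING_STATES: tuple[str, ...] = ("D", "L")
TRANSIENT_STATES: tuple[str, ...] = ("H", "O", "N")
N_STATES: int = 5
N_ABSORBING: int = 2
N_TRANSIENT: int = 3

STATE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STATE_LABELS)}


def state_index(label: str) -> int:
    """Return the canonical index of a state label (D=0, L=1, H=2, O=3, N=4)."""
    try:
        return STATE_INDEX[label]
    except KeyError:
        raise ValueError(f"unknown state label {label!r}; expected one of {STATE_LABELS}") from None


def is_absorbing(label: str) -> bool:
    return label in ABSORBING_STATES


@dataclass(frozen=True)
class StateSequence:
    """Cycle-indexed state path for one patient.

    ``states[k-1]`` is the state occupied in cycle ``k`` (cycles are 1-based;
    cycle 1 covers the first 4 months after baseline). Once ``D`` or ``L``
    appears every later entry equals it. ``n_complete_cycles`` counts cycles
    whose 4-month window closed on or before the study end date; trailing
    entries beyond it can only be absorbing states carried forward (a known
    death or disengagement persists past the administrative window).
    """

    patient_id: str
    states: tuple[str, ...]
    n_complete_cycles: int

    def __post_init__(self) -> None:
        absorbed_as: str | None = None
        for k, s in enumerate(self.states, start=1):
            if s not in STATE_INDEX:
                raise ValueError(f"patient {self.patient_id}: invalid state {s!r} at cycle {k}")
            if absorbed_as is not None and s != absorbed_as:
                raise ValueError(
                    f"patient {self.patient_id}: state {s!r} at cycle {k} after "
                    f"absorption into {absorbed_as!r}"
                )
            if absorbed_as is None and is_absorbing(s):
                absorbed_as = s
        if self.n_complete_cycles < 0:
            raise ValueError("n_complete_cycles must be nonnegative")

    def state_at(self, cycle: int) -> str | None:
        """State at 1-based ``cycle``, extending absorbing states indefinitely.

        Returns None when the cycle is administratively censored (beyond the
        recorded path and the patient was not absorbed).
        """
        if cycle < 1:
            raise ValueError("cycle is 1-based")
        if cycle <= len(self.states):
            return self.states[cycle - 1]
        if self.states and is_absorbing(self.states[-1]):
            return self.states[-1]
        return None

    @property
    def absorbed_state(self) -> str | None:
        for s in self.states:
            if is_absorbing(s):
                return s
        return None


class DiagnosticCategory(str, enum.Enum):
    """Baseline diagnostic cohorts from LVEF and NT-proBNP.

    HeFREF is heart failure with reduced ejection fraction (LVEF <= 40%).
    HeFPEF (preserved ejection fraction) is split at the guideline NT-proBNP
    thresholds of 400 and 125 ng/L. Patients with LVEF > 40% and NT-proBNP
    below 125 ng/L did not fulfil criteria for cardiac dysfunction
    ("controls"); those with no NT-proBNP measurement remain diagnostically
    uncertain.
    """

    HEFREF = "HeFREF"
    HEFPEF_GE400 = "HeFPEF_ge400"
    HEFPEF_125_399 = "HeFPEF_125_399"
    CONTROL = "Control"
    NO_NTPROBNP = "NoNTproBNP"


class MissingLVEFError(ValueError):
    """Raised when LVEF is unavailable: the patient is excluded, not classified."""


def classify_diagnosis(
    lvef_percent: float | None,
    ntprobnp_ng_per_l: float | None,
) -> DiagnosticCategory:
    """Classify a patient into a diagnostic category at baseline.

    Parameters
    ----------
    lvef_percent
        Left-ventricular ejection fraction in percent. Required: patients
        without a baseline LVEF are excluded upstream.
    ntprobnp_ng_per_l
        NT-proBNP in ng/L, or None if the assay result is unavailable.

    Returns
    -------
    DiagnosticCategory

    Raises
    ------
    MissingLVEFError
        If ``lvef_percent`` is None — an exclusion signal, not a category.
    """
    if lvef_percent is None:
        raise MissingLVEFError("LVEF unavailable at baseline: patient excluded from classification")
    if lvef_percent <= 40.0:
        return DiagnosticCategory.HEFREF
    if ntprobnp_ng_per_l is None:
        return DiagnosticCategory.NO_NTPROBNP
    if ntprobnp_ng_per_l >= 400.0:
        return DiagnosticCategory.HEFPEF_GE400
    if ntprobnp_ng_per_l >= 125.0:
        return DiagnosticCategory.HEFPEF_125_399
    return DiagnosticCategory.CONTROL
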