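"""Published reference values for a UK heart-failure registry cohort (n=7496).

These are the transition-probability blocks, first-transition tallies and
observed per-cycle distributions reported for a single-centre registry of
7496 consecutive patients assessed for suspected heart failure and followed
at 4-month intervals. They let the whole pipeline run and be checked without
access to the registry itself, and serve as the default ground truth for the
synthetic generator.

Two entries of the published transient-to-absorbing block R are treated as
unspecified rather than taken at face value:

* the OPD-to-Left entry was printed as 0.18, which makes that row sum to
  1.09 and contradicts the published limiting matrix; the unit-row-sum
  complement is 0.09, which reproduces both the limiting matrix and the
  published prediction table;
* the NoEvent-to-Left entry was not printed at all; its complement is 0.00.

Both completions are performed by :func:`hfmarkov.estimation.repair_matrix`
and disclosed in its repair report. The published limiting matrix prints the
NoEvent-origin death probability as 0.51 where F·R gives 0.52 — kept here as
printed, with the discrepancy attributed to rounding of the inputs.
"""

from __future__ import annotations

import numpy as np

from .estimation import CanonicalAMC, RepairReport, TransitionCounts, repair_matrix

__all__ = [
    "REFERENCE_Q",
    "REFERENCE_R_PRINTED",
    "REFERENCE_R_INPUT",
    "REFERENCE_F",
    "REFERENCE_TOTAL_CYCLES",
    "REFERENCE_B_DEATH_PRINTED",
    "FIRST_TRANSITION_COUNTS",
    "FIRST_TRANSITION_PROBS",
    "OBSERVED_TABLE",
    "reference_model",
    "first_transition_counts",
]

#: Transient->transient block Q over (H, O, N), second transition, as printed.
REFERENCE_Q = np.array(
    [
        [0.24, 0.14, 0.38],
        [0.12, 0.22, 0.55],
        [0.19, 0.13, 0.63],
    ]
)

#: Transient->absorbing block R over (H, O, N) x (D, L) as printed. The
#: OPD->L entry 0.18 is inconsistent (see module docstring); the N->L entry
#: was not printed and is recorded here as NaN.
REFERENCE_R_PRINTED = np.array(
    [
        [0.07, 0.17],
        [0.02, 0.18],
        [0.05, np.nan],
    ]
)

#: R as fed to repair_matrix: the two suspect entries left unspecified so the
#: unit-row-sum completion (0.09 and 0.00) is derived, not asserted.
REFERENCE_R_INPUT = np.array(
    [
        [0.07, 0.17],
        [0.02, np.nan],
        [0.05, np.nan],
    ]
)

#: Published fundamental matrix F over (H, O, N), at 2 decimal places.
REFERENCE_F = np.array(
    [
        [2.65, 1.24, 4.56],
        [1.82, 2.55, 5.66],
        [2.00, 1.53, 7.02],
    ]
)

#: Published row sums of F (expected cycles to absorption).
REFERENCE_TOTAL_CYCLES = np.array([8.45, 10.03, 10.55])

#: Published death-absorption probabilities by transient origin (H, O, N).
#: The N entry recomputes as 0.52 from F·R; 0.51 is kept as printed.
REFERENCE_B_DEATH_PRINTED = np.array([0.43, 0.46, 0.51])

#: First-transition tallies over (D, L, H, O, N): of 7496 patients, 427 had
#: died, 1842 had left the service, 1559 had been admitted, 2254 had attended
#: clinic and 1414 had no contact.
FIRST_TRANSITION_COUNTS = np.array([427, 1842, 1559, 2254, 1414])
FIRST_TRANSITION_PROBS = np.array([0.06, 0.25, 0.21, 0.30, 0.19])

#: Observed per-cycle distributions over (D, L, H, O, N), cycles 1..6, as
#: published. The cycle-6 row printed only four values; which state is
#: missing was not stated, so that row carries a NaN and is never used as a
#: numeric target.
OBSERVED_TABLE = {
    1: (0.06, 0.25, 0.21, 0.30, 0.19),
    2: (0.09, 0.31, 0.12, 0.12, 0.36),
    3: (0.11, 0.34, 0.11, 0.26, 0.18),
    4: (0.14, 0.41, 0.10, 0.15, 0.21),
    5: (0.16, 0.47, 0.10, 0.07, 0.20),
    6: (0.18, 0.54, 0.08, 0.19, np.nan),
}

#: Observed cycle-2 distribution: the seed for every forward prediction.
OBSERVED_CYCLE2 = np.array(OBSERVED_TABLE[2])


def reference_model() -> tuple[CanonicalAMC, RepairReport]:
    """Assemble the published chain, completing R by unit row sums.

    Returns the validated canonical chain together with the repair report
    disclosing the two derived entries (OPD->Left = 0.09, NoEvent->Left = 0.00).
    """
    P = np.zeros((5, 5))
    P[0, 0] = 1.0
    P[1, 1] = 1.0
    P[2:, :2] = REFERENCE_R_INPUT
    P[2:, 2:] = REFERENCE_Q
    return repair_matrix(P)


def first_transition_counts() -> TransitionCounts:
    """The published first-transition tally as a TransitionCounts object.

    All origin mass sits in the OPD row: every patient starts the process at
    the baseline clinic assessment.
    """
    counts = np.zeros((5, 5), dtype=np.int64)
    counts[3, :] = FIRST_TRANSITION_COUNTS
    return TransitionCounts(transition_index=1, counts=counts)
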