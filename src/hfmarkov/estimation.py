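"""Transition counting and estimation of the canonical absorbing-chain matrix.

States are ordered (D, L, H, O, N) so the one-step matrix P partitions as::

        | I  0 |      I: 2x2 identity   (absorbing rows)
    P = |      |      R: 3x2 transient -> absorbing
        | R  Q |      Q: 3x3 transient -> transient

Transition index ``t`` is 1-based: t=1 is baseline -> end of cycle 1, t=2 is
cycle 1 -> cycle 2, and so on. Every patient starts the process in the OPD
state at baseline (the baseline assessment is a clinic contact), so for t=1
all origin mass sits in the O row.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .states import (
    ABSORBING_STATES,
    N_ABSORBING,
    N_STATES,
    N_TRANSIENT,
    STATE_LABELS,
    STATE_INDEX,
    StateSequence,
    is_absorbing,
)

__all__ = [
    "TransitionCounts",
    "CanonicalAMC",
    "count_transitions",
    "estimate_matrix",
    "assemble_model",
    "repair_matrix",
    "RepairReport",
]

ZeroRowPolicy = Literal["error", "self_loop"]


class EmptyCountsError(ValueError):
    """No patient contributed a transition at the requested index."""


class ZeroRowError(ValueError):
    """A transient origin state had no observed transitions."""


@dataclass(frozen=True)
class TransitionCounts:
    """5x5 nonnegative integer transition tally for one transition index.

    Rows are origin states, columns destination states, both in canonical
    (D, L, H, O, N) order. Any mass in an absorbing row sits on the diagonal.
    """

    transition_index: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (N_STATES, N_STATES):
            raise ValueError(f"counts must be {N_STATES}x{N_STATES}, got {c.shape}")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("counts must be nonnegative integers")
        for i, s in enumerate(ABSORBING_STATES):
            row = c[i]
            if row.sum() != row[i]:
                raise ValueError(f"absorbing row {s} has off-diagonal mass: {row}")
        if self.transition_index < 1:
            raise ValueError("transition_index is 1-based")
        object.__setattr__(self, "counts", c)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(STATE_LABELS), columns=list(STATE_LABELS))

    def __add__(self, other: "TransitionCounts") -> "TransitionCounts":
        return TransitionCounts(
            transition_index=min(self.transition_index, other.transition_index),
            counts=self.counts + other.counts,
        )


@dataclass(frozen=True)
class RepairReport:
    """What :func:`repair_matrix` changed, entry by entry."""

    completed: tuple[tuple[str, str, float], ...] = ()  # (row, col, value filled in)
    renormalized: tuple[tuple[str, float], ...] = ()  # (row, original row sum)

    @property
    def was_repaired(self) -> bool:
        return bool(self.completed or self.renormalized)

    def to_dict(self) -> dict:
        return {
            "completed_entries": [
                {"from": r, "to": c, "value": v} for r, c, v in self.completed
            ],
            "renormalized_rows": [{"row": r, "original_sum": s} for r, s in self.renormalized],
        }


class CanonicalAMC:
    """Row-stochastic 5x5 transition matrix in canonical absorbing form.

    Validates on construction: entries in [0, 1], rows summing to 1 within
    1e-9, absorbing rows exactly unit vectors. Certain absorption (spectral
    radius of Q below 1) is checked by default but can be waived for
    degenerate chains used as algebraic edge cases.
    """

    def __init__(self, P, *, require_absorption: bool = True):
        P = np.asarray(P, dtype=float)
        if P.shape != (N_STATES, N_STATES):
            raise ValueError(f"P must be {N_STATES}x{N_STATES}, got {P.shape}")
        if np.any(P < -1e-12) or np.any(P > 1 + 1e-12):
            raise ValueError("transition probabilities must lie in [0, 1]")
        sums = P.sum(axis=1)
        bad = np.where(np.abs(sums - 1.0) > 1e-9)[0]
        if bad.size:
            rows = ", ".join(f"{STATE_LABELS[i]} (sum {sums[i]:.6g})" for i in bad)
            raise ValueError(f"rows must sum to 1: {rows}")
        for i in range(N_ABSORBING):
            unit = np.zeros(N_STATES)
            unit[i] = 1.0
            if not np.array_equal(P[i], unit):
                raise ValueError(f"absorbing row {STATE_LABELS[i]} must be a unit vector")
        self._P = np.clip(P, 0.0, 1.0)
        if require_absorption and self.spectral_radius_Q >= 1 - 1e-12:
            raise ValueError(
                "Q has spectral radius >= 1: absorption is not certain "
                "(pass require_absorption=False for degenerate chains)"
            )

    @property
    def P(self) -> np.ndarray:
        return self._P.copy()

    @property
    def Q(self) -> np.ndarray:
        """Transient -> transient block, 3x3 over (H, O, N)."""
        return self._P[N_ABSORBING:, N_ABSORBING:].copy()

    @property
    def R(self) -> np.ndarray:
        """Transient -> absorbing block, 3x2 over (H, O, N) x (D, L)."""
        return self._P[N_ABSORBING:, :N_ABSORBING].copy()

    @property
    def spectral_radius_Q(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self._P[N_ABSORBING:, N_ABSORBING:]))))

    @classmethod
    def from_blocks(cls, R, Q, *, require_absorption: bool = True) -> "CanonicalAMC":
        R = np.asarray(R, dtype=float)
        Q = np.asarray(Q, dtype=float)
        P = np.zeros((N_STATES, N_STATES))
        P[:N_ABSORBING, :N_ABSORBING] = np.eye(N_ABSORBING)
        P[N_ABSORBING:, :N_ABSORBING] = R
        P[N_ABSORBING:, N_ABSORBING:] = Q
        return cls(P, require_absorption=require_absorption)

    def __eq__(self, other) -> bool:
        return isinstance(other, CanonicalAMC) and np.array_equal(self._P, other._P)

    def __repr__(self) -> str:
        with np.printoptions(precision=4, suppress=True):
            return f"CanonicalAMC(\n{self._P}\n)"

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self._P, index=list(STATE_LABELS), columns=list(STATE_LABELS))

    def to_csv(self, path: str | os.PathLike) -> None:
        self.to_dataframe().to_csv(path, index_label="from")

    @classmethod
    def read_csv(cls, path: str | os.PathLike, *, require_absorption: bool = True) -> "CanonicalAMC":
        frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
        if list(frame.index) != list(STATE_LABELS) or list(frame.columns) != list(STATE_LABELS):
            raise ValueError("matrix CSV must be labelled by states (D, L, H, O, N)")
        return cls(frame.to_numpy(), require_absorption=require_absorption)

    def to_json(self, path: str | os.PathLike, *, metadata: dict | None = None) -> None:
        payload = {
            "states": list(STATE_LABELS),
            "R": self.R.tolist(),
            "Q": self.Q.tolist(),
            "metadata": metadata or {},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def read_json(cls, path: str | os.PathLike, *, require_absorption: bool = True) -> "CanonicalAMC":
        with open(path) as fh:
            payload = json.load(fh)
        return cls.from_blocks(payload["R"], payload["Q"], require_absorption=require_absorption)


def count_transitions(
    sequences: Iterable[StateSequence],
    t: int,
) -> TransitionCounts:
    """Tally origin -> destination state pairs at transition index ``t``.

    For t=1 the origin is the baseline pseudo-state O for every patient with
    a recorded cycle-1 state; for t >= 2 it is the state at cycle t-1.
    Patients whose cycle ``t`` is administratively censored contribute
    nothing.
    """
    if t < 1:
        raise ValueError("transition index t is 1-based")
    counts = np.zeros((N_STATES, N_STATES), dtype=np.int64)
    o = STATE_INDEX["O"]
    contributed = 0
    for seq in sequences:
        dest = seq.state_at(t)  # None when cycle t is censored
        if dest is None:
            continue
        if t == 1:
            origin = o
        else:
            prev = seq.state_at(t - 1)
            if prev is None:
                continue
            origin = STATE_INDEX[prev]
        counts[origin, STATE_INDEX[dest]] += 1
        contributed += 1
    if contributed == 0:
        raise EmptyCountsError(f"no patient contributes a transition at t={t}")
    return TransitionCounts(transition_index=t, counts=counts)


def estimate_matrix(
    counts: TransitionCounts,
    zero_row_policy: ZeroRowPolicy = "error",
) -> CanonicalAMC:
    """Row-normalize transition counts into a canonical matrix.

    Absorbing rows are forced to exact unit vectors regardless of counts.
    A transient row with no observations raises by default; the
    ``self_loop`` policy instead puts all its mass on the diagonal (with a
    warning), which makes the state spuriously absorbing-like — use only for
    exploratory subgroup fits.
    """
    c = counts.counts.astype(float)
    P = np.zeros_like(c)
    P[:N_ABSORBING, :N_ABSORBING] = np.eye(N_ABSORBING)
    used_fallback = False
    for i in range(N_ABSORBING, N_STATES):
        row_sum = c[i].sum()
        if row_sum == 0:
            if zero_row_policy == "error":
                raise ZeroRowError(
                    f"transient state {STATE_LABELS[i]} has no observed transitions "
                    f"at t={counts.transition_index}"
                )
            import warnings

            warnings.warn(
                f"transient state {STATE_LABELS[i]} unobserved at "
                f"t={counts.transition_index}; falling back to a self-loop",
                stacklevel=2,
            )
            P[i, i] = 1.0
            used_fallback = True
        else:
            P[i] = c[i] / row_sum
    # a self-loop fallback makes that state spuriously absorbing; waive the
    # certain-absorption check in that case only
    return CanonicalAMC(P, require_absorption=not used_fallback)


def assemble_model(
    counts_t1: TransitionCounts,
    counts_t2: TransitionCounts,
    pooling: Literal["transition2_only", "pooled_counts"] = "transition2_only",
    zero_row_policy: ZeroRowPolicy = "error",
) -> CanonicalAMC:
    """Build the one-step chain from the first two transition tallies.

    ``transition2_only`` (default) estimates the matrix from the second
    transition alone — the first transition starts from a degenerate all-OPD
    origin and serves only to set the initial distribution. ``pooled_counts``
    sums both tallies before normalizing, which weights each origin row by
    its total observation count across the two transitions.
    """
    if pooling == "transition2_only":
        return estimate_matrix(counts_t2, zero_row_policy)
    if pooling == "pooled_counts":
        return estimate_matrix(counts_t1 + counts_t2, zero_row_policy)
    raise ValueError(f"unknown pooling mode {pooling!r}")


def repair_matrix(
    P,
    tolerance: float = 0.005,
) -> tuple[CanonicalAMC, RepairReport]:
    """Validate a near-canonical matrix, completing unspecified entries.

    Accepts a 5x5 array that may contain NaN for unspecified entries — as
    when re-keying a matrix printed at 2 decimal places. Each row must either
    be fully specified with sum within ``tolerance`` of 1 (it is then
    renormalized), or contain exactly one NaN, which is replaced by its
    unit-sum complement clamped at 0. Returns the validated chain together
    with a report of every change made.
    """
    P = np.asarray(P, dtype=float).copy()
    if P.shape != (N_STATES, N_STATES):
        raise ValueError(f"P must be {N_STATES}x{N_STATES}, got {P.shape}")
    completed: list[tuple[str, str, float]] = []
    renormalized: list[tuple[str, float]] = []
    bad_rows: list[str] = []
    for i in range(N_STATES):
        row = P[i]
        nan_idx = np.where(np.isnan(row))[0]
        if nan_idx.size == 1:
            j = int(nan_idx[0])
            value = max(0.0, 1.0 - np.nansum(row))
            P[i, j] = value
            completed.append((STATE_LABELS[i], STATE_LABELS[j], value))
            row = P[i]
        elif nan_idx.size > 1:
            bad_rows.append(f"{STATE_LABELS[i]} ({nan_idx.size} unspecified entries)")
            continue
        s = row.sum()
        if abs(s - 1.0) > tolerance:
            bad_rows.append(f"{STATE_LABELS[i]} (sum {s:.4g})")
        elif abs(s - 1.0) > 1e-12:
            P[i] = row / s
            if abs(s - 1.0) > 1e-9:  # report only substantive renormalizations
                renormalized.append((STATE_LABELS[i], float(s)))
    if bad_rows:
        raise ValueError(
            "rows not repairable to unit sum within tolerance "
            f"{tolerance}: {', '.join(bad_rows)}"
        )
    return CanonicalAMC(P), RepairReport(tuple(completed), tuple(renormalized))
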