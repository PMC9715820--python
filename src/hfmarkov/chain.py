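"""Absorbing Markov chain mathematics.

For a canonical chain P = [[I, 0], [R, Q]] over (D, L | H, O, N):

* the fundamental matrix ``F = (I - Q)^{-1}`` gives, at entry (i, j), the
  expected number of cycles spent in transient state j before absorption
  when starting from transient state i; its row sums are the expected number
  of cycles to absorption;
* ``B = F R`` gives the probability of ending in each absorbing state
  (death, or leaving the service) by starting transient state;
* the limiting matrix embeds B in the full 5x5 layout with identity
  absorbing rows and zero transient columns.

All linear algebra goes through solves of (I - Q) rather than explicit
inversion; F is still exposed as a dense matrix, which is the object users
read.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import validate_distribution
from .estimation import CanonicalAMC
from .states import (
    ABSORBING_STATES,
    N_ABSORBING,
    N_STATES,
    N_TRANSIENT,
    STATE_LABELS,
    TRANSIENT_STATES,
)

__all__ = [
    "AbsorptionSummary",
    "DistributionTrajectory",
    "fundamental_matrix",
    "absorption_probabilities",
    "iterate_distribution",
    "survival_curve",
    "monte_carlo_absorption",
]


class AbsorptionImpossibleError(ValueError):
    """(I - Q) is singular / Q is not strictly substochastic in spectrum."""


@dataclass(frozen=True)
class AbsorptionSummary:
    """Long-run summary of an absorbing chain.

    Attributes
    ----------
    F : (3, 3) ndarray
        Fundamental matrix over transient states (H, O, N).
    expected_cycles : (3,) ndarray
        Row sums of F: expected number of 4-month cycles before absorption
        by starting state.
    B : (3, 2) ndarray
        Absorption probabilities, transient origin x absorbing destination
        (D, L).
    limiting : (5, 5) ndarray
        Limiting matrix: identity on absorbing rows, B in the transient x
        absorbing block, zeros elsewhere.
    """

    F: np.ndarray
    expected_cycles: np.ndarray
    B: np.ndarray
    limiting: np.ndarray

    def fundamental_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.F, index=list(TRANSIENT_STATES), columns=list(TRANSIENT_STATES)
        )
        frame["total_cycles"] = self.expected_cycles
        return frame

    def absorption_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.B, index=list(TRANSIENT_STATES), columns=list(ABSORBING_STATES))

    def limiting_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.limiting, index=list(STATE_LABELS), columns=list(STATE_LABELS))


@dataclass(frozen=True)
class DistributionTrajectory:
    """Per-cycle distributions over the five states.

    ``distributions[k]`` is the 5-vector for ``cycles[k]``; each row is a
    probability distribution and absorbing mass (D, L) never decreases along
    the trajectory when produced by forward iteration.
    """

    cycles: tuple[int, ...]
    distributions: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distributions, dtype=float)
        if d.ndim != 2 or d.shape[1] != N_STATES:
            raise ValueError(f"distributions must be (n_cycles, {N_STATES})")
        if d.shape[0] != len(self.cycles):
            raise ValueError("cycles and distributions length mismatch")
        object.__setattr__(self, "distributions", d)

    def at(self, cycle: int) -> np.ndarray:
        try:
            idx = self.cycles.index(cycle)
        except ValueError:
            raise KeyError(f"cycle {cycle} not in trajectory {self.cycles}") from None
        return self.distributions[idx].copy()

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.distributions, index=pd.Index(self.cycles, name="cycle"), columns=list(STATE_LABELS)
        )


def fundamental_matrix(model: CanonicalAMC) -> AbsorptionSummary:
    """Compute F = (I - Q)^{-1}, expected cycles, B = F R and the limiting matrix.

    Raises
    ------
    AbsorptionImpossibleError
        If the spectral radius of Q reaches 1, so (I - Q) is (near) singular
        and absorption is not certain.
    """
    Q = model.Q
    R = model.R
    if np.max(np.abs(np.linalg.eigvals(Q))) >= 1 - 1e-12:
        raise AbsorptionImpossibleError(
            "spectral radius of Q is >= 1; the chain cannot be absorbed from every state"
        )
    eye = np.eye(N_TRANSIENT)
    try:
        F = np.linalg.solve(eye - Q, eye)
        B = np.linalg.solve(eye - Q, R)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by radius check
        raise AbsorptionImpossibleError(str(exc)) from exc
    expected = F.sum(axis=1)
    limiting = np.zeros((N_STATES, N_STATES))
    limiting[:N_ABSORBING, :N_ABSORBING] = np.eye(N_ABSORBING)
    limiting[N_ABSORBING:, :N_ABSORBING] = B
    return AbsorptionSummary(F=F, expected_cycles=expected, B=B, limiting=limiting)


def absorption_probabilities(model: CanonicalAMC) -> np.ndarray:
    """Absorption-probability matrix B = F R (3x2, rows H, O, N; columns D, L)."""
    return fundamental_matrix(model).B


def iterate_distribution(
    model: CanonicalAMC,
    initial,
    n_cycles: int,
    first_cycle: int = 0,
) -> DistributionTrajectory:
    """Iterate the cohort-level state distribution forward.

    Parameters
    ----------
    model
        One-step canonical chain.
    initial
        5-vector over (D, L, H, O, N) at ``first_cycle``; must sum to 1.
    n_cycles
        Number of one-step applications of P.
    first_cycle
        Cycle label of the initial distribution (so predictions seeded at the
        observed cycle-2 distribution carry cycle labels 2, 3, ...).

    Returns
    -------
    DistributionTrajectory
        Distributions at cycles ``first_cycle .. first_cycle + n_cycles``,
        the initial vector included.
    """
    v = validate_distribution(initial, "initial distribution")
    if n_cycles < 0:
        raise ValueError("n_cycles must be nonnegative")
    P = model.P
    out = np.empty((n_cycles + 1, N_STATES))
    out[0] = v
    for k in range(1, n_cycles + 1):
        out[k] = out[k - 1] @ P
    cycles = tuple(range(first_cycle, first_cycle + n_cycles + 1))
    return DistributionTrajectory(cycles=cycles, distributions=out)


def survival_curve(trajectory: DistributionTrajectory) -> pd.Series:
    """Per-cycle survival probability S(k) = 1 - Dead component. Non-increasing."""
    dead = trajectory.distributions[:, 0]
    return pd.Series(
        1.0 - dead, index=pd.Index(trajectory.cycles, name="cycle"), name="survival"
    )


def monte_carlo_absorption(
    model: CanonicalAMC,
    n_walks: int = 100_000,
    seed: int = 0,
    max_cycles: int = 10_000,
) -> np.ndarray:
    """Simulate absorption frequencies as an independent check on B = F R.

    Runs ``n_walks`` chain trajectories from each transient origin until
    absorption and returns the 3x2 matrix of empirical absorption
    frequencies. Standard error per entry is sqrt(b(1-b)/n_walks).
    """
    rng = np.random.default_rng(seed)
    P = model.P
    cum = np.cumsum(P, axis=1)
    freq = np.zeros((N_TRANSIENT, N_ABSORBING))
    for origin in range(N_TRANSIENT):
        state = np.full(n_walks, N_ABSORBING + origin, dtype=np.int64)
        active = state >= N_ABSORBING
        for _ in range(max_cycles):
            if not active.any():
                break
            u = rng.random(active.sum())
            state[active] = (u[:, None] < cum[state[active]]).argmax(axis=1)
            active = state >= N_ABSORBING
        if active.any():
            raise RuntimeError(
                f"{int(active.sum())} walks not absorbed after {max_cycles} cycles"
            )
        freq[origin] = np.bincount(state, minlength=N_ABSORBING)[:N_ABSORBING] / n_walks
    return freq
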