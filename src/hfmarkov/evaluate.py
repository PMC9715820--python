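"""Predicted-vs-observed validation tables, subgroup chains and survival curves.

The chain is assembled from the first two transitions only; its forward
predictions are seeded at the *observed* cycle-2 distribution and iterated
one step per cycle, so cycles 1 and 2 carry no prediction and the signed
error (predicted minus observed; negative = underestimation) measures how
far the frozen early-course dynamics drift from the cohort's later course.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .chain import (
    AbsorptionSummary,
    DistributionTrajectory,
    fundamental_matrix,
    iterate_distribution,
    survival_curve,
)
from .cohort import PatientTimeline
from .estimation import CanonicalAMC, assemble_model, count_transitions
from .states import N_STATES, STATE_INDEX, STATE_LABELS, StateSequence

__all__ = [
    "PredictionTable",
    "SubgroupSpec",
    "SubgroupResult",
    "observed_distributions",
    "build_prediction_table",
    "fit_subgroup_models",
    "survival_report",
]


@dataclass(frozen=True)
class PredictionTable:
    """Per-cycle predicted and observed distributions with signed errors.

    Rows run over cycles 3..K (the model is built from the first two
    transitions, so it makes no prediction for cycles 1-2). ``error`` is
    predicted - observed, entrywise; observed entries may be NaN when a
    published row is incomplete, in which case the error is NaN too.
    """

    cycles: tuple[int, ...]
    predicted: np.ndarray
    observed: np.ndarray
    error: np.ndarray

    def __post_init__(self) -> None:
        for name in ("predicted", "observed", "error"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.shape != (len(self.cycles), N_STATES):
                raise ValueError(f"{name} must be ({len(self.cycles)}, {N_STATES})")
            object.__setattr__(self, name, a)
        with np.errstate(invalid="ignore"):
            if not np.allclose(
                self.error, self.predicted - self.observed, equal_nan=True, atol=1e-12
            ):
                raise ValueError("error must equal predicted - observed exactly")

    def max_abs_error(self) -> float:
        return float(np.nanmax(np.abs(self.error)))

    def to_dataframe(self, round_to: int | None = None) -> pd.DataFrame:
        cols = pd.MultiIndex.from_product(
            [["predicted", "observed", "error"], list(STATE_LABELS)]
        )
        data = np.hstack([self.predicted, self.observed, self.error])
        frame = pd.DataFrame(data, index=pd.Index(self.cycles, name="cycle"), columns=cols)
        if round_to is not None:
            from ._utils import round_half_away

            frame = frame.apply(lambda c: round_half_away(c.to_numpy(), round_to))
        return frame


@dataclass(frozen=True)
class SubgroupSpec:
    """Cohort stratifier: by sex, or by age band at a threshold (default 65)."""

    stratifier: Literal["sex", "age_band", "none"]
    age_threshold: float = 65.0

    def stratum_of(self, patient: PatientTimeline) -> str:
        if self.stratifier == "none":
            return "all"
        if self.stratifier == "sex":
            if patient.sex is None:
                raise ValueError(f"patient {patient.patient_id} has no recorded sex")
            return patient.sex
        if patient.age_years is None:
            raise ValueError(f"patient {patient.patient_id} has no recorded age")
        return (
            f"age_ge_{self.age_threshold:g}"
            if patient.age_years >= self.age_threshold
            else f"age_lt_{self.age_threshold:g}"
        )


@dataclass(frozen=True)
class SubgroupResult:
    stratum: str
    n_patients: int
    model: CanonicalAMC
    summary: AbsorptionSummary


def observed_distributions(
    sequences: Iterable[StateSequence],
    K: int,
) -> DistributionTrajectory:
    """Empirical per-cycle state fractions over the baseline cohort.

    The denominator is the full cohort size at every cycle; patients in an
    absorbing state stay counted there. Cycles where some transient patients
    are administratively censored keep the full denominator (the censored
    patients simply contribute nothing), with a warning; ``K`` is truncated
    to the last cycle with any assignable state.
    """
    seqs = list(sequences)
    if not seqs:
        raise ValueError("no sequences supplied")
    n = len(seqs)
    max_assignable = max(
        (len(s.states) if s.absorbed_state is None else K) for s in seqs
    )
    if K > max_assignable:
        warnings.warn(
            f"K={K} exceeds the {max_assignable} assignable cycles; truncating",
            stacklevel=2,
        )
        K = max_assignable
    dist = np.zeros((K, N_STATES))
    censored_cycles = set()
    for s in seqs:
        for k in range(1, K + 1):
            st = s.state_at(k)
            if st is None:
                censored_cycles.add(k)
                continue
            dist[k - 1, STATE_INDEX[st]] += 1
    dist /= n
    if censored_cycles:
        warnings.warn(
            f"cycles {sorted(censored_cycles)} include administratively censored "
            "patients; fractions there use the full-cohort denominator",
            stacklevel=2,
        )
    return DistributionTrajectory(cycles=tuple(range(1, K + 1)), distributions=dist)


def build_prediction_table(
    model: CanonicalAMC,
    observed: DistributionTrajectory,
    K: int = 6,
) -> PredictionTable:
    """Iterate the chain from the observed cycle-2 distribution and compare.

    Predictions cover cycles 3..K; rounding to table precision happens only
    at presentation (``to_dataframe(round_to=2)``), never inside the
    comparison.
    """
    if 2 not in observed.cycles:
        raise ValueError("observed trajectory must include cycle 2 to seed predictions")
    if K < 3:
        raise ValueError("K must be >= 3: the first predicted cycle is 3")
    start = observed.at(2)
    predicted_traj = iterate_distribution(model, start, n_cycles=K - 2, first_cycle=2)
    cycles = tuple(range(3, K + 1))
    predicted = predicted_traj.distributions[1:]
    obs = np.full((len(cycles), N_STATES), np.nan)
    for i, c in enumerate(cycles):
        if c in observed.cycles:
            obs[i] = observed.at(c)
    with np.errstate(invalid="ignore"):
        error = predicted - obs
    return PredictionTable(cycles=cycles, predicted=predicted, observed=obs, error=error)


def fit_subgroup_models(
    cohort: Iterable[PatientTimeline],
    sequences: Iterable[StateSequence],
    spec: SubgroupSpec,
    pooling: Literal["transition2_only", "pooled_counts"] = "transition2_only",
) -> dict[str, SubgroupResult]:
    """Fit an independent chain (and absorption summary) per stratum.

    Strata partition the cohort; an empty stratum, or one missing a transient
    origin at the second transition, is skipped with a warning rather than
    aborting the whole report.
    """
    cohort = list(cohort)
    seq_by_id = {s.patient_id: s for s in sequences}
    strata: dict[str, list[StateSequence]] = {}
    for p in cohort:
        if p.patient_id not in seq_by_id:
            raise ValueError(f"no state sequence for patient {p.patient_id}")
        strata.setdefault(spec.stratum_of(p), []).append(seq_by_id[p.patient_id])
    results: dict[str, SubgroupResult] = {}
    for name in sorted(strata):
        seqs = strata[name]
        try:
            c1 = count_transitions(seqs, 1)
            c2 = count_transitions(seqs, 2)
            model = assemble_model(c1, c2, pooling=pooling)
            summary = fundamental_matrix(model)
        except ValueError as exc:
            warnings.warn(f"stratum {name!r} skipped: {exc}", stacklevel=2)
            continue
        results[name] = SubgroupResult(
            stratum=name, n_patients=len(seqs), model=model, summary=summary
        )
    return results


def survival_report(
    trajectories: Mapping[str, DistributionTrajectory],
    K: int = 9,
) -> pd.DataFrame:
    """Tabulate per-cycle survival S(k) = 1 - Dead for each stratum, k <= K.

    Accepts one forward trajectory per stratum (e.g. from
    :func:`~hfmarkov.chain.iterate_distribution` seeded at each stratum's
    observed early distribution). Columns are strata; survival is
    non-increasing down each column.
    """
    out: dict[str, pd.Series] = {}
    for name, traj in trajectories.items():
        s = survival_curve(traj)
        out[name] = s[s.index <= K]
    frame = pd.DataFrame(out)
    frame.index.name = "cycle"
    return frame
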