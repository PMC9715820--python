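"""scikit-learn style estimators wrapping the pipeline.

``TimelineStateEncoder`` is a stateless transformer turning patient
timelines into cycle-state sequences; ``AbsorbingChainRiskModel`` fits the
canonical absorbing chain from the first two observed transitions and
exposes the fundamental-matrix machinery as fitted attributes. Both follow
the scikit-learn estimator contract (``get_params``/``set_params``,
``fit``/``transform`` or ``fit``/``predict_*``, trailing-underscore fitted
attributes) so they compose with :class:`sklearn.pipeline.Pipeline` and
:func:`sklearn.base.clone`.
"""

from __future__ import annotations

from typing import Iterable, Literal

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import NotFittedError

from .chain import DistributionTrajectory, fundamental_matrix, iterate_distribution
from .cohort import PatientTimeline
from .engine import assign_states
from .estimation import assemble_model, count_transitions, estimate_matrix
from .evaluate import PredictionTable, build_prediction_table, observed_distributions
from .states import StateSequence

__all__ = ["TimelineStateEncoder", "AbsorbingChainRiskModel"]


class TimelineStateEncoder(TransformerMixin, BaseEstimator):
    """Encode patient timelines as cycle-indexed five-state sequences.

    Parameters
    ----------
    cycle_length_months : int, default=4
        Length of each cycle window in calendar months.
    horizon : int or None, default=None
        Number of cycles to emit per patient; None means every complete
        cycle inside each patient's administrative window.
    """

    def __init__(self, cycle_length_months: int = 4, horizon: int | None = None):
        self.cycle_length_months = cycle_length_months
        self.horizon = horizon

    def fit(self, X: Iterable[PatientTimeline], y=None):
        # stateless: nothing to learn, but validate parameters eagerly
        if self.cycle_length_months < 1:
            raise ValueError("cycle_length_months must be >= 1")
        if self.horizon is not None and self.horizon < 1:
            raise ValueError("horizon must be >= 1 when given")
        self.n_features_in_ = 1
        return self

    def transform(self, X: Iterable[PatientTimeline]) -> list[StateSequence]:
        self.fit(X)
        return [assign_states(p, self.cycle_length_months, self.horizon) for p in X]


class AbsorbingChainRiskModel(BaseEstimator):
    """Absorbing Markov chain fitted from the first two observed transitions.

    The model discretises follow-up into 4-month cycles over five states
    (Dead, Left, Hosp, OPD, NoEvent), tallies the baseline->cycle-1 and
    cycle-1->cycle-2 transitions, and estimates a one-step canonical matrix
    [[I, 0], [R, Q]]. Long-run behaviour (fundamental matrix, expected
    cycles to absorption, absorption probabilities) and forward cohort
    distributions follow from that single matrix.

    Parameters
    ----------
    pooling : {"transition2_only", "pooled_counts"}, default="transition2_only"
        How the two transition tallies combine: the default estimates the
        chain from the second transition alone (the first transition starts
        from the degenerate all-OPD origin and only sets the initial
        distribution); ``pooled_counts`` sums both tallies first.
    zero_row_policy : {"error", "self_loop"}, default="error"
        What to do when a transient origin state is unobserved at fit time.

    Attributes
    ----------
    chain_ : CanonicalAMC
        The fitted one-step canonical matrix.
    counts_t1_, counts_t2_ : TransitionCounts
        The two transition tallies.
    initial_distribution_ : ndarray of shape (5,)
        Empirical cycle-1 distribution (the first transition's destination
        frequencies).
    Q_, R_ : ndarray
        Transient blocks of the fitted matrix.
    fundamental_matrix_ : ndarray of shape (3, 3)
        F = (I - Q)^{-1}.
    expected_cycles_ : ndarray of shape (3,)
        Row sums of F: expected cycles to absorption by origin.
    absorption_probabilities_ : ndarray of shape (3, 2)
        B = F R over origins (H, O, N) x destinations (D, L).
    limiting_matrix_ : ndarray of shape (5, 5)
        Long-run matrix embedding B.
    n_patients_ : int
        Number of sequences seen at fit.
    """

    def __init__(
        self,
        pooling: Literal["transition2_only", "pooled_counts"] = "transition2_only",
        zero_row_policy: Literal["error", "self_loop"] = "error",
    ):
        self.pooling = pooling
        self.zero_row_policy = zero_row_policy

    def fit(self, X: Iterable[StateSequence], y=None):
        """Fit the chain from a collection of state sequences.

        ``y`` is ignored; present for scikit-learn API compatibility.
        """
        seqs = list(X)
        if not seqs:
            raise ValueError("cannot fit on an empty collection of sequences")
        self.counts_t1_ = count_transitions(seqs, 1)
        self.counts_t2_ = count_transitions(seqs, 2)
        self.chain_ = assemble_model(
            self.counts_t1_, self.counts_t2_, self.pooling, self.zero_row_policy
        )
        t1 = self.counts_t1_.counts.sum(axis=0).astype(float)
        self.initial_distribution_ = t1 / t1.sum()
        summary = fundamental_matrix(self.chain_)
        self.Q_ = self.chain_.Q
        self.R_ = self.chain_.R
        self.fundamental_matrix_ = summary.F
        self.expected_cycles_ = summary.expected_cycles
        self.absorption_probabilities_ = summary.B
        self.limiting_matrix_ = summary.limiting
        self.n_patients_ = len(seqs)
        self._sequences = seqs
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "chain_"):
            raise NotFittedError("this AbsorbingChainRiskModel instance is not fitted yet")

    def predict_distribution(
        self,
        initial=None,
        n_cycles: int = 4,
        first_cycle: int | None = None,
    ) -> DistributionTrajectory:
        """Iterate the fitted chain forward from ``initial``.

        Defaults to the empirical cycle-1 distribution as the start (labelled
        cycle 1), giving cohort-level forecasts for cycles 2, 3, ...
        """
        self._check_fitted()
        if initial is None:
            initial = self.initial_distribution_
            first_cycle = 1 if first_cycle is None else first_cycle
        return iterate_distribution(
            self.chain_, initial, n_cycles, first_cycle=first_cycle or 0
        )

    def prediction_table(
        self, X: Iterable[StateSequence] | None = None, K: int = 6
    ) -> PredictionTable:
        """Predicted-vs-observed table for cycles 3..K.

        Uses the sequences seen at fit time unless ``X`` is given; the
        prediction is seeded at the observed cycle-2 distribution.
        """
        self._check_fitted()
        seqs = list(X) if X is not None else self._sequences
        observed = observed_distributions(seqs, K)
        return build_prediction_table(self.chain_, observed, K)
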