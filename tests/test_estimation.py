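"""Transition counting, matrix estimation, pooling algebra and matrix repair."""

import numpy as np
import pytest

from hfmarkov.estimation import (
    CanonicalAMC,
    EmptyCountsError,
    TransitionCounts,
    ZeroRowError,
    assemble_model,
    count_transitions,
    estimate_matrix,
    repair_matrix,
)
from hfmarkov.states import STATE_INDEX, StateSequence


def seq(pid, *states):
    return StateSequence(pid, tuple(states), n_complete_cycles=len(states))


class TestCountTransitions:
    def test_first_transition_origin_is_the_baseline_opd_pseudostate(self):
        seqs = [seq("a", "H", "H"), seq("b", "D", "D"), seq("c", "N", "O")]
        c = count_transitions(seqs, 1)
        o = STATE_INDEX["O"]
        assert c.counts[o].tolist() == [1, 0, 1, 0, 1]
        assert c.counts.sum() == 3

    def test_second_transition_hand_count(self):
        seqs = [seq("a", "H", "H"), seq("b", "H", "D")]
        c = count_transitions(seqs, 2)
        h, d = STATE_INDEX["H"], STATE_INDEX["D"]
        assert c.counts[h, h] == 1
        assert c.counts[h, d] == 1
        assert c.counts.sum() == 2

    def test_absorbed_patients_count_on_the_absorbing_diagonal(self):
        seqs = [seq("a", "D", "D"), seq("b", "L", "L")]
        c = count_transitions(seqs, 2)
        assert c.counts[0, 0] == 1 and c.counts[1, 1] == 1
        assert c.counts.sum() == 2

    def test_censored_cycles_contribute_nothing(self):
        # patient observed only one complete cycle: no t=2 transition
        seqs = [seq("a", "H", "O"), StateSequence("b", ("H",), 1)]
        c = count_transitions(seqs, 2)
        assert c.counts.sum() == 1

    def test_no_contributions_is_an_error(self):
        with pytest.raises(EmptyCountsError):
            count_transitions([StateSequence("a", ("H",), 1)], 2)


class TestEstimateMatrix:
    def test_single_observed_transition_gives_unit_probability(self):
        counts = np.zeros((5, 5), dtype=np.int64)
        counts[STATE_INDEX["H"], STATE_INDEX["D"]] = 1
        counts[STATE_INDEX["O"], STATE_INDEX["D"]] = 3
        counts[STATE_INDEX["N"], STATE_INDEX["D"]] = 2
        m = estimate_matrix(TransitionCounts(2, counts))
        assert m.P[STATE_INDEX["H"], STATE_INDEX["D"]] == 1.0

    def test_random_counts_normalize_to_unit_rows(self):
        rng = np.random.default_rng(5)
        counts = np.zeros((5, 5), dtype=np.int64)
        counts[2:, :] = rng.integers(1, 500, size=(3, 5))
        counts[0, 0] = 7
        counts[1, 1] = 11
        m = estimate_matrix(TransitionCounts(2, counts))
        assert np.allclose(m.P.sum(axis=1), 1.0, atol=1e-12)

    def test_unobserved_transient_row_raises_by_default(self):
        counts = np.zeros((5, 5), dtype=np.int64)
        counts[STATE_INDEX["H"], 0] = 4
        counts[STATE_INDEX["O"], 0] = 4
        with pytest.raises(ZeroRowError, match="N"):
            estimate_matrix(TransitionCounts(2, counts))

    def test_self_loop_policy_warns_instead(self):
        counts = np.zeros((5, 5), dtype=np.int64)
        counts[STATE_INDEX["H"], 0] = 4
        counts[STATE_INDEX["O"], 0] = 4
        with pytest.warns(UserWarning, match="self-loop"):
            m = estimate_matrix(TransitionCounts(2, counts), zero_row_policy="self_loop")
        assert m.P[STATE_INDEX["N"], STATE_INDEX["N"]] == 1.0


class TestAssembleModel:
    def test_identical_counts_make_both_pooling_modes_agree(self):
        rng = np.random.default_rng(11)
        counts = np.zeros((5, 5), dtype=np.int64)
        counts[2:, :] = rng.integers(1, 100, size=(3, 5))
        c1 = TransitionCounts(1, counts)
        c2 = TransitionCounts(2, counts.copy())
        a = assemble_model(c1, c2, "transition2_only")
        b = assemble_model(c1, c2, "pooled_counts")
        assert np.allclose(a.P, b.P, atol=1e-12)

    def test_pooled_probabilities_are_row_count_weighted_averages(self):
        # brute-force check on small integer counts
        rng = np.random.default_rng(3)
        k1 = np.zeros((5, 5), dtype=np.int64)
        k2 = np.zeros((5, 5), dtype=np.int64)
        k1[2:, :] = rng.integers(1, 20, size=(3, 5))
        k2[2:, :] = rng.integers(1, 20, size=(3, 5))
        pooled = assemble_model(TransitionCounts(1, k1), TransitionCounts(2, k2), "pooled_counts")
        for i in range(2, 5):
            n1, n2 = k1[i].sum(), k2[i].sum()
            p1, p2 = k1[i] / n1, k2[i] / n2
            expected = (n1 * p1 + n2 * p2) / (n1 + n2)
            assert np.allclose(pooled.P[i], expected, atol=1e-12)


class TestRepairMatrix:
    def test_unspecified_entry_completed_by_unit_row_sum(self):
        P = np.array(
            [
                [1, 0, 0, 0, 0],
                [0, 1, 0, 0, 0],
                [0.07, 0.17, 0.24, 0.14, 0.38],
                [0.02, np.nan, 0.12, 0.22, 0.55],
                [0.05, np.nan, 0.19, 0.13, 0.63],
            ]
        )
        model, report = repair_matrix(P)
        o, l = STATE_INDEX["O"], STATE_INDEX["L"]
        assert model.P[o, l] == pytest.approx(0.09, abs=1e-12)
        assert model.P[STATE_INDEX["N"], l] == 0.0
        filled = {(r, c): v for r, c, v in report.completed}
        assert filled[("O", "L")] == pytest.approx(0.09, abs=1e-12)

    def test_perfectly_stochastic_matrix_returned_unchanged(self):
        P = np.array(
            [
                [1, 0, 0, 0, 0],
                [0, 1, 0, 0, 0],
                [0.1, 0.1, 0.2, 0.3, 0.3],
                [0.25, 0.25, 0.2, 0.2, 0.1],
                [0.3, 0.2, 0.1, 0.2, 0.2],
            ]
        )
        model, report = repair_matrix(P)
        assert np.array_equal(model.P, P)
        assert not report.was_repaired

    def test_overfull_fully_specified_row_is_a_validation_error(self):
        P = np.eye(5)
        P[2] = [0.3, 0.3, 0.3, 0.2, 0.1]  # sums to 1.20
        P[3] = [0.2, 0.2, 0.2, 0.2, 0.2]
        P[4] = [0.2, 0.2, 0.2, 0.2, 0.2]
        with pytest.raises(ValueError, match="H"):
            repair_matrix(P)

    def test_two_unspecified_entries_in_a_row_cannot_be_repaired(self):
        P = np.eye(5)
        P[2] = [np.nan, np.nan, 0.3, 0.2, 0.1]
        P[3] = [0.2, 0.2, 0.2, 0.2, 0.2]
        P[4] = [0.2, 0.2, 0.2, 0.2, 0.2]
        with pytest.raises(ValueError, match="unspecified"):
            repair_matrix(P)


class TestCanonicalAMC:
    def test_block_views_match_the_full_matrix(self, reference_chain):
        P = reference_chain.P
        assert np.array_equal(reference_chain.Q, P[2:, 2:])
        assert np.array_equal(reference_chain.R, P[2:, :2])

    def test_non_stochastic_matrix_rejected(self):
        P = np.eye(5)
        P[2, 2] = 0.5
        with pytest.raises(ValueError, match="sum to 1"):
            CanonicalAMC(P)

    def test_absorbing_rows_must_be_unit_vectors(self):
        P = np.full((5, 5), 0.2)
        with pytest.raises(ValueError, match="unit vector"):
            CanonicalAMC(P)

    def test_identity_chain_needs_the_absorption_waiver(self):
        with pytest.raises(ValueError, match="spectral radius"):
            CanonicalAMC(np.eye(5))
        m = CanonicalAMC(np.eye(5), require_absorption=False)
        assert m.spectral_radius_Q == pytest.approx(1.0)

    def test_csv_and_json_round_trips(self, reference_chain, tmp_path):
        reference_chain.to_csv(tmp_path / "m.csv")
        assert CanonicalAMC.read_csv(tmp_path / "m.csv") == reference_chain
        reference_chain.to_json(tmp_path / "m.json", metadata={"source": "test"})
        assert CanonicalAMC.read_json(tmp_path / "m.json") == reference_chain
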