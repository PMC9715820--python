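"""Predicted-vs-observed tables, subgroup chains and survival reports."""

import numpy as np
import pytest

from hfmarkov._utils import round_half_away
from hfmarkov.chain import DistributionTrajectory, iterate_distribution
from hfmarkov.engine import assign_cohort_states
from hfmarkov.estimation import CanonicalAMC, repair_matrix
from hfmarkov.evaluate import (
    PredictionTable,
    SubgroupSpec,
    build_prediction_table,
    fit_subgroup_models,
    observed_distributions,
    survival_report,
)
from hfmarkov.reference import OBSERVED_TABLE, reference_model
from hfmarkov.simulate import GeneratorConfig, generate_cohort
from hfmarkov.states import StateSequence


def seq(pid, *states):
    return StateSequence(pid, tuple(states), n_complete_cycles=len(states))


def reference_observed():
    cycles = sorted(OBSERVED_TABLE)
    return DistributionTrajectory(
        cycles=tuple(cycles), distributions=np.array([OBSERVED_TABLE[c] for c in cycles])
    )


class TestObservedDistributions:
    def test_absorbed_patient_keeps_its_mass_in_the_absorbing_state(self):
        traj = observed_distributions([seq("a", "O", "D", "D")], K=3)
        assert traj.at(2).tolist() == [1.0, 0, 0, 0, 0]
        assert traj.at(3).tolist() == [1.0, 0, 0, 0, 0]

    def test_fractions_sum_to_one_at_every_cycle(self, medium_synthetic):
        _, _, _, sequences = medium_synthetic
        traj = observed_distributions(sequences[:2000], K=12)
        assert np.allclose(traj.distributions.sum(axis=1), 1.0, atol=1e-9)

    def test_K_beyond_available_cycles_truncates_with_warning(self):
        with pytest.warns(UserWarning, match="truncating"):
            traj = observed_distributions([seq("a", "O", "H"), seq("b", "H", "O")], K=5)
        assert traj.cycles == (1, 2)


class TestPredictionTable:
    def test_published_cycle3_row_reproduced_exactly_at_table_precision(self, reference_chain):
        table = build_prediction_table(reference_chain, reference_observed(), K=6)
        cycle3 = round_half_away(table.predicted[0], 2)
        assert cycle3.tolist() == [0.12, 0.34, 0.11, 0.09, 0.34]

    def test_cycle4_opd_error_matches_published_table(self, reference_chain):
        table = build_prediction_table(reference_chain, reference_observed(), K=6)
        # predicted 0.079 vs observed 0.15 out-patient attendance at cycle 4
        err = round_half_away(table.error[1], 2)
        assert err[3] == pytest.approx(-0.07)

    def test_identity_model_predicts_the_frozen_cycle2_distribution(self):
        m = CanonicalAMC(np.eye(5), require_absorption=False)
        table = build_prediction_table(m, reference_observed(), K=6)
        assert np.allclose(table.predicted, table.predicted[0])

    def test_errors_negate_when_predicted_and_observed_swap(self, reference_chain):
        table = build_prediction_table(reference_chain, reference_observed(), K=6)
        swapped = PredictionTable(
            cycles=table.cycles,
            predicted=table.observed,
            observed=table.predicted,
            error=table.observed - table.predicted,
        )
        assert np.allclose(swapped.error, -table.error, equal_nan=True)

    def test_error_definition_is_enforced(self, reference_chain):
        table = build_prediction_table(reference_chain, reference_observed(), K=6)
        with pytest.raises(ValueError, match="predicted - observed"):
            PredictionTable(
                cycles=table.cycles,
                predicted=table.predicted,
                observed=table.observed,
                error=table.error + 0.01,
            )

    def test_missing_cycle2_observation_blocks_prediction(self, reference_chain):
        obs = DistributionTrajectory(cycles=(1,), distributions=np.array([[0.06, 0.25, 0.21, 0.30, 0.18]]))
        with pytest.raises(ValueError, match="cycle 2"):
            build_prediction_table(reference_chain, obs, K=6)


def higher_mortality_variant(model: CanonicalAMC, extra: float = 0.10) -> CanonicalAMC:
    """Shift probability mass from each transient row's largest Q entry to death."""
    P = model.P
    for i in range(2, 5):
        j = 2 + int(np.argmax(P[i, 2:]))
        P[i, 0] += extra
        P[i, j] -= extra
    m, _ = repair_matrix(P)
    return m


@pytest.fixture(scope="module")
def age_coupled_cohort(reference_chain):
    old_chain = higher_mortality_variant(reference_chain)

    def matrix_for(age, sex):
        return old_chain if age >= 65 else None

    config = GeneratorConfig(
        ground_truth=reference_chain,
        seed=314,
        n_patients=20_000,
        horizon_cycles=6,
        first_transition_target=None,  # first transition from each chain's OPD row
        matrix_for=matrix_for,
    )
    cohort = generate_cohort(config)
    return cohort, assign_cohort_states(cohort), old_chain


class TestSubgroups:
    def test_age_strata_partition_the_cohort(self, age_coupled_cohort):
        cohort, seqs, _ = age_coupled_cohort
        results = fit_subgroup_models(cohort, seqs, SubgroupSpec("age_band"))
        assert sum(r.n_patients for r in results.values()) == len(cohort)

    def test_higher_death_hazard_recovered_in_the_older_stratum(self, age_coupled_cohort):
        cohort, seqs, _ = age_coupled_cohort
        results = fit_subgroup_models(cohort, seqs, SubgroupSpec("age_band"))
        young = results["age_lt_65"].summary.B[:, 0]
        old = results["age_ge_65"].summary.B[:, 0]
        assert np.all(old > young)

    def test_single_stratum_equals_the_whole_cohort_model(self, medium_synthetic):
        _, cohort, _, seqs = medium_synthetic
        from hfmarkov.estimation import assemble_model, count_transitions

        whole = assemble_model(count_transitions(seqs, 1), count_transitions(seqs, 2))
        results = fit_subgroup_models(cohort, seqs, SubgroupSpec("none"))
        assert list(results) == ["all"]
        assert results["all"].model == whole


class TestSurvivalReport:
    def test_reference_survival_reaches_081_at_two_years(self, reference_chain):
        traj = iterate_distribution(
            reference_chain, reference_observed().at(2), n_cycles=7, first_cycle=2
        )
        report = survival_report({"overall": traj}, K=9)
        assert round_half_away(report.loc[6, "overall"], 2) == 0.81
        assert report.index.max() == 9

    def test_survival_curves_are_monotone_non_increasing(self, reference_chain):
        old = higher_mortality_variant(reference_chain)
        trajs = {
            name: iterate_distribution(m, [0, 0, 0, 1, 0], 9)
            for name, m in [("overall", reference_chain), ("older", old)]
        }
        report = survival_report(trajs, K=9)
        assert np.all(report.diff().dropna().to_numpy() <= 1e-12)

    def test_deathless_stratum_has_a_flat_unit_curve(self):
        R = np.tile([0.0, 1.0], (3, 1)) * 0.2
        Q = np.tile([0.2, 0.3, 0.3], (3, 1))
        m = CanonicalAMC.from_blocks(R, Q)
        traj = iterate_distribution(m, [0, 0, 0, 1, 0], 9)
        assert np.allclose(survival_report({"s": traj}, K=9)["s"], 1.0)
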