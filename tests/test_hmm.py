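import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lymphmm as lm
from conftest import random_theta
from oracle_helpers import (
    binom_weights,
    final_state_distribution,
    patient_likelihood_oracle,
    step_probability,
)

TWO_LEVEL_ORACLE = dict(
    levels=["A", "B"],
    parents={"B": ["A"]},
)


def two_level_theta(bA, bB, tAB, p_late=0.5):
    return lm.ParameterVector(b=(bA, bB), t=(tAB,), p_late=p_late)


class TestNodeTransitionProb:
    def test_no_involved_parents_reduces_to_base(self, default_graph, theta_star):
        s = lm.HiddenState.from_bits((0, 0, 0, 0))
        assert lm.node_transition_prob("I", s, theta_star, default_graph) == pytest.approx(0.39)

    def test_noisy_or_with_one_involved_parent(self, two_level_graph):
        theta = two_level_theta(0.5, 0.5, 0.5)
        s = lm.HiddenState.from_bits((1, 0))
        # 1 - (1-0.5)*(1-0.5)
        assert lm.node_transition_prob("B", s, theta, two_level_graph) == pytest.approx(0.75)

    def test_zero_base_and_healthy_parents(self, two_level_graph):
        theta = two_level_theta(0.3, 0.0, 0.9)
        s = lm.HiddenState.from_bits((0, 0))
        assert lm.node_transition_prob("B", s, theta, two_level_graph) == 0.0

    def test_involved_level_rejected(self, two_level_graph):
        theta = two_level_theta(0.3, 0.3, 0.3)
        s = lm.HiddenState.from_bits((1, 0))
        with pytest.raises(ValueError):
            lm.node_transition_prob("A", s, theta, two_level_graph)


class TestTransitionMatrix:
    def test_all_zero_parameters_give_identity(self, default_graph):
        theta = lm.ParameterVector(b=(0, 0, 0, 0), t=(0, 0, 0), p_late=0.5)
        A = lm.build_transition_matrix(default_graph, theta)
        assert np.array_equal(A, np.eye(16))

    def test_entry_matches_stepwise_oracle(self, default_graph):
        theta = lm.ParameterVector(b=(0.39, 0.53, 0.03, 0.0), t=(0.5, 0.3, 0.2), p_late=0.5)
        A = lm.build_transition_matrix(default_graph, theta)
        b = dict(zip("I II III IV".split(), theta.b))
        t = {("I", "II"): 0.5, ("II", "III"): 0.3, ("III", "IV"): 0.2}
        parents = {"II": ["I"], "III": ["II"], "IV": ["III"]}
        levels = ["I", "II", "III", "IV"]
        expected = step_probability(
            frozenset(), frozenset({"I"}), levels, parents, b, t
        )
        # spread can cascade within a step, so staying II-healthy after I
        # becomes involved carries the (1 - t12) factor
        assert expected == pytest.approx(0.39 * (0.47 * 0.5) * 0.97 * 1.0)
        assert A[0, 1] == pytest.approx(expected, abs=1e-14)

    def test_full_state_is_absorbing(self, default_graph, theta_star):
        A = lm.build_transition_matrix(default_graph, theta_star)
        expected = np.zeros(16)
        expected[15] = 1.0
        assert np.array_equal(A[15], expected)

    def test_rows_stochastic_and_monotone_for_random_parameters(self, default_graph):
        rng = np.random.default_rng(42)
        idx = np.arange(16)
        not_progression = (idx[:, None] & idx[None, :]) != idx[:, None]
        for _ in range(50):
            A = lm.build_transition_matrix(default_graph, random_theta(default_graph, rng))
            assert np.max(np.abs(A.sum(axis=1) - 1.0)) < 1e-12
            assert np.all(A[not_progression] == 0.0)

    def test_out_of_range_parameter_rejected(self):
        with pytest.raises(ValueError):
            lm.ParameterVector(b=(1.2, 0, 0, 0), t=(0, 0, 0), p_late=0.5)


class TestObservationMatrix:
    def test_all_negative_given_all_healthy(self, default_graph, obs_model):
        B = lm.build_observation_matrix(obs_model, default_graph)
        assert B[0, 0] == pytest.approx(0.63**4)

    def test_perfect_observation_is_identity(self, default_graph):
        B = lm.build_observation_matrix(
            lm.ObservationModel(sensitivity=1.0, specificity=1.0), default_graph
        )
        assert np.array_equal(B, np.eye(16))

    def test_single_level_sensitivity(self):
        g = lm.LymphGraph(levels=("A",))
        B = lm.build_observation_matrix(lm.ObservationModel(), g)
        assert B[1, 1] == pytest.approx(0.81)  # involved read positive

    def test_rows_stochastic(self, default_graph):
        rng = np.random.default_rng(0)
        for _ in range(20):
            obs = lm.ObservationModel(rng.uniform(), rng.uniform())
            B = lm.build_observation_matrix(obs, default_graph)
            assert np.max(np.abs(B.sum(axis=1) - 1.0)) < 1e-12


def test_matrix_frame_uses_bit_pattern_labels(default_graph, theta_star):
    A = lm.build_transition_matrix(default_graph, theta_star)
    frame = lm.matrix_to_frame(A, default_graph)
    assert list(frame.index[:3]) == ["0000", "1000", "0100"]
    assert frame.loc["1111", "1111"] == 1.0
    assert np.allclose(frame.to_numpy(), A)


class TestBinomialTimePrior:
    @pytest.mark.parametrize(
        "t_max,p,expected",
        [
            (10, 0.0, [1.0] + [0.0] * 10),
            (10, 1.0, [0.0] * 10 + [1.0]),
            (2, 0.5, [0.25, 0.5, 0.25]),
        ],
    )
    def test_known_weights(self, t_max, p, expected):
        prior = lm.binomial_time_prior(t_max, p)
        assert np.allclose(prior.weights, expected, atol=1e-14)

    @settings(derandomize=True, max_examples=30)
    @given(
        t_max=st.integers(1, 20),
        p=st.floats(0.0, 1.0, allow_nan=False),
    )
    def test_matches_hand_pmf_and_normalizes(self, t_max, p):
        prior = lm.binomial_time_prior(t_max, p)
        assert sum(prior.weights) == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(prior.weights, binom_weights(t_max, p), atol=1e-12)


class TestStateDistribution:
    def test_time_zero_is_all_healthy(self, default_graph, theta_star):
        d = lm.state_distribution(theta_star, 0, default_graph)
        assert d[0] == 1.0 and d[1:].sum() == 0.0

    def test_single_step_equals_transition_row(self, default_graph, theta_star):
        A = lm.build_transition_matrix(default_graph, theta_star)
        assert np.allclose(
            lm.state_distribution(theta_star, 1, default_graph), A[0], atol=1e-14
        )

    def test_three_steps_match_trajectory_enumeration(self, two_level_graph):
        theta = two_level_theta(0.3, 0.2, 0.6)
        d = lm.state_distribution(theta, 3, two_level_graph)
        oracle = final_state_distribution(
            TWO_LEVEL_ORACLE["levels"],
            TWO_LEVEL_ORACLE["parents"],
            {"A": 0.3, "B": 0.2},
            {("A", "B"): 0.6},
            [0, 0, 0, 1],  # point mass at t=3
        )
        for s, pr in oracle.items():
            idx = ("A" in s) + 2 * ("B" in s)
            assert d[idx] == pytest.approx(pr, abs=1e-12)

    def test_occupancy_nondecreasing_in_time(self, default_graph):
        rng = np.random.default_rng(7)
        S = lm.graph.state_bits(default_graph)
        for _ in range(20):
            theta = random_theta(default_graph, rng)
            occ = [
                lm.state_distribution(theta, t, default_graph) @ S
                for t in range(8)
            ]
            occ = np.array(occ)
            assert np.all(np.diff(occ, axis=0) >= -1e-12)

    def test_all_involved_absorbs_in_the_long_run(self, default_graph):
        theta = lm.ParameterVector(b=(0.3, 0.3, 0.3, 0.3), t=(0.3, 0.3, 0.3), p_late=0.5)
        d = lm.state_distribution(theta, 200, default_graph)
        assert d[-1] == pytest.approx(1.0, abs=1e-9)


class TestMarginalStateDistribution:
    def test_point_mass_priors(self, default_graph, theta_star, time_config):
        at0 = lm.TimePrior(t_max=1, weights=(1.0, 0.0))
        d0 = lm.marginal_state_distribution(
            theta_star, "early", default_graph, time_config, time_prior=at0
        )
        assert d0[0] == 1.0
        at1 = lm.TimePrior(t_max=1, weights=(0.0, 1.0))
        d1 = lm.marginal_state_distribution(
            theta_star, "early", default_graph, time_config, time_prior=at1
        )
        assert np.allclose(d1, lm.state_distribution(theta_star, 1, default_graph))

    def test_binomial_weighted_sum_matches_oracle(self, two_level_graph):
        theta = two_level_theta(0.4, 0.1, 0.7, p_late=0.35)
        tc = lm.TimeConfig(t_max=10, p_early=0.3)
        for stage, p in (("early", 0.3), ("late", 0.35)):
            d = lm.marginal_state_distribution(theta, stage, two_level_graph, tc)
            oracle = final_state_distribution(
                TWO_LEVEL_ORACLE["levels"],
                TWO_LEVEL_ORACLE["parents"],
                {"A": 0.4, "B": 0.1},
                {("A", "B"): 0.7},
                binom_weights(10, p),
            )
            assert d.sum() == pytest.approx(1.0, abs=1e-12)
            for s, pr in oracle.items():
                idx = ("A" in s) + 2 * ("B" in s)
                assert d[idx] == pytest.approx(pr, abs=1e-10)

    def test_unknown_stage_rejected(self, default_graph, theta_star, time_config):
        with pytest.raises(ValueError):
            lm.marginal_state_distribution(theta_star, "mid", default_graph, time_config)


class TestPatientLikelihood:
    def test_perfect_observation_at_time_zero(self, default_graph, theta_star, time_config):
        perfect = lm.ObservationModel(sensitivity=1.0, specificity=1.0)
        at0 = lm.TimePrior(t_max=1, weights=(1.0, 0.0))
        neg = lm.Diagnosis((0, 0, 0, 0))
        pos = lm.Diagnosis((0, 1, 0, 0))
        assert lm.patient_likelihood(
            theta_star, neg, "early", default_graph, perfect, time_config, at0
        ) == pytest.approx(1.0)
        assert lm.patient_likelihood(
            theta_star, pos, "early", default_graph, perfect, time_config, at0
        ) == 0.0

    def test_fully_unknown_diagnosis_has_unit_probability(
        self, default_graph, theta_star, obs_model, time_config
    ):
        unk = lm.Diagnosis((None,) * 4)
        assert lm.patient_likelihood(
            theta_star, unk, "late", default_graph, obs_model, time_config
        ) == pytest.approx(1.0, abs=1e-12)

    def test_matches_trajectory_times_observation_enumeration(self, two_level_graph):
        theta = two_level_theta(0.35, 0.15, 0.6, p_late=0.45)
        obs = lm.ObservationModel(0.81, 0.63)
        tc = lm.TimeConfig(t_max=4, p_early=0.3)
        for stage, p in (("early", 0.3), ("late", 0.45)):
            for diag in [(0, 1), (1, 1), (0, None), (None, 1)]:
                got = lm.patient_likelihood(
                    theta, lm.Diagnosis(diag), stage, two_level_graph, obs, tc
                )
                want = patient_likelihood_oracle(
                    TWO_LEVEL_ORACLE["levels"],
                    TWO_LEVEL_ORACLE["parents"],
                    {"A": 0.35, "B": 0.15},
                    {("A", "B"): 0.6},
                    binom_weights(4, p),
                    list(diag),
                    0.81,
                    0.63,
                )
                assert got == pytest.approx(want, abs=1e-10)


class TestCohortLogLikelihood:
    def test_empty_cohort_is_zero(self, default_graph, theta_star, obs_model, time_config):
        empty = lm.CohortTable(records=[], levels=default_graph.levels)
        assert lm.cohort_log_likelihood(
            theta_star, empty, default_graph, obs_model, time_config
        ) == 0.0

    def test_additivity_over_duplicated_patient(
        self, default_graph, theta_star, obs_model, time_config
    ):
        rec = lm.PatientRecord(patient_id="P1", t_stage=2, observed=(0, 1, 0, 0))
        single = lm.CohortTable(records=[rec], levels=default_graph.levels)
        five = lm.CohortTable(
            records=[
                lm.PatientRecord(patient_id=f"P{i}", t_stage=2, observed=(0, 1, 0, 0))
                for i in range(5)
            ],
            levels=default_graph.levels,
        )
        one = lm.cohort_log_likelihood(theta_star, single, default_graph, obs_model, time_config)
        assert lm.cohort_log_likelihood(
            theta_star, five, default_graph, obs_model, time_config
        ) == pytest.approx(5 * one, rel=1e-12)

    def test_impossible_patient_gives_minus_infinity(self, default_graph, time_config):
        theta = lm.ParameterVector(b=(0, 0, 0, 0), t=(0, 0, 0), p_late=0.5)
        perfect = lm.ObservationModel(1.0, 1.0)
        rec = lm.PatientRecord(patient_id="P1", t_stage=1, observed=(1, 0, 0, 0))
        cohort = lm.CohortTable(records=[rec], levels=default_graph.levels)
        assert lm.cohort_log_likelihood(
            theta, cohort, default_graph, perfect, time_config
        ) == -np.inf

    def test_sum_of_per_patient_oracles(self, two_level_graph):
        theta = two_level_theta(0.3, 0.25, 0.5, p_late=0.6)
        obs = lm.ObservationModel(0.81, 0.63)
        tc = lm.TimeConfig(t_max=3, p_early=0.3)
        rng = np.random.default_rng(11)
        records = [
            lm.PatientRecord(
                patient_id=f"P{i}",
                t_stage=int(rng.integers(1, 5)),
                observed=tuple(rng.integers(0, 2, size=2)),
            )
            for i in range(10)
        ]
        cohort = lm.CohortTable(records=records, levels=two_level_graph.levels)
        got = lm.cohort_log_likelihood(theta, cohort, two_level_graph, obs, tc)
        want = sum(
            np.log(
                patient_likelihood_oracle(
                    TWO_LEVEL_ORACLE["levels"],
                    TWO_LEVEL_ORACLE["parents"],
                    {"A": 0.3, "B": 0.25},
                    {("A", "B"): 0.5},
                    binom_weights(3, 0.3 if r.stage_class == "early" else 0.6),
                    list(r.observed),
                    0.81,
                    0.63,
                )
            )
            for r in records
        )
        assert got == pytest.approx(want, abs=1e-10)
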