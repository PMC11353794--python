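"""Markov chains: estimation, stationarity, reversal, closed-form variants."""

import numpy as np
import pytest
from scipy.linalg import expm, logm

from contrastinfo import (
    VARIANTS,
    CTMCModel,
    DTMCModel,
    StepOffsets,
    contrast_from_joint,
    ctmc_contrast,
    dtmc_contrast,
    estimate_ctmc,
    estimate_dtmc,
    load_model,
    markov_joint,
    markov_profile,
    reverse_matrix,
    save_model,
    simulate,
    stationary_distribution,
)

from conftest import random_dtmc

# observed-symbol arguments each variant conditions on, for tests that need
# a generic positive-probability assignment
VARIANT_ARGS = {
    "predictive": dict(x="s0", y="s1"),
    "connective": dict(x="s0", y="s1"),
    "reflective": dict(x="s0", z="s1"),
    "b-predictive": dict(y="s1", z="s0"),
    "b-connective": dict(y="s1", z="s0"),
    "b-reflective": dict(x="s0", z="s1"),
}

# (source, context) outcomes of the assembled joint matching VARIANT_ARGS
VARIANT_ROLES = {
    "predictive": ("s1", "s0"),
    "connective": ("s0", "s1"),
    "reflective": ("s1", "s0"),
    "b-predictive": ("s1", "s0"),
    "b-connective": ("s0", "s1"),
    "b-reflective": ("s0", "s1"),
}


class TestEstimateDTMC:
    def test_hand_counted_transitions(self):
        model = estimate_dtmc([["R", "R", "G", "R"]])
        r, g = model.index("R"), model.index("G")
        assert model.P[r, r] == pytest.approx(0.5)
        assert model.P[g, r] == pytest.approx(0.5)
        assert model.P[r, g] == pytest.approx(1.0)

    def test_single_symbol_chain(self):
        model = estimate_dtmc([["x", "x", "x"]])
        assert model.P.tolist() == [[1.0]]

    def test_dead_state_without_pseudocount_raises(self):
        with pytest.raises(ValueError, match="'b'"):
            estimate_dtmc([["a", "b"]])

    def test_pseudocount_fills_columns(self):
        model = estimate_dtmc([["a", "b"]], pseudocount=1.0)
        assert np.allclose(model.P.sum(axis=0), 1.0)
        assert model.P[model.index("b"), model.index("a")] == pytest.approx(2 / 3)

    def test_simulation_recovery(self):
        truth = DTMCModel(
            ("a", "b", "c"),
            np.array([[0.7, 0.2, 0.1], [0.2, 0.5, 0.3], [0.1, 0.3, 0.6]]),
        )
        seq = simulate(truth, length=100_000, seed=101)
        est = estimate_dtmc([list(seq.values)], alphabet=truth.alphabet)
        assert np.max(np.abs(est.P - truth.P)) <= 0.01


class TestStationaryDistribution:
    def test_symmetric_two_state(self):
        model = DTMCModel("ab", np.array([[0.6, 0.4], [0.4, 0.6]]))
        assert np.allclose(model.pi, [0.5, 0.5])

    def test_random_chain_residual(self):
        rng = np.random.default_rng(5)
        model = random_dtmc(rng, 4)
        pi = stationary_distribution(model)
        assert np.max(np.abs(model.P @ pi - pi)) <= 1e-12
        assert np.all(pi > 0)

    def test_ctmc_null_space(self):
        rng = np.random.default_rng(6)
        Q = rng.random((3, 3))
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=0))
        model = CTMCModel("abc", Q)
        assert np.max(np.abs(Q @ model.pi)) <= 1e-12

    def test_reducible_chain_raises(self):
        P = np.eye(2)
        with pytest.raises(ValueError, match="reducible"):
            DTMCModel("ab", P).pi

    def test_periodic_chain_raises(self):
        P = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="periodic"):
            DTMCModel("ab", P).pi


class TestReverseMatrix:
    def test_symmetric_chain_is_self_reverse(self):
        P = np.array([[0.8, 0.2], [0.2, 0.8]])
        model = DTMCModel("ab", P)
        assert np.allclose(reverse_matrix(model), P)

    def test_elementwise_formula_and_column_sums(self):
        rng = np.random.default_rng(8)
        model = random_dtmc(rng, 5)
        R = reverse_matrix(model)
        pi = model.pi
        for j in range(5):
            for k in range(5):
                assert R[j, k] == pytest.approx(pi[j] * model.P[k, j] / pi[k], abs=1e-12)
        assert np.max(np.abs(R.sum(axis=0) - 1.0)) <= 1e-12


class TestDTMCContrast:
    def test_stop_light_values(self, example1_chain):
        green = dtmc_contrast(example1_chain, "predictive", x="RED", y="GREEN")
        red = dtmc_contrast(example1_chain, "predictive", x="RED", y="RED")
        assert round(green, 2) == 2.95
        assert round(red, 2) == 0.02

    def test_connective_zero_for_any_chain(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            model = random_dtmc(rng)
            s = model.alphabet
            assert dtmc_contrast(model, "connective", x=s[0], y=s[-1]) == 0.0
            assert dtmc_contrast(model, "b-connective", y=s[0], z=s[-1]) == 0.0

    @pytest.mark.parametrize("j,k", [(1, 1), (2, 1), (2, 3)])
    def test_all_variants_match_definitional_oracle(self, j, k):
        rng = np.random.default_rng(j * 10 + k)
        model = random_dtmc(rng, 4)
        off = StepOffsets(j, k)
        for variant in VARIANTS:
            closed = dtmc_contrast(model, variant, offsets=off, **VARIANT_ARGS[variant])
            joint = markov_joint(model, variant, off)
            oracle = contrast_from_joint(joint, *VARIANT_ROLES[variant])
            assert closed == pytest.approx(oracle, abs=1e-10)

    def test_time_reversal_duality(self):
        """Backward variants equal forward variants on the reversed chain."""
        rng = np.random.default_rng(13)
        model = random_dtmc(rng, 4)
        rev = DTMCModel(model.alphabet, reverse_matrix(model), model.pi)
        off = StepOffsets(2, 3)
        rev_off = StepOffsets(3, 2)  # past and future swap roles
        assert dtmc_contrast(model, "b-predictive", y="s1", z="s0", offsets=off) == (
            pytest.approx(
                dtmc_contrast(rev, "predictive", x="s0", y="s1", offsets=rev_off),
                abs=1e-12,
            )
        )
        assert dtmc_contrast(model, "b-reflective", x="s2", z="s0", offsets=off) == (
            pytest.approx(
                dtmc_contrast(rev, "reflective", x="s0", z="s2", offsets=rev_off),
                abs=1e-12,
            )
        )

    def test_unknown_symbol_raises(self, example1_chain):
        with pytest.raises(KeyError, match="BLUE"):
            dtmc_contrast(example1_chain, "predictive", x="RED", y="BLUE")

    def test_nats_base(self, example1_chain):
        bits = dtmc_contrast(example1_chain, "predictive", x="RED", y="GREEN")
        nats = dtmc_contrast(example1_chain, "predictive", x="RED", y="GREEN", base="nats")
        assert nats == pytest.approx(bits * np.log(2))


class TestEstimateCTMC:
    def test_hand_counted_rates(self):
        model = estimate_ctmc([[("A", 0.0, 2.0), ("B", 2.0, 1.0)]])
        a, b = model.index("A"), model.index("B")
        assert model.Q[b, a] == pytest.approx(0.5)
        assert model.Q[a, a] == pytest.approx(-0.5)
        assert np.allclose(model.Q.sum(axis=0), 0.0)

    def test_repeated_symbol_merged_into_one_dwell(self):
        split = [("A", 0.0, 1.0), ("A", 1.0, 1.0), ("B", 2.0, 1.0)]
        merged = [("A", 0.0, 2.0), ("B", 2.0, 1.0)]
        assert np.allclose(estimate_ctmc([split]).Q, estimate_ctmc([merged]).Q)

    def test_constraints_on_random_data(self):
        rng = np.random.default_rng(14)
        Q = rng.random((3, 3)) + 0.2
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=0))
        truth = CTMCModel("abc", Q)
        seq = simulate(truth, horizon=500.0, seed=3)
        est = estimate_ctmc([seq.timed_events()], alphabet=truth.alphabet)
        off = est.Q - np.diag(np.diag(est.Q))
        assert np.all(off >= 0)
        assert np.max(np.abs(est.Q.sum(axis=0))) <= 1e-12

    def test_simulation_recovery(self):
        rng = np.random.default_rng(15)
        Q = rng.random((3, 3)) + 0.3
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=0))
        truth = CTMCModel("abc", Q)
        # ~1e4 jumps at this chain's overall jump rate
        seq = simulate(truth, horizon=8000.0, seed=16)
        assert len(seq) >= 9000
        est = estimate_ctmc([seq.timed_events()], alphabet=truth.alphabet)
        offt = Q - np.diag(np.diag(Q))
        offh = est.Q - np.diag(np.diag(est.Q))
        rel = np.abs(offh - offt)[offt > 0] / offt[offt > 0]
        assert np.max(rel) <= 0.05


class TestCTMCContrast:
    def test_connective_zero(self):
        rng = np.random.default_rng(17)
        Q = rng.random((3, 3))
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=0))
        model = CTMCModel("abc", Q)
        assert ctmc_contrast(model, "connective", x="a", y="b", u=0.7, v=1.3) == 0.0
        assert ctmc_contrast(model, "b-connective", y="a", z="b", u=0.7, v=1.3) == 0.0

    def test_matrix_logarithm_consistency_with_dtmc(self, example1_chain):
        """Q = logm(P) at u = v = 1 reproduces the one-step DTMC values."""
        Q = logm(example1_chain.P).real
        model = CTMCModel(example1_chain.alphabet, Q)
        ct = ctmc_contrast(model, "predictive", x="RED", y="GREEN", u=1.0, v=1.0)
        dt = dtmc_contrast(example1_chain, "predictive", x="RED", y="GREEN")
        assert ct == pytest.approx(dt, abs=1e-10)

    def test_all_variants_match_definitional_oracle(self):
        rng = np.random.default_rng(18)
        Q = rng.random((4, 4)) + 0.1
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=0))
        model = CTMCModel(tuple(f"s{i}" for i in range(4)), Q)
        u, v = 0.5, 1.25
        for variant in VARIANTS:
            closed = ctmc_contrast(model, variant, u=u, v=v, **VARIANT_ARGS[variant])
            joint = markov_joint(model, variant, (u, v))
            oracle = contrast_from_joint(joint, *VARIANT_ROLES[variant])
            assert closed == pytest.approx(oracle, abs=1e-10)

    def test_unit_sampling_reproduces_dtmc(self):
        rng = np.random.default_rng(19)
        Q = rng.random((3, 3)) + 0.1
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=0))
        cm = CTMCModel("abc", Q)
        dm = DTMCModel("abc", expm(Q))
        for variant in VARIANTS:
            args = {k: {"s0": "a", "s1": "b"}[s] for k, s in VARIANT_ARGS[variant].items()}
            assert ctmc_contrast(cm, variant, u=2.0, v=1.0, **args) == pytest.approx(
                dtmc_contrast(dm, variant, offsets=StepOffsets(2, 1), **args), abs=1e-10
            )


class TestMarkovProfile:
    def test_iid_chain_gives_zero_predictive_profile(self):
        # all columns equal: the present carries nothing about the future
        p = np.array([0.5, 0.3, 0.2])
        model = DTMCModel("abc", np.tile(p[:, None], 3))
        prof = markov_profile(model, ["a", "b", "c", "a", "b"], "predictive")
        assert np.allclose(prof["value_bits"], 0.0, atol=1e-12)

    def test_rows_match_single_point_calls_and_count(self, example1_chain):
        seq = ["RED", "RED", "GREEN", "GREEN", "RED"]
        prof = markov_profile(example1_chain, seq, "predictive")
        assert len(prof) == len(seq) - 2
        for _, row in prof.iterrows():
            n = int(row.event_index)
            direct = dtmc_contrast(
                example1_chain, "predictive", x=seq[n - 1], y=seq[n]
            )
            assert row.value_bits == pytest.approx(direct, abs=1e-12)

    def test_symbol_outside_alphabet_reports_index(self, example1_chain):
        with pytest.raises(ValueError, match="event 2"):
            markov_profile(example1_chain, ["RED", "RED", "BLUE"], "predictive")

    def test_ctmc_profile_matches_pointwise_calls(self):
        from contrastinfo import EventSequence

        rng = np.random.default_rng(20)
        Q = rng.random((2, 2)) + 0.2
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=0))
        model = CTMCModel("ab", Q)
        seq = EventSequence(["a", "b", "a"], [0.0, 1.0, 2.5], [1.0, 1.5, 1.0])
        prof = markov_profile(model, seq, "predictive", grid_step=0.25)
        assert len(prof) > 0
        for _, row in prof.iterrows():
            direct = ctmc_contrast(
                model, "predictive", x="a", y="b", u=1.0, v=row.time - 1.0
            )
            assert row.value_bits == pytest.approx(direct, abs=1e-12)


def test_model_json_round_trip(tmp_path, example1_chain):
    path = tmp_path / "model.json"
    save_model(example1_chain, path)
    loaded = load_model(path)
    assert loaded.alphabet == example1_chain.alphabet
    assert np.allclose(loaded.P, example1_chain.P)
    assert np.allclose(loaded.pi, example1_chain.pi)
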