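"""Core HMM: matrices, encounter-history likelihood, conditioning contract."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridcr import (
    CRDataset,
    EncounterHistory,
    ParameterSet,
    build_event_matrix,
    build_transition_matrix,
    dataset_negloglik,
    history_loglik,
)
from hybridcr.model_core import ParameterError

from conftest import oracle_history_prob, random_history, random_params

prob = st.floats(0.0, 1.0, allow_nan=False)


def make_params(**kw):
    base = dict(pi_p=0.5, phi_p=0.5, phi_h=0.5, p_p=0.5, p_h=0.5, delta_p=0.5, delta_h=0.5)
    base.update(kw)
    return ParameterSet(**base)


class TestMatrices:
    def test_transition_matrix_structure(self):
        m = build_transition_matrix(make_params(phi_p=0.8, phi_h=0.7))
        np.testing.assert_allclose(
            m, [[0.8, 0.0, 0.2], [0.0, 0.7, 0.3], [0.0, 0.0, 1.0]], atol=1e-15
        )

    @pytest.mark.parametrize(
        "phi_p,phi_h,alive_rows",
        [(1.0, 1.0, [[1, 0, 0], [0, 1, 0]]), (0.0, 0.0, [[0, 0, 1], [0, 0, 1]])],
    )
    def test_transition_matrix_degenerate(self, phi_p, phi_h, alive_rows):
        m = build_transition_matrix(make_params(phi_p=phi_p, phi_h=phi_h))
        np.testing.assert_allclose(m[:2], alive_rows, atol=1e-15)
        np.testing.assert_allclose(m[2], [0, 0, 1], atol=1e-15)

    def test_event_matrix_values(self):
        q = make_params(p_p=0.9, p_h=0.8, delta_p=0.7, delta_h=0.7)
        m = build_event_matrix(q)
        np.testing.assert_allclose(m[0], [0.1, 0.63, 0.0, 0.27], atol=1e-15)
        np.testing.assert_allclose(m[1], [0.2, 0.0, 0.56, 0.24], atol=1e-15)
        np.testing.assert_allclose(m[2], [1.0, 0.0, 0.0, 0.0], atol=1e-15)

    def test_event_matrix_first_capture_conditions_out_detection(self):
        q = make_params(delta_p=1.0, delta_h=1.0)
        m = build_event_matrix(q, at_first_capture=True)
        np.testing.assert_allclose(m[0], [0, 1, 0, 0], atol=1e-15)
        np.testing.assert_allclose(m[1], [0, 0, 1, 0], atol=1e-15)

    @settings(max_examples=50, deadline=None)
    @given(v=st.lists(prob, min_size=7, max_size=7))
    def test_rows_stochastic(self, v):
        q = ParameterSet(*v)
        for m in (
            build_transition_matrix(q),
            build_event_matrix(q),
            build_event_matrix(q, at_first_capture=True),
        ):
            np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)
            assert (m >= 0).all()

    @pytest.mark.parametrize("bad", [dict(phi_p=1.2), dict(delta_h=-0.1), dict(pi_p=np.nan)])
    def test_invalid_probability_names_parameter(self, bad):
        with pytest.raises(ParameterError, match=next(iter(bad))):
            make_params(**bad)


class TestHistoryLoglik:
    def test_pr303_two_term_expression(self, example_params):
        q = example_params
        expected = math.log(
            q.pi_h * (1 - q.delta_h) * q.phi_h * (1 - q.p_h) * q.phi_h * q.p_h * (1 - q.delta_h)
            + q.pi_p * (1 - q.delta_p) * q.phi_p * (1 - q.p_p) * q.phi_p * q.p_p * (1 - q.delta_p)
        )
        assert history_loglik("303", q) == pytest.approx(expected, abs=1e-12)

    def test_single_certain_capture(self):
        q = make_params(pi_p=0.35, delta_p=1.0, delta_h=1.0)
        assert history_loglik("1", q) == pytest.approx(math.log(0.35), abs=1e-12)

    def test_forward_matches_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            T = int(rng.integers(1, 7))
            q = random_params(rng)
            ev = random_history(rng, T)
            ref = oracle_history_prob(ev, q)
            got = history_loglik(ev, q)
            if ref == 0.0:  # structurally impossible, e.g. events 1 then 2
                assert got == -np.inf
            else:
                assert got == pytest.approx(math.log(ref), abs=1e-10)

    def test_conditioning_ignores_occasions_before_first_detection(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            q = random_params(rng)
            ev = random_history(rng, 4)
            padded = (0, 0) + ev
            assert history_loglik(padded, q) == pytest.approx(history_loglik(ev, q), abs=1e-12)

    def test_all_zero_history_rejected(self):
        with pytest.raises(ValueError, match="detected at least once"):
            history_loglik("000", make_params())

    def test_cjs_mixture_when_assignment_certain(self):
        """With delta=1 and only events 0/1 the model reduces to a single
        Cormack-Jolly-Seber likelihood for the Parental state, weighted by pi_p
        (event 1 is impossible from the Hybrid state)."""

        def cjs_loglik(ev, phi, p):
            f = next(i for i, e in enumerate(ev) if e != 0)
            last = max(i for i, e in enumerate(ev) if e != 0)
            ll = 0.0
            for t in range(f + 1, last + 1):
                ll += math.log(phi) + math.log(p if ev[t] == 1 else 1 - p)
            chi = 1.0  # P(never seen after last)
            for _ in range(len(ev) - 1 - last):
                chi = 1 - phi + phi * (1 - p) * chi
            return ll + math.log(chi)

        rng = np.random.default_rng(5)
        for ev in [(1, 0, 1), (1, 1, 0, 0), (0, 1, 0, 0, 1), (1, 0, 0, 1, 0)]:
            r = random_params(rng)
            q = ParameterSet(
                pi_p=r.pi_p, phi_p=r.phi_p, phi_h=r.phi_h, p_p=r.p_p, p_h=r.p_h,
                delta_p=1.0, delta_h=1.0,
            )
            expected = math.log(q.pi_p) + cjs_loglik(ev, q.phi_p, q.p_p)
            assert history_loglik(ev, q) == pytest.approx(expected, abs=1e-10)


class TestFirstCaptureOnlyAssignment:
    """Re-detections repeat the first recorded class deterministically."""

    def test_uncertain_first_capture_hand_computed(self, example_params):
        # "33": classified uncertain once; re-detection must repeat event 3.
        q = example_params
        expected = math.log(
            q.pi_h * (1 - q.delta_h) * q.phi_h * q.p_h
            + q.pi_p * (1 - q.delta_p) * q.phi_p * q.p_p
        )
        assert history_loglik("33", q, delta_first_only=True) == pytest.approx(
            expected, abs=1e-12
        )

    def test_class_switch_has_zero_probability(self, example_params):
        # first classified parental, later recorded uncertain: impossible
        assert history_loglik("13", example_params, delta_first_only=True) == -np.inf

    def test_forward_matches_enumeration(self, example_params):
        from hybridcr.model_core import enumerate_history_prob

        rng = np.random.default_rng(21)
        for _ in range(30):
            q = random_params(rng)
            ev = random_history(rng, 5)
            got = history_loglik(ev, q, delta_first_only=True)
            ref = enumerate_history_prob(ev, q, delta_first_only=True)
            if ref == 0.0:
                assert got == -np.inf
            else:
                assert got == pytest.approx(math.log(ref), abs=1e-10)


class TestDatasetNegloglik:
    def test_multiplicity_equals_repetition(self, example_params):
        once = CRDataset([EncounterHistory.from_string("303", count=2)])
        twice = CRDataset(
            [EncounterHistory.from_string("303", id="a"), EncounterHistory.from_string("303", id="b")]
        )
        assert dataset_negloglik(once, example_params) == pytest.approx(
            dataset_negloglik(twice, example_params), abs=1e-12
        )

    def test_singleton_dataset_equals_negative_history_loglik(self, example_params):
        ds = CRDataset([EncounterHistory.from_string("2031")])
        assert dataset_negloglik(ds, example_params) == pytest.approx(
            -history_loglik("2031", example_params), abs=1e-12
        )

    def test_simulated_dataset_matches_bruteforce_product(self):
        rng = np.random.default_rng(17)
        q = random_params(rng)
        rows = []
        while len(rows) < 10:
            ev = random_history(rng, 4)
            if oracle_history_prob(ev, q) > 0.0:
                rows.append(ev)
        ds = CRDataset.from_events(rows)
        expected = -sum(math.log(oracle_history_prob(ev, q)) for ev in rows)
        assert dataset_negloglik(ds, q) == pytest.approx(expected, abs=1e-9)

    def test_uniform_length_required(self):
        with pytest.raises(ValueError, match="unequal"):
            CRDataset.from_events(["101", "1001"])
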