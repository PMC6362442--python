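import numpy as np
import pytest

from hybridcr import CRDataset, ParameterSet, make_scenario, simulate_dataset


def random_params(rng, low=0.05, high=0.95) -> ParameterSet:
    v = rng.uniform(low, high, size=7)
    return ParameterSet(
        pi_p=v[0], phi_p=v[1], phi_h=v[2], p_p=v[3], p_h=v[4], delta_p=v[5], delta_h=v[6]
    )


def random_history(rng, T):
    """A random valid encounter history of length T (at least one detection)."""
    while True:
        ev = rng.integers(0, 4, size=T)
        if (ev != 0).any():
            return tuple(int(e) for e in ev)


@pytest.fixture
def example_params() -> ParameterSet:
    """Survival truths from the simulation design; illustrative p and delta."""
    return ParameterSet(
        pi_p=0.7, phi_p=0.8, phi_h=0.7, p_p=0.9, p_h=0.8, delta_p=0.7, delta_h=0.7
    )


@pytest.fixture
def small_dataset() -> CRDataset:
    return CRDataset.from_events(
        ["303", "101", "022", "310", "203", "111", "030", "102"],
    )


@pytest.fixture
def scenario3_dataset():
    """One simulated scenario-3 cohort (n=100, T=5, high detectability)."""
    sc = make_scenario(3, "high", T=5, n_individuals=100, seed=11)
    return sc, simulate_dataset(sc, [11, 0])


# ---------------------------------------------------------------------------
# Independent brute-force oracle: matrices and path enumeration written from
# the model definition, sharing no code with the package implementation.
# ---------------------------------------------------------------------------

def oracle_history_prob(events, q) -> float:
    """Sum of path probabilities over all hidden state sequences.

    States indexed 0=P, 1=H, 2=D.  q is a ParameterSet.  Conditional on
    first detection: initial distribution and assignment-only event matrix
    at the first nonzero event, transition x full event matrix afterwards.
    """
    import itertools

    pi = [q.pi_p, 1.0 - q.pi_p, 0.0]
    tr = [
        [q.phi_p, 0.0, 1.0 - q.phi_p],
        [0.0, q.phi_h, 1.0 - q.phi_h],
        [0.0, 0.0, 1.0],
    ]
    ev_full = [
        [1 - q.p_p, q.p_p * q.delta_p, 0.0, q.p_p * (1 - q.delta_p)],
        [1 - q.p_h, 0.0, q.p_h * q.delta_h, q.p_h * (1 - q.delta_h)],
        [1.0, 0.0, 0.0, 0.0],
    ]
    ev_first = [
        [0.0, q.delta_p, 0.0, 1 - q.delta_p],
        [0.0, 0.0, q.delta_h, 1 - q.delta_h],
        [1.0, 0.0, 0.0, 0.0],
    ]
    f = next(i for i, e in enumerate(events) if e != 0)
    tail = events[f:]
    total = 0.0
    for path in itertools.product(range(3), repeat=len(tail)):
        prob = pi[path[0]] * ev_first[path[0]][tail[0]]
        for k in range(1, len(tail)):
            prob *= tr[path[k - 1]][path[k]] * ev_full[path[k]][tail[k]]
        total += prob
    return total


def oracle_best_path(events, q):
    """Argmax state sequence by exhaustive enumeration; ties prefer the
    lexicographically smallest path in (P, H, D) order."""
    import itertools

    pi = [q.pi_p, 1.0 - q.pi_p, 0.0]
    tr = [
        [q.phi_p, 0.0, 1.0 - q.phi_p],
        [0.0, q.phi_h, 1.0 - q.phi_h],
        [0.0, 0.0, 1.0],
    ]
    ev_full = [
        [1 - q.p_p, q.p_p * q.delta_p, 0.0, q.p_p * (1 - q.delta_p)],
        [1 - q.p_h, 0.0, q.p_h * q.delta_h, q.p_h * (1 - q.delta_h)],
        [1.0, 0.0, 0.0, 0.0],
    ]
    ev_first = [
        [0.0, q.delta_p, 0.0, 1 - q.delta_p],
        [0.0, 0.0, q.delta_h, 1 - q.delta_h],
        [1.0, 0.0, 0.0, 0.0],
    ]
    f = next(i for i, e in enumerate(events) if e != 0)
    tail = events[f:]
    best, best_prob = None, -1.0
    for path in itertools.product(range(3), repeat=len(tail)):
        prob = pi[path[0]] * ev_first[path[0]][tail[0]]
        for k in range(1, len(tail)):
            prob *= tr[path[k - 1]][path[k]] * ev_full[path[k]][tail[k]]
        if prob > best_prob:
            best, best_prob = path, prob
    return best, best_prob
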