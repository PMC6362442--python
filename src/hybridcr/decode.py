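"""Viterbi decoding of the most likely latent state sequence per individual.

Resolving each uncertain observation to its most probable state lets the
per-occasion counts of observed parentals and hybrids be reconstructed, the
input the Horvitz-Thompson abundance step needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import (
    CRDataset,
    ParameterSet,
    STATES,
    _as_history,
    _repeat_event_matrices,
    build_event_matrix,
    build_transition_matrix,
)

__all__ = ["StatePath", "viterbi_path", "assigned_counts", "paths_to_frame"]


@dataclass(frozen=True)
class StatePath:
    """Most likely state sequence for one individual, from first capture on.

    ``first_occasion`` is 1-based; ``states[k]`` is the decoded state at
    occasion ``first_occasion + k``.  The transition structure forbids
    P<->H switches, and events 1/2 pin the state at their occasion.
    """

    id: str
    first_occasion: int
    states: tuple[str, ...]
    path_log_prob: float

    def state_at(self, occasion: int) -> str | None:
        """Decoded state at a 1-based occasion; None before first capture."""
        k = occasion - self.first_occasion
        return self.states[k] if 0 <= k < len(self.states) else None


def viterbi_path(history, params: ParameterSet, delta_first_only: bool = False) -> StatePath:
    """Most probable hidden state sequence given the observed events.

    Maximizes the joint probability of states and events under the same
    first-capture convention as the likelihood (detection conditioned out at
    the first encounter).  Exact log-probability ties are broken toward the
    earlier state in the (P, H, D) order, so decoding is deterministic.
    """
    h = _as_history(history)
    f = h.first_capture
    T = h.T
    with np.errstate(divide="ignore"):
        log_gamma = np.log(build_transition_matrix(params))
        log_B = np.log(build_event_matrix(params))
        log_Bf = np.log(build_event_matrix(params, at_first_capture=True))
        log_init = np.log(np.array([params.pi_p, params.pi_h, 0.0]))
        log_Brep = (
            np.log(_repeat_event_matrices(params)[h.events[f]]) if delta_first_only else None
        )

    n = T - f
    score = np.full((n, 3), -np.inf)
    back = np.zeros((n, 3), dtype=np.int64)
    score[0] = log_init + log_Bf[:, h.events[f]]
    for k in range(1, n):
        e = h.events[f + k]
        obs = log_Brep[:, e] if delta_first_only else log_B[:, e]
        cand = score[k - 1][:, None] + log_gamma  # (from, to)
        back[k] = cand.argmax(axis=0)
        score[k] = cand[back[k], np.arange(3)] + obs

    path = np.zeros(n, dtype=np.int64)
    path[-1] = int(score[-1].argmax())
    for k in range(n - 1, 0, -1):
        path[k - 1] = back[k, path[k]]
    return StatePath(
        id=h.id,
        first_occasion=f + 1,
        states=tuple(STATES[s] for s in path),
        path_log_prob=float(score[-1, path[-1]]),
    )


def assigned_counts(
    dataset: CRDataset, params: ParameterSet, delta_first_only: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Per-occasion counts of detected individuals decoded as P and as H.

    Returns ``(n_p, n_h)``, each of length T.  An individual contributes to
    occasion t only if it was detected at t (event != 0); its contribution
    goes to the class of its decoded state at t.  Hence
    ``n_p[t] + n_h[t]`` equals the number detected at t.
    """
    T = dataset.T
    n_p = np.zeros(T, dtype=np.int64)
    n_h = np.zeros(T, dtype=np.int64)
    cache: dict[tuple[int, ...], StatePath] = {}
    for h in dataset.histories:
        sp = cache.get(h.events)
        if sp is None:
            sp = viterbi_path(h, params, delta_first_only)
            cache[h.events] = sp
        for t, e in enumerate(h.events):
            if e == 0:
                continue
            state = sp.state_at(t + 1)
            if state == "P":
                n_p[t] += h.count
            elif state == "H":
                n_h[t] += h.count
    return n_p, n_h


def paths_to_frame(
    dataset: CRDataset, params: ParameterSet, delta_first_only: bool = False
) -> pd.DataFrame:
    """Decoded paths in long form: id, occasion, event, decoded_state."""
    rows = []
    for h in dataset.histories:
        sp = viterbi_path(h, params, delta_first_only)
        for t, e in enumerate(h.events, start=1):
            rows.append(
                dict(id=h.id, occasion=t, event=e, decoded_state=sp.state_at(t) or "")
            )
    return pd.DataFrame(rows)
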