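"""Core 3-state / 4-event hidden Markov model for multievent capture-recapture.

Latent states are Parental (P), Hybrid (H) and Dead (D); D is absorbing and
no P<->H transitions exist, so survival is the only state dynamic.  Observed
events per occasion are coded 0 = not detected, 1 = detected as parental,
2 = detected as hybrid, 3 = detected as uncertain.

All likelihoods are conditional on the first detection: an individual must be
encountered at least once to enter the dataset, so the capture process is not
modelled at the first encounter, but the classification (certain vs uncertain)
is.  The initial state distribution (pi_p, pi_h) applies at that occasion.

State order is (P, H, D) and event order (0, 1, 2, 3) everywhere; any I/O
re-maps to this order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "STATES",
    "EVENTS",
    "ParameterSet",
    "EncounterHistory",
    "CRDataset",
    "ParameterError",
    "build_transition_matrix",
    "build_event_matrix",
    "history_loglik",
    "dataset_negloglik",
]

STATES = ("P", "H", "D")
EVENTS = (0, 1, 2, 3)

_P, _H, _D = 0, 1, 2


class ParameterError(ValueError):
    """A model probability lies outside [0, 1]."""


@dataclass(frozen=True)
class ParameterSet:
    """Probabilities of the multievent model, one value per state.

    Parameters
    ----------
    pi_p : float
        Probability that an individual is Parental at first encounter
        (``pi_h = 1 - pi_p``).
    phi_p, phi_h : float
        Apparent survival per interval for Parental / Hybrid individuals.
    p_p, p_h : float
        Detection probability per occasion for alive individuals.
    delta_p, delta_h : float
        Probability that a detected individual is assigned to its state
        rather than recorded as uncertain.
    """

    pi_p: float
    phi_p: float
    phi_h: float
    p_p: float
    p_h: float
    delta_p: float
    delta_h: float

    def __post_init__(self) -> None:
        for name in ("pi_p", "phi_p", "phi_h", "p_p", "p_h", "delta_p", "delta_h"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0.0 or v > 1.0:
                raise ParameterError(f"parameter {name}={v!r} is not a probability in [0, 1]")

    @property
    def pi_h(self) -> float:
        return 1.0 - self.pi_p

    def as_dict(self) -> dict[str, float]:
        return {
            "pi_p": self.pi_p,
            "pi_h": self.pi_h,
            "phi_p": self.phi_p,
            "phi_h": self.phi_h,
            "p_p": self.p_p,
            "p_h": self.p_h,
            "delta_p": self.delta_p,
            "delta_h": self.delta_h,
        }


def build_transition_matrix(params: ParameterSet) -> np.ndarray:
    """State transition matrix, rows = state at t, columns = state at t+1.

    Row order (P, H, D).  A Parental survives with probability ``phi_p`` and
    cannot become Hybrid (and vice versa); Dead is absorbing.
    """
    return np.array(
        [
            [params.phi_p, 0.0, 1.0 - params.phi_p],
            [0.0, params.phi_h, 1.0 - params.phi_h],
            [0.0, 0.0, 1.0],
        ]
    )


def build_event_matrix(params: ParameterSet, at_first_capture: bool = False) -> np.ndarray:
    """Event (observation) matrix, states in rows, events 0..3 in columns.

    With ``at_first_capture=True`` detection is conditioned out (the
    individual is in the dataset because it was detected) and only the
    assignment process remains: a Parental is recorded as event 1 with
    probability ``delta_p`` and as uncertain (event 3) otherwise.
    """
    if at_first_capture:
        return np.array(
            [
                [0.0, params.delta_p, 0.0, 1.0 - params.delta_p],
                [0.0, 0.0, params.delta_h, 1.0 - params.delta_h],
                [1.0, 0.0, 0.0, 0.0],
            ]
        )
    pp, ph = params.p_p, params.p_h
    dp, dh = params.delta_p, params.delta_h
    return np.array(
        [
            [1.0 - pp, pp * dp, 0.0, pp * (1.0 - dp)],
            [1.0 - ph, 0.0, ph * dh, ph * (1.0 - dh)],
            [1.0, 0.0, 0.0, 0.0],
        ]
    )


def _repeat_event_matrices(params: ParameterSet) -> np.ndarray:
    """Post-first-capture event matrices under the first-capture-only
    assignment rule, indexed by the class recorded at first capture.

    When classification is performed once per individual (e.g. a genotype is
    assessed a single time), a re-detection deterministically repeats the
    first recorded class: the emitted event carries detection information
    only.  Returns an array of shape (4, 3, 4); index 0 is unused.
    """
    out = np.zeros((4, 3, 4))
    for c in (1, 2, 3):
        out[c, _P, 0] = 1.0 - params.p_p
        out[c, _P, c] = params.p_p
        out[c, _H, 0] = 1.0 - params.p_h
        out[c, _H, c] = params.p_h
        out[c, _D, 0] = 1.0
    return out


@dataclass(frozen=True)
class EncounterHistory:
    """One individual's event sequence over T occasions.

    ``count`` is a multiplicity: a history with count k is equivalent to k
    identical rows.  At least one event must be nonzero.
    """

    events: tuple[int, ...]
    id: str = ""
    count: int = 1

    def __post_init__(self) -> None:
        ev = tuple(int(e) for e in self.events)
        object.__setattr__(self, "events", ev)
        label = self.id or "<history>"
        if len(ev) == 0:
            raise ValueError(f"{label}: empty encounter history")
        bad = [e for e in ev if e not in (0, 1, 2, 3)]
        if bad:
            raise ValueError(f"{label}: invalid event code {bad[0]!r} (must be 0-3)")
        if all(e == 0 for e in ev):
            raise ValueError(f"{label}: all-zero history; an individual must be detected at least once")
        if self.count < 1:
            raise ValueError(f"{label}: count must be a positive integer")

    @classmethod
    def from_string(cls, s: str, id: str = "", count: int = 1) -> "EncounterHistory":
        return cls(tuple(int(ch) for ch in s.strip()), id=id, count=count)

    @property
    def T(self) -> int:
        return len(self.events)

    @property
    def first_capture(self) -> int:
        """0-based index of the first detection occasion."""
        return next(i for i, e in enumerate(self.events) if e != 0)

    def __str__(self) -> str:
        return "".join(str(e) for e in self.events)


@dataclass
class CRDataset:
    """A capture-recapture dataset: encounter histories with a common T."""

    histories: list[EncounterHistory]
    _packed: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.histories:
            raise ValueError("dataset must contain at least one encounter history")
        Ts = {h.T for h in self.histories}
        if len(Ts) > 1:
            raise ValueError(f"histories have unequal lengths: {sorted(Ts)}")

    @classmethod
    def from_events(cls, rows, ids=None, counts=None) -> "CRDataset":
        hist = []
        for i, row in enumerate(rows):
            ev = tuple(int(ch) for ch in row) if not isinstance(row, str) else tuple(
                int(ch) for ch in row.strip()
            )
            hist.append(
                EncounterHistory(
                    ev,
                    id=str(ids[i]) if ids is not None else f"ind{i + 1}",
                    count=int(counts[i]) if counts is not None else 1,
                )
            )
        return cls(hist)

    @property
    def T(self) -> int:
        return self.histories[0].T

    @property
    def n_individuals(self) -> int:
        return sum(h.count for h in self.histories)

    def expand(self) -> list[EncounterHistory]:
        """One EncounterHistory per individual (counts unrolled)."""
        out = []
        for h in self.histories:
            out.extend(
                EncounterHistory(h.events, id=f"{h.id}#{k + 1}" if h.count > 1 else h.id)
                for k in range(h.count)
            )
        return out

    def packed(self):
        """Unique histories as arrays: (events (m,T), counts, first, first_class).

        Duplicate rows are merged so the likelihood is computed once per
        distinct history.
        """
        if self._packed is None:
            agg: dict[tuple[int, ...], int] = {}
            for h in self.histories:
                agg[h.events] = agg.get(h.events, 0) + h.count
            keys = sorted(agg)
            events = np.array(keys, dtype=np.int64)
            counts = np.array([agg[k] for k in keys], dtype=np.float64)
            first = (events != 0).argmax(axis=1)
            # rows sorted by first-capture occasion so the forward recursion
            # can address "already entered" rows as a contiguous prefix
            order = np.argsort(first, kind="stable")
            events, counts, first = events[order], counts[order], first[order]
            first_class = events[np.arange(len(keys)), first]
            self._packed = (events, counts, first, first_class)
        return self._packed


def _batch_forward(
    events: np.ndarray,
    first: np.ndarray,
    first_class: np.ndarray,
    params: ParameterSet,
    delta_first_only: bool = False,
) -> np.ndarray:
    """Scaled forward recursion over a batch of histories.

    Returns the per-history log-likelihood conditional on first capture.
    Histories whose probability is exactly zero under ``params`` get -inf.
    """
    m, T = events.shape
    gamma = build_transition_matrix(params)
    B = build_event_matrix(params)
    Bf = build_event_matrix(params, at_first_capture=True)
    Brep = _repeat_event_matrices(params) if delta_first_only else None

    init = np.array([params.pi_p, params.pi_h, 0.0])
    alpha = np.zeros((m, 3))
    loglik = np.zeros(m)
    sorted_by_first = bool(np.all(first[:-1] <= first[1:]))
    with np.errstate(divide="ignore"):
        for t in range(T):
            e = events[:, t]
            if sorted_by_first:
                # rows with first < t are the prefix [0:b0); first == t is [b0:b1)
                b0 = int(np.searchsorted(first, t, side="left"))
                b1 = int(np.searchsorted(first, t, side="right"))
                if b1 > b0:
                    alpha[b0:b1] = init * Bf[:, e[b0:b1]].T
                if b0 > 0:
                    prop = alpha[:b0] @ gamma
                    if delta_first_only:
                        obs = Brep[first_class[:b0], :, e[:b0]]
                    else:
                        obs = B[:, e[:b0]].T
                    alpha[:b0] = prop * obs
                act = alpha[:b1]
                s = act.sum(axis=1)
                loglik[:b1] += np.log(s)
                act /= np.where(s > 0.0, s, 1.0)[:, None]
            else:
                start = first == t
                if start.any():
                    alpha[start] = init * Bf[:, e[start]].T
                after = first < t
                if after.any():
                    prop = alpha[after] @ gamma
                    if delta_first_only:
                        obs = Brep[first_class[after], :, e[after]]
                    else:
                        obs = B[:, e[after]].T
                    alpha[after] = prop * obs
                active = first <= t
                s = alpha[active].sum(axis=1)
                loglik[active] += np.log(s)
                alpha[active] /= np.where(s > 0.0, s, 1.0)[:, None]
    return loglik


def _as_history(history) -> EncounterHistory:
    if isinstance(history, EncounterHistory):
        return history
    if isinstance(history, str):
        return EncounterHistory.from_string(history)
    return EncounterHistory(tuple(history))


def history_loglik(history, params: ParameterSet, delta_first_only: bool = False) -> float:
    """Log-probability of one encounter history, conditional on first capture.

    The probability sums over all hidden state sequences: the initial state
    distribution and the first-capture event matrix apply at the first
    detection occasion, transition and event matrices thereafter.  Occasions
    before first detection are ignored.

    Accepts an :class:`EncounterHistory`, an event-code string like ``"303"``,
    or a sequence of ints.
    """
    h = _as_history(history)
    events = np.array([h.events], dtype=np.int64)
    first = np.array([h.first_capture])
    fclass = np.array([h.events[h.first_capture]])
    return float(_batch_forward(events, first, fclass, params, delta_first_only)[0])


def dataset_negloglik(dataset, params: ParameterSet, delta_first_only: bool = False) -> float:
    """Negative log-likelihood of a dataset (histories weighted by count).

    Individual histories are independent, so the dataset log-likelihood is
    the count-weighted sum of the per-history values.
    """
    if not isinstance(dataset, CRDataset):
        dataset = CRDataset([_as_history(h) for h in dataset])
    events, counts, first, fclass = dataset.packed()
    ll = _batch_forward(events, first, fclass, params, delta_first_only)
    return -float(counts @ ll)


def enumerate_history_prob(history, params: ParameterSet, delta_first_only: bool = False) -> float:
    """Brute-force probability by enumerating every hidden state sequence.

    Exponential in T; intended for validation on short histories only.
    """
    h = _as_history(history)
    f = h.first_capture
    n_free = h.T - f
    gamma = build_transition_matrix(params)
    B = build_event_matrix(params)
    Bf = build_event_matrix(params, at_first_capture=True)
    Brep = _repeat_event_matrices(params) if delta_first_only else None
    init = np.array([params.pi_p, params.pi_h, 0.0])
    c = h.events[f]
    total = 0.0
    for path in itertools.product(range(3), repeat=n_free):
        prob = init[path[0]] * Bf[path[0], h.events[f]]
        for k in range(1, n_free):
            prob *= gamma[path[k - 1], path[k]]
            obs = Brep[c] if delta_first_only else B
            prob *= obs[path[k], h.events[f + k]]
        total += prob
    return total
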