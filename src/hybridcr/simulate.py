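"""Cohort simulator and estimator-performance study.

A closed cohort of individuals enters at the first occasion; each is Parental
with probability ``pi_p``, survives between occasions with a state-specific
probability, and while alive is detected and (if detected) classified with
state-specific Bernoulli probabilities.  No recruitment.  Individuals that
are never detected are dropped from the fitted dataset but kept in the truth
accounting, so the realized true prevalence at each occasion uses every
simulated individual alive then, detected or not.

Three canned scenarios mirror a wolf x dog hybridization design:

1. state-dependent detectability (p_p > p_h), homogeneous assignment;
2. homogeneous detectability, state-dependent assignment (delta_p > delta_h);
3. homogeneous detectability and assignment.

Each comes in a low- and a high-detectability variant and with 5 or 10
occasions.  Shared truths: pi_p = 0.7, phi_p = 0.8, phi_h = 0.7.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fit import ModelStructure, fit_model
from .model_core import (
    CRDataset,
    EncounterHistory,
    ParameterSet,
    build_event_matrix,
    build_transition_matrix,
)
from .prevalence import bootstrap_ci, model_prevalence

__all__ = [
    "SimulationScenario",
    "SimulatedDataset",
    "PerformanceTable",
    "make_scenario",
    "generating_structure",
    "simulate_dataset",
    "simulate_cohort",
    "run_performance_study",
]

# Detection / assignment truths per (scenario, detect_level).  The shared
# survival and initial-state truths are fixed; these complete each scenario's
# parameter set.
_SCENARIO_TRUTHS: dict[tuple[int, str], dict[str, float]] = {
    (1, "low"): dict(p_p=0.4, p_h=0.2, delta_p=0.7, delta_h=0.7),
    (1, "high"): dict(p_p=0.8, p_h=0.6, delta_p=0.7, delta_h=0.7),
    (2, "low"): dict(p_p=0.3, p_h=0.3, delta_p=0.9, delta_h=0.6),
    (2, "high"): dict(p_p=0.7, p_h=0.7, delta_p=0.9, delta_h=0.6),
    (3, "low"): dict(p_p=0.3, p_h=0.3, delta_p=0.7, delta_h=0.7),
    (3, "high"): dict(p_p=0.7, p_h=0.7, delta_p=0.7, delta_h=0.7),
}

_SHARED_TRUTHS = dict(pi_p=0.7, phi_p=0.8, phi_h=0.7)


@dataclass(frozen=True)
class SimulationScenario:
    """A simulation design: cohort size, occasions, truth and replication."""

    scenario_id: int
    detect_level: str
    T: int = 5
    n_individuals: int = 100
    n_replicates: int = 100
    truth: ParameterSet = None  # type: ignore[assignment]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario_id not in (1, 2, 3):
            raise ValueError("scenario_id must be 1, 2 or 3")
        if self.detect_level not in ("low", "high"):
            raise ValueError("detect_level must be 'low' or 'high'")
        if self.truth is None:
            object.__setattr__(
                self,
                "truth",
                ParameterSet(
                    **_SHARED_TRUTHS, **_SCENARIO_TRUTHS[(self.scenario_id, self.detect_level)]
                ),
            )
        t = self.truth
        if self.scenario_id == 1 and not (t.p_p > t.p_h and t.delta_p == t.delta_h):
            raise ValueError("scenario 1 requires p_p > p_h and delta_p == delta_h")
        if self.scenario_id == 2 and not (t.p_p == t.p_h and t.delta_p > t.delta_h):
            raise ValueError("scenario 2 requires p_p == p_h and delta_p > delta_h")
        if self.scenario_id == 3 and not (t.p_p == t.p_h and t.delta_p == t.delta_h):
            raise ValueError("scenario 3 requires homogeneous p and delta")


def make_scenario(
    scenario_id: int,
    detect_level: str = "high",
    T: int = 5,
    n_individuals: int = 100,
    n_replicates: int = 100,
    seed: int = 0,
    truth: ParameterSet | None = None,
) -> SimulationScenario:
    return SimulationScenario(
        scenario_id=scenario_id,
        detect_level=detect_level,
        T=T,
        n_individuals=n_individuals,
        n_replicates=n_replicates,
        truth=truth,
        seed=seed,
    )


def generating_structure(scenario: SimulationScenario) -> ModelStructure:
    """The model structure whose sharing pattern matches the scenario's truth."""
    return ModelStructure(
        phi="state",
        p="state" if scenario.scenario_id == 1 else "constant",
        delta="state" if scenario.scenario_id == 2 else "constant",
    )


@dataclass
class SimulatedDataset:
    """One simulated cohort with full truth accounting.

    ``dataset`` holds only the individuals detected at least once;
    ``true_states`` (n_total x T, codes 0=P 1=H 2=D) and ``true_prevalence``
    cover the whole cohort.
    """

    dataset: CRDataset
    true_states: np.ndarray
    events: np.ndarray  # (n_total, T) including never-detected rows
    true_prevalence: np.ndarray  # (T,) hybrids alive / total alive, NaN if none alive
    detected: np.ndarray  # (n_total,) bool


def simulate_dataset(scenario: SimulationScenario, replicate_seed) -> SimulatedDataset:
    """Draw one cohort under the scenario's truth.

    ``replicate_seed`` feeds ``numpy.random.default_rng`` directly, so a
    sequence like ``[master_seed, replicate_index]`` gives a documented,
    reproducible per-replicate stream.
    """
    return simulate_cohort(
        scenario.truth, scenario.n_individuals, scenario.T, replicate_seed
    )


def simulate_cohort(truth: ParameterSet, n: int, T: int, seed) -> SimulatedDataset:
    """Draw one closed cohort under an arbitrary truth (no scenario checks)."""
    rng = np.random.default_rng(seed)
    gamma = build_transition_matrix(truth)
    B = build_event_matrix(truth)

    states = np.zeros((n, T), dtype=np.int64)
    states[:, 0] = (rng.random(n) >= truth.pi_p).astype(np.int64)  # 0=P, 1=H
    for t in range(1, T):
        u = rng.random(n)
        prev = states[:, t - 1]
        cum = gamma.cumsum(axis=1)
        states[:, t] = (u[:, None] >= cum[prev]).sum(axis=1)

    events = np.zeros((n, T), dtype=np.int64)
    u = rng.random((n, T))
    cumB = B.cumsum(axis=1)
    events = (u[:, :, None] >= cumB[states]).sum(axis=2)

    detected = (events != 0).any(axis=1)
    alive = states != 2
    hybrids = states == 1
    with np.errstate(invalid="ignore"):
        true_prev = hybrids.sum(axis=0) / alive.sum(axis=0)

    rows = events[detected]
    histories = [
        EncounterHistory(tuple(int(e) for e in row), id=f"sim{i + 1}")
        for i, row in enumerate(rows)
    ]
    return SimulatedDataset(
        dataset=CRDataset(histories),
        true_states=states,
        events=events,
        true_prevalence=true_prev,
        detected=detected,
    )


def parameter_recovery(
    scenario: SimulationScenario,
    fit_structure: ModelStructure | None = None,
    n_starts: int = 5,
) -> pd.DataFrame:
    """Per-replicate ML estimates of every model parameter.

    Simulates ``scenario.n_replicates`` cohorts, fits ``fit_structure``
    (default: the generating structure) to each, and returns one row per
    converged replicate with the seven state-expanded estimates.  Used to
    check that estimation is unbiased under the generating model.
    """
    if fit_structure is None:
        fit_structure = generating_structure(scenario)
    rows = []
    for r in range(scenario.n_replicates):
        sim = simulate_dataset(scenario, [scenario.seed, r])
        try:
            f = fit_model(
                sim.dataset, fit_structure, n_starts=n_starts,
                seed=int(3_000_000 + r), compute_se=False,
            )
        except RuntimeError:
            continue
        if not f.converged:
            continue
        rows.append(dict(replicate=r, **f.estimates.as_dict()))
    if not rows:
        raise RuntimeError("no replicate produced a converged fit")
    return pd.DataFrame(rows)


@dataclass
class PerformanceTable:
    """Aggregated estimator performance across simulation replicates."""

    scenario: SimulationScenario
    rmse_naive: np.ndarray
    rmse_model: np.ndarray
    relbias_naive: np.ndarray
    relbias_model: np.ndarray
    coverage_model: np.ndarray  # NaN when no bootstrap was run
    n_replicates_used: int
    n_replicates_failed: int
    naive_estimates: np.ndarray = field(repr=False, default=None)  # (R, T)
    model_estimates: np.ndarray = field(repr=False, default=None)
    true_prevalence: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        T = len(self.rmse_naive)
        return pd.DataFrame(
            dict(
                occasion=np.arange(1, T + 1),
                rmse_naive=self.rmse_naive,
                rmse_model=self.rmse_model,
                relbias_naive=self.relbias_naive,
                relbias_model=self.relbias_model,
                coverage_model=self.coverage_model,
                n_replicates=self.n_replicates_used,
            )
        )


def run_performance_study(
    scenario: SimulationScenario,
    fit_structure: ModelStructure | None = None,
    B_bootstrap: int = 0,
    n_starts: int = 3,
) -> PerformanceTable:
    """Simulate-fit-decode across replicates and score both estimators.

    Per replicate: simulate a cohort, fit ``fit_structure`` (default: the
    generating structure), Viterbi-decode, and record naive (raw certain-event
    tallies) and model-based prevalence per occasion.  With ``B_bootstrap >
    0`` a percentile CI is computed per replicate and coverage scored against
    the replicate's own realized true prevalence.

    RMSE and relative bias are averaged over replicates per occasion,
    NaN-aware (an occasion with no classified detections contributes nothing
    for that replicate).
    """
    if fit_structure is None:
        fit_structure = generating_structure(scenario)
    R, T = scenario.n_replicates, scenario.T
    naive = np.full((R, T), np.nan)
    model = np.full((R, T), np.nan)
    truthp = np.full((R, T), np.nan)
    covered = np.full((R, T), np.nan)
    n_failed = 0

    for r in range(R):
        sim = simulate_dataset(scenario, [scenario.seed, r])
        try:
            f = fit_model(
                sim.dataset, fit_structure, n_starts=n_starts, seed=int(1_000_000 + r),
                compute_se=False,
            )
        except RuntimeError:
            n_failed += 1
            continue
        if not f.converged:
            n_failed += 1
            continue
        est = model_prevalence(sim.dataset, f)
        naive[r] = est.P_naive
        model[r] = est.P_model
        truthp[r] = sim.true_prevalence
        if B_bootstrap > 0:
            boot = bootstrap_ci(
                sim.dataset,
                fit_structure,
                B=B_bootstrap,
                seed=int(2_000_000 + r),
                base_fit=f,
            )
            ok = ~(np.isnan(boot.ci_lo) | np.isnan(sim.true_prevalence))
            covered[r, ok] = (
                (boot.ci_lo[ok] <= sim.true_prevalence[ok])
                & (sim.true_prevalence[ok] <= boot.ci_hi[ok])
            ).astype(float)

    if n_failed == R:
        raise RuntimeError("all simulation replicates failed to fit")

    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)
        rmse_n = np.sqrt(np.nanmean((naive - truthp) ** 2, axis=0))
        rmse_m = np.sqrt(np.nanmean((model - truthp) ** 2, axis=0))
        relb_n = np.nanmean((naive - truthp) / truthp, axis=0)
        relb_m = np.nanmean((model - truthp) / truthp, axis=0)
        cov = np.nanmean(covered, axis=0)
    return PerformanceTable(
        scenario=scenario,
        rmse_naive=rmse_n,
        rmse_model=rmse_m,
        relbias_naive=relb_n,
        relbias_model=relb_m,
        coverage_model=cov,
        n_replicates_used=R - n_failed,
        n_replicates_failed=n_failed,
        naive_estimates=naive,
        model_estimates=model,
        true_prevalence=truthp,
    )
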