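"""Naive and model-based hybrid prevalence with bootstrap confidence intervals.

Naive prevalence is the raw proportion of observed hybrids among classified
detections and ignores both imperfect detection and the uncertain
individuals.  The model-based estimate Viterbi-assigns uncertain detections,
inflates the per-class counts by the estimated detection probabilities
(Horvitz-Thompson) and takes the hybrid share of total abundance:

    N_hat_tot = n_p / p_hat_p + n_h / p_hat_h = N_hat_p + N_hat_h
    P_model   = N_hat_h / (N_hat_p + N_hat_h)

Confidence intervals come from a nonparametric bootstrap that resamples
individual encounter histories (the independent units of the likelihood),
refits the model and recomputes the prevalence per occasion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decode import assigned_counts
from .fit import FitResult, ModelAverage, ModelStructure, fit_model
from .model_core import CRDataset, ParameterSet

__all__ = [
    "naive_prevalence",
    "ht_abundance",
    "model_prevalence",
    "bootstrap_ci",
    "prevalence_report",
    "PrevalenceEstimate",
    "BootstrapResult",
]

logger = logging.getLogger(__name__)

HT_DETECTION_FLOOR = 0.05


def naive_prevalence(n_h: float, n_p: float) -> float:
    """Proportion of observed hybrids among classified detections; NaN if none."""
    if n_h < 0 or n_p < 0:
        raise ValueError("counts must be nonnegative")
    tot = n_h + n_p
    if tot == 0:
        return float("nan")
    return n_h / tot


def ht_abundance(
    n_p: float,
    n_h: float,
    p_hat_p: float,
    p_hat_h: float,
    floor: float = HT_DETECTION_FLOOR,
) -> tuple[float, float, float]:
    """Horvitz-Thompson abundances (N_hat_p, N_hat_h, N_hat_tot).

    Each observed count is divided by its class's estimated detection
    probability.  Detection estimates below ``floor`` trigger a warning:
    the estimator becomes unstable as p_hat -> 0.
    """
    for name, p in (("p_hat_p", p_hat_p), ("p_hat_h", p_hat_h)):
        if not (0.0 < p <= 1.0):
            raise ValueError(f"{name}={p!r} must be in (0, 1]")
        if p < floor:
            warnings.warn(
                f"{name}={p:.4f} is below {floor}; Horvitz-Thompson abundance is unstable",
                stacklevel=2,
            )
    N_p = n_p / p_hat_p
    N_h = n_h / p_hat_h
    return N_p, N_h, N_p + N_h


@dataclass
class PrevalenceEstimate:
    """Per-occasion prevalence report (1-based occasions).

    ``n_p``/``n_h`` are Viterbi-assigned detection counts; ``raw_n_p``/
    ``raw_n_h`` tally only certain events (1 and 2) and feed the naive
    estimate.  CI fields are NaN until a bootstrap is attached.
    """

    occasions: np.ndarray
    n_p: np.ndarray
    n_h: np.ndarray
    raw_n_p: np.ndarray
    raw_n_h: np.ndarray
    N_hat_p: np.ndarray
    N_hat_h: np.ndarray
    N_hat_tot: np.ndarray
    P_naive: np.ndarray
    P_model: np.ndarray
    ci_level: float = 0.95
    ci_lo: np.ndarray | None = None
    ci_hi: np.ndarray | None = None
    B: int = 0
    seed: int | None = None
    n_boot_failed: int = 0

    def to_frame(self) -> pd.DataFrame:
        T = len(self.occasions)
        return pd.DataFrame(
            dict(
                occasion=self.occasions,
                n_p=self.n_p,
                n_h=self.n_h,
                N_hat_p=self.N_hat_p,
                N_hat_h=self.N_hat_h,
                P_naive=self.P_naive,
                P_model=self.P_model,
                ci_lo=self.ci_lo if self.ci_lo is not None else np.full(T, np.nan),
                ci_hi=self.ci_hi if self.ci_hi is not None else np.full(T, np.nan),
            )
        )


def _resolve_params(fitted) -> tuple[ParameterSet, bool]:
    if isinstance(fitted, FitResult):
        return fitted.estimates, fitted.structure.delta_first_only
    if isinstance(fitted, ModelAverage):
        return fitted.estimates, False
    if isinstance(fitted, ParameterSet):
        return fitted, False
    raise TypeError(f"expected FitResult, ModelAverage or ParameterSet, got {type(fitted)!r}")


def raw_certain_counts(dataset: CRDataset) -> tuple[np.ndarray, np.ndarray]:
    """Per-occasion tallies of certain events: (#event 1, #event 2)."""
    events, counts, _, _ = dataset.packed()
    n1 = ((events == 1) * counts[:, None]).sum(axis=0).astype(np.int64)
    n2 = ((events == 2) * counts[:, None]).sum(axis=0).astype(np.int64)
    return n1, n2


def model_prevalence(
    dataset: CRDataset, fitted, delta_first_only: bool | None = None
) -> PrevalenceEstimate:
    """Point estimates of naive and model-based prevalence per occasion.

    ``fitted`` may be a :class:`FitResult`, a :class:`ModelAverage`, or a
    bare :class:`ParameterSet`.  Occasions with zero detections yield NaN
    prevalence and are logged.
    """
    params, dfo = _resolve_params(fitted)
    if delta_first_only is not None:
        dfo = delta_first_only
    T = dataset.T
    n_p, n_h = assigned_counts(dataset, params, dfo)
    raw_p, raw_h = raw_certain_counts(dataset)

    N_p = np.full(T, np.nan)
    N_h = np.full(T, np.nan)
    P_model = np.full(T, np.nan)
    P_naive = np.array([naive_prevalence(h, p) for h, p in zip(raw_h, raw_p)])
    for t in range(T):
        if n_p[t] + n_h[t] == 0:
            logger.info("occasion %d has no detections; prevalence undefined", t + 1)
            continue
        N_p[t], N_h[t], _ = ht_abundance(n_p[t], n_h[t], params.p_p, params.p_h)
        P_model[t] = N_h[t] / (N_p[t] + N_h[t])
    return PrevalenceEstimate(
        occasions=np.arange(1, T + 1),
        n_p=n_p,
        n_h=n_h,
        raw_n_p=raw_p,
        raw_n_h=raw_h,
        N_hat_p=N_p,
        N_hat_h=N_h,
        N_hat_tot=N_p + N_h,
        P_naive=P_naive,
        P_model=P_model,
    )


@dataclass
class BootstrapResult:
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    level: float
    B: int
    n_failed: int
    replicates: np.ndarray  # (B_used, T) bootstrap P_model values


def bootstrap_ci(
    dataset: CRDataset,
    structure: ModelStructure,
    B: int = 500,
    seed: int | None = None,
    level: float = 0.95,
    base_fit: FitResult | None = None,
    max_failure_rate: float = 0.2,
) -> BootstrapResult:
    """Percentile bootstrap intervals for model-based prevalence per occasion.

    Individuals (rows, with multiplicity unrolled) are resampled with
    replacement; each resample is refit — warm-started at the original
    estimates — then decoded, and its per-occasion prevalence recorded.
    Non-converged resamples are dropped and counted; a failure rate above
    ``max_failure_rate`` raises, suggesting a simpler structure.
    """
    rng = np.random.default_rng(seed)
    if base_fit is None:
        base_fit = fit_model(dataset, structure, n_starts=5, seed=seed)
    individuals = dataset.expand()
    n = len(individuals)
    T = dataset.T
    start = structure.truth_vector(base_fit.estimates)

    reps = np.full((B, T), np.nan)
    n_failed = 0
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        boot = CRDataset([individuals[i] for i in idx])
        try:
            f = fit_model(
                boot, structure, n_starts=1, seed=None, start=start, compute_se=False
            )
        except RuntimeError:
            n_failed += 1
            continue
        if not f.converged:
            n_failed += 1
            continue
        reps[b] = model_prevalence(boot, f).P_model
    used = reps[~np.isnan(reps).all(axis=1)]
    if n_failed > max_failure_rate * B:
        raise RuntimeError(
            f"{n_failed}/{B} bootstrap resamples failed to converge; "
            "consider a simpler model structure"
        )
    alpha = (1.0 - level) / 2.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN occasions
        lo = np.nanpercentile(used, 100 * alpha, axis=0)
        hi = np.nanpercentile(used, 100 * (1 - alpha), axis=0)
    if n_failed:
        logger.info("bootstrap: dropped %d/%d non-converged resamples", n_failed, B)
    return BootstrapResult(ci_lo=lo, ci_hi=hi, level=level, B=B, n_failed=n_failed, replicates=used)


def prevalence_report(
    dataset: CRDataset,
    structure: ModelStructure,
    B: int = 500,
    seed: int | None = None,
    level: float = 0.95,
    n_starts: int = 10,
) -> PrevalenceEstimate:
    """Fit, decode, estimate prevalence and attach bootstrap CIs in one call."""
    base = fit_model(dataset, structure, n_starts=n_starts, seed=seed)
    est = model_prevalence(dataset, base)
    boot = bootstrap_ci(dataset, structure, B=B, seed=seed, level=level, base_fit=base)
    est.ci_lo, est.ci_hi = boot.ci_lo, boot.ci_hi
    est.ci_level = level
    est.B = B
    est.seed = seed
    est.n_boot_failed = boot.n_failed
    return est
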