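"""Maximum-likelihood fitting of multievent model structures.

A model structure declares, for each parameter family (pi, phi, p, delta),
whether it is shared between the Parental and Hybrid states ("constant") or
"state"-dependent, plus an optional rule restricting assignment to the first
capture.  Free parameters are optimized on the logit scale with multi-start
local optimization; standard errors come from the inverse numerical Hessian
with a delta-method back-transform.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit
from statsmodels.tools.numdiff import approx_hess

from .model_core import CRDataset, ParameterSet, _batch_forward

__all__ = [
    "ModelStructure",
    "FitResult",
    "fit_model",
    "aicc",
    "model_average",
    "select_models",
    "ModelAverage",
]

_EXPANDED_NAMES = ("pi_p", "phi_p", "phi_h", "p_p", "p_h", "delta_p", "delta_h")

# markers accepted by the structure mini-language
_CONST = {".", "i", "constant"}
_STATE = {"state", "f", "s"}


@dataclass(frozen=True)
class ModelStructure:
    """Which parameters are constant vs state-dependent.

    ``pi`` always has exactly one free parameter (``pi_h = 1 - pi_p``).
    ``delta_first_only=True`` models classification only at the first
    capture; re-detections repeat the first recorded class deterministically
    (the rule used when state assessment is done once per individual).
    """

    phi: str = "constant"
    p: str = "constant"
    delta: str = "constant"
    delta_first_only: bool = False

    def __post_init__(self) -> None:
        for fam in ("phi", "p", "delta"):
            if getattr(self, fam) not in ("constant", "state"):
                raise ValueError(f"{fam} must be 'constant' or 'state', got {getattr(self, fam)!r}")

    @property
    def K(self) -> int:
        """Number of free parameters."""
        return 1 + sum(2 if getattr(self, fam) == "state" else 1 for fam in ("phi", "p", "delta"))

    @property
    def param_names(self) -> tuple[str, ...]:
        names = ["pi_p"]
        for fam in ("phi", "p", "delta"):
            if getattr(self, fam) == "state":
                names += [f"{fam}_p", f"{fam}_h"]
            else:
                names.append(fam)
        return tuple(names)

    @property
    def label(self) -> str:
        def mark(fam: str) -> str:
            s = "state" if getattr(self, fam) == "state" else "."
            if fam == "delta" and self.delta_first_only:
                s += ",first"
            return s

        return f"pi(.)phi({mark('phi')})p({mark('p')})delta({mark('delta')})"

    @classmethod
    def parse(cls, text: str) -> "ModelStructure":
        """Parse a structure string like ``"pi(.) phi(state) p(.) delta(.,first)"``.

        ``(.)`` or ``(i)`` marks a constant parameter, ``(state)`` or ``(f)``
        a state-dependent one.  For delta, appending ``first`` (or the
        shorthand ``a1+a2_fix``) restricts assignment to first capture.
        Families not mentioned default to constant.
        """
        spec: dict[str, str] = {}
        first_only = False
        for fam, arg in re.findall(r"(pi|phi|p|delta)\s*\(([^)]*)\)", text.replace(" ", "")):
            tokens = [t for t in re.split(r"[,+\s]+", arg.strip().lower()) if t]
            if fam == "delta" and any(t in ("first", "a1", "a2_fix", "a1+a2_fix") for t in tokens):
                first_only = True
                tokens = [t for t in tokens if t not in ("first", "a1", "a2_fix")]
            kind = tokens[0] if tokens else "."
            if kind in _CONST:
                spec[fam] = "constant"
            elif kind in _STATE:
                spec[fam] = "state"
            else:
                raise ValueError(f"unknown specifier {kind!r} for {fam} in {text!r}")
        spec.pop("pi", None)  # pi always has one free parameter
        return cls(
            phi=spec.get("phi", "constant"),
            p=spec.get("p", "constant"),
            delta=spec.get("delta", "constant"),
            delta_first_only=first_only,
        )

    def expand(self, probs: np.ndarray) -> ParameterSet:
        """Map a free-parameter vector (probability scale) to a ParameterSet."""
        vals = {}
        i = 0
        vals["pi_p"] = probs[0]
        i = 1
        for fam in ("phi", "p", "delta"):
            if getattr(self, fam) == "state":
                vals[f"{fam}_p"], vals[f"{fam}_h"] = probs[i], probs[i + 1]
                i += 2
            else:
                vals[f"{fam}_p"] = vals[f"{fam}_h"] = probs[i]
                i += 1
        return ParameterSet(**vals)

    def truth_vector(self, params: ParameterSet) -> np.ndarray:
        """Free-parameter vector (probability scale) implied by ``params``."""
        out = [params.pi_p]
        for fam in ("phi", "p", "delta"):
            if getattr(self, fam) == "state":
                out += [getattr(params, f"{fam}_p"), getattr(params, f"{fam}_h")]
            else:
                out.append(getattr(params, f"{fam}_p"))
        return np.array(out)


@dataclass(eq=False)
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    structure: ModelStructure
    estimates: ParameterSet
    theta: np.ndarray  # working (logit) scale
    param_names: tuple[str, ...]
    loglik: float
    deviance: float
    K: int
    n_individuals: int
    aicc: float
    se: dict[str, float] | None
    ci95: dict[str, tuple[float, float]] | None
    converged: bool
    identifiable: bool
    diagnostics: dict = field(default_factory=dict)

    def expanded_se(self) -> dict[str, float]:
        """SEs mapped onto the seven state-expanded parameter names."""
        out: dict[str, float] = {}
        if self.se is None:
            return {n: np.nan for n in _EXPANDED_NAMES}
        for fam in ("phi", "p", "delta"):
            if getattr(self.structure, fam) == "constant":
                out[f"{fam}_p"] = out[f"{fam}_h"] = self.se[fam]
            else:
                out[f"{fam}_p"] = self.se[f"{fam}_p"]
                out[f"{fam}_h"] = self.se[f"{fam}_h"]
        out["pi_p"] = self.se["pi_p"]
        return out


def aicc(fit: FitResult, n_effective: int) -> float:
    """Small-sample corrected AIC: deviance + 2K + 2K(K+1)/(n - K - 1)."""
    K = fit.K
    if n_effective <= K + 1:
        raise ValueError(f"n_effective={n_effective} must exceed K+1={K + 1} for AICc")
    return fit.deviance + 2 * K + 2 * K * (K + 1) / (n_effective - K - 1)


def fit_model(
    dataset: CRDataset,
    structure: ModelStructure,
    n_starts: int = 10,
    seed: int | None = None,
    tol: float = 1e-8,
    start: np.ndarray | None = None,
    compute_se: bool = True,
    n_effective: int | None = None,
    c_hat: float = 1.0,
    boundary_tol: float = 1e-4,
) -> FitResult:
    """Maximize the likelihood of ``dataset`` under ``structure``.

    Free parameters are optimized on the logit scale with ``n_starts``
    random restarts (plus an optional warm ``start``, on the probability
    scale); the best local optimum is retained.  ``c_hat > 1`` applies a
    quasi-likelihood overdispersion correction to the deviance used in AICc.

    Boundary estimates (within ``boundary_tol`` of 0 or 1) are flagged in
    ``diagnostics['boundary']``; a singular or ill-conditioned Hessian sets
    ``identifiable=False``.
    """
    events, counts, first, fclass = dataset.packed()
    dfo = structure.delta_first_only
    K = structure.K

    def nll(theta: np.ndarray) -> float:
        if not np.all(np.isfinite(theta)):
            return np.inf
        params = structure.expand(expit(theta))
        ll = _batch_forward(events, first, fclass, params, dfo)
        return -float(counts @ ll)

    rng = np.random.default_rng(seed)
    starts: list[np.ndarray] = []
    if start is not None:
        starts.append(logit(np.clip(np.asarray(start, float), 1e-6, 1 - 1e-6)))
    if len(starts) < max(n_starts, 1):
        starts.append(np.zeros(K))
    while len(starts) < max(n_starts, 1):
        starts.append(rng.uniform(-2.5, 2.5, size=K))

    best = None
    any_ok = False
    for x0 in starts:
        res = minimize(nll, x0, method="L-BFGS-B", options={"ftol": tol, "maxiter": 500})
        if not np.isfinite(res.fun):
            continue
        any_ok = any_ok or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError("likelihood is degenerate at every start (is the data compatible with the structure?)")

    theta = np.asarray(best.x, float)
    probs = expit(theta)
    estimates = structure.expand(probs)
    loglik = -float(best.fun)
    deviance = 2.0 * float(best.fun)
    names = structure.param_names

    diagnostics: dict = {}
    se = ci95 = None
    identifiable = True
    boundary = [n for n, v in zip(names, probs) if v < boundary_tol or v > 1 - boundary_tol]
    if boundary:
        # the logit-scale Hessian degenerates at 0/1, so Wald inference
        # (and hence the estimability check) is invalid for these parameters
        diagnostics["boundary"] = boundary
        diagnostics["identifiability"] = (
            f"estimates at the boundary of [0, 1]: {', '.join(boundary)}"
        )
        identifiable = False
    if compute_se:
        try:
            H = approx_hess(theta, nll)
            evals = np.linalg.eigvalsh(H)
            cond = float(evals.max() / evals.min()) if evals.min() > 0 else np.inf
            diagnostics["hessian_condition"] = cond
            if evals.min() <= 0 or cond > 1e8:
                identifiable = False
                diagnostics["identifiability"] = (
                    "Hessian not positive definite or ill-conditioned; "
                    "some parameters are not estimable from these data"
                )
            cov = np.linalg.pinv(H)
            se_logit = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
            se_prob = se_logit * probs * (1 - probs)
            lo = expit(theta - 1.959963984540054 * se_logit)
            hi = expit(theta + 1.959963984540054 * se_logit)
            se = dict(zip(names, se_prob))
            ci95 = {n: (float(l), float(h)) for n, l, h in zip(names, lo, hi)}
        except np.linalg.LinAlgError:
            identifiable = False
            diagnostics["identifiability"] = "Hessian could not be inverted"

    n_ind = dataset.n_individuals
    n_eff = n_effective if n_effective is not None else n_ind
    fit = FitResult(
        structure=structure,
        estimates=estimates,
        theta=theta,
        param_names=names,
        loglik=loglik,
        deviance=deviance,
        K=K,
        n_individuals=n_ind,
        aicc=np.nan,
        se=se,
        ci95=ci95,
        converged=any_ok,
        identifiable=identifiable,
        diagnostics=diagnostics,
    )
    fit.deviance = deviance / c_hat if c_hat != 1.0 else deviance
    fit.aicc = aicc(fit, n_eff) if n_eff > K + 1 else np.nan
    return fit


@dataclass
class ModelAverage:
    """Akaike-weighted average across candidate model fits."""

    estimates: ParameterSet
    weights: np.ndarray
    models: list[str]
    se: dict[str, float]
    ci95: dict[str, tuple[float, float]]


def model_average(fits: list[FitResult]) -> ModelAverage:
    """Average parameter estimates over models with Akaike weights.

    Weights are ``w_i = exp(-d_i/2) / sum_j exp(-d_j/2)`` from AICc
    differences; each state-expanded parameter is averaged at its
    structure-implied value per model.  The unconditional standard error
    follows Burnham & Anderson:
    ``se_u = sum_i w_i * sqrt(var_i + (theta_i - theta_bar)^2)``.
    Only converged, identifiable fits enter the average.
    """
    usable = [f for f in fits if f.converged and f.identifiable and np.isfinite(f.aicc)]
    if not usable:
        raise ValueError("no converged, identifiable fits to average")
    a = np.array([f.aicc for f in usable])
    d = a - a.min()
    w = np.exp(-d / 2.0)
    w /= w.sum()

    est: dict[str, float] = {}
    se_u: dict[str, float] = {}
    ci: dict[str, tuple[float, float]] = {}
    for name in _EXPANDED_NAMES:
        vals = np.array([getattr(f.estimates, name) for f in usable])
        ses = np.array([f.expanded_se()[name] for f in usable])
        bar = float(w @ vals)
        su = float(w @ np.sqrt(ses**2 + (vals - bar) ** 2))
        est[name] = bar
        se_u[name] = su
        ci[name] = (max(0.0, bar - 1.96 * su), min(1.0, bar + 1.96 * su))
    return ModelAverage(
        estimates=ParameterSet(**est),
        weights=w,
        models=[f.structure.label for f in usable],
        se=se_u,
        ci95=ci,
    )


def select_models(fits: list[FitResult], delta_threshold: float = 2.0) -> pd.DataFrame:
    """Rank fits by AICc; models within ``delta_threshold`` are 'supported'.

    Non-identifiable or non-converged fits are excluded from the ranking but
    reported at the bottom with no delta/weight.
    """
    if not fits:
        raise ValueError("no fits to rank")
    rows = []
    ranked = [f for f in fits if f.converged and f.identifiable and np.isfinite(f.aicc)]
    excluded = [f for f in fits if f not in ranked]
    if ranked:
        amin = min(f.aicc for f in ranked)
        dd = np.array([f.aicc - amin for f in ranked])
        ww = np.exp(-dd / 2.0)
        ww /= ww.sum()
    for f, dlt, wt in sorted(
        zip(ranked, dd, ww) if ranked else [], key=lambda x: x[1]
    ):
        rows.append(
            dict(
                model=f.structure.label,
                K=f.K,
                deviance=f.deviance,
                aicc=f.aicc,
                delta_aicc=float(dlt),
                weight=float(wt),
                supported=bool(dlt <= delta_threshold),
                converged=f.converged,
                identifiable=f.identifiable,
            )
        )
    for f in excluded:
        rows.append(
            dict(
                model=f.structure.label,
                K=f.K,
                deviance=f.deviance,
                aicc=np.nan,
                delta_aicc=np.nan,
                weight=np.nan,
                supported=False,
                converged=f.converged,
                identifiable=f.identifiable,
            )
        )
    return pd.DataFrame(rows)
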