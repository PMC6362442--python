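# hybridcr

Multievent capture–recapture estimation of the prevalence of hybrids in an
animal population, under imperfect detection and uncertain state assignment.

## The problem

Monitoring hybridization (for example wolf × dog admixture from non-invasively
collected scats) yields individual encounter histories over discrete capture
occasions.  At each occasion an individual is either not detected, or detected
and classified as *parental*, as *hybrid*, or — when the genetic or
morphological evidence is inconclusive — as *uncertain*.  The raw ("naive")
proportion of observed hybrids is a biased estimate of hybrid prevalence
whenever the two classes differ in detectability or in how often they can be
classified, and it has no principled way to use the uncertain individuals.

`hybridcr` implements a hidden Markov (multievent) capture–recapture model
that separates the biological process from the observation process:

* **States** (latent): alive-parental *P*, alive-hybrid *H*, dead *D*
  (absorbing; no transitions between *P* and *H*).
* **State process**: an individual is *P* at first encounter with probability
  π_p; it survives each interval with state-specific apparent survival
  φ_p or φ_h.
* **Observation process**: an alive individual is detected with probability
  p_p or p_h; a detected individual is assigned to its state with probability
  δ_p or δ_h, and recorded as uncertain otherwise.  Events are coded
  0 = not detected, 1 = detected as parental, 2 = detected as hybrid,
  3 = detected as uncertain.

The likelihood of each history is computed by a scaled forward recursion,
conditional on the first detection (the capture process is not modelled at
first encounter, but the classification is).  Parameters are estimated by
maximum likelihood on the logit scale with multi-start optimization; model
structures (constant vs state-dependent parameter families) are compared by
AICc, with Akaike-weight model averaging.

Prevalence at occasion *t* is then estimated in three steps:

1. **Viterbi decoding** assigns every uncertain detection to its most
   probable state, giving per-occasion counts n_p(t), n_h(t);
2. **Horvitz–Thompson abundance** corrects for detection:
   N̂_p = n_p/p̂_p, N̂_h = n_h/p̂_h;
3. **model-based prevalence** P_model(t) = N̂_h / (N̂_p + N̂_h), with
   percentile confidence intervals from a nonparametric bootstrap that
   resamples individual histories.

A simulation engine generates closed cohorts under three canned scenarios
(state-dependent detectability; state-dependent assignment; fully
homogeneous) and scores naive vs model-based prevalence by RMSE, relative
bias and bootstrap-CI coverage.

## Worked example

```python
import numpy as np
from hybridcr import (make_scenario, simulate_dataset, generating_structure,
                      fit_model, model_prevalence)

sc = make_scenario(scenario_id=1, detect_level="high", T=5,
                   n_individuals=100, seed=7)        # p_p=0.8 > p_h=0.6
sim = simulate_dataset(sc, replicate_seed=[7, 0])
fit = fit_model(sim.dataset, generating_structure(sc), seed=0)
est = model_prevalence(sim.dataset, fit)
print(est.to_frame().round(3).to_string(index=False))
```

```
 occasion  n_p  n_h  N_hat_p  N_hat_h  P_naive  P_model  ci_lo  ci_hi
        1   62   11   75.277   22.108    0.180    0.227    NaN    NaN
        2   50    8   60.707   16.079    0.178    0.209    NaN    NaN
        3   38    8   46.138   16.079    0.167    0.258    NaN    NaN
        4   30    1   36.424    2.010    0.043    0.052    NaN    NaN
        5   26    1   31.568    2.010    0.048    0.060    NaN    NaN
```

`n_p`/`n_h` are the per-occasion detection counts after Viterbi assignment of
the uncertain individuals, and `N_hat_*` the Horvitz–Thompson abundances.
Hybrids are harder to detect than parentals in this scenario, so the naive
proportion (`P_naive`, computed from certain classifications only) sits below
the realized true prevalence — `sim.true_prevalence` is
`[0.250 0.213 0.193 0.116 0.059]` for this cohort — at every occasion, while
the model-based estimate (`P_model`) corrects both the uncertain
classifications (via decoding) and the detection imbalance (via
Horvitz–Thompson).  Attach bootstrap confidence intervals with
`prevalence_report(sim.dataset, generating_structure(sc), B=500, seed=7)`.

The same pipeline is available from the shell:

```bash
hybridcr simulate --scenario 1 --detect high -T 5 --n 100 --seed 42 --out hist.csv
hybridcr fit --data hist.csv --structure "pi(.) phi(state) p(state) delta(.)"
hybridcr prevalence --data hist.csv --structure "pi(.) phi(state) p(state) delta(.)" --B 500 --seed 7
hybridcr study --scenario 1 --detect high --reps 100 --seed 0
```

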