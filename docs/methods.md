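# Methods

## Model

`hybridcr` treats encounter histories as realizations of a hidden Markov
chain observed through a noisy classification channel, conditional on first
capture — the multievent formulation of capture–recapture.

**States.**  Parental (P), Hybrid (H), Dead (D), in that fixed order.
"Hybrid" covers every admixture class, not only first-generation crosses.
D is absorbing and P↔H transitions are structurally zero: an individual's
hybridization status is a property of its genotype and cannot change, so the
only state dynamic is survival.  The transition matrix (rows = state at t,
columns = state at t+1) is

```
        P      H      D
P  [  φ_p     0    1−φ_p ]
H  [   0     φ_h   1−φ_h ]
D  [   0      0      1   ]
```

φ is *apparent* survival: it confounds mortality with permanent emigration.

**Events.**  0 = not detected, 1 = detected as parental, 2 = detected as
hybrid, 3 = detected as uncertain, in fixed column order.  Away from the
first capture the event matrix is the product of a detection step and an
assignment step:

```
        0          1         2         3
P  [ 1−p_p      p_p·δ_p      0     p_p·(1−δ_p) ]
H  [ 1−p_h        0      p_h·δ_h   p_h·(1−δ_h) ]
D  [   1          0          0          0      ]
```

A parental can never be recorded as event 2 (nor a hybrid as event 1):
misclassification between the two alive classes is assumed impossible; the
only classification failure mode is "uncertain".

**Conditioning on first capture.**  An individual enters the dataset only
because it was detected at least once, so the detection probability at the
first encounter carries no information and is conditioned out.  At that
occasion the initial state distribution (π_p, 1−π_p) applies together with
an assignment-only event matrix (row P: event 1 with probability δ_p, event
3 otherwise; analogously for H).  Occasions before the first detection are
ignored entirely.  For a three-occasion history "303" this yields exactly a
two-term sum — the all-Hybrid and the all-Parental path — which the test
suite checks in closed form.

**Likelihood.**  Per-history likelihoods are computed by a forward recursion
with per-occasion scaling (normalizing the forward vector and accumulating
log scale factors), which is exact and underflow-safe for long histories.
Identical histories are merged and weighted by their multiplicity.  The
recursion is vectorized across histories, with rows sorted by first-capture
occasion so that the "already entered" set is a contiguous array prefix;
this matters because bootstrap and simulation studies perform 10^4–10^5
likelihood maximizations.

**First-capture-only assignment** (`delta_first_only`).  When the state
assessment is performed once per individual (one genotype, assessed once),
re-detections repeat the first recorded class deterministically: an
individual first recorded uncertain emits event 3 at every later detection
with probability 1, and certain individuals repeat events 1/2.  The
post-first-capture event matrix then carries detection information only.
This is the "assignment estimated at first capture only" constraint used
when fitting sparse field datasets.  A history that violates the repeat rule
(e.g. event 1 followed by event 3 under this model) has probability zero and
log-likelihood −inf, which surfaces immediately rather than silently.

## Estimation

Free parameters are the logits of π_p and of one or two values per family
(φ, p, δ) depending on the declared structure; "constant" ties the P and H
values.  Optimization is L-BFGS-B on the unconstrained scale, relative
function tolerance 1e−8, with multi-start (default 10: a logit-0 start plus
uniform(−2.5, 2.5) random starts) keeping the best local optimum.  Standard
errors come from the inverse numerical Hessian on the working scale
(`statsmodels.tools.numdiff.approx_hess`), delta-method-transformed to the
probability scale; 95% Wald intervals are formed on the logit scale and
back-transformed so they respect [0, 1].

**Identifiability flagging.**  A fit is flagged non-identifiable when the
Hessian is not positive definite, its condition number exceeds 1e8, or any
estimate sits within 1e−4 of 0 or 1.  The boundary rule is deliberate: at a
boundary the logit-scale Hessian degenerates and Wald inference is invalid,
so such fits are excluded from AICc ranking and model averaging (they are
still reported).  Typical triggers: datasets with no uncertain observations
(δ̂ → 1) and small samples fitted with state-dependent δ.

**Model selection and averaging.**  AICc = deviance + 2K + 2K(K+1)/(n−K−1)
with n defaulting to the number of individuals (configurable; no effective-
sample-size convention is universal for capture–recapture).  An
overdispersion factor ĉ > 1 may be supplied, turning the criterion into
QAICc.  Models within ΔAICc ≤ 2 are marked "supported".  Averaging uses
Akaike weights w_i ∝ exp(−Δ_i/2); each state-expanded parameter is averaged
at its structure-implied value per model, with Burnham–Anderson
unconditional standard errors
se_u = Σ w_i √(var_i + (θ̂_i − θ̄)²).

## Prevalence

Naive prevalence at occasion t is n_h/(n_p+n_h) from **certain** events only
(1 and 2): uncertain individuals are unclassified in the raw data, so they
are excluded from the naive tally, mirroring a field count.  Model-based
prevalence Viterbi-decodes every individual (ties broken toward P, the first
state in order — ties arise only on degenerate parameter sets), reconstructs
per-occasion assigned counts, inflates them by the fitted state-specific
detection probabilities (Horvitz–Thompson) and takes the hybrid share.  When
p̂_p = p̂_h the inflation cancels and P_model reduces exactly to the
assigned-count proportion (tested as an algebraic identity).  Decoding
defaults to the point estimates of whichever fit (or model average) is
supplied; both decode-with-averaged-parameters and decode-per-model are
possible since decoding is a pure function of (history, parameters).

Bootstrap confidence intervals resample **individual histories** with
replacement — histories are the independent units of the likelihood — refit
the same structure (warm-started at the original estimates, one start),
decode, and recompute P_model; percentile intervals are taken per occasion
(default B = 500, level 0.95; BCa was not used).  Non-converged resamples
are dropped and counted; a failure rate above 20% raises with advice to
simplify the structure.  Occasions with no detections in a resample
contribute nothing to that occasion's percentile.

## Simulation engine

A closed cohort (no recruitment) of n individuals enters at occasion 1;
initial states are Bernoulli(π_p), survival follows the transition matrix,
and events are drawn from the full event matrix at every occasion.
Individuals never detected are dropped from the fitted dataset but retained
in the truth accounting: realized true prevalence at t is (hybrids alive at
t)/(all alive at t) over the whole cohort.  Per-replicate randomness derives
from `default_rng([master_seed, replicate_index])`, so any replicate can be
regenerated in isolation.

Scenario truths.  All scenarios share π_p = 0.7, φ_p = 0.8, φ_h = 0.7
(survival values typical of the wolf population that motivates the design,
with parental survival above hybrid survival).  The detection/assignment
truths are:

| scenario | pattern                    | low detectability      | high detectability     |
|----------|----------------------------|------------------------|------------------------|
| 1        | p state-dep., δ shared     | p=(0.4, 0.2), δ=0.7    | p=(0.8, 0.6), δ=0.7    |
| 2        | p shared, δ state-dep.     | p=0.3, δ=(0.9, 0.6)    | p=0.7, δ=(0.9, 0.6)    |
| 3        | fully homogeneous          | p=0.3, δ=0.7           | p=0.7, δ=0.7           |

The homogeneous low/high detection values (0.3/0.7), the shared δ = 0.7 and
scenario 2's (0.9, 0.6) follow the design this package reproduces; the
scenario-1 state-dependent pairs (0.4, 0.2) and (0.8, 0.6) are this
package's choice of plausible field values straddling the low/high labels
while keeping p_p > p_h.  All truths are overridable per scenario.

The performance study fits the generating structure to each replicate by
default (fitting a selected model per replicate is possible by passing any
other structure), scores RMSE and relative bias of naive vs model-based
prevalence per occasion against each replicate's realized true prevalence
(relative bias is reported on the proportion scale), and — when a bootstrap
size is given — empirical CI coverage.  NaN-aware averaging drops
replicate-occasions with no classified detections.

**What the simulator does and does not emulate.**  It reproduces the
probabilistic structure of the model exactly (it is the model run forward),
so estimator-performance results validate the estimation machinery, not the
model's adequacy for real data: real scat surveys add genotyping error,
heterogeneous individual detectability, temporary emigration and
non-independence between occasions, none of which are simulated.  Passing
tests therefore demonstrate internal consistency and correct inference under
the stated assumptions.

## Problem sizes used in the checked studies

Parameter-recovery checks use 100 replicates of n = 100 individuals over
T = 5 occasions (scenario 3, high detectability) — enough for Monte Carlo
error on a mean of ~0.01.  Coverage checks use 50 replicates with B = 200
bootstrap resamples (scenario 1, high detectability, T = 5), a replication
level at which empirical coverage of a 0.95-nominal interval has a binomial
standard error of about 0.03.  Bias-direction checks use 60 replicates
without bootstrap.

## Known limitations

* Time-varying survival or detection, individual covariates, movement
  states, recruitment (Jolly–Seber-style entry) and goodness-of-fit tests
  are out of scope.
* Wald intervals and the Hessian-based identifiability diagnostic are
  unreliable near boundaries — by design such fits are flagged instead.
* Horvitz–Thompson abundance is unstable when detection estimates are small;
  estimates below 0.05 trigger a warning rather than an error.
* Posterior state probabilities (forward–backward smoothing) are not
  implemented; decoding commits to the single most probable path.
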