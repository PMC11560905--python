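# Methods

## The behaviour model

A patient's interaction with the clinic is a finite-horizon MDP with
five states — scheduled in-person consult (`IP`), scheduled telehealth
consult (`TH`), and the terminal exits discharge (`DIS`), admission
(`ADM`) and removal (`REM`) — and two actions, attend (`ATT`) and fail to
attend (`NA`), available only at the two modality states. The clinic (the
environment) books modalities and decides exits; the patient controls
attendance.

Behaviour is modelled at the trajectory level: the probability of a full
state–action sequence is proportional to its environment weight times the
exponentiated linear reward,

    p_θ(τ) ∝ p₀(s₀) · ∏ₜ T(sₜ, aₜ, sₜ₊₁) · exp(θᵀφ(τ)),

with φ(τ) the sum of one-hot state indicators over all visited states
(each state counted when visited, the final state once) and θ a
five-vector of preference weights constrained to [−1, 1] so the fitted
values read as bounded relative preferences. Actions carry implicit
weight one in the normalizer, so at θ = 0 and horizon 1 the partition
function is exactly 2 (one unit of environment mass per available
action). This model assumes patients are forward-looking — the
attractiveness of attending today reflects the whole distribution over
futures it induces — and that they care about trajectory-level feature
totals.

A known consequence of conditioning whole trajectories is that the model
tilts *environment* stochasticity as well as the patient's choices:
conditional on attending, the model routes exits toward the
higher-reward terminal state more often than the environment's raw
split. Synthetic data drawn from this model therefore shows a
discharge:admission ratio among attended exits of roughly 88:12 at the
default reference weights rather than the environment's 65:35; the
generator's Bernoulli-attendance mode (actions i.i.d., environment
transitions untilted) restores the raw split and is the right baseline
for model-misspecification experiments.

## Dynamics parameters

All defaults are the expert-estimated clinic dynamics and are exposed via
`DynamicsParams` and the YAML `dynamics:` block:

| parameter | meaning | default |
| --- | --- | --- |
| `p_ip` | probability the first consult is in-person | 0.95 |
| `p_n` | exit (removal) probability after a missed consult | 0.55 |
| `p_a` | exit probability after an attended consult | 0.15 |
| `d` | share of attendance exits that are discharges | 0.65 |
| `sigma_a` | modality-switch chance after attendance | 0.001 |
| `sigma_n` | modality-switch chance after non-attendance | 0.0001 |
| `horizon` | decision steps L (the data's maximum interaction length) | 13 |
| `discount` | per-step feature discount | 1.0 |

Quoted switching odds of "1 in N" are read as probability 1/N; a
`strict_odds` flag converts to 1/(N+1), a distinction below every
reported precision. Attendance exits split between discharge and
admission; non-attendance exits go to removal — the only routing
consistent with the clinic's process graph. The feature discount defaults
to 1 (undiscounted visit counts); a far-sighted 0.999 is available and is
numerically indistinguishable at L = 13.

## Exact inference

Variable-length interactions are embedded in a fixed-horizon chain by an
absorbing padding convention: terminal states pass with probability one
into a zero-reward padding state, so every trajectory has nominal length
L, each terminal state accrues its reward exactly once, and interactions
still open at the horizon (censored) remain in the event space with their
prefix weight. A censored trajectory has L actions and L+1 states — its
final state is the scheduled-but-uncaptured next consult, which is why
the extract renderer gives censored interactions one extra row with a
missing attendance flag.

Forward and backward messages over the six-state extended chain run in
linear space with per-step renormalization (the scaling trick used for
hidden-Markov-model inference): every step is a small dense product, the
accumulated log normalizers give log Z exactly, and per-time marginals
are formed from same-time message products where the scales cancel. This
is immune to under/overflow at any horizon and costs O(L·|S|²·|A|) —
about 0.2 ms per sweep here, which matters because the bootstrap suites
perform tens of thousands of refits. The implementation is verified
against brute-force enumeration of every trajectory (horizons 1–6, the
enumeration is guarded at 7) to 1e-10 for log Z, all marginals, and all
trajectory probabilities, and the exact sampler (local policies plus
reward-tilted transitions) is verified to reproduce enumerated
trajectory probabilities to machine precision.

## Estimation

The mean negative log-likelihood is log Z(θ) minus the data's mean reward
and environment weight; it is convex, with exact gradient
E_θ[φ] − mean(φ). Fitting uses L-BFGS-B inside the [−1, 1] box from a
zero start (convexity makes the start cosmetic; fixing it makes runs
reproducible), projected-gradient tolerance 1e-6, at most 500 iterations.
At an interior optimum the model's expected features match the empirical
means (checked in tests); components may sit on the box bounds, which the
result flags (`at_bound`), and groups smaller than 30 trajectories log a
small-sample warning but are fitted — tiny groups are a real feature of
groupwise clinic analyses.

### Identifiability geometry

The three terminal-state indicators sum to one on every terminated
trajectory, and ~97.5% of trajectories terminate at the default reference
weights. The Fisher information therefore has a near-null eigenvalue
(~4×10⁻⁴ per trajectory) along the direction that shifts
(θ_DIS, θ_ADM, θ_REM) by a common constant: only the rare
horizon-censored interactions distinguish such shifts. Consequences,
verified empirically: the modality weights are estimated to ±0.01–0.04
at n ≈ 1000–2000, while the terminal weights wander together with
standard errors an order of magnitude larger (the box bounds often
catch θ_DIS at +1 or θ_REM at −1), and the admission weight — the
rarest state — is the least reproducible single component. Mean absolute
recovery error per component at n = 2000 is below 0.1 and falls with n,
but no per-replicate ±0.1 guarantee on the terminal components is
possible at that sample size. Contrasts *within* the terminal block, and
everything involving IP/TH, are well identified.

## Bootstrap uncertainty and the preference test

All uncertainty comes from resampling whole patient trajectories with
replacement (consult rows within a patient are dependent, so the patient
interaction is the exchangeable unit), refitting each resample (default
B = 100), and reporting symmetric normal intervals — point estimate
±1.96 resample standard deviations — matching the "value ± halfwidth"
convention of the reference tables; percentile intervals are an option,
with a logged warning below 200 resamples. The telehealth-vs-in-person
preference test inverts the bootstrap CI of the contrast θ_TH − θ_IP
against zero at α = 0.05.

Calibration of that test depends on group size, because telehealth
starts are rare (5%): with 150 trajectories a group carries ~8
telehealth interactions, the bootstrap SE of the contrast is biased low
(≈0.10 vs a true sampling SD of ≈0.12), and the nominal 5% test rejects
~20% of null groups. Measured null rejection rates are 20% (n = 150),
9% (n = 400) and 2% (n = 1026): the test is honest at the scale of a
full cohort and anticonservative for small demographic subgroups, which
is the appropriate caveat for the smallest groups this kind of analysis
fits (down to n = 8). Between-group significance tests are deliberately
not offered: groupwise bootstraps are uncoupled and do not license them.

## Odds ratios

The modality NA odds ratio divides the time-summed conditional NA
probability at telehealth states by the same sum at in-person states,
t = 1..L−1 exactly as the formula prints (t = 0 excludable by option);
the trait OR compares those sums, added over the two modality states,
between a group's θ and its complement's. Terms at unreachable states
are zero; the inner sums are sums of conditional probabilities and may
exceed one — they are used as printed, not renormalized. Identities that
hold exactly (and are tested): equal weights give OR = 1; swapping the
two groups inverts the trait OR; relabelling the modalities under a
symmetric start inverts the modality OR; the modality OR moves by less
than 0.005 between L = 8 and L = 13 at the reference weights.

One structural property deserves emphasis: because the per-time ratio
p_t(s, NA)/p_t(s) is exactly the model's conditional action probability
π_t(NA|s), any reward vector with θ_TH > θ_IP yields a modality OR
*below* one under this behaviour model — staying in the system is less
costly at the preferred modality, which makes attending relatively more
attractive there. A preference for telehealth and a modality NA odds
ratio above one cannot coexist under these formulas.

Bootstrap ORs pair resample i with resample i across the two groups,
report the resample mean, and attach symmetric 95% intervals.

## Synthetic clinic extracts

The generator emulates the restricted scheduling extract: a cohort of
(by default) 1,026 patient interactions with the published demographic
margins — 35.96% male, 0.78% privately funded, 3.08% interpreter
required (53/1026 missing), 3.13% First Nations identification (67/1026
missing), six age bands — sampled independently per key because only
marginals are available (a documented simplification: real demographic
keys are correlated). Attendance behaviour is sampled from the fitted
model class itself at configurable weights (globally, or keyed by one
demographic column), which makes parameter recovery well-posed;
trajectories are rendered as long-form rows with 1-based consult
indices, ordinal integer dates (uniform starts over a 1,000-day window,
30-day spacing — no calendar semantics), and outcome codes naming the
next state. A window filter reproduces the exclusion of interactions
that begin before the capture window.

What passing tests on these data do show: the full pipeline (generation
→ CSV round-trip → trajectory conversion → groupwise fits → tests →
odds ratios) is internally consistent, and estimation recovers the
generating weights up to the identifiability limits above. What they do
not show: robustness to behaviour outside the model class (use the
Bernoulli-attendance mode to probe that), correlated demographics,
calendar effects such as waiting times, or the environment-faithful
65:35 discharge:admission split, which self-consistent sampling tilts to
~88:12 as discussed.

## Numerical choices and degenerate inputs

Tolerances: transition rows sum to one within 1e-12; marginal
normalization is exact by construction and checked to 1e-10; fit
convergence is 1e-6 on the projected gradient with bound saturation
detected at 1e-9. Degenerate inputs are defined, not special-cased: a
dataset of identical trajectories gives zero bootstrap halfwidth; a
state never visited drives its weight to the −1 bound (flagged); an
unreachable odds-ratio denominator raises an explicit undefined-OR
error rather than returning infinity; 0/0 marginal terms contribute
zero. The enumeration oracle refuses horizons above 7.

## Problem sizes used by the test and acceptance suites

Oracle comparisons run horizons 1–6 with 20 weight draws each; recovery
replicates use 10 datasets of 2,000 trajectories; null calibration uses
200 groups of 150 trajectories at B = 50 (plus a 60-group cohort-scale
check at n = 1026); Monte-Carlo feature checks use 2×10⁴ samples at a
3.5-sigma band; realism checks use one cohort of 1,026. These sizes were
chosen so the whole suite completes in a few minutes on one core while
every stochastic assertion retains a comfortable margin.

## Known limitations

* Discrete time only: no waiting-time or inter-appointment-duration
  states, though these are known drivers of non-attendance.
* Dynamics are expert-estimated inputs, not learned from data.
* The trajectory-level maximum-entropy form tilts environment
  stochasticity (see above); a causal-entropy variant would remove this
  at the cost of a different inference scheme, and is out of scope.
* The common-shift direction of the terminal weights is near-unidentified
  in cohorts where almost all interactions terminate; report terminal
  weights with their intervals, not as point values.
* The bootstrap preference test over-rejects in small groups; treat
  subgroup significance claims below a few hundred interactions with
  caution.
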