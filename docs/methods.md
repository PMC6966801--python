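# Methods

## Conditional power on the information scale

A two-arm superiority trial accumulates Fisher information I as patients
and events accrue; the information at the k-th interim analysis is
`I_k = SE(theta_hat_k)^-2` and the information time is `t_k = I_k / I_K`,
where `I_K` is the planned total. On this scale the score process
`S(t) = theta_hat(t) * I(t)` behaves as Brownian motion with drift theta
(the true effect), which is the standard large-sample model for group
sequential monitoring. The interim statistic is `Z_k = S(t_k) / sqrt(I_K
t_k)`, and `B_k = Z_k sqrt(t_k)` is the B-value.

Conditional power at look k under a hypothesised future effect theta is
the probability of final rejection given the interim data:

    one-sided:  CP_k(theta) = 1 - Phi( (c - Z_k sqrt(t_k)
                                       - theta sqrt(I_K) (1 - t_k))
                                      / sqrt(1 - t_k) )

    two-sided:  the same term plus
                Phi( (-c - Z_k sqrt(t_k) - theta sqrt(I_K) (1 - t_k))
                     / sqrt(1 - t_k) )

with critical value `c = Phi^-1(1 - alpha)` one-sided and
`c = Phi^-1(1 - alpha/2)` two-sided. The alpha/2 convention for two-sided
tests is a deliberate choice: it makes the unconditional two-sided
rejection probability under the null exactly alpha, and the convention
actually used is recorded in every `CpResult`. Note that the two-sided
expression counts rejections in *either* direction; as a consequence
two-sided CP is not monotone in theta globally — it decreases below
`theta_min = -Z_k sqrt(t_k) / ((1 - t_k) sqrt(I_K))`, where the
wrong-direction tail dominates. This matters when comparing hypotheses for
trials with negative interim trends at early looks.

Four future-data hypotheses are supported: **current trend** (future data
continue the interim estimate), **design** (the protocol effect still
holds), **upper confidence limit** (optimistic: the upper limit of a
two-sided interim CI at a chosen level), and **null** (no effect). A trial
is classified futile when CP falls strictly below a threshold; the default
threshold is 0.15, in the conventional 0.10–0.15 range for
stochastic-curtailment rules, and every entry point accepts an override.

When `I_K` is not given it is derived from the design via
`I_K = ((c + Phi^-1(power)) / |theta_d|)^2`, the sample-size identity that
makes unconditional power at `theta_d` equal the planned power. An
explicitly supplied `I_K` always takes precedence, and `I_K` is never
derived from the planned sample size alone (that would require a variance
model the report does not supply). An interim at or beyond full
information (`t_k >= 1`) raises a distinct error — CP is undefined there
and the pipeline surfaces a flag rather than clamping.

## Effect-scale conversion

Reports print effects on many scales; converters normalise them to a
(estimate, SE, Z, information) quadruple on the natural analysis scale,
benefit-positive, with log scales for ratio measures so that
`theta * sqrt(I_K)` is dimensionless. The variance conventions are the
most common ones in trial reports and are recorded in a `method` tag on
every converted state:

* risk difference — unpooled Wald SE `sqrt(p1 q1/n1 + p0 q0/n0)`;
* log odds ratio — Woolf SE `sqrt(1/a + 1/b + 1/c + 1/d)`, with an opt-in
  (default off) +0.5 continuity correction on all four cells, required
  when a cell is zero;
* mean difference — unpooled two-sample Wald SE;
* log hazard ratio — `SE^-2` when the SE is reported, otherwise the d/4
  approximation (total events over four, exact under 1:1 allocation and
  the null), flagged approximate;
* p-value — `Z = Phi^-1(1 - p)` (one-sided) or `Phi^-1(1 - p/2)` signed
  by the reported direction. Only exact p-values are accepted: a bound
  such as "<0.001" is refused rather than imputed, mirroring how an audit
  must treat under-reported trials.

## Sequential simulator

`simulate_sequential_trial` draws exact-normal score increments between
looks (mean `theta I_K dt`, variance `I_K dt`), evaluates CP at each look
under the configured hypothesis — current trend re-uses the *running*
estimate `S_k / I_k` at every look, not the first-look estimate — and
stops at the first look where CP drops strictly below the threshold. The
estimate reported at a stop is the unadjusted interim estimate `S_k /
I_k`, matching how truncated trials report effects. `monte_carlo_cp`
simulates only the single future increment and is the brute-force oracle
for the closed form: the two must agree within Monte-Carlo error
everywhere, and the test suite checks this on a 200-point random grid at
1e5 draws per point.

This simulator realises the directional estimation effects of futility
rules as assertable facts: conditional on stopping the effect is
under-estimated; conditional on completing it is over-estimated (stopping
removes the unluckiest trajectories from the completing stratum); and the
overall mean is biased downward, because the stopped stratum's deficit
outweighs the completers' surplus. With the default demonstration
conditions (one-sided alpha 0.025, 90% power at theta_d = 0.3, true effect
theta_d/2, one look at t = 0.5, threshold 0.15, 1e5 replicates) all three
directions resolve beyond three Monte-Carlo standard errors, and setting
the threshold to zero removes the bias. One RNG stream per trial is
derived from (master seed, trial index), so results are independent of
execution order and reproducible byte for byte.

## Synthetic registry generator

`generate_registry` emulates the per-trial table of a survey of 52
randomised trials stopped early for futility. Its defaults are the
survey's printed marginals: outcome types 33 binary / 10 continuous / 8
time-to-event (the survey's single trinomial trial is out of scope),
sponsor 21 industry / 31 non-industry, sidedness 14 one- / 33 two-sided /
5 unstated, planned power bands 1:32:15 across 70s/80s/90s+ (rows with
unstated power are not generated, since no CP could be computed from
them), planned total sample sizes lognormal with median 209 and sigma set
from the quartile ratio 586/133 (the printed IQR is asymmetric around the
median, so a single lognormal matches the ratio, not both quartiles),
information fraction at the last look binned 11:20:12:6 across
<40/40–59/60–79/80+ percent plus 3 unstated, and the three-way CP
evaluation split 11 reported-only / 25 computable / 16 insufficient
(`reported_only_fraction` and `insufficient_fraction`).

Two generator choices go beyond the marginals. First, the true effect
behind each trial's interim data defaults to half its design effect
(`true_effect_model`, a point mass at r = 0.5): observed effects in
stopped trials run well below their targets, and r is configurable when a
different population is wanted. Second, every emulated trial *actually
stopped*, so interim results are drawn conditional on looking unpromising:
a drawn `Z_k` is kept when its current-trend CP falls below the futility
threshold, and admitted anyway with small probability (`high_cp_admit`,
default 2/25) to reproduce the minority of surveyed stops whose CP was not
low. Insufficient rows carry the survey's characteristic missingness —
no estimate, SE or Z, at most a p-value bound; reported-only rows carry a
`reported_cp` (the current-trend CP of their generated interim state) but
no recomputable inputs.

What the generator does *not* emulate: joint dependencies between columns
(sponsor, outcome type, power and timing are drawn independently, which
the survey's tables cannot confirm or deny), covariate adjustment,
non-normal small-sample behaviour of the interim statistics, and
outcome-level data (simulation lives on the score scale). Tests passing
on this registry therefore demonstrate the audit machinery's correctness
and the CP formula's properties, not distributional claims about real
trial reports.

## Audit pipeline

`audit_trial` resolves each record by a fixed precedence chain
(documented in `registry_schema.md`), attempts CP under the current-trend
and design hypotheses independently, and emits one of three statuses:
`computed`, `reported_only` (author-reported CP retained verbatim — never
back-solved, since the authors' conventions are usually unstated), or
`insufficient` with a machine-readable failure reason. Computed values
win over reported ones when both exist, but both are always emitted. Each
audit also carries an assumption log (e.g. "sidedness not stated; assumed
two-sided") so that every number is traceable to what the record actually
contained.

Summaries bin CP into [0, 0.15), [0.15, 0.30), [0.30, 0.50), [0.50, 1] —
left-closed so that "less than 15%" is literal — stratify the
current-trend bins by sponsor, and treat reported-only values as
current-trend values when binning. Conservation (statuses sum to the
number of trials, bins sum to the number of binned values) is asserted on
every run.

## Numerical choices

Normal CDF/quantile evaluations use double-precision `scipy.special`
routines. Redundant inputs (Z vs estimate/SE, information vs SE^-2) must
agree to relative tolerance 1e-8 or the record is rejected. CP is clamped
into [0, 1] only against floating-point overshoot up to 1e-12; anything
larger is treated as a bug, not noise. Futility is a strict inequality
(CP exactly at the threshold is not futile), and bin edges are
left-closed. Monotonicity grid tests avoid arguments where CP underflows
double precision (ties at exactly 0 are representation, not mathematics).

## Problem sizes

The shipped checks use a 52-trial registry (the surveyed size), a
200-point oracle fuzz grid at 1e5 Monte-Carlo draws per point, and 1e5
replicates per bias condition; the whole suite runs in well under a
minute on one core. All sizes are plain parameters and scale up directly
when sharper Monte-Carlo resolution is wanted.

## Known limitations

The package audits *reported* summaries; it cannot recover information a
trial report omitted, and deliberately refuses to guess (p-value bounds,
missing SEs). The d/4 survival information rule degrades under unbalanced
allocation. Trinomial outcomes are unsupported. The simulator's Brownian
model is exact for the normal-increments idealisation that underlies the
CP formula itself, so simulator-vs-formula agreement validates the
implementation, not the adequacy of the asymptotic model for any given
small trial. No adjustment of post-stopping estimates is attempted —
quantifying that bias, not correcting it, is the point.
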