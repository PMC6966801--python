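"""Group-sequential trial simulation and synthetic registry generation.

Two jobs live here.

First, a Monte-Carlo oracle and a score-process simulator for the
conditional power machinery.  The accumulating score S(t) of a trial is
modelled as Brownian motion on the information scale: between information
times t and t' the increment is normal with mean theta * I_K * (t' - t) and
variance I_K * (t' - t), so Z_k = S(t_k) / sqrt(I_K * t_k) and the running
effect estimate is S(t_k) / I_k.  This is the canonical model under which
the closed-form conditional power expression is exact, which makes
:func:`monte_carlo_cp` an independent brute-force check of the closed form,
and :func:`simulate_sequential_trial` a testbed for the estimation-bias
consequences of futility stopping (under-estimation in trials that stop,
over-estimation in trials that continue, overall negative bias).

Second, :func:`generate_registry` emits synthetic per-trial registry tables
that emulate the marginal composition of a survey of 52 randomised trials
stopped early for futility: the outcome-type, sponsor, sidedness and power
mixes, the planned-sample-size distribution, the information-fraction
distribution at the last interim look, and the three-way split of trials
into CP reported by the authors / computable from the report / impossible
to compute.  All randomness flows from explicit seeds, one stream per trial
derived from (master seed, trial index), so results are reproducible and
independent of execution order.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cp import (
    DesignSpec,
    FutureHypothesis,
    HypothesisKind,
    InterimState,
    Sidedness,
    DomainError,
    DEFAULT_FUTILITY_THRESHOLD,
    classify_futility,
    conditional_power,
    critical_value,
    total_information_from_design,
)

__all__ = [
    "SimConfig",
    "SimRecord",
    "BiasSummary",
    "StratumSummary",
    "RegistryConfig",
    "monte_carlo_cp",
    "simulate_sequential_trial",
    "run_simulation",
    "estimate_stopping_probability",
    "bias_summary",
    "generate_registry",
    "write_registry",
    "sim_records_to_frame",
    "run_manifest",
]


# --------------------------------------------------------------------------
# Monte-Carlo conditional power oracle
# --------------------------------------------------------------------------

def monte_carlo_cp(
    interim: InterimState,
    design: DesignSpec,
    theta: float,
    n_draws: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Brute-force conditional power by simulating the future score increment.

    Draws the final statistic as

        Z_K = Z_k*sqrt(t_k) + theta*sqrt(I_K)*(1 - t_k) + eps*sqrt(1 - t_k)

    with eps standard normal, and returns the rejection fraction at level
    alpha (respecting sidedness) together with its binomial standard error.
    """
    if n_draws < 1:
        raise DomainError(f"n_draws must be positive, got {n_draws}")
    i_total = total_information_from_design(design)
    from .cp import _resolve_t_k  # shared resolution logic

    t_k = _resolve_t_k(interim, i_total)
    c = critical_value(design.alpha, design.sidedness)
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(n_draws)
    z_final = (
        interim.z_value * math.sqrt(t_k)
        + theta * math.sqrt(i_total) * (1.0 - t_k)
        + eps * math.sqrt(1.0 - t_k)
    )
    if design.sidedness is Sidedness.two:
        reject = np.abs(z_final) > c
    else:
        reject = z_final > c
    p_hat = float(np.mean(reject))
    se = math.sqrt(max(p_hat * (1.0 - p_hat), 1.0 / n_draws) / n_draws)
    return p_hat, se


# --------------------------------------------------------------------------
# Sequential trial simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Configuration of a simulated group-sequential trial with a futility rule.

    ``look_fractions`` is the strictly increasing schedule of information
    times at which futility is evaluated; ``hypothesis`` picks the theta the
    interim CP assumes (current_trend re-uses the running estimate at each
    look); a trial stops at the first look whose CP falls strictly below
    ``threshold``.
    """

    theta_true: float
    design: DesignSpec
    look_fractions: tuple[float, ...] = (0.5,)
    hypothesis: FutureHypothesis = field(
        default_factory=lambda: FutureHypothesis(HypothesisKind.current_trend)
    )
    threshold: float = DEFAULT_FUTILITY_THRESHOLD
    n_sim: int = 1000
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "look_fractions", tuple(self.look_fractions))
        fr = self.look_fractions
        if not fr:
            raise DomainError("at least one look fraction is required")
        if any(not 0.0 < t < 1.0 for t in fr):
            raise DomainError(f"look fractions must lie in (0, 1), got {fr}")
        if any(b <= a for a, b in zip(fr, fr[1:])):
            raise DomainError(f"look fractions must be strictly increasing, got {fr}")
        if not 0.0 <= self.threshold <= 1.0:
            raise DomainError(f"threshold must be in [0, 1], got {self.threshold}")
        if self.n_sim < 1:
            raise DomainError(f"n_sim must be positive, got {self.n_sim}")


@dataclass(frozen=True)
class SimRecord:
    """One simulated trial: where (if anywhere) it stopped, and its estimate.

    ``stopped_at_look`` is 0 for a trial that ran to completion.  The final
    estimate is the running interim estimate S_k / I_k at a stop (no bias
    adjustment, mirroring how truncated trials report effects) and the
    full-data estimate otherwise.  ``significant`` refers to the final test
    at level alpha and is only meaningful for completed trials.
    """

    stopped_at_look: int
    final_estimate: float
    significant: bool
    cp_at_looks: tuple[float, ...]


def simulate_sequential_trial(config: SimConfig, trial_seed) -> SimRecord:
    """Simulate one trial as Brownian motion with drift on the information scale."""
    design = config.design
    i_total = total_information_from_design(design)
    if design.total_information is None:
        design = replace(design, total_information=i_total)
    rng = np.random.default_rng(trial_seed)
    c = critical_value(design.alpha, design.sidedness)

    s = 0.0
    t_prev = 0.0
    cp_at_looks: list[float] = []
    for k, t_k in enumerate(config.look_fractions, start=1):
        dt = t_k - t_prev
        s += rng.normal(config.theta_true * i_total * dt, math.sqrt(i_total * dt))
        i_k = i_total * t_k
        interim = InterimState(
            look_index=k,
            z_value=s / math.sqrt(i_k),
            information=i_k,
            info_fraction=t_k,
            estimate=s / i_k,
            se=i_k ** -0.5,
        )
        result = conditional_power(interim, design, config.hypothesis, config.threshold)
        cp_at_looks.append(result.cp)
        if result.futile:
            return SimRecord(
                stopped_at_look=k,
                final_estimate=s / i_k,
                significant=False,
                cp_at_looks=tuple(cp_at_looks),
            )
        t_prev = t_k

    dt = 1.0 - t_prev
    s += rng.normal(config.theta_true * i_total * dt, math.sqrt(i_total * dt))
    z_final = s / math.sqrt(i_total)
    if design.sidedness is Sidedness.two:
        significant = abs(z_final) > c
    else:
        significant = z_final > c
    return SimRecord(
        stopped_at_look=0,
        final_estimate=s / i_total,
        significant=significant,
        cp_at_looks=tuple(cp_at_looks),
    )


def run_simulation(config: SimConfig) -> list[SimRecord]:
    """Run ``config.n_sim`` independent trials, one child RNG stream each."""
    return [
        simulate_sequential_trial(config, [config.seed, idx])
        for idx in range(config.n_sim)
    ]


def estimate_stopping_probability(config: SimConfig) -> tuple[float, float]:
    """Fraction of simulated trials stopping for futility, with binomial SE."""
    if config.n_sim < 100:
        raise DomainError(f"n_sim must be >= 100 for a stable estimate, got {config.n_sim}")
    records = run_simulation(config)
    stopped = sum(1 for r in records if r.stopped_at_look > 0)
    p_hat = stopped / config.n_sim
    se = math.sqrt(max(p_hat * (1.0 - p_hat), 1.0 / config.n_sim) / config.n_sim)
    return p_hat, se


@dataclass(frozen=True)
class StratumSummary:
    n: int
    mean_estimate: Optional[float]
    mc_se: Optional[float]
    bias: Optional[float]

    @property
    def empty(self) -> bool:
        return self.n == 0


@dataclass(frozen=True)
class BiasSummary:
    """Mean final estimates by stopping stratum, versus the true effect."""

    theta_true: float
    stopped: StratumSummary
    completed: StratumSummary
    overall: StratumSummary


def _stratum(estimates: Sequence[float], theta_true: float) -> StratumSummary:
    n = len(estimates)
    if n == 0:
        return StratumSummary(n=0, mean_estimate=None, mc_se=None, bias=None)
    arr = np.asarray(estimates, dtype=float)
    mean = float(arr.mean())
    se = float(arr.std(ddof=1) / math.sqrt(n)) if n > 1 else float("inf")
    return StratumSummary(n=n, mean_estimate=mean, mc_se=se, bias=mean - theta_true)


def bias_summary(records: Sequence[SimRecord], theta_true: float) -> BiasSummary:
    """Conditional and overall mean estimates with Monte-Carlo SEs.

    A stratum with no members is reported as empty rather than as a number.
    """
    if not records:
        raise DomainError("bias_summary requires a nonempty list of records")
    stopped = [r.final_estimate for r in records if r.stopped_at_look > 0]
    completed = [r.final_estimate for r in records if r.stopped_at_look == 0]
    overall = [r.final_estimate for r in records]
    return BiasSummary(
        theta_true=theta_true,
        stopped=_stratum(stopped, theta_true),
        completed=_stratum(completed, theta_true),
        overall=_stratum(overall, theta_true),
    )


# --------------------------------------------------------------------------
# Synthetic registry generation
# --------------------------------------------------------------------------

def _validated_mix(name: str, mix: dict) -> dict:
    total = sum(mix.values())
    if any(p < 0 for p in mix.values()):
        raise DomainError(f"{name} has negative probabilities: {mix}")
    if abs(total - 1.0) > 1e-9:
        raise DomainError(f"{name} probabilities must sum to 1, got {total}")
    return dict(mix)


# Default marginal mixes emulating the surveyed registry of 52 trials
# stopped early for futility.  Outcome types 33 binary / 10 continuous /
# 8 time-to-event over the 51 supported trials (the single trinomial trial
# is unsupported); sponsor 21 industry / 31 non-industry; sidedness
# 14 one- / 33 two-sided / 5 unclear; information fraction at the last
# interim look binned 11 / 20 / 12 / 6 / 3-unclear; CP evaluation split
# 11 reported-only / 25 computable / 16 insufficient.
_DEF_OUTCOME_MIX = {"binary": 33 / 51, "continuous": 10 / 51, "time_to_event": 8 / 51}
_DEF_SPONSOR_MIX = {"industry": 21 / 52, "non_industry": 31 / 52}
_DEF_SIDEDNESS_MIX = {"one": 14 / 52, "two": 33 / 52, "unclear": 5 / 52}
# planned power: 1 trial at 70-79%, 32 at 80-89%, 15 at 90%+ among the 48
# trials where it was stated; split within bands across round values.
_DEF_POWER_MIX = {0.75: 1 / 48, 0.80: 20 / 48, 0.85: 12 / 48, 0.90: 10 / 48, 0.95: 5 / 48}
_DEF_INFO_FRACTION_MIX = {
    "lt40": 11 / 52, "40-59": 20 / 52, "60-79": 12 / 52, "80plus": 6 / 52,
    "not_stated": 3 / 52,
}
_INFO_BIN_RANGES = {
    "lt40": (0.11, 0.40), "40-59": (0.40, 0.60), "60-79": (0.60, 0.80),
    "80plus": (0.80, 0.95), "not_stated": (0.40, 0.60),
}
_DEF_DECISION_MIX = {
    "investigators_on_dsmb_advice": 30 / 52, "dsmb": 3 / 52, "sponsor": 3 / 52,
    "executive_committee": 1 / 52, "not_stated": 15 / 52,
}
_DEF_LOOKS_ACTUAL_MIX = {0: 2 / 52, 1: 41 / 52, 2: 7 / 52, 3: 1 / 52, 5: 1 / 52}


@dataclass(frozen=True)
class RegistryConfig:
    """Generator settings for a synthetic futility-stop registry.

    Defaults reproduce the surveyed marginals: 52 trials, the outcome /
    sponsor / sidedness / power mixes above, planned total sample sizes
    lognormal with median ~209 and quartile ratio matching an IQR of
    133-586, and the 11/25/16 reported-only / computed / insufficient split
    (``reported_only_fraction`` + ``insufficient_fraction``).  The true
    effect behind each trial's interim data is ``r * theta_d`` with r drawn
    from ``true_effect_model`` (default: point mass at 0.5 — observed
    effects in stopped trials run well below their targets).
    """

    n_trials: int = 52
    outcome_mix: dict = field(default_factory=lambda: dict(_DEF_OUTCOME_MIX))
    sponsor_mix: dict = field(default_factory=lambda: dict(_DEF_SPONSOR_MIX))
    sidedness_mix: dict = field(default_factory=lambda: dict(_DEF_SIDEDNESS_MIX))
    power_mix: dict = field(default_factory=lambda: dict(_DEF_POWER_MIX))
    planned_n_log_median: float = math.log(209.0)
    planned_n_log_sigma: float = math.log(586.0 / 133.0) / (2.0 * 0.674489750196082)
    info_fraction_distribution: dict = field(
        default_factory=lambda: dict(_DEF_INFO_FRACTION_MIX)
    )
    insufficient_fraction: float = 16 / 52
    reported_only_fraction: float = 11 / 52
    true_effect_model: dict = field(
        default_factory=lambda: {"kind": "point", "value": 0.5}
    )
    futility_threshold: float = DEFAULT_FUTILITY_THRESHOLD
    high_cp_admit: float = 2 / 25
    seed: int = 0

    def __post_init__(self):
        if self.n_trials < 1:
            raise DomainError(f"n_trials must be positive, got {self.n_trials}")
        for name in ("outcome_mix", "sponsor_mix", "sidedness_mix", "power_mix",
                     "info_fraction_distribution"):
            _validated_mix(name, getattr(self, name))
        if not 0.0 <= self.insufficient_fraction <= 1.0:
            raise DomainError("insufficient_fraction must be in [0, 1]")
        if not 0.0 <= self.reported_only_fraction <= 1.0:
            raise DomainError("reported_only_fraction must be in [0, 1]")
        if not 0.0 <= self.futility_threshold <= 1.0:
            raise DomainError("futility_threshold must be in [0, 1]")
        if not 0.0 <= self.high_cp_admit <= 1.0:
            raise DomainError("high_cp_admit must be in [0, 1]")
        if self.insufficient_fraction + self.reported_only_fraction > 1.0:
            raise DomainError(
                "insufficient_fraction + reported_only_fraction exceeds 1"
            )
        kind = self.true_effect_model.get("kind")
        if kind not in ("point", "uniform"):
            raise DomainError(
                f"true_effect_model kind must be 'point' or 'uniform', got {kind!r}"
            )


REGISTRY_COLUMNS = [
    "trial_id", "alpha", "sidedness", "planned_power", "design_effect",
    "design_effect_scale", "planned_total_n", "outcome_kind", "measure",
    "total_information", "estimate", "se", "z_value", "p_value", "p_is_bound",
    "info_fraction", "interim_n", "n_looks_planned", "n_looks_actual",
    "sponsor", "dsmb", "decision_maker", "reported_cp",
    "reported_cp_hypothesis", "data_collection_continued",
]


def _choice(rng: np.random.Generator, mix: dict):
    keys = list(mix.keys())
    probs = np.asarray([mix[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def _draw_true_effect_ratio(rng: np.random.Generator, model: dict) -> float:
    if model["kind"] == "point":
        return float(model["value"])
    return float(rng.uniform(model["low"], model["high"]))


def _generate_row(config: RegistryConfig, idx: int) -> dict:
    rng = np.random.default_rng([config.seed, idx])
    row: dict = {col: None for col in REGISTRY_COLUMNS}
    row["trial_id"] = f"T{idx + 1:03d}"

    outcome = _choice(rng, config.outcome_mix)
    row["outcome_kind"] = outcome
    sided_cat = _choice(rng, config.sidedness_mix)
    sided = "two" if sided_cat == "unclear" else sided_cat
    row["sidedness"] = None if sided_cat == "unclear" else sided_cat
    alpha = 0.025 if sided == "one" else 0.05
    row["alpha"] = alpha
    power = float(_choice(rng, config.power_mix))
    row["planned_power"] = power
    row["planned_total_n"] = int(
        max(20, round(math.exp(rng.normal(config.planned_n_log_median,
                                          config.planned_n_log_sigma))))
    )

    # Design effect on the natural analysis scale; time-to-event trials
    # record the target hazard ratio with scale=log_ratio to mirror how
    # reports print ratio effects.
    if outcome == "binary":
        theta_d = float(rng.uniform(0.05, 0.20))
        row["design_effect"] = round(theta_d, 4)
        row["design_effect_scale"] = "natural"
        row["measure"] = "risk_difference"
    elif outcome == "continuous":
        theta_d = float(rng.uniform(0.2, 0.6))
        row["design_effect"] = round(theta_d, 4)
        row["design_effect_scale"] = "natural"
    else:  # time_to_event
        hr = float(rng.uniform(0.50, 0.80))
        theta_d = abs(math.log(hr))
        row["design_effect"] = round(hr, 4)
        row["design_effect_scale"] = "log_ratio"

    design = DesignSpec(
        alpha=alpha, sidedness=sided, planned_power=power, design_effect=theta_d,
    )
    i_total = total_information_from_design(design)

    info_bin = _choice(rng, config.info_fraction_distribution)
    lo, hi = _INFO_BIN_RANGES[info_bin]
    t_k = float(rng.uniform(lo, hi))
    if info_bin != "not_stated":
        row["info_fraction"] = round(t_k, 4)
    row["interim_n"] = int(round(t_k * row["planned_total_n"]))

    theta_true = _draw_true_effect_ratio(rng, config.true_effect_model) * theta_d
    i_k = t_k * i_total
    se = i_k ** -0.5
    design_known_ik = replace(design, total_information=i_total)
    hypothesis_ct = FutureHypothesis(HypothesisKind.current_trend)
    # Every emulated trial actually stopped for futility, so the interim
    # result is drawn conditional on looking unpromising: keep a draw whose
    # current-trend CP falls below the futility threshold, and admit a
    # higher-CP draw only with a small probability (a minority of surveyed
    # stops had CP above threshold).
    for _ in range(1000):
        z_k = float(rng.normal(theta_true * math.sqrt(i_k), 1.0))
        estimate = z_k * se
        interim = InterimState(
            look_index=1, z_value=z_k, info_fraction=t_k,
            estimate=estimate, se=se, information=i_k,
        )
        cp_ct = conditional_power(interim, design_known_ik, hypothesis_ct).cp
        if classify_futility(cp_ct, config.futility_threshold):
            break
        if rng.random() < config.high_cp_admit:
            break

    looks_actual = int(_choice(rng, _DEF_LOOKS_ACTUAL_MIX))
    row["n_looks_actual"] = looks_actual
    row["n_looks_planned"] = _choice(
        rng, {1: 19 / 52, 2: 5 / 52, 3: 2 / 52, None: 26 / 52}
    )
    row["sponsor"] = _choice(rng, config.sponsor_mix)
    row["dsmb"] = bool(rng.random() < 36 / 52)
    row["decision_maker"] = _choice(rng, _DEF_DECISION_MIX)
    row["data_collection_continued"] = _choice(
        rng, {True: 21 / 52, False: 23 / 52, None: 8 / 52}
    )

    # CP-evaluation channel: reported-only trials print a CP value but not
    # the interim statistics behind it; insufficient trials print neither
    # (at most a p-value bound); the rest are fully computable.
    u = rng.random()
    if u < config.reported_only_fraction:
        row["reported_cp"] = round(cp_ct, 3)
        # only a minority of reporting trials state their assumption
        if rng.random() < 2 / 11:
            row["reported_cp_hypothesis"] = "current_trend"
        row["p_value"] = 0.2
        row["p_is_bound"] = True
    elif u < config.reported_only_fraction + config.insufficient_fraction:
        row["p_value"] = 0.05
        row["p_is_bound"] = True
    else:
        row["estimate"] = round(estimate, 6)
        row["se"] = round(se, 6)
        row["z_value"] = round(estimate, 6) / round(se, 6)
    return row


def generate_registry(config: RegistryConfig) -> pd.DataFrame:
    """Generate a synthetic registry table in the documented audit schema.

    Deterministic given ``config.seed``: each row draws from its own RNG
    stream keyed by (seed, trial index).
    """
    rows = [_generate_row(config, idx) for idx in range(config.n_trials)]
    return pd.DataFrame(rows, columns=REGISTRY_COLUMNS)


def write_registry(frame: pd.DataFrame, path) -> None:
    """Write a registry table as UTF-8 CSV with empty cells for nulls."""
    frame.to_csv(path, index=False, na_rep="")


def sim_records_to_frame(records: Sequence[SimRecord]) -> pd.DataFrame:
    """Tabulate simulation records for delimited-text output."""
    return pd.DataFrame(
        {
            "stopped_at_look": [r.stopped_at_look for r in records],
            "final_estimate": [r.final_estimate for r in records],
            "significant": [r.significant for r in records],
            "cp_at_looks": [json.dumps(list(r.cp_at_looks)) for r in records],
        }
    )


def run_manifest(config) -> str:
    """JSON run manifest echoing the full configuration, including seeds."""

    def _default(obj):
        if isinstance(obj, (DesignSpec, FutureHypothesis, SimConfig, RegistryConfig)):
            return asdict(obj)
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if hasattr(obj, "value"):
            return obj.value
        raise TypeError(f"cannot serialise {type(obj)}")

    return json.dumps(asdict(config), default=_default, indent=2, sort_keys=True)
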