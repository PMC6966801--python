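"""Convert trial-report summaries into interim states on the information scale.

Trial reports rarely print (Z_k, I_k) directly; they print per-arm event
counts, means with standard deviations, hazard ratios, or p-values.  Each
converter here builds an :class:`~cpaudit.cp.InterimState` with a consistent
(estimate, se, z, information) quadruple and a ``method`` tag recording the
variance formula used, so downstream audits are traceable.

Conventions fixed by this module (common trial-report choices):

* risk difference: unpooled Wald standard error;
* log odds ratio: Woolf standard error 1/a + 1/b + 1/c + 1/d, with an
  opt-in +0.5 continuity correction on all four cells;
* survival: information from se(log HR) when given, otherwise the d/4
  approximation (total events / 4, valid near 1:1 allocation), flagged as
  approximate.

Orientation is benefit-positive: the caller supplies summaries such that a
positive effect favours the experimental arm (flip arm labels or the sign
of a log hazard ratio beforehand if a lower rate/hazard is the benefit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from scipy.special import ndtri

from .cp import DomainError, InsufficientInformationError, InterimState, Sidedness

__all__ = [
    "BinaryMeasure",
    "Direction",
    "BinaryArms",
    "ContinuousArms",
    "SurvivalSummary",
    "interim_from_binary",
    "interim_from_continuous",
    "interim_from_survival",
    "z_from_pvalue",
]


class BinaryMeasure(str, Enum):
    risk_difference = "risk_difference"
    log_odds_ratio = "log_odds_ratio"


class Direction(str, Enum):
    benefit = "benefit"
    harm = "harm"


@dataclass(frozen=True)
class BinaryArms:
    """Per-arm event counts for a binary outcome (events favour benefit)."""

    events_treat: int
    n_treat: int
    events_ctrl: int
    n_ctrl: int
    measure: BinaryMeasure = BinaryMeasure.risk_difference

    def __post_init__(self):
        object.__setattr__(self, "measure", BinaryMeasure(self.measure))
        for events, n, arm in (
            (self.events_treat, self.n_treat, "treatment"),
            (self.events_ctrl, self.n_ctrl, "control"),
        ):
            if n < 1:
                raise DomainError(f"{arm} arm size must be positive, got {n}")
            if not 0 <= events <= n:
                raise DomainError(
                    f"{arm} arm events must lie in [0, n]: got {events}/{n}"
                )


@dataclass(frozen=True)
class ContinuousArms:
    """Per-arm means and standard deviations for a continuous outcome."""

    mean_treat: float
    mean_ctrl: float
    sd_treat: float
    sd_ctrl: float
    n_treat: int
    n_ctrl: int

    def __post_init__(self):
        if self.sd_treat <= 0 or self.sd_ctrl <= 0:
            raise DomainError("standard deviations must be positive")
        if self.n_treat < 2 or self.n_ctrl < 2:
            raise DomainError("each arm needs at least 2 observations")


@dataclass(frozen=True)
class SurvivalSummary:
    """Log hazard ratio with either its standard error or the event count."""

    log_hazard_ratio: float
    total_events: Optional[int] = None
    se_log_hr: Optional[float] = None

    def __post_init__(self):
        if self.total_events is None and self.se_log_hr is None:
            raise InsufficientInformationError(
                "survival summary needs total_events or se_log_hr"
            )
        if self.total_events is not None and self.total_events < 1:
            raise DomainError(f"total_events must be positive, got {self.total_events}")
        if self.se_log_hr is not None and self.se_log_hr <= 0:
            raise DomainError(f"se_log_hr must be positive, got {self.se_log_hr}")


def _build_state(theta: float, se: float, method: str, approximate: bool = False,
                 look_index: int = 1) -> InterimState:
    return InterimState(
        look_index=look_index,
        z_value=theta / se,
        information=se ** -2,
        estimate=theta,
        se=se,
        method=method,
        approximate=approximate,
    )


def interim_from_binary(
    arms: BinaryArms, continuity_correction: bool = False, look_index: int = 1
) -> InterimState:
    """Interim state from two-arm binomial counts.

    risk_difference: theta = p1 - p0 with the unpooled Wald SE
    sqrt(p1(1-p1)/n1 + p0(1-p0)/n0).  log_odds_ratio: theta = log(ad/bc)
    with the Woolf SE sqrt(1/a + 1/b + 1/c + 1/d); a zero cell raises
    unless ``continuity_correction`` adds 0.5 to all four cells.
    """
    if arms.measure is BinaryMeasure.risk_difference:
        p1 = arms.events_treat / arms.n_treat
        p0 = arms.events_ctrl / arms.n_ctrl
        theta = p1 - p0
        var = p1 * (1 - p1) / arms.n_treat + p0 * (1 - p0) / arms.n_ctrl
        if var == 0.0:
            raise DomainError(
                "degenerate proportions (0 or 1) in both arms give zero "
                "Wald variance; risk-difference information is undefined"
            )
        approx = p1 in (0.0, 1.0) or p0 in (0.0, 1.0)
        return _build_state(
            theta, math.sqrt(var), "wald_risk_difference",
            approximate=approx, look_index=look_index,
        )

    # log odds ratio
    a = float(arms.events_treat)
    b = float(arms.n_treat - arms.events_treat)
    c = float(arms.events_ctrl)
    d = float(arms.n_ctrl - arms.events_ctrl)
    cells = {"events_treat": a, "nonevents_treat": b, "events_ctrl": c, "nonevents_ctrl": d}
    zero_cells = [name for name, v in cells.items() if v == 0.0]
    if zero_cells:
        if not continuity_correction:
            raise DomainError(
                f"zero cell(s) {zero_cells} make the log odds ratio "
                "undefined; enable the +0.5 continuity correction"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        method = "woolf_log_odds_ratio+0.5"
    elif continuity_correction:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        method = "woolf_log_odds_ratio+0.5"
    else:
        method = "woolf_log_odds_ratio"
    theta = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return _build_state(theta, se, method, approximate=bool(zero_cells),
                        look_index=look_index)


def interim_from_continuous(arms: ContinuousArms, look_index: int = 1) -> InterimState:
    """Interim state from a two-sample mean difference (unpooled Wald SE)."""
    theta = arms.mean_treat - arms.mean_ctrl
    se = math.sqrt(arms.sd_treat ** 2 / arms.n_treat + arms.sd_ctrl ** 2 / arms.n_ctrl)
    return _build_state(theta, se, "wald_mean_difference", look_index=look_index)


def interim_from_survival(s: SurvivalSummary, look_index: int = 1) -> InterimState:
    """Interim state from a survival summary on the log hazard ratio scale.

    With se(log HR) the information is exact (se**-2); with only the event
    count d the log-rank approximation I = d/4 is used (1:1 allocation) and
    the state is flagged approximate.
    """
    if s.se_log_hr is not None:
        info = s.se_log_hr ** -2
        approx = False
        method = "se_log_hr"
    else:
        info = s.total_events / 4.0
        approx = True
        method = "events_over_4"
    se = info ** -0.5
    theta = s.log_hazard_ratio
    return InterimState(
        look_index=look_index,
        z_value=theta * math.sqrt(info),
        information=info,
        estimate=theta,
        se=se,
        method=method,
        approximate=approx,
    )


def z_from_pvalue(
    p: float, sidedness: Sidedness | str, direction: Direction | str = Direction.benefit
) -> float:
    """Reconstruct a signed Z statistic from an exact reported p-value.

    One-sided: Z = Phi^-1(1 - p); two-sided: |Z| = Phi^-1(1 - p/2).  The
    sign is taken from ``direction`` (benefit-positive).  Only exact
    p-values are accepted: a bound such as "<0.001" carries too little
    information and must be refused upstream rather than imputed.
    """
    sidedness = Sidedness(sidedness)
    direction = Direction(direction)
    if not 0.0 < p < 1.0:
        raise DomainError(f"p-value must lie strictly in (0, 1), got {p}")
    tail = p if sidedness is Sidedness.one else p / 2.0
    z = float(ndtri(1.0 - tail))
    return z if direction is Direction.benefit else -z
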