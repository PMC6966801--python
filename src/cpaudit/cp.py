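"""Closed-form conditional power on the information-time scale.

Conditional power (CP) at the k-th interim analysis of a group-sequential
trial is the probability of rejecting the null hypothesis at trial
completion, given the interim data and a hypothesised true treatment effect
theta for the as-yet unobserved future data.  On the information scale the
accumulating score process is Brownian motion with drift theta, so with

* ``Z_k``  the interim test statistic,
* ``t_k = I_k / I_K``  the information fraction (information time),
* ``I_k = SE(theta_hat_k)**-2``  the interim information,
* ``c``    the final-analysis critical value,

the one-sided conditional power is

    CP_k(theta) = 1 - Phi( (c - Z_k*sqrt(t_k) - theta*sqrt(I_K)*(1 - t_k))
                           / sqrt(1 - t_k) )

and the two-sided version adds the symmetric lower-tail term with -c.

Sign convention is benefit-positive throughout: positive theta and Z favour
the experimental arm, and theta lives on the natural analysis scale (the
same scale as its standard error; log scale for ratio measures) so that
``theta * sqrt(I_K)`` is a dimensionless drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from scipy.special import ndtr, ndtri

__all__ = [
    "Sidedness",
    "OutcomeKind",
    "HypothesisKind",
    "DesignSpec",
    "InterimState",
    "FutureHypothesis",
    "CpResult",
    "DomainError",
    "InsufficientInformationError",
    "FullInformationError",
    "DEFAULT_FUTILITY_THRESHOLD",
    "critical_value",
    "total_information_from_design",
    "information_from_se",
    "information_fraction",
    "resolve_theta",
    "conditional_power",
    "classify_futility",
]

#: Futility threshold used throughout unless overridden; typical thresholds
#: quoted for stochastic-curtailment rules lie in 0.10-0.15.
DEFAULT_FUTILITY_THRESHOLD = 0.15

#: Relative tolerance for internal consistency checks (z vs estimate/se,
#: information vs se**-2).
CONSISTENCY_RTOL = 1e-8

#: Guard against floating-point overshoot when clamping CP into [0, 1].
CLAMP_GUARD = 1e-12


class DomainError(ValueError):
    """An argument lies outside its mathematical domain."""


class InsufficientInformationError(ValueError):
    """The available quantities do not determine the requested value.

    Mirrors the situation of a trial report that does not provide enough
    detail to compute conditional power; the audit layer catches this and
    records an ``insufficient`` status rather than failing.
    """


class FullInformationError(ValueError):
    """Interim information at or beyond the planned total.

    CP is undefined at t_k >= 1; the trial has (over-)reached full
    information and the final test should simply be evaluated.  Raised as a
    distinct class so pipelines can flag rather than silently clamp.
    """


class Sidedness(str, Enum):
    one = "one"
    two = "two"


class OutcomeKind(str, Enum):
    binary = "binary"
    continuous = "continuous"
    time_to_event = "time_to_event"
    other = "other"


class HypothesisKind(str, Enum):
    current_trend = "current_trend"
    design = "design"
    upper_cl = "upper_cl"
    null = "null"


def _as_enum(value, enum_cls):
    try:
        return enum_cls(value)
    except ValueError as exc:
        raise DomainError(
            f"{value!r} is not a valid {enum_cls.__name__}; "
            f"expected one of {[e.value for e in enum_cls]}"
        ) from exc


@dataclass(frozen=True)
class DesignSpec:
    """Planning parameters of a trial.

    Parameters
    ----------
    alpha
        Type-I error rate, in (0, 0.5].
    sidedness
        ``"one"`` or ``"two"``; governs the critical value convention.
    planned_power
        Power at the design effect, in (0, 1).
    design_effect
        Target treatment effect theta_d on the natural analysis scale,
        benefit-positive, nonzero.
    total_information
        Planned total Fisher information I_K.  Optional; when absent it is
        derived from (alpha, planned_power, design_effect).
    planned_total_n
        Planned total sample size (descriptive only; information is never
        derived from it because no variance model would be available).
    outcome_kind
        Statistical type of the primary outcome.
    """

    alpha: float
    sidedness: Sidedness
    planned_power: float
    design_effect: float
    total_information: Optional[float] = None
    planned_total_n: Optional[int] = None
    outcome_kind: OutcomeKind = OutcomeKind.other

    def __post_init__(self):
        object.__setattr__(self, "sidedness", _as_enum(self.sidedness, Sidedness))
        object.__setattr__(self, "outcome_kind", _as_enum(self.outcome_kind, OutcomeKind))
        if not 0.0 < self.alpha <= 0.5:
            raise DomainError(f"alpha must be in (0, 0.5], got {self.alpha}")
        if not 0.0 < self.planned_power < 1.0:
            raise DomainError(f"planned_power must be in (0, 1), got {self.planned_power}")
        if self.design_effect == 0:
            raise DomainError("design_effect must be nonzero")
        if self.total_information is not None and not self.total_information > 0:
            raise DomainError(f"total_information must be > 0, got {self.total_information}")
        if self.planned_total_n is not None and not self.planned_total_n > 0:
            raise DomainError(f"planned_total_n must be > 0, got {self.planned_total_n}")


@dataclass(frozen=True)
class InterimState:
    """The state of a trial at its k-th interim look.

    At least one of ``information`` / ``info_fraction`` must be present by
    the time conditional power is computed.  When redundant quantities are
    supplied they must be mutually consistent: ``information == se**-2`` and
    ``z_value == estimate / se`` to relative tolerance 1e-8.
    """

    look_index: int
    z_value: float
    information: Optional[float] = None
    info_fraction: Optional[float] = None
    estimate: Optional[float] = None
    se: Optional[float] = None
    # provenance tags set by the effect-scale converters
    method: Optional[str] = None
    approximate: bool = False

    def __post_init__(self):
        if self.look_index < 1:
            raise DomainError(f"look_index must be >= 1, got {self.look_index}")
        if self.information is not None and not self.information > 0:
            raise DomainError(f"information must be > 0, got {self.information}")
        if self.info_fraction is not None and not 0.0 < self.info_fraction < 1.0:
            raise DomainError(
                f"info_fraction must lie strictly in (0, 1), got {self.info_fraction}"
            )
        if self.se is not None and not self.se > 0:
            raise DomainError(f"se must be > 0, got {self.se}")
        if self.se is not None and self.information is not None:
            if not math.isclose(self.information, self.se ** -2, rel_tol=CONSISTENCY_RTOL):
                raise DomainError(
                    f"information ({self.information}) inconsistent with "
                    f"se**-2 ({self.se ** -2})"
                )
        if self.se is not None and self.estimate is not None:
            if not math.isclose(
                self.z_value, self.estimate / self.se, rel_tol=CONSISTENCY_RTOL, abs_tol=1e-12
            ):
                raise DomainError(
                    f"z_value ({self.z_value}) inconsistent with "
                    f"estimate/se ({self.estimate / self.se})"
                )


@dataclass(frozen=True)
class FutureHypothesis:
    """Which theta the CP calculation assumes for the unobserved future data.

    ``current_trend`` continues the interim estimate; ``design`` retains the
    protocol effect; ``upper_cl`` optimistically adopts the upper limit of a
    two-sided interim confidence interval at ``confidence_level``; ``null``
    assumes no treatment effect.
    """

    kind: HypothesisKind
    confidence_level: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "kind", _as_enum(self.kind, HypothesisKind))
        if self.kind is HypothesisKind.upper_cl:
            if self.confidence_level is None:
                raise DomainError("upper_cl hypothesis requires a confidence_level")
            if not 0.0 < self.confidence_level < 1.0:
                raise DomainError(
                    f"confidence_level must be in (0, 1), got {self.confidence_level}"
                )
        elif self.confidence_level is not None:
            raise DomainError(
                f"confidence_level is only meaningful for upper_cl, got kind={self.kind.value}"
            )


@dataclass(frozen=True)
class CpResult:
    """A conditional power evaluation and the convention it used."""

    cp: float
    theta_used: float
    t_k: float
    critical_value: float
    sidedness: Sidedness
    futile: bool
    threshold: float
    hypothesis: HypothesisKind


def critical_value(alpha: float, sidedness: Sidedness | str) -> float:
    """Final-analysis critical value on the Z scale.

    Phi^-1(1 - alpha) for a one-sided test, Phi^-1(1 - alpha/2) for a
    two-sided test (so the unconditional two-sided rejection probability
    under the null equals alpha).
    """
    sidedness = _as_enum(sidedness, Sidedness)
    if not 0.0 < alpha <= 0.5:
        raise DomainError(f"alpha must be in (0, 0.5], got {alpha}")
    tail = alpha if sidedness is Sidedness.one else alpha / 2.0
    return float(ndtri(1.0 - tail))


def total_information_from_design(design: DesignSpec) -> float:
    """Planned total information I_K.

    An explicitly specified ``total_information`` takes precedence.
    Otherwise I_K is derived from the standard sample-size identity on the
    information scale,

        I_K = ((c + Phi^-1(power)) / |theta_d|) ** 2,

    which makes the unconditional power at theta_d equal the planned power.
    """
    if design.total_information is not None:
        return design.total_information
    c = critical_value(design.alpha, design.sidedness)
    z_power = float(ndtri(design.planned_power))
    return ((c + z_power) / abs(design.design_effect)) ** 2


def information_from_se(se: float) -> float:
    """Fisher information implied by a standard error: I = SE**-2."""
    if not se > 0:
        raise DomainError(f"se must be > 0, got {se}")
    return se ** -2


def information_fraction(i_k: float, i_total: float) -> float:
    """Information time t_k = I_k / I_K, strictly inside (0, 1).

    Raises
    ------
    FullInformationError
        If ``i_k >= i_total``: the interim is at or beyond full information
        (one surveyed trial's interim sample size slightly exceeded its
        original target), where CP is undefined and the final test should be
        reported instead.  Never clamped.
    """
    if not i_k > 0 or not i_total > 0:
        raise DomainError(f"information values must be > 0, got ({i_k}, {i_total})")
    if i_k >= i_total:
        raise FullInformationError(
            f"interim information {i_k} is at or beyond total {i_total}: "
            "CP undefined; report current significance instead"
        )
    return i_k / i_total


def resolve_theta(
    interim: InterimState, design: DesignSpec, hypothesis: FutureHypothesis
) -> float:
    """Treatment effect assumed for future data under ``hypothesis``.

    current_trend -> interim estimate; design -> protocol effect; null -> 0;
    upper_cl at level gamma -> estimate + Phi^-1((1+gamma)/2) * se (the
    upper limit of the usual two-sided interim confidence interval).
    """
    kind = hypothesis.kind
    if kind is HypothesisKind.null:
        return 0.0
    if kind is HypothesisKind.design:
        return design.design_effect
    if interim.estimate is None:
        raise InsufficientInformationError(
            f"{kind.value} hypothesis requires an interim effect estimate"
        )
    if kind is HypothesisKind.current_trend:
        return interim.estimate
    # upper_cl
    if interim.se is None:
        raise InsufficientInformationError(
            "upper_cl hypothesis requires the interim standard error"
        )
    gamma = hypothesis.confidence_level
    return interim.estimate + float(ndtri((1.0 + gamma) / 2.0)) * interim.se


def _resolve_t_k(interim: InterimState, i_total: float) -> float:
    if interim.info_fraction is not None:
        return interim.info_fraction
    information = interim.information
    if information is None and interim.se is not None:
        information = information_from_se(interim.se)
    if information is None:
        raise InsufficientInformationError(
            "cannot resolve the information fraction: interim has neither "
            "info_fraction nor information (nor an se to derive it from)"
        )
    return information_fraction(information, i_total)


def conditional_power(
    interim: InterimState,
    design: DesignSpec,
    hypothesis: FutureHypothesis,
    threshold: float = DEFAULT_FUTILITY_THRESHOLD,
) -> CpResult:
    """Closed-form conditional power at an interim analysis.

    Resolves theta via :func:`resolve_theta`, I_K via
    :func:`total_information_from_design`, and t_k from the interim state,
    then evaluates

        one-sided: CP = 1 - Phi(u(c)),
        two-sided: CP = 1 - Phi(u(c)) + Phi(u(-c) - ...),

    with u(c) = (c - Z_k*sqrt(t_k) - theta*sqrt(I_K)*(1-t_k)) / sqrt(1-t_k).
    The result is clamped into [0, 1] only against floating-point overshoot
    (guard 1e-12).  ``futile`` is set by strict ``cp < threshold``.
    """
    if not 0.0 <= threshold <= 1.0:
        raise DomainError(f"threshold must be in [0, 1], got {threshold}")
    theta = resolve_theta(interim, design, hypothesis)
    i_total = total_information_from_design(design)
    t_k = _resolve_t_k(interim, i_total)
    if not 0.0 < t_k < 1.0:
        raise DomainError(f"information fraction must lie in (0, 1), got {t_k}")
    c = critical_value(design.alpha, design.sidedness)

    drift = theta * math.sqrt(i_total) * (1.0 - t_k)
    scale = math.sqrt(1.0 - t_k)
    b = interim.z_value * math.sqrt(t_k)  # B-value: Brownian motion at time t_k
    cp = 1.0 - float(ndtr((c - b - drift) / scale))
    if design.sidedness is Sidedness.two:
        cp += float(ndtr((-c - b - drift) / scale))

    if cp < 0.0:
        if cp < -CLAMP_GUARD:
            raise AssertionError(f"conditional power {cp} below clamp guard")
        cp = 0.0
    elif cp > 1.0:
        if cp > 1.0 + CLAMP_GUARD:
            raise AssertionError(f"conditional power {cp} above clamp guard")
        cp = 1.0

    return CpResult(
        cp=cp,
        theta_used=theta,
        t_k=t_k,
        critical_value=c,
        sidedness=design.sidedness,
        futile=classify_futility(cp, threshold),
        threshold=threshold,
        hypothesis=hypothesis.kind,
    )


def classify_futility(cp: float, threshold: float) -> bool:
    """True iff conditional power falls strictly below the futility threshold."""
    if not 0.0 <= cp <= 1.0:
        raise DomainError(f"cp must be in [0, 1], got {cp}")
    if not 0.0 <= threshold <= 1.0:
        raise DomainError(f"threshold must be in [0, 1], got {threshold}")
    return cp < threshold
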