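"""Registry ingestion and conditional-power auditing of stopped trials.

The audit asks, for every trial in a registry of futility stops: given what
the report discloses, what conditional power did the trial have at its last
interim analysis, under (i) the current-trend hypothesis and (ii) the
original design hypothesis?  Each trial ends in one of three statuses:

* ``computed``      — at least one CP could be recomputed from the report;
* ``reported_only`` — nothing recomputable, but the authors printed a CP
  value, which is retained verbatim (never back-solved, since the authors'
  sidedness/hypothesis conventions are usually unstated);
* ``insufficient``  — neither recomputable nor reported (the report gives
  at most a p-value bound), with a machine-readable failure reason.

Summaries bin CP into <15%, 15-30%, 30-50% and >50% and stratify by
sponsor; reported-only values are binned under the current-trend hypothesis,
the convention of treating author-reported CPs as current-trend values.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .cp import (
    DesignSpec,
    DomainError,
    FullInformationError,
    FutureHypothesis,
    HypothesisKind,
    InsufficientInformationError,
    InterimState,
    Sidedness,
    DEFAULT_FUTILITY_THRESHOLD,
    classify_futility,
    conditional_power,
    information_fraction,
    information_from_se,
    total_information_from_design,
)
from . import scales

logger = logging.getLogger(__name__)

__all__ = [
    "TrialRecord",
    "CpAudit",
    "SurveySummary",
    "RegistryFormatError",
    "CP_BIN_EDGES",
    "CP_BIN_LABELS",
    "read_trial_table",
    "records_from_frame",
    "audit_trial",
    "audit_table",
    "bin_cp",
    "summarize_survey",
    "audits_to_frame",
]

CP_BIN_EDGES = (0.15, 0.30, 0.50)
CP_BIN_LABELS = ("<15%", "15-30%", "30-50%", ">50%")


class RegistryFormatError(ValueError):
    """The registry file violates a hard structural constraint."""


@dataclass(frozen=True)
class TrialRecord:
    """One registry row; every column except ``trial_id`` may be missing.

    ``design_effect`` is interpreted through ``design_effect_scale``:
    ``natural`` means the value already lives on the analysis scale, while
    ``log_ratio`` means the cell holds a ratio (odds/hazard ratio) whose log
    is the analysis-scale effect.  Unknown columns are preserved in
    ``extra``; parse-time domain violations are collected in ``issues`` and
    exclude the record from CP computation without aborting the run.
    """

    trial_id: str
    # design
    alpha: Optional[float] = None
    sidedness: Optional[str] = None
    planned_power: Optional[float] = None
    design_effect: Optional[float] = None
    design_effect_scale: Optional[str] = None
    planned_total_n: Optional[int] = None
    outcome_kind: Optional[str] = None
    measure: Optional[str] = None
    total_information: Optional[float] = None
    # interim
    estimate: Optional[float] = None
    se: Optional[float] = None
    z_value: Optional[float] = None
    p_value: Optional[float] = None
    p_is_bound: Optional[bool] = None
    info_fraction: Optional[float] = None
    interim_n: Optional[int] = None
    n_looks_planned: Optional[int] = None
    n_looks_actual: Optional[int] = None
    # optional arm-level summaries
    events_treat: Optional[int] = None
    n_treat: Optional[int] = None
    events_ctrl: Optional[int] = None
    n_ctrl: Optional[int] = None
    mean_treat: Optional[float] = None
    mean_ctrl: Optional[float] = None
    sd_treat: Optional[float] = None
    sd_ctrl: Optional[float] = None
    # metadata
    sponsor: Optional[str] = None
    dsmb: Optional[bool] = None
    decision_maker: Optional[str] = None
    reported_cp: Optional[float] = None
    reported_cp_hypothesis: Optional[str] = None
    data_collection_continued: Optional[bool] = None
    issues: tuple = ()
    extra: dict = field(default_factory=dict)


@dataclass(frozen=True)
class CpAudit:
    """Audit verdict for one trial."""

    trial_id: str
    status: str  # computed | reported_only | insufficient
    cp_current_trend: Optional[float] = None
    cp_design: Optional[float] = None
    reported_cp: Optional[float] = None
    futile_at_threshold: Optional[bool] = None
    failure_reason: Optional[str] = None
    assumptions: tuple = ()

    def __post_init__(self):
        if self.status not in ("computed", "reported_only", "insufficient"):
            raise DomainError(f"unknown audit status {self.status!r}")
        has_cp = self.cp_current_trend is not None or self.cp_design is not None
        if (self.status == "computed") != has_cp:
            raise DomainError("status 'computed' must coincide with a computed CP")
        if (self.status == "insufficient") != (self.failure_reason is not None):
            raise DomainError("status 'insufficient' must coincide with a failure_reason")


# --------------------------------------------------------------------------
# Table reading
# --------------------------------------------------------------------------

_FLOAT_COLS = {
    "alpha", "planned_power", "design_effect", "total_information", "estimate",
    "se", "z_value", "p_value", "info_fraction", "reported_cp",
    "mean_treat", "mean_ctrl", "sd_treat", "sd_ctrl",
}
_INT_COLS = {
    "planned_total_n", "interim_n", "n_looks_planned", "n_looks_actual",
    "events_treat", "n_treat", "events_ctrl", "n_ctrl",
}
_BOOL_COLS = {"p_is_bound", "dsmb", "data_collection_continued"}
_TRUE_TOKENS = {"true", "yes", "y", "1", "1.0"}
_FALSE_TOKENS = {"false", "no", "n", "0", "0.0"}

# (predicate, message) domain checks applied at parse time; failing rows are
# kept but excluded from CP computation.
_DOMAIN_CHECKS = {
    "alpha": (lambda v: 0.0 < v <= 0.5, "alpha out of domain (0, 0.5]"),
    "planned_power": (lambda v: 0.0 < v < 1.0, "planned_power out of domain (0, 1)"),
    "se": (lambda v: v > 0.0, "se must be positive"),
    "p_value": (lambda v: 0.0 < v < 1.0, "p_value out of domain (0, 1)"),
    "reported_cp": (lambda v: 0.0 <= v <= 1.0, "reported_cp out of domain [0, 1]"),
    "total_information": (lambda v: v > 0.0, "total_information must be positive"),
    "sidedness": (lambda v: v in ("one", "two"), "sidedness must be 'one' or 'two'"),
    "design_effect_scale": (
        lambda v: v in ("natural", "log_ratio"),
        "design_effect_scale must be 'natural' or 'log_ratio'",
    ),
}

_KNOWN_FIELDS = {f.name for f in dc_fields(TrialRecord)} - {"issues", "extra"}


def _parse_cell(name: str, raw: str, issues: list):
    text = raw.strip()
    if text == "":
        return None
    if name in _FLOAT_COLS:
        try:
            value = float(text)
        except ValueError:
            issues.append(f"{name}: unparseable number {text!r}")
            return None
    elif name in _INT_COLS:
        try:
            value = int(float(text))
        except ValueError:
            issues.append(f"{name}: unparseable integer {text!r}")
            return None
    elif name in _BOOL_COLS:
        low = text.lower()
        if low in _TRUE_TOKENS:
            return True
        if low in _FALSE_TOKENS:
            return False
        issues.append(f"{name}: unparseable boolean {text!r}")
        return None
    else:
        value = text
    check = _DOMAIN_CHECKS.get(name)
    if check is not None and not check[0](value):
        issues.append(f"{name}: {check[1]} (got {value!r})")
        return None
    return value


def records_from_frame(frame: pd.DataFrame) -> list[TrialRecord]:
    """Parse a raw (string-valued or typed) table into validated records."""
    if "trial_id" not in frame.columns:
        raise RegistryFormatError("registry table has no trial_id column")
    records: list[TrialRecord] = []
    seen: dict[str, int] = {}
    for pos, row in enumerate(frame.to_dict(orient="records")):
        raw_id = row.get("trial_id")
        trial_id = "" if raw_id is None or (isinstance(raw_id, float) and math.isnan(raw_id)) \
            else str(raw_id).strip()
        if not trial_id:
            raise RegistryFormatError(f"row {pos}: missing trial_id")
        if trial_id in seen:
            raise RegistryFormatError(
                f"duplicate trial_id {trial_id!r} at rows {seen[trial_id]} and {pos}"
            )
        seen[trial_id] = pos
        issues: list = []
        kwargs: dict = {"trial_id": trial_id}
        extra: dict = {}
        for name, raw in row.items():
            if name == "trial_id":
                continue
            if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                text = ""
            else:
                text = str(raw)
            if name in _KNOWN_FIELDS:
                kwargs[name] = _parse_cell(name, text, issues)
            else:
                extra[name] = text if text else None
        # percent-style information fractions are auto-detected
        frac = kwargs.get("info_fraction")
        if frac is not None and 1.0 < frac <= 100.0:
            logger.warning(
                "trial %s: info_fraction %s interpreted as a percentage",
                trial_id, frac,
            )
            kwargs["info_fraction"] = frac / 100.0
        records.append(TrialRecord(issues=tuple(issues), extra=extra, **kwargs))
    return records


def read_trial_table(path, delimiter: str = ",") -> list[TrialRecord]:
    """Read a registry CSV into validated :class:`TrialRecord` objects.

    Missing cells become ``None``; per-cell domain violations are collected
    in each record's ``issues`` (non-fatal); a missing or duplicated
    trial_id is a hard error.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    return records_from_frame(frame)


# --------------------------------------------------------------------------
# Per-trial audit
# --------------------------------------------------------------------------

def _design_from_record(
    record: TrialRecord, default_sidedness: str, assumptions: list
) -> DesignSpec:
    missing = [name for name in ("alpha", "planned_power", "design_effect")
               if getattr(record, name) is None]
    if missing:
        raise InsufficientInformationError(
            "missing design parameters: " + ", ".join(missing)
        )
    sidedness = record.sidedness
    if sidedness is None:
        sidedness = default_sidedness
        assumptions.append(f"sidedness not stated; assumed {default_sidedness}-sided")
    theta_d = record.design_effect
    if record.design_effect_scale == "log_ratio":
        if theta_d <= 0:
            raise DomainError(
                f"design_effect {theta_d} on a ratio scale must be positive"
            )
        theta_d = abs(math.log(theta_d))
        assumptions.append("design effect converted from ratio to log scale")
    else:
        theta_d = abs(theta_d)
    return DesignSpec(
        alpha=record.alpha,
        sidedness=sidedness,
        planned_power=record.planned_power,
        design_effect=theta_d,
        total_information=record.total_information,
        planned_total_n=record.planned_total_n,
        outcome_kind=record.outcome_kind or "other",
    )


def _interim_from_arms(record: TrialRecord, assumptions: list) -> Optional[InterimState]:
    binary_cols = (record.events_treat, record.n_treat, record.events_ctrl, record.n_ctrl)
    cont_cols = (record.mean_treat, record.mean_ctrl, record.sd_treat,
                 record.sd_ctrl, record.n_treat, record.n_ctrl)
    if all(v is not None for v in binary_cols) and record.mean_treat is None:
        arms = scales.BinaryArms(
            events_treat=record.events_treat, n_treat=record.n_treat,
            events_ctrl=record.events_ctrl, n_ctrl=record.n_ctrl,
            measure=record.measure or "risk_difference",
        )
        assumptions.append("interim effect reconstructed from per-arm event counts")
        return scales.interim_from_binary(arms)
    if all(v is not None for v in cont_cols):
        arms = scales.ContinuousArms(
            mean_treat=record.mean_treat, mean_ctrl=record.mean_ctrl,
            sd_treat=record.sd_treat, sd_ctrl=record.sd_ctrl,
            n_treat=record.n_treat, n_ctrl=record.n_ctrl,
        )
        assumptions.append("interim effect reconstructed from per-arm means/SDs")
        return scales.interim_from_continuous(arms)
    return None


def _assemble_interim(
    record: TrialRecord, design: DesignSpec, assumptions: list
) -> InterimState:
    """Best-available reconstruction: z > estimate+se > exact p > arm summaries."""
    look = max(record.n_looks_actual or 1, 1)
    z = record.z_value
    estimate, se = record.estimate, record.se
    if z is None and estimate is not None and se is not None:
        z = estimate / se
    if z is None and record.p_value is not None:
        if record.p_is_bound:
            raise InsufficientInformationError(
                "p_value is only a bound; cannot reconstruct the interim Z"
            )
        direction = "benefit"
        if estimate is not None and estimate < 0:
            direction = "harm"
        elif estimate is None:
            assumptions.append("p_value direction not stated; assumed benefit")
        z = scales.z_from_pvalue(record.p_value, design.sidedness, direction)
        assumptions.append("interim Z reconstructed from the exact p_value")
    if z is None:
        from_arms = _interim_from_arms(record, assumptions)
        if from_arms is not None:
            z, estimate, se = from_arms.z_value, from_arms.estimate, from_arms.se
    if z is None:
        raise InsufficientInformationError(
            "no interim test statistic: needs z_value, estimate+se, an exact "
            "p_value, or per-arm summaries"
        )
    if estimate is None and se is not None:
        estimate = z * se

    # information fraction: stated > sample-size ratio > information ratio
    t_k = record.info_fraction
    if t_k is None and record.interim_n is not None and record.planned_total_n is not None:
        t_k = record.interim_n / record.planned_total_n
        assumptions.append("information fraction taken as interim_n / planned_total_n")
    if t_k is None and se is not None:
        i_k = information_from_se(se)
        i_total = total_information_from_design(design)
        t_k = information_fraction(i_k, i_total)  # raises beyond full information
        assumptions.append("information fraction taken as I_k / I_K from the SE")
    if t_k is None:
        raise InsufficientInformationError(
            "no information fraction: needs info_fraction, interim and planned "
            "sample sizes, or an SE with resolvable total information"
        )
    if t_k >= 1.0:
        raise FullInformationError(
            f"information fraction {t_k} at or beyond full information; "
            "CP undefined, report current significance instead"
        )
    return InterimState(
        look_index=look, z_value=z, info_fraction=t_k, estimate=estimate, se=se,
    )


def audit_trial(
    record: TrialRecord,
    threshold: float = DEFAULT_FUTILITY_THRESHOLD,
    default_sidedness: str = "two",
) -> CpAudit:
    """Audit one trial: recompute CP where possible, else fall back.

    Both hypotheses are attempted independently; a failure of one never
    blocks the other.  The futility flag uses the current-trend CP when
    present, else the design CP.  Nothing here is fatal: every failure mode
    becomes a status.
    """
    assumptions: list = []
    failures: list = []

    if record.issues:
        return CpAudit(
            trial_id=record.trial_id,
            status="reported_only" if record.reported_cp is not None else "insufficient",
            reported_cp=record.reported_cp,
            failure_reason=None if record.reported_cp is not None
            else "domain issues at parse time: " + "; ".join(record.issues),
            assumptions=tuple(record.issues),
        )

    cp_current = cp_design = None
    try:
        design = _design_from_record(record, default_sidedness, assumptions)
        interim = _assemble_interim(record, design, assumptions)
    except (InsufficientInformationError, FullInformationError, DomainError) as exc:
        failures.append(str(exc))
    else:
        for kind, slot in ((HypothesisKind.current_trend, "current"),
                           (HypothesisKind.design, "design")):
            try:
                result = conditional_power(
                    interim, design, FutureHypothesis(kind), threshold
                )
            except (InsufficientInformationError, FullInformationError,
                    DomainError) as exc:
                failures.append(f"{kind.value}: {exc}")
            else:
                if slot == "current":
                    cp_current = result.cp
                else:
                    cp_design = result.cp

    if cp_current is not None or cp_design is not None:
        flag_cp = cp_current if cp_current is not None else cp_design
        return CpAudit(
            trial_id=record.trial_id,
            status="computed",
            cp_current_trend=cp_current,
            cp_design=cp_design,
            reported_cp=record.reported_cp,
            futile_at_threshold=classify_futility(flag_cp, threshold),
            assumptions=tuple(assumptions),
        )
    if record.reported_cp is not None:
        return CpAudit(
            trial_id=record.trial_id,
            status="reported_only",
            reported_cp=record.reported_cp,
            assumptions=tuple(assumptions),
        )
    return CpAudit(
        trial_id=record.trial_id,
        status="insufficient",
        failure_reason="; ".join(failures) or "no usable interim information",
        assumptions=tuple(assumptions),
    )


def audit_table(
    records: Sequence[TrialRecord],
    threshold: float = DEFAULT_FUTILITY_THRESHOLD,
    default_sidedness: str = "two",
) -> list[CpAudit]:
    return [audit_trial(r, threshold, default_sidedness) for r in records]


# --------------------------------------------------------------------------
# Summaries
# --------------------------------------------------------------------------

def bin_cp(values: Sequence[float]) -> tuple[int, int, int, int]:
    """Bin CP values into [0, 0.15), [0.15, 0.30), [0.30, 0.50), [0.50, 1].

    Left-closed/right-open except the last bin, which is closed at 1; this
    makes "conditional power below 15%" literal.
    """
    counts = [0, 0, 0, 0]
    for v in values:
        if not 0.0 <= v <= 1.0:
            raise DomainError(f"CP value out of [0, 1]: {v}")
        if v < CP_BIN_EDGES[0]:
            counts[0] += 1
        elif v < CP_BIN_EDGES[1]:
            counts[1] += 1
        elif v < CP_BIN_EDGES[2]:
            counts[2] += 1
        else:
            counts[3] += 1
    return tuple(counts)


@dataclass(frozen=True)
class SurveySummary:
    """Registry-level tallies in the style of a futility-stop survey report."""

    n_trials: int
    status_counts: dict
    bins_current_trend: tuple  # computed + reported-only, current-trend convention
    bins_design: tuple
    bins_by_sponsor: dict  # sponsor -> 4-bin tuple (current-trend convention)
    categorical_tallies: dict  # column -> {value: count}

    def __post_init__(self):
        if sum(self.status_counts.values()) != self.n_trials:
            raise DomainError("audit status counts do not sum to n_trials")


_CATEGORICAL_COLUMNS = (
    "outcome_kind", "sidedness", "sponsor", "dsmb", "decision_maker",
    "data_collection_continued", "measure", "reported_cp_hypothesis",
)


def summarize_survey(
    audits: Sequence[CpAudit], records: Sequence[TrialRecord]
) -> SurveySummary:
    """Aggregate audits into status counts, CP bins and metadata tallies.

    Reported-only CPs are binned under the current-trend hypothesis (the
    convention for author-reported values whose assumptions are unstated).
    Conservation is asserted: statuses sum to n_trials and bins sum to the
    number of CP values binned per hypothesis.
    """
    audit_ids = [a.trial_id for a in audits]
    record_ids = [r.trial_id for r in records]
    if set(audit_ids) != set(record_ids) or len(audit_ids) != len(record_ids):
        orphans = set(audit_ids) ^ set(record_ids)
        raise DomainError(f"audits and records do not match; orphans: {sorted(orphans)}")

    status_counts = Counter(a.status for a in audits)
    by_id = {r.trial_id: r for r in records}

    current_values = [a.cp_current_trend for a in audits if a.cp_current_trend is not None]
    current_values += [a.reported_cp for a in audits
                       if a.status == "reported_only" and a.reported_cp is not None]
    design_values = [a.cp_design for a in audits if a.cp_design is not None]

    bins_current = bin_cp(current_values)
    bins_design = bin_cp(design_values)
    assert sum(bins_current) == len(current_values)
    assert sum(bins_design) == len(design_values)

    bins_by_sponsor: dict = {}
    sponsor_values: dict = {}
    for a in audits:
        value = a.cp_current_trend
        if value is None and a.status == "reported_only":
            value = a.reported_cp
        if value is None:
            continue
        sponsor = by_id[a.trial_id].sponsor or "unknown"
        sponsor_values.setdefault(sponsor, []).append(value)
    for sponsor, values in sorted(sponsor_values.items()):
        bins_by_sponsor[sponsor] = bin_cp(values)

    tallies: dict = {}
    for column in _CATEGORICAL_COLUMNS:
        values = [getattr(r, column) for r in records]
        if all(v is None for v in values):
            continue
        counter = Counter("missing" if v is None else str(v) for v in values)
        tallies[column] = dict(sorted(counter.items()))

    return SurveySummary(
        n_trials=len(records),
        status_counts=dict(status_counts),
        bins_current_trend=bins_current,
        bins_design=bins_design,
        bins_by_sponsor=bins_by_sponsor,
        categorical_tallies=tallies,
    )


def audits_to_frame(audits: Sequence[CpAudit]) -> pd.DataFrame:
    """Tabulate audit verdicts for delimited-text output."""
    return pd.DataFrame(
        {
            "trial_id": [a.trial_id for a in audits],
            "status": [a.status for a in audits],
            "cp_current_trend": [a.cp_current_trend for a in audits],
            "cp_design": [a.cp_design for a in audits],
            "reported_cp": [a.reported_cp for a in audits],
            "futile_at_threshold": [a.futile_at_threshold for a in audits],
            "failure_reason": [a.failure_reason for a in audits],
            "assumptions": ["; ".join(a.assumptions) for a in audits],
        }
    )
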