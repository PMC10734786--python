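"""Participant eligibility, cohort-composition quotas and stability checks.

A cfPWV validation cohort must contain >= 85 analysable participants
(>= 90 enrolled), span the reference PWV range (>= 5% of readings <= 6 m/s,
>= 20% >= 8 m/s, >= 5% >= 10 m/s; cutoffs scaled for other arterial beds),
and spread over four age bands (<30, 30-49, 50-69, >= 70 years) with at
least 10 participants and >= 40% of each sex per band. Individual
participants are excluded for age < 18, BMI >= 40 kg/m2, non-sinus rhythm
or pacemaker dependence, relevant arterial stenosis between the measurement
sites, severe aortic valve stenosis, impalpable arteries, or measurement
within the acute-effect window of a vasoactive dose.

Sequential transit-time sessions additionally require hemodynamic
stability: < 5% change in heart rate and in systolic and diastolic blood
pressure between the start and end of the recordings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

from .agreement import AGE_BANDS, MeasurementSession, age_band_label
from .errors import DomainError, ValidationDataError

__all__ = [
    "ParticipantRecord",
    "EligibilityDecision",
    "CompositionReport",
    "StabilityDecision",
    "check_eligibility",
    "check_composition",
    "check_hemodynamic_stability",
    "VASOACTIVE_ACUTE_WINDOW_H",
    "STABILITY_THRESHOLD",
]

#: Default acute-effect window (hours) after a vasoactive dose during which
#: validation measurements must not be recorded. The protocol names the
#: window without a number; 24 h covers the common long-acting agents.
VASOACTIVE_ACUTE_WINDOW_H = 24.0

#: Maximum relative hemodynamic change tolerated in sequential sessions.
STABILITY_THRESHOLD = 0.05

Sex = Literal["male", "female"]
Rhythm = Literal["sinus", "afib", "paced", "other"]


@dataclass(frozen=True)
class ParticipantRecord:
    id: str
    age: float                 # years
    sex: Sex
    bmi: float                 # kg/m2
    rhythm: Rhythm = "sinus"
    vasoactive_meds: bool = False
    hours_since_dose: float | None = None
    relevant_stenosis: bool = False
    severe_aortic_stenosis: bool = False
    palpable_arteries: bool = True
    reference_pwv: float | None = None  # mean of reference readings, m/s

    def __post_init__(self) -> None:
        if self.age < 0:
            raise DomainError(f"age must be >= 0, got {self.age}")
        if self.bmi <= 0:
            raise DomainError(f"bmi must be > 0, got {self.bmi}")


@dataclass(frozen=True)
class EligibilityDecision:
    eligible: bool
    failed_rules: tuple[str, ...]


@dataclass(frozen=True)
class CompositionReport:
    """Cohort-composition findings; empty ``violations`` means all quotas met."""

    n_total: int
    n_complete: int
    n_enrolled: int
    age_band_counts: dict[str, int]
    age_band_sex_fractions: dict[str, dict[str, float]]
    pwv_fractions: dict[str, float]      # fractions at the (scaled) cutoffs
    evenness_ratio: float                # min/max band count (reported only)
    violations: tuple[tuple[str, float, float], ...]  # (rule, observed, required)

    @property
    def satisfied(self) -> bool:
        return not self.violations


@dataclass(frozen=True)
class StabilityDecision:
    stable: bool
    changes_percent: dict[str, float]    # per-variable relative change, %


def check_eligibility(record: ParticipantRecord,
                      vasoactive_window_h: float = VASOACTIVE_ACUTE_WINDOW_H,
                      ) -> EligibilityDecision:
    """Apply the participant selection criteria; every failed rule is listed."""
    failed: list[str] = []
    if record.age < 18:
        failed.append("age: participants must be >= 18 years")
    if record.bmi >= 40.0:
        failed.append("bmi: body mass index >= 40 kg/m2 (path-length "
                      "measurement unreliable)")
    if record.rhythm != "sinus":
        failed.append(f"rhythm: must be sinus, not {record.rhythm} "
                      "(pacemaker dependence / beat-to-beat variation)")
    if record.relevant_stenosis:
        failed.append("stenosis: relevant arterial stenosis between "
                      "measurement sites")
    if record.severe_aortic_stenosis:
        failed.append("aortic_stenosis: severe aortic valve stenosis")
    if not record.palpable_arteries:
        failed.append("palpation: relevant arteries not palpable")
    if record.vasoactive_meds:
        if record.hours_since_dose is None:
            raise ValidationDataError(
                "vasoactive_meds set but hours_since_dose missing",
                participant_id=record.id)
        if record.hours_since_dose < vasoactive_window_h:
            failed.append(
                f"vasoactive: measured {record.hours_since_dose:g} h after "
                f"dose, within the {vasoactive_window_h:g} h acute window")
    return EligibilityDecision(eligible=not failed, failed_rules=tuple(failed))


#: (rule id, cutoff m/s, direction, minimum fraction) for cfPWV cohorts.
_PWV_QUOTAS = (("pwv<=6 >=5%", 6.0, "le", 0.05),
               ("pwv>=8 >=20%", 8.0, "ge", 0.20),
               ("pwv>=10 >=5%", 10.0, "ge", 0.05))

MIN_COMPLETE = 85
MIN_ENROLLED = 90
MIN_PER_BAND = 10
MIN_SEX_FRACTION = 0.40


def check_composition(cohort: Sequence[ParticipantRecord],
                      scale_factor: float = 1.0,
                      n_enrolled: int | None = None) -> CompositionReport:
    """Check cohort composition against the protocol quotas.

    ``scale_factor`` multiplies the 6 / 8 / 10 m/s reference-PWV cutoffs for
    arterial beds other than carotid-femoral (1.0 for cfPWV). ``n_enrolled``
    defaults to the cohort size (no separate dropout bookkeeping). A report
    is always returned; quota failures are listed in ``violations`` as
    (rule id, observed, required) and never raise.
    """
    if not cohort:
        raise DomainError("cohort must be nonempty")
    if scale_factor <= 0:
        raise DomainError("scale_factor must be > 0")
    n_total = len(cohort)
    complete = [r for r in cohort if r.reference_pwv is not None]
    n_complete = len(complete)
    n_enr = n_total if n_enrolled is None else n_enrolled

    violations: list[tuple[str, float, float]] = []
    if n_complete < MIN_COMPLETE:
        violations.append(("n_complete>=85", n_complete, MIN_COMPLETE))
    if n_enr < MIN_ENROLLED:
        violations.append(("n_enrolled>=90", n_enr, MIN_ENROLLED))

    pwv_fracs: dict[str, float] = {}
    if complete:
        pwvs = [r.reference_pwv for r in complete]
        for rule, cutoff, direction, frac_req in _PWV_QUOTAS:
            c = cutoff * scale_factor
            hit = sum(1 for v in pwvs
                      if (v <= c if direction == "le" else v >= c))
            frac = hit / len(pwvs)
            pwv_fracs[rule] = frac
            if frac < frac_req:
                violations.append((rule, frac, frac_req))

    band_counts: dict[str, int] = {}
    band_sex: dict[str, dict[str, float]] = {}
    for lo, hi in AGE_BANDS:
        label = age_band_label(lo)
        members = [r for r in cohort if lo <= r.age < hi]
        band_counts[label] = len(members)
        if len(members) < MIN_PER_BAND:
            violations.append((f"age_band[{label}]>=10", len(members),
                               MIN_PER_BAND))
        fracs = {}
        for sex in ("male", "female"):
            f = (sum(1 for r in members if r.sex == sex) / len(members)
                 if members else 0.0)
            fracs[sex] = f
            if f < MIN_SEX_FRACTION:
                violations.append((f"sex[{sex}]@{label}>=40%", f,
                                   MIN_SEX_FRACTION))
        band_sex[label] = fracs

    counts = list(band_counts.values())
    evenness = (min(counts) / max(counts)) if max(counts) > 0 else 0.0
    return CompositionReport(
        n_total=n_total, n_complete=n_complete, n_enrolled=n_enr,
        age_band_counts=band_counts, age_band_sex_fractions=band_sex,
        pwv_fractions=pwv_fracs, evenness_ratio=evenness,
        violations=tuple(violations))


def check_hemodynamic_stability(session: MeasurementSession,
                                threshold: float = STABILITY_THRESHOLD,
                                ) -> StabilityDecision:
    """Stable iff HR, SBP and DBP each changed by strictly less than 5%.

    Relative change is |after - before| / before per variable; the decision
    is strict (a change of exactly 5% is unstable).
    """
    pairs = {"hr": (session.hr_before, session.hr_after),
             "sbp": (session.sbp_before, session.sbp_after),
             "dbp": (session.dbp_before, session.dbp_after)}
    changes: dict[str, float] = {}
    for name, (before, after) in pairs.items():
        if before is None or after is None:
            raise ValidationDataError(
                f"{name} before/after values required for stability check",
                participant_id=session.participant_id)
        if before <= 0:
            raise ValidationDataError(
                f"{name} baseline must be > 0, got {before}",
                participant_id=session.participant_id)
        changes[name] = 100.0 * abs(after - before) / before
    stable = all(c < 100.0 * threshold for c in changes.values())
    return StabilityDecision(stable=stable, changes_percent=changes)
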