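"""End-to-end validation runs and publication-style reporting.

``run_validation`` drives the whole protocol on a study dataset:
eligibility screening, hemodynamic-stability checks on sequential sessions,
measurement pairing, cohort and stratified Bland-Altman agreement,
tolerable-error grading, cohort-composition quotas, and the reporting
checklist. Every number in the emitted report is recomputed from the input
data by the library API, and discarded measurements are counted with their
reasons; the protocol requires quality criteria to be declared in advance,
so a configuration without them refuses to run.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import normative
from .agreement import (AgreementSummary, MeasurementSession,
                        PairedDifferences, age_band_label, pair_session,
                        stratified_agreement, summarize_agreement)
from .errors import ConfigurationError, InsufficientDataError
from .screening import (CompositionReport, ParticipantRecord,
                        check_composition, check_eligibility,
                        check_hemodynamic_stability)

__all__ = ["ValidationConfig", "ValidationReport", "ChecklistItem",
           "run_validation", "render_checklist", "render_bland_altman_plot"]


@dataclass(frozen=True)
class ValidationConfig:
    """Pre-declared study configuration.

    ``quality_criteria`` must be declared before the run (the protocol
    requires failure criteria to be stated in advance); at minimum it
    carries the hemodynamic stability threshold.
    """

    quality_criteria: dict = field(default_factory=dict)
    scale_factor: float = 1.0          # PWV-quota scaling (1.0 for cfPWV)
    n_enrolled: int | None = None
    software_version: str = ""
    hardware_version: str = ""
    measurement_principle: str = ""
    fiducial_point: str = ""
    detection_method: str = ""
    data_availability: str = ""
    training_validation_separate: bool | None = None

    def require_quality_criteria(self) -> None:
        if not self.quality_criteria:
            raise ConfigurationError(
                "quality criteria must be declared in advance of the run "
                "(e.g. {'stability_threshold': 0.05})")

    @property
    def stability_threshold(self) -> float:
        return float(self.quality_criteria.get("stability_threshold", 0.05))


@dataclass(frozen=True)
class ChecklistItem:
    item: str
    status: str      # pass | fail | not_applicable
    detail: str = ""


@dataclass(frozen=True)
class ValidationReport:
    n_input: int
    n_analyzed: int
    summary: AgreementSummary
    grading: normative.GradingResult
    empirical_within_good: float          # fraction of |diff| <= 1.0 m/s
    stratified: dict[str, dict[str, AgreementSummary | None]]
    composition: CompositionReport
    hemodynamics: dict[str, dict[str, float]]  # var -> {mean/sd before/after}
    discarded: tuple[tuple[str, str], ...]     # (participant id, reason)
    software_version: str
    hardware_version: str
    checklist: tuple[ChecklistItem, ...]

    @property
    def grade(self) -> str:
        return self.grading.grade

    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v)
                        for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {str(k): conv(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [conv(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, float) and math.isnan(obj):
                return None
            return obj
        return conv(dataclasses.asdict(self))

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)

    def to_markdown(self) -> str:
        s = self.summary
        g = self.grading
        lines = [
            "# PWV device validation report",
            "",
            f"- Participants analysed: {self.n_analyzed} of {self.n_input}",
            f"- Mean difference (test - reference): {s.mean_diff:.2f} m/s",
            f"- SD of difference: {s.sd_diff:.2f} m/s",
            f"- Limits of agreement (mean +- 2 SD): "
            f"[{s.loa_low:.2f}, {s.loa_high:.2f}] m/s",
            f"- Tolerable-error bound (85%): {g.error85_reported:.2f} m/s "
            f"(rounded mean {g.rounded_mean:.2f}, rounded SD {g.rounded_sd:.2f})",
            f"- **Grade: {g.grade}**",
            f"- Empirical fraction within 1.0 m/s: "
            f"{self.empirical_within_good:.3f}",
            f"- Device version: software {self.software_version or 'n/a'}, "
            f"hardware {self.hardware_version or 'n/a'}",
            "",
            "## Discarded measurements",
        ]
        if self.discarded:
            lines += [f"- {pid}: {reason}" for pid, reason in self.discarded]
        else:
            lines.append("- none")
        lines += ["", "## Hemodynamics (before / after)"]
        for var, stats in self.hemodynamics.items():
            lines.append(
                f"- {var}: {stats['mean_before']:.1f} ({stats['sd_before']:.1f})"
                f" / {stats['mean_after']:.1f} ({stats['sd_after']:.1f})")
        lines += ["", "## Stratified analyses"]
        for stratum, levels in self.stratified.items():
            for level, summ in levels.items():
                if summ is None:
                    lines.append(f"- {stratum}={level}: not estimable (n < 2)")
                else:
                    lines.append(
                        f"- {stratum}={level}: n={summ.n}, "
                        f"mean {summ.mean_diff:.2f}, SD {summ.sd_diff:.2f}")
        lines += ["", "## Cohort composition"]
        if self.composition.satisfied:
            lines.append("- all quotas satisfied")
        else:
            for rule, obs, req in self.composition.violations:
                lines.append(f"- VIOLATION {rule}: observed {obs:g}, "
                             f"required {req:g}")
        lines += ["", "## Reporting checklist"]
        for item in self.checklist:
            lines.append(f"- [{item.status}] {item.item}"
                         + (f" — {item.detail}" if item.detail else ""))
        return "\n".join(lines) + "\n"


def _hemodynamics(sessions: Sequence[MeasurementSession]) -> dict:
    out = {}
    for var in ("hr", "sbp", "dbp"):
        before = [getattr(s, f"{var}_before") for s in sessions
                  if getattr(s, f"{var}_before") is not None]
        after = [getattr(s, f"{var}_after") for s in sessions
                 if getattr(s, f"{var}_after") is not None]
        if before and after:
            out[var] = {
                "mean_before": float(np.mean(before)),
                "sd_before": float(np.std(before, ddof=1)) if len(before) > 1 else 0.0,
                "mean_after": float(np.mean(after)),
                "sd_after": float(np.std(after, ddof=1)) if len(after) > 1 else 0.0,
            }
    return out


def run_validation(records: Sequence[ParticipantRecord],
                   sessions: Sequence[MeasurementSession],
                   config: ValidationConfig) -> ValidationReport:
    """Run the full validation pipeline and assemble the report.

    Stages: eligibility -> hemodynamic stability (sequential sessions) ->
    pairing -> agreement + grading -> stratification (sex, age band,
    vasoactive-drug use) -> composition quotas -> checklist. Ineligible or
    unstable participants are discarded with recorded reasons, never
    silently.
    """
    config.require_quality_criteria()
    by_id = {r.id: r for r in records}
    discarded: list[tuple[str, str]] = []
    analyzed_pairs: list[PairedDifferences] = []
    analyzed_records: list[ParticipantRecord] = []
    analyzed_sessions: list[MeasurementSession] = []

    for session in sessions:
        rec = by_id.get(session.participant_id)
        if rec is None:
            discarded.append((session.participant_id,
                              "no participant record"))
            continue
        decision = check_eligibility(rec)
        if not decision.eligible:
            discarded.append((rec.id, "ineligible: "
                              + "; ".join(decision.failed_rules)))
            continue
        if session.mode == "sequential":
            stability = check_hemodynamic_stability(
                session, threshold=config.stability_threshold)
            if not stability.stable:
                worst = max(stability.changes_percent.items(),
                            key=lambda kv: kv[1])
                discarded.append((rec.id,
                                  f"hemodynamic instability ({worst[0]} "
                                  f"changed {worst[1]:.1f}%)"))
                continue
        analyzed_pairs.append(pair_session(session))
        analyzed_records.append(rec)
        analyzed_sessions.append(session)

    if len(analyzed_pairs) < 2:
        raise InsufficientDataError(
            f"only {len(analyzed_pairs)} analysable participants")

    summary = summarize_agreement(analyzed_pairs)
    diffs = np.array([p.participant_mean_difference for p in analyzed_pairs])
    empirical = float(np.mean(np.abs(diffs) <= normative.GOOD_ERROR_MS))

    stratified = {
        "sex": stratified_agreement(
            analyzed_pairs, [r.sex for r in analyzed_records], "sex"),
        "age_band": stratified_agreement(
            analyzed_pairs, [age_band_label(r.age) for r in analyzed_records],
            "age_band"),
        "vasoactive_drug_use": stratified_agreement(
            analyzed_pairs,
            ["yes" if r.vasoactive_meds else "no" for r in analyzed_records],
            "vasoactive_drug_use"),
    }
    composition = check_composition(analyzed_records,
                                    scale_factor=config.scale_factor,
                                    n_enrolled=config.n_enrolled)
    report = ValidationReport(
        n_input=len(sessions), n_analyzed=len(analyzed_pairs),
        summary=summary, grading=summary.grading,
        empirical_within_good=empirical,
        stratified=stratified, composition=composition,
        hemodynamics=_hemodynamics(analyzed_sessions),
        discarded=tuple(discarded),
        software_version=config.software_version,
        hardware_version=config.hardware_version,
        checklist=())
    checklist = render_checklist(report, config)
    return dataclasses.replace(report, checklist=checklist)


def render_checklist(report: ValidationReport,
                     config: ValidationConfig) -> tuple[ChecklistItem, ...]:
    """Itemised reporting checklist for a validation-study publication."""
    items: list[ChecklistItem] = []

    def add(item: str, ok: bool, detail: str = "") -> None:
        items.append(ChecklistItem(item=item,
                                   status="pass" if ok else "fail",
                                   detail=detail))

    add("Measurement principle disclosed",
        bool(config.measurement_principle), config.measurement_principle)
    add("Fiducial point and detection method described",
        bool(config.fiducial_point and config.detection_method),
        f"{config.fiducial_point} / {config.detection_method}".strip(" /"))
    if config.training_validation_separate is None:
        items.append(ChecklistItem(
            item="Training and validation sets separate",
            status="not_applicable",
            detail="no trained algorithm declared"))
    else:
        add("Training and validation sets separate",
            config.training_validation_separate,
            "training and validation sets should be separate")
    add("Device software/hardware versions reported",
        bool(report.software_version and report.hardware_version),
        f"sw={report.software_version or '?'} hw={report.hardware_version or '?'}")
    add("Data availability statement", bool(config.data_availability),
        config.data_availability)
    add("Stratified analyses (sex, age bands) present",
        bool(report.stratified.get("sex")) and bool(
            report.stratified.get("age_band")))
    add("HR and BP reported before and after the procedure",
        {"hr", "sbp", "dbp"} <= set(report.hemodynamics))
    add("Discarded measurements counted with reasons", True,
        f"{len(report.discarded)} discarded")
    return tuple(items)


def render_bland_altman_plot(summary: AgreementSummary,
                             paired: Sequence[PairedDifferences],
                             path) -> None:
    """Bland-Altman plot with every element the protocol requires.

    Scatter of per-participant difference vs average, solid mean line with
    its numerical value, dashed mean +- 2 SD lines, and the regression line
    with equation, R-squared and p-value. Numeric annotations match the
    summary to 2 decimals.
    """
    if len(paired) < 2:
        raise InsufficientDataError("Bland-Altman plot requires n >= 2")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    avgs = np.array([p.participant_mean_average for p in paired])
    diffs = np.array([p.participant_mean_difference for p in paired])
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.scatter(avgs, diffs, s=18, color="#30505f", alpha=0.75, zorder=3)
    ax.axhline(summary.mean_diff, color="black", lw=1.5)
    ax.axhline(summary.loa_low, color="black", lw=1.0, ls="--")
    ax.axhline(summary.loa_high, color="black", lw=1.0, ls="--")
    x1 = avgs.max()
    ax.annotate(f"mean = {summary.mean_diff:.2f}",
                (x1, summary.mean_diff), ha="right", va="bottom", fontsize=9)
    ax.annotate(f"mean - 2 SD = {summary.loa_low:.2f} (SD = {summary.sd_diff:.2f})",
                (x1, summary.loa_low), ha="right", va="top", fontsize=9)
    ax.annotate(f"mean + 2 SD = {summary.loa_high:.2f}",
                (x1, summary.loa_high), ha="right", va="bottom", fontsize=9)
    reg = summary.ba_regression
    if reg is not None:
        xs = np.linspace(avgs.min(), avgs.max(), 50)
        ax.plot(xs, reg.intercept + reg.slope * xs, color="#a03030", lw=1.2)
        ax.set_title(f"y = {reg.slope:.3f}x + {reg.intercept:.2f}, "
                     f"$R^2$ = {reg.r_squared:.3f}, p = {reg.p_value:.3g}",
                     fontsize=10)
    ax.set_xlabel("Mean of test and reference PWV (m/s)")
    ax.set_ylabel("Test - reference PWV (m/s)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
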