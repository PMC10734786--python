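"""Measurement pairing, Bland-Altman agreement and test-retest precision.

The validation protocol acquires three readings with the device under test
(T1..T3). With a simultaneous-capable reference device, three reference
readings are taken at the same times and pair 1:1. Otherwise four reference
readings (R1..R4) interleave the test readings and each T_i is compared
against the mean of the two reference readings closest in time — under the
canonical order R1 T1 R2 T2 R3 T3 R4 this gives mean(R1,R2), mean(R2,R3),
mean(R3,R4).

The unit of analysis is the participant: the error of the device is the mean
of the three pair differences, and cohort agreement statistics (Bland-Altman
mean bias, SD, limits of agreement mean +- 2*SD, difference-vs-average
regression) are computed over those per-participant means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.stats import linregress

from . import normative
from .errors import (ConfigurationError, DomainError, InsufficientDataError,
                     ValidationDataError)

__all__ = [
    "Reading",
    "MeasurementSession",
    "PairedDifferences",
    "BARegression",
    "AgreementSummary",
    "pair_session",
    "pair_simultaneous",
    "pair_sequential",
    "summarize_agreement",
    "stratified_agreement",
    "coefficient_of_variation",
    "test_retest_report",
    "TestRetestReport",
]

Mode = Literal["simultaneous", "sequential"]

#: Number of test readings per session.
N_TEST_READINGS = 3
#: Number of reference readings per session, by pairing mode.
N_REFERENCE_READINGS = {"simultaneous": 3, "sequential": 4}


@dataclass(frozen=True)
class Reading:
    """One PWV reading: acquisition time (s) and value (m/s)."""

    timestamp: float
    pwv: float


@dataclass(frozen=True)
class MeasurementSession:
    """One participant's ordered test and reference readings with context.

    ``hr_*`` in bpm, ``sbp_*``/``dbp_*`` in mmHg, recorded immediately
    before and after the acquisition; used for the hemodynamic-stability
    check of sequential sessions.
    """

    participant_id: str
    mode: Mode
    test_readings: tuple[Reading, ...]
    reference_readings: tuple[Reading, ...]
    hr_before: float | None = None
    hr_after: float | None = None
    sbp_before: float | None = None
    sbp_after: float | None = None
    dbp_before: float | None = None
    dbp_after: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in N_REFERENCE_READINGS:
            raise ValidationDataError(f"unknown mode {self.mode!r}",
                                      participant_id=self.participant_id)
        if len(self.test_readings) != N_TEST_READINGS:
            raise ValidationDataError(
                f"expected {N_TEST_READINGS} test readings, "
                f"got {len(self.test_readings)}",
                participant_id=self.participant_id)
        n_ref = N_REFERENCE_READINGS[self.mode]
        if len(self.reference_readings) != n_ref:
            raise ValidationDataError(
                f"expected {n_ref} reference readings in {self.mode} mode, "
                f"got {len(self.reference_readings)}",
                participant_id=self.participant_id)
        for readings, role in ((self.test_readings, "test"),
                               (self.reference_readings, "reference")):
            ts = [r.timestamp for r in readings]
            if any(t2 <= t1 for t1, t2 in zip(ts, ts[1:])):
                raise ValidationDataError(
                    f"{role} timestamps must be strictly increasing",
                    participant_id=self.participant_id)
            if any(r.pwv <= 0 for r in readings):
                raise ValidationDataError(
                    f"{role} PWV values must be > 0",
                    participant_id=self.participant_id)


@dataclass(frozen=True)
class PairedDifferences:
    """Per-pair and per-participant difference statistics for one session."""

    participant_id: str
    per_pair: tuple[tuple[float, float, float], ...]  # (test, comparator, diff)
    participant_mean_difference: float
    participant_mean_average: float


@dataclass(frozen=True)
class BARegression:
    """OLS fit of difference against per-participant average PWV."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float


@dataclass(frozen=True)
class AgreementSummary:
    """Cohort-level Bland-Altman summary with tolerable-error grading."""

    n: int
    mean_diff: float
    sd_diff: float
    loa_low: float    # mean - 2*SD
    loa_high: float   # mean + 2*SD
    ba_regression: BARegression | None
    grading: normative.GradingResult


def pair_simultaneous(session: MeasurementSession) -> PairedDifferences:
    """Pair test and reference readings acquired simultaneously (1:1)."""
    if session.mode != "simultaneous":
        raise ValidationDataError("session mode is not simultaneous",
                                  participant_id=session.participant_id)
    pairs = tuple(
        (t.pwv, r.pwv, t.pwv - r.pwv)
        for t, r in zip(session.test_readings, session.reference_readings))
    return _finish_pairs(session.participant_id, pairs)


def pair_sequential(session: MeasurementSession) -> PairedDifferences:
    """Pair each test reading with its two temporally closest reference readings.

    The comparator for T_i is the mean of the two reference readings whose
    timestamps are closest to T_i's. Distance ties are resolved by preferring
    the earlier reading first and then the later member of the tied pair, so
    a test reading exactly between two reference readings uses both
    flanking readings (the canonical interleaving case).
    """
    if session.mode != "sequential":
        raise ValidationDataError("session mode is not sequential",
                                  participant_id=session.participant_id)
    refs = sorted(session.reference_readings, key=lambda r: r.timestamp)
    pairs = []
    for t in session.test_readings:
        ranked = sorted(refs, key=lambda r: (abs(r.timestamp - t.timestamp),
                                             r.timestamp))
        chosen = ranked[:2]
        comparator = 0.5 * (chosen[0].pwv + chosen[1].pwv)
        pairs.append((t.pwv, comparator, t.pwv - comparator))
    return _finish_pairs(session.participant_id, tuple(pairs))


def pair_session(session: MeasurementSession) -> PairedDifferences:
    """Dispatch to the pairing scheme matching the session mode."""
    if session.mode == "simultaneous":
        return pair_simultaneous(session)
    return pair_sequential(session)


def _finish_pairs(pid: str, pairs) -> PairedDifferences:
    diffs = [d for _, _, d in pairs]
    avgs = [(t + c) / 2.0 for t, c, _ in pairs]
    return PairedDifferences(
        participant_id=pid,
        per_pair=pairs,
        participant_mean_difference=float(np.mean(diffs)),
        participant_mean_average=float(np.mean(avgs)))


def summarize_agreement(paired: Sequence[PairedDifferences],
                        probability: float = normative.DEFAULT_PROBABILITY,
                        ) -> AgreementSummary:
    """Cohort Bland-Altman summary over per-participant mean differences.

    Mean and sample SD (n-1 denominator) are taken over the participant
    mean differences; limits of agreement are mean -+ 2*SD as the protocol
    prescribes (not 1.96*SD). The Bland-Altman regression fits difference
    against per-participant average by OLS; grading delegates to
    :func:`pwvalid.normative.grade_device`.
    """
    n = len(paired)
    if n < 2:
        raise InsufficientDataError(
            f"agreement summary requires >= 2 participants, got {n}")
    diffs = np.array([p.participant_mean_difference for p in paired])
    avgs = np.array([p.participant_mean_average for p in paired])
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    if np.ptp(avgs) > 0:
        fit = linregress(avgs, diffs)
        reg = BARegression(slope=float(fit.slope),
                           intercept=float(fit.intercept),
                           r_squared=float(fit.rvalue ** 2),
                           p_value=float(fit.pvalue))
    else:  # degenerate abscissa: regression undefined
        reg = None
    grading = normative.grade_device(
        normative.DifferenceModel(mean_diff, sd_diff), probability)
    return AgreementSummary(n=n, mean_diff=mean_diff, sd_diff=sd_diff,
                            loa_low=mean_diff - 2.0 * sd_diff,
                            loa_high=mean_diff + 2.0 * sd_diff,
                            ba_regression=reg, grading=grading)


#: Age bands (years) used for stratified analysis, half-open intervals.
AGE_BANDS = ((18, 30), (30, 50), (50, 70), (70, math.inf))


def age_band_label(age: float) -> str:
    """Label of the protocol age band containing ``age``."""
    if age < 18:
        raise DomainError(f"age {age} below the adult threshold of 18")
    for lo, hi in AGE_BANDS:
        if lo <= age < hi:
            return f"{lo}-{hi - 1:.0f}" if math.isfinite(hi) else f">={lo}"
    raise AssertionError("unreachable: bands partition [18, inf)")


def stratified_agreement(paired: Sequence[PairedDifferences],
                         labels: Sequence[str],
                         stratum_name: str = "stratum",
                         ) -> dict[str, AgreementSummary | None]:
    """Agreement summaries per stratum level (sex, age band, drug use, ...).

    ``labels[i]`` is the stratum level of ``paired[i]``. Levels with fewer
    than 2 participants are reported as ``None`` (not estimable), never
    silently dropped.
    """
    if len(labels) != len(paired):
        raise ConfigurationError(
            f"{stratum_name}: got {len(labels)} labels for "
            f"{len(paired)} participants")
    out: dict[str, AgreementSummary | None] = {}
    for level in dict.fromkeys(labels):  # preserve first-seen order
        members = [p for p, lab in zip(paired, labels) if lab == level]
        out[str(level)] = (summarize_agreement(members)
                           if len(members) >= 2 else None)
    return out


def coefficient_of_variation(m1: float, m2: float) -> float:
    """CV of two repeated measurements, percent.

    SD of two values with the n-1 denominator is |m1 - m2| / sqrt(2);
    CV = 100 * SD / mean. Scale invariant.
    """
    if m1 <= 0 or m2 <= 0:
        raise DomainError("measurements must be > 0 for a CV")
    sd = abs(m1 - m2) / math.sqrt(2.0)
    return 100.0 * sd / ((m1 + m2) / 2.0)


@dataclass(frozen=True)
class TestRetestReport:
    """Within-device precision summary (test-retest reproducibility)."""

    n: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    agreement_limit: float                 # predefined clinical limit, m/s
    per_participant_cv: tuple[float, ...]  # percent
    mean_cv: float
    exceeding_limit: tuple[str, ...]       # participant ids with |diff| > limit
    excluded: tuple[tuple[str, str], ...]  # (participant id, reason)


def test_retest_report(repeats: dict[str, Sequence[float]],
                       agreement_limit: float = normative.GOOD_ERROR_MS,
                       ) -> TestRetestReport:
    """Bland-Altman precision analysis of repeated same-device measurements.

    ``repeats`` maps participant id to its repeated PWV measurements; the
    first two repeats are analysed (difference = second - first). The
    predefined clinical agreement limit defaults to 1.0 m/s, the minimum
    clinically important difference; participants whose repeat difference
    exceeds it in absolute value are flagged. Participants with fewer than
    two repeats are excluded with a logged reason.
    """
    diffs, cvs, flagged, excluded = [], [], [], []
    for pid, values in repeats.items():
        vals = list(values)
        if len(vals) < 2:
            excluded.append((pid, f"only {len(vals)} repeat(s), need 2"))
            continue
        m1, m2 = vals[0], vals[1]
        d = m2 - m1
        diffs.append(d)
        cvs.append(coefficient_of_variation(m1, m2))
        if abs(d) > agreement_limit:
            flagged.append(pid)
    n = len(diffs)
    if n < 2:
        raise InsufficientDataError(
            f"test-retest analysis requires >= 2 participants with "
            f"2 repeats, got {n}")
    arr = np.asarray(diffs)
    mean_diff = float(arr.mean())
    sd_diff = float(arr.std(ddof=1))
    return TestRetestReport(
        n=n, mean_diff=mean_diff, sd_diff=sd_diff,
        loa_low=mean_diff - 2.0 * sd_diff,
        loa_high=mean_diff + 2.0 * sd_diff,
        agreement_limit=agreement_limit,
        per_participant_cv=tuple(cvs),
        mean_cv=float(np.mean(cvs)),
        exceeding_limit=tuple(flagged),
        excluded=tuple(excluded))
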