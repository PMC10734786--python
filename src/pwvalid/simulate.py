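"""Synthetic validation-study simulator with known ground truth.

Emulates a cfPWV device-validation cohort: ages drawn over the four
protocol age bands, an age-linear true PWV with between-subject scatter,
a device under test with constant + proportional bias (optionally
heterogeneous across participants), and independent per-reading Gaussian
noise on both devices. Defaults reproduce the worked grading scenario of
the normative model — constant bias 0.36 m/s and a per-participant
mean-difference SD of 0.44 m/s — so a default simulated study exercises the
full pipeline at realistic operating conditions.

The age→PWV coefficients are fixture parameters chosen to span the
protocol's reference-PWV quotas (5% <= 6 m/s, 20% >= 8 m/s, 5% >= 10 m/s
at roughly even age-band weights); they are not claims about physiology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .agreement import AGE_BANDS, MeasurementSession, Reading
from .errors import ConfigurationError
from .screening import ParticipantRecord

__all__ = ["SimulationConfig", "simulate_cohort", "simulate_sessions",
           "simulate_study", "quota_satisfying_cohort"]

#: Upper age used when drawing within the open-ended >= 70 band.
_MAX_AGE = 90.0
#: True PWV floor, m/s.
_PWV_FLOOR = 3.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a simulated validation study.

    ``pwv_intercept``/``pwv_slope_per_decade`` define the age-linear true
    PWV (m/s); ``pwv_between_sd`` its between-subject SD. ``bias_constant``
    and ``bias_proportional`` define the test-device systematic error;
    ``bias_between_sd`` adds a per-participant random device offset so that
    the SD of participant mean differences can be set independently of the
    per-reading noise. With the defaults the participant-mean-difference SD
    is sqrt(0.409^2 + 2*0.2^2/3) ~= 0.44 m/s.
    """

    n_participants: int = 85
    age_band_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    sex_balance: float = 0.5            # fraction male
    pwv_intercept: float = 4.0          # m/s at age 0
    pwv_slope_per_decade: float = 0.85  # m/s per decade of age
    pwv_between_sd: float = 0.9         # m/s
    bias_constant: float = 0.36         # m/s
    bias_proportional: float = 0.0      # per m/s of true PWV
    bias_between_sd: float = 0.409      # m/s, per-participant device offset
    test_noise_sd: float = 0.2          # m/s per reading
    reference_noise_sd: float = 0.2     # m/s per reading
    mode: str = "sequential"
    n_unstable: int = 0                 # sessions given a >5% HR jump
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        w = np.asarray(self.age_band_weights, dtype=float)
        if w.size != 4 or np.any(w < 0) or not math.isclose(w.sum(), 1.0,
                                                            abs_tol=1e-9):
            raise ConfigurationError(
                "age_band_weights must be 4 non-negative values summing to 1")
        for name in ("pwv_between_sd", "bias_between_sd",
                     "test_noise_sd", "reference_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.sex_balance <= 1.0:
            raise ConfigurationError("sex_balance must be in [0, 1]")
        if self.mode not in ("simultaneous", "sequential"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")


def _band_bounds() -> list[tuple[float, float]]:
    return [(lo, hi if math.isfinite(hi) else _MAX_AGE) for lo, hi in AGE_BANDS]


def true_pwv(config: SimulationConfig, age, noise=0.0):
    """Deterministic part of the age->PWV model plus optional noise term."""
    v = config.pwv_intercept + config.pwv_slope_per_decade * (np.asarray(age) / 10.0)
    return np.maximum(v + noise, _PWV_FLOOR)


def simulate_cohort(config: SimulationConfig) -> list[ParticipantRecord]:
    """Draw a cohort of eligible participants with known true PWV.

    Ages are drawn band-first (per ``age_band_weights``, uniform within a
    band); sex per ``sex_balance``; true PWV from the age-linear model with
    between-subject scatter, floored at 3 m/s. The true PWV is stored in
    ``reference_pwv`` until sessions are simulated. Reproducible under seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    bands = _band_bounds()
    idx = rng.choice(4, size=n, p=np.asarray(config.age_band_weights))
    ages = np.array([rng.uniform(*bands[i]) for i in idx])
    sexes = np.where(rng.random(n) < config.sex_balance, "male", "female")
    pwv = true_pwv(config, ages, rng.normal(0.0, config.pwv_between_sd, n))
    bmi = np.clip(rng.normal(26.0, 4.0, n), 17.0, 39.5)
    return [ParticipantRecord(
        id=f"P{i + 1:03d}", age=float(ages[i]), sex=str(sexes[i]),
        bmi=float(round(bmi[i], 1)), rhythm="sinus",
        reference_pwv=float(pwv[i])) for i in range(n)]


def simulate_sessions(cohort: list[ParticipantRecord],
                      config: SimulationConfig) -> list[MeasurementSession]:
    """Simulate one measurement session per participant.

    Reference readings are true PWV plus Normal(0, reference_noise_sd);
    test readings add the constant, proportional and per-participant bias
    plus Normal(0, test_noise_sd). Readings are recorded to 0.01 m/s.
    Sequential sessions interleave R1 T1 R2 T2 R3 T3 R4 at 60 s spacing;
    simultaneous sessions share acquisition times pairwise. The first
    ``n_unstable`` sessions are given a 10% heart-rate increase (all others
    stay within the 5% stability window).
    """
    rng = np.random.default_rng(None if config.seed is None
                                else config.seed + 1)
    n_ref = 4 if config.mode == "sequential" else 3
    sessions = []
    for k, rec in enumerate(cohort):
        v = rec.reference_pwv
        offset = rng.normal(0.0, config.bias_between_sd)
        ref_vals = v + rng.normal(0.0, config.reference_noise_sd, n_ref)
        test_vals = (v + config.bias_constant + config.bias_proportional * v
                     + offset + rng.normal(0.0, config.test_noise_sd, 3))
        ref_vals = np.round(np.maximum(ref_vals, 0.5), 2)
        test_vals = np.round(np.maximum(test_vals, 0.5), 2)
        if config.mode == "sequential":
            # canonical interleaving R1 T1 R2 T2 R3 T3 R4
            ref_ts = (0.0, 120.0, 240.0, 360.0)
            test_ts = (60.0, 180.0, 300.0)
        else:
            ref_ts = (0.0, 60.0, 120.0)
            test_ts = ref_ts
        hr = float(rng.uniform(55.0, 85.0))
        sbp = float(rng.uniform(105.0, 145.0))
        dbp = float(rng.uniform(65.0, 90.0))
        drift = 1.0 + rng.uniform(-0.02, 0.02)
        hr_drift = 1.10 if k < config.n_unstable else drift
        sessions.append(MeasurementSession(
            participant_id=rec.id, mode=config.mode,
            test_readings=tuple(Reading(t, float(p))
                                for t, p in zip(test_ts, test_vals)),
            reference_readings=tuple(Reading(t, float(p))
                                     for t, p in zip(ref_ts, ref_vals)),
            hr_before=round(hr, 1), hr_after=round(hr * hr_drift, 1),
            sbp_before=round(sbp, 1), sbp_after=round(sbp * drift, 1),
            dbp_before=round(dbp, 1), dbp_after=round(dbp * drift, 1)))
    return sessions


def simulate_study(config: SimulationConfig
                   ) -> tuple[list[ParticipantRecord],
                              list[MeasurementSession]]:
    """Cohort plus sessions; records carry the mean of the simulated
    reference readings as their ``reference_pwv`` (as real data would)."""
    cohort = simulate_cohort(config)
    sessions = simulate_sessions(cohort, config)
    out = []
    for rec, s in zip(cohort, sessions):
        mean_ref = float(np.mean([r.pwv for r in s.reference_readings]))
        out.append(replace(rec, reference_pwv=mean_ref))
    return out, sessions


def quota_satisfying_cohort(config: SimulationConfig
                            ) -> list[ParticipantRecord]:
    """Deterministic cohort guaranteed to pass every composition quota.

    Allocation: participants split as evenly as possible over the four age
    bands (each >= 10), sexes alternated within each band (>= 40% each),
    and true PWV assigned so that >= 5% are at 5.5 m/s, >= 5% at 10.5 m/s,
    a further tranche at 8.5 m/s until >= 20% are >= 8 m/s, and the rest
    mid-range — with the low-PWV tranche in the youngest band and the
    high-PWV tranches in the oldest, so values stay physiologically
    ordered. Raises on n too small for the band quota.
    """
    n = config.n_participants
    if n < 40:
        raise ConfigurationError(
            f"n={n} cannot satisfy 4 age bands x >= 10 participants "
            "(binding constraint: band minimum)")
    base, extra = divmod(n, 4)
    band_sizes = [base + (1 if i < extra else 0) for i in range(4)]
    bands = _band_bounds()

    n_low = math.ceil(0.05 * n)            # <= 6 m/s tranche
    n_high = math.ceil(0.05 * n)           # >= 10 m/s tranche
    n_mid_high = max(0, math.ceil(0.20 * n) - n_high)  # >= 8 m/s tranche
    pwv_pool = ([5.5] * n_low + [10.5] * n_high + [8.5] * n_mid_high
                + [7.0] * (n - n_low - n_high - n_mid_high))

    records = []
    i = 0
    low_iter = iter([v for v in pwv_pool if v == 5.5])
    high_iter = iter([v for v in pwv_pool if v >= 8.5])
    mid_iter = iter([v for v in pwv_pool if v == 7.0])
    for b, size in enumerate(band_sizes):
        lo, hi = bands[b]
        for j in range(size):
            age = lo + (j + 0.5) * (hi - lo) / size
            sex = "male" if j % 2 == 0 else "female"
            if b == 0:
                pwv = next(low_iter, None) or next(mid_iter, None) \
                    or next(high_iter)
            elif b == 3:
                pwv = next(high_iter, None) or next(mid_iter, None) \
                    or next(low_iter)
            else:
                pwv = next(mid_iter, None) or next(high_iter, None) \
                    or next(low_iter)
            records.append(ParticipantRecord(
                id=f"P{i + 1:03d}", age=float(age), sex=sex, bmi=26.0,
                rhythm="sinus", reference_pwv=float(pwv)))
            i += 1
    return records
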