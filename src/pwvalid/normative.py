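"""Tolerable-error model, device grading and sample-size calculus.

The accuracy criterion for a pulse wave velocity (PWV) device under test is
probabilistic: modelling the per-participant test-minus-reference differences
as Normal(mu, sigma^2), the device passes with *good* accuracy when the bound
E containing 85% of the probability mass of |D| satisfies E <= 1.0 m/s, with
*acceptable* accuracy when 1.0 < E <= 1.5 m/s, and fails otherwise. Before
grading, |mu| and sigma are rounded up to 0.05 m/s precision (conservative
lookup convention); the reported error bound is rounded up to 0.01 m/s.

The sample-size calculus is binomial: with n = 85 analysable participants,
a Wald 90% interval around an 85% tolerable-error probability has half-width
~6.4 percentage points, i.e. the true probability is assured to be >= 78%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.stats import norm

from .errors import DomainError, InfeasibleMeanError

__all__ = [
    "DifferenceModel",
    "GradingResult",
    "SampleSizePlan",
    "error_at_probability",
    "max_sd_for_error",
    "round_up_to_grid",
    "grade_device",
    "generate_cutoff_table",
    "margin_of_error",
    "assured_lower_bound",
    "DEFAULT_PROBABILITY",
    "GOOD_ERROR_MS",
    "ACCEPTABLE_ERROR_MS",
    "ROUNDING_GRID_MS",
]

#: Probability of tolerable error required of a validated device.
DEFAULT_PROBABILITY = 0.85
#: Tolerable error (m/s) for a "good" grade — the minimum clinically
#: important difference for carotid-femoral PWV.
GOOD_ERROR_MS = 1.0
#: Tolerable error (m/s) for an "acceptable" grade.
ACCEPTABLE_ERROR_MS = 1.5
#: Grid (m/s) to which mean and SD are rounded up before grading.
ROUNDING_GRID_MS = 0.05

Grade = Literal["good", "acceptable", "fail"]


@dataclass(frozen=True)
class DifferenceModel:
    """Normal model of test-minus-reference PWV differences.

    Parameters
    ----------
    mean_diff : float
        Mean difference in m/s, signed (test minus reference).
    sd_diff : float
        Standard deviation of per-participant mean differences, m/s, >= 0.
    """

    mean_diff: float
    sd_diff: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.mean_diff) or not math.isfinite(self.sd_diff):
            raise DomainError("mean_diff and sd_diff must be finite")
        if self.sd_diff < 0:
            raise DomainError(f"sd_diff must be >= 0, got {self.sd_diff}")


@dataclass(frozen=True)
class GradingResult:
    """Outcome of grading a device against the tolerable-error criterion."""

    rounded_mean: float   # |mean_diff| rounded up to 0.05 m/s
    rounded_sd: float     # sd_diff rounded up to 0.05 m/s
    error85: float        # unrounded tolerable-error bound, m/s
    grade: Grade

    @property
    def error85_reported(self) -> float:
        """Error bound as displayed: rounded up to 0.01 m/s precision."""
        return round_up_to_grid(self.error85, 0.01)


@dataclass(frozen=True)
class SampleSizePlan:
    """Binomial precision plan for a validation study."""

    n_analysis: int = 85
    n_enroll: int = 90
    target_probability: float = DEFAULT_PROBABILITY
    confidence: float = 0.90

    def __post_init__(self) -> None:
        if self.n_enroll < self.n_analysis:
            raise DomainError("n_enroll must be >= n_analysis")

    @property
    def margin(self) -> float:
        """Half-width of the binomial CI, percentage points."""
        return margin_of_error(self.n_analysis, self.target_probability,
                               self.confidence)

    @property
    def lower_bound(self) -> float:
        """Assured lower bound on the tolerable-error probability, percent."""
        return assured_lower_bound(self.n_analysis, self.target_probability,
                                   self.confidence)


def _central_mass(E: float, mean: float, sd: float) -> float:
    # P(|D| <= E) for D ~ Normal(mean, sd^2)
    return norm.cdf((E - mean) / sd) - norm.cdf((-E - mean) / sd)


def error_at_probability(model: DifferenceModel, probability: float = DEFAULT_PROBABILITY,
                         tol: float = 1e-6) -> float:
    """Bound E >= 0 such that P(|D| <= E) = probability under ``model``.

    Solved by bracketing bisection on [0, |mean| + 10*SD] to absolute
    tolerance ``tol`` (m/s). Symmetric in the sign of the mean difference.
    When ``sd_diff == 0`` all mass sits at the mean, so the bound degenerates
    to ``|mean_diff|`` for any requested probability in (0, 1).
    """
    if not 0.0 < probability < 1.0:
        raise DomainError(f"probability must be in (0, 1), got {probability}")
    mu = abs(model.mean_diff)
    sd = model.sd_diff
    if sd == 0.0:
        return mu
    lo, hi = 0.0, mu + 10.0 * sd
    if _central_mass(hi, mu, sd) < probability:  # pragma: no cover - generous bracket
        raise DomainError("bisection bracket does not contain the solution")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _central_mass(mid, mu, sd) < probability:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def max_sd_for_error(mean_diff: float, error_max: float,
                     probability: float = DEFAULT_PROBABILITY,
                     tol: float = 1e-6) -> float:
    """Largest SD such that the tolerable-error bound stays <= ``error_max``.

    The bound is strictly increasing in sigma, so monotone bisection applies.
    Inverse-consistent with :func:`error_at_probability`. Requires
    ``|mean_diff| < error_max``; otherwise no positive SD is feasible.
    """
    if not 0.0 < probability < 1.0:
        raise DomainError(f"probability must be in (0, 1), got {probability}")
    if error_max <= 0:
        raise DomainError("error_max must be > 0")
    mu = abs(mean_diff)
    if mu >= error_max:
        raise InfeasibleMeanError(
            f"|mean_diff| = {mu} >= error_max = {error_max}: "
            "no SD can satisfy the bound")

    def bound(sd: float) -> float:
        return error_at_probability(DifferenceModel(mu, sd), probability,
                                    tol=tol * 0.1)

    lo = 0.0
    hi = error_max  # bound(sigma) > sigma * z_{(1+p)/2} > sigma for p >= 0.85
    while bound(hi) <= error_max:  # pragma: no cover - defensive bracket growth
        hi *= 2.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if bound(mid) <= error_max:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def round_up_to_grid(value: float, grid: float = ROUNDING_GRID_MS) -> float:
    """Smallest multiple of ``grid`` that is >= ``value``.

    Exact multiples are returned unchanged (to numeric tolerance). Negative
    values are a domain error: absolute values must be taken upstream.
    """
    if value < 0:
        raise DomainError(f"value must be >= 0, got {value}")
    if grid <= 0:
        raise DomainError(f"grid must be > 0, got {grid}")
    # guard against float ratios like 0.45/0.05 = 9.000000000000002
    k = math.ceil(round(value / grid, 9))
    return k * grid


def grade_device(model: DifferenceModel,
                 probability: float = DEFAULT_PROBABILITY) -> GradingResult:
    """Grade a device from its difference model.

    |mean| and SD are rounded up to 0.05 m/s, the tolerable-error bound is
    computed at the requested probability (default 85%), and the grade is
    assigned by the 1.0 / 1.5 m/s thresholds. Grading uses the unrounded
    bound; reports display it rounded up to 0.01 m/s.
    """
    rounded_mean = round_up_to_grid(abs(model.mean_diff))
    rounded_sd = round_up_to_grid(model.sd_diff)
    error85 = error_at_probability(DifferenceModel(rounded_mean, rounded_sd),
                                   probability)
    if error85 <= GOOD_ERROR_MS:
        grade: Grade = "good"
    elif error85 <= ACCEPTABLE_ERROR_MS:
        grade = "acceptable"
    else:
        grade = "fail"
    return GradingResult(rounded_mean=rounded_mean, rounded_sd=rounded_sd,
                         error85=error85, grade=grade)


def generate_cutoff_table(mean_grid=None, error_maxes=(GOOD_ERROR_MS, ACCEPTABLE_ERROR_MS),
                          probability: float = DEFAULT_PROBABILITY):
    """Maximal acceptable SD of the difference per mean difference.

    Returns a pandas DataFrame with one row per mean value and one
    ``max_sd_*`` column per error bound (NaN plus an ``*_infeasible`` flag
    where ``|mean| >= bound``). Default grid: 0 to 0.95 m/s in 0.05 steps.
    """
    import pandas as pd

    if mean_grid is None:
        mean_grid = np.round(np.arange(0.0, 1.0, ROUNDING_GRID_MS), 10)
    mean_grid = np.asarray(list(mean_grid), dtype=float)
    if np.any(mean_grid < 0):
        raise DomainError("mean values must be non-negative")

    cols: dict[str, list] = {"mean_diff": list(mean_grid)}
    for emax in error_maxes:
        label = "good" if emax == GOOD_ERROR_MS else (
            "acceptable" if emax == ACCEPTABLE_ERROR_MS else f"{emax:g}")
        sds, infeasible = [], []
        for mu in mean_grid:
            if mu >= emax:
                sds.append(float("nan"))
                infeasible.append(True)
            else:
                sds.append(max_sd_for_error(mu, emax, probability))
                infeasible.append(False)
        cols[f"max_sd_{label}"] = sds
        cols[f"max_sd_{label}_infeasible"] = infeasible
    return pd.DataFrame(cols)


def margin_of_error(n: int, p: float, confidence: float,
                    method: str = "wald") -> float:
    """Half-width of a binomial CI for a proportion, in percentage points.

    The default Wald (normal-approximation) interval,
    ``100 * z_{(1+c)/2} * sqrt(p(1-p)/n)``, reproduces the protocol's
    n >= 85 / +-7% / 78% calculus. A Wilson half-width is available as a
    non-default alternative (``method="wilson"``).
    """
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    if not 0.0 < p < 1.0 or not 0.0 < confidence < 1.0:
        raise DomainError("p and confidence must be in (0, 1)")
    z = norm.ppf((1.0 + confidence) / 2.0)
    if method == "wald":
        return 100.0 * z * math.sqrt(p * (1.0 - p) / n)
    if method == "wilson":
        denom = 1.0 + z * z / n
        half = z * math.sqrt(p * (1.0 - p) / n + z * z / (4.0 * n * n)) / denom
        return 100.0 * half
    raise DomainError(f"unknown interval method {method!r}")


def assured_lower_bound(n: int, p: float, confidence: float,
                        method: str = "wald") -> float:
    """Assured lower bound on the tolerable-error probability, percent.

    ``100*p - margin_of_error(n, p, confidence)``; for (85, 0.85, 0.90)
    this exceeds 78%.
    """
    return 100.0 * p - margin_of_error(n, p, confidence, method=method)
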