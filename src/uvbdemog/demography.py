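"""Cohort life-table demography.

Implements the classical discrete-age life-table quantities for a cohort of
females censused daily from hatch until the last death:

* age-specific survivorship    ``l_x = n_x / n_0``
* age-specific fecundity       ``m_x = b_x / n_x``
* net reproductive rate        ``R0 = sum_x l_x m_x``
* generation time              ``T = sum_x x l_x m_x / R0``
* intrinsic rate of increase   ``r ≈ ln(R0) / T`` (the standard
  approximation) and the exact Euler–Lotka root of
  ``sum_x exp(-r x) l_x m_x = 1``.

Ages are integer days with ``x = 0`` at hatch, matching a 24-h census
cadence.  All functions are pure and deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.optimize import brentq

GENERATIONS = ("F1", "F5")
TREATMENTS = ("control", "low", "mid", "high")
FEEDINGS = ("fed", "starved")

#: UVB irradiance (W/m^2) delivered for 2 h per treatment level.
TREATMENT_INTENSITY = {"control": 0.0, "low": 1.3, "mid": 3.7, "high": 5.0}


class InvalidCohortError(ValueError):
    """The cohort cannot be analysed at all (e.g. no founders)."""


class DataIntegrityError(ValueError):
    """The census contradicts itself (e.g. survivor counts increase)."""


class UndefinedParameterError(ValueError):
    """A demographic parameter is undefined for this cohort (R0 == 0)."""


class NumericalFailureError(RuntimeError):
    """Root bracketing for the Euler–Lotka equation failed."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, the convention used in report tables.

    Python's built-in ``round`` is banker's rounding; printed life-history
    tables conventionally use half-up (32.15 -> 32.2).
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CohortCensus:
    """Daily census of one replicate cohort.

    Parameters
    ----------
    cohort_id : str
        Unique label for the cohort.
    generation : str
        ``"F1"`` or ``"F5"`` — the generation whose life table is followed.
    treatment : str
        Maternal UVB treatment: ``control`` (0), ``low`` (1.3), ``mid``
        (3.7) or ``high`` (5.0 W/m^2).
    feeding : str
        ``"fed"`` or ``"starved"``.
    replicate_id : str
        Replicate label within the (generation, treatment, feeding) cell.
    days : numpy.ndarray
        Integer ages in days since hatch, contiguous from 0.
    n_x : numpy.ndarray
        Number of surviving females at each age.
    b_x : numpy.ndarray
        Number of neonates hatched at each age.
    censored : numpy.ndarray or None
        Optional per-day count of females removed alive (right-censored).
        Ignored by the life-table sums, used by Kaplan–Meier utilities.
    """

    cohort_id: str
    generation: str
    treatment: str
    feeding: str
    replicate_id: str
    days: np.ndarray
    n_x: np.ndarray
    b_x: np.ndarray
    censored: np.ndarray | None = None

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=int)
        n_x = np.asarray(self.n_x, dtype=int)
        b_x = np.asarray(self.b_x, dtype=int)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "n_x", n_x)
        object.__setattr__(self, "b_x", b_x)
        if self.censored is not None:
            object.__setattr__(self, "censored", np.asarray(self.censored, dtype=int))
        self.validate()

    def validate(self) -> None:
        if self.generation not in GENERATIONS:
            raise DataIntegrityError(
                f"{self.cohort_id}: unknown generation {self.generation!r}"
            )
        if self.treatment not in TREATMENTS:
            raise DataIntegrityError(
                f"{self.cohort_id}: unknown treatment {self.treatment!r}"
            )
        if self.feeding not in FEEDINGS:
            raise DataIntegrityError(
                f"{self.cohort_id}: unknown feeding {self.feeding!r}"
            )
        if len(self.days) == 0:
            raise InvalidCohortError(f"{self.cohort_id}: empty census")
        if not (len(self.days) == len(self.n_x) == len(self.b_x)):
            raise DataIntegrityError(f"{self.cohort_id}: ragged census columns")
        if self.days[0] != 0 or np.any(np.diff(self.days) != 1):
            raise DataIntegrityError(
                f"{self.cohort_id}: days must be contiguous integers from 0"
            )
        if np.any(self.n_x < 0) or np.any(self.b_x < 0):
            raise DataIntegrityError(f"{self.cohort_id}: negative counts")
        rising = np.nonzero(np.diff(self.n_x) > 0)[0]
        if rising.size:
            day = int(self.days[rising[0] + 1])
            raise DataIntegrityError(
                f"{self.cohort_id}: survivors increase on day {day}"
            )
        bad = np.nonzero((self.n_x == 0) & (self.b_x > 0))[0]
        if bad.size:
            day = int(self.days[bad[0]])
            raise DataIntegrityError(
                f"{self.cohort_id}: births recorded with no survivors on day {day}"
            )
        if self.censored is not None and len(self.censored) != len(self.days):
            raise DataIntegrityError(f"{self.cohort_id}: ragged censor column")

    @property
    def n0(self) -> int:
        """Number of founding females (survivors at day 0)."""
        return int(self.n_x[0])

    @property
    def cell(self) -> tuple[str, str, str]:
        """(generation, treatment, feeding) design cell of this cohort."""
        return (self.generation, self.treatment, self.feeding)

    def death_days(self) -> np.ndarray:
        """Age at death of each founder, survivors assigned the last census day.

        A female counted alive on day ``x-1`` but not on day ``x`` is
        recorded as dying at age ``x``.
        """
        deaths = -np.diff(self.n_x)
        ages = np.repeat(self.days[1:], deaths)
        still_alive = int(self.n_x[-1])
        if still_alive:
            ages = np.concatenate([ages, np.full(still_alive, self.days[-1])])
        return np.sort(ages)

    def mean_lifespan(self) -> float:
        """Mean age at death across founders, in days."""
        return float(self.death_days().mean())


@dataclass(frozen=True)
class Schedules:
    """Age-specific survivorship ``l_x`` and fecundity ``m_x`` schedules."""

    days: np.ndarray
    l_x: np.ndarray
    m_x: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "days", np.asarray(self.days, dtype=int))
        object.__setattr__(self, "l_x", np.asarray(self.l_x, dtype=float))
        object.__setattr__(self, "m_x", np.asarray(self.m_x, dtype=float))
        if self.l_x[0] != 1.0:
            raise DataIntegrityError("l_x must start at 1")
        if np.any(self.l_x < 0) or np.any(self.l_x > 1):
            raise DataIntegrityError("l_x outside [0, 1]")
        if np.any(np.diff(self.l_x) > 1e-12):
            raise DataIntegrityError("l_x must be non-increasing")
        if np.any(self.m_x < 0):
            raise DataIntegrityError("m_x must be non-negative")


@dataclass(frozen=True)
class LifetableResult:
    """All life-table scalars for one cohort.

    ``r_approx`` is ln(R0)/T; ``r_exact`` is the Euler–Lotka root, an
    internal cross-check that is reported alongside but never substituted
    for the approximation.  When ``R0 == 0`` the derived parameters are
    undefined and flagged rather than silently NaN.
    """

    cohort_id: str
    generation: str
    treatment: str
    feeding: str
    replicate_id: str
    schedules: Schedules
    mean_lifespan: float
    R0: float
    T: float | None
    r_approx: float | None
    r_exact: float | None
    flags: dict = field(default_factory=dict)

    @property
    def undefined(self) -> bool:
        return bool(self.flags.get("undefined_T_r", False))


@dataclass(frozen=True)
class FounderRecord:
    """One founding female's full history: age at death and daily births.

    ``births[x]`` is the number of neonates she produced on day x; she is
    censused alive on days 0..death_day-1, so births are only allowed at
    ages below ``death_day``.  The resampling unit for bootstrap
    confidence intervals.
    """

    death_day: int
    births: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "births", np.asarray(self.births, dtype=int))
        if self.death_day < 1:
            raise DataIntegrityError("death day must be >= 1")
        if np.any(self.births < 0):
            raise DataIntegrityError("negative birth counts")
        if np.any(self.births[self.death_day :] > 0):
            raise DataIntegrityError("births at or after the death-day census")


def census_from_founders(
    founders: list[FounderRecord],
    *,
    cohort_id: str = "cohort",
    generation: str = "F1",
    treatment: str = "control",
    feeding: str = "fed",
    replicate_id: str = "r1",
) -> CohortCensus:
    """Aggregate individual founder histories into a daily cohort census.

    A founder with ``death_day = d`` is counted among survivors on days
    0..d-1 (she dies between the day d-1 and day d censuses); ``death_day
    = 0`` would mean dead at the founding census and is disallowed.
    """
    if not founders:
        raise InvalidCohortError("no founders")
    deaths = np.array([f.death_day for f in founders])
    horizon = max(
        int(deaths.max()),
        max(len(f.births) - 1 for f in founders),
    )
    days = np.arange(horizon + 1)
    # n_x[d] = #{founders with death_day > d}; deaths are small integers
    death_counts = np.bincount(deaths, minlength=horizon + 2)
    n_x = len(founders) - np.cumsum(death_counts)[:horizon + 1]
    b_x = np.zeros(horizon + 1, dtype=int)
    for f in founders:
        b_x[: len(f.births)] += f.births
    return CohortCensus(
        cohort_id=cohort_id,
        generation=generation,
        treatment=treatment,
        feeding=feeding,
        replicate_id=replicate_id,
        days=days,
        n_x=n_x,
        b_x=b_x,
    )


# ---------------------------------------------------------------------------
# schedule construction
# ---------------------------------------------------------------------------

def compute_survivorship(census: CohortCensus) -> np.ndarray:
    """Survivorship schedule l_x = n_x / n0."""
    if census.n0 == 0:
        raise InvalidCohortError(f"{census.cohort_id}: no founding females")
    return census.n_x / census.n0


def compute_fecundity(census: CohortCensus) -> np.ndarray:
    """Per-capita fecundity m_x = b_x / n_x, defined as 0 where n_x == 0.

    Ages with no survivors contribute nothing to R0 or T, so the 0/0
    convention is harmless; births at such ages are rejected upstream as a
    data-integrity violation.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        m_x = np.where(census.n_x > 0, census.b_x / np.maximum(census.n_x, 1), 0.0)
    return m_x


def schedules_from_census(census: CohortCensus) -> Schedules:
    return Schedules(
        days=census.days,
        l_x=compute_survivorship(census),
        m_x=compute_fecundity(census),
    )


# ---------------------------------------------------------------------------
# scalar life-history parameters
# ---------------------------------------------------------------------------

def net_reproductive_rate(schedules: Schedules) -> float:
    """R0 = sum_x l_x m_x, expected lifetime offspring per female."""
    return float(np.sum(schedules.l_x * schedules.m_x))


def generation_time(schedules: Schedules) -> float:
    """T = sum_x x l_x m_x / R0, the mean maternal age at offspring production."""
    r0 = net_reproductive_rate(schedules)
    if r0 == 0:
        raise UndefinedParameterError("generation time undefined: R0 == 0")
    return float(np.sum(schedules.days * schedules.l_x * schedules.m_x) / r0)


def intrinsic_rate_approx(r0: float, t: float) -> float:
    """r ≈ ln(R0)/T; negative when R0 < 1 (declining cohort)."""
    if r0 == 0:
        raise UndefinedParameterError("r undefined: R0 == 0")
    if t <= 0:
        raise UndefinedParameterError("r undefined: T <= 0")
    return math.log(r0) / t


def intrinsic_rate_exact(schedules: Schedules, tol: float = 1e-10) -> float:
    """Exact intrinsic rate: root of f(r) = sum_x exp(-r x) l_x m_x - 1.

    f is strictly decreasing in r whenever reproduction occurs at a
    positive age, so the root is unique.  Bracketed by geometric expansion
    then solved with Brent's method to ``|f(r)| < tol``.
    """
    phi = schedules.l_x * schedules.m_x
    if not np.any(phi > 0):
        raise UndefinedParameterError("Euler-Lotka root undefined: no reproduction")
    x = schedules.days.astype(float)

    def f(r: float) -> float:
        return float(np.sum(np.exp(-r * x) * phi) - 1.0)

    r0 = float(np.sum(phi))
    if r0 == 1.0:
        # f(0) = R0 - 1 = 0 exactly
        return 0.0
    lo, hi = -1.0, 1.0
    for _ in range(80):
        if f(lo) > 0 > f(hi):
            break
        if f(lo) <= 0:
            lo *= 2.0
        if f(hi) >= 0:
            hi *= 2.0
    else:
        raise NumericalFailureError("could not bracket the Euler-Lotka root")
    root = brentq(f, lo, hi, xtol=1e-14, maxiter=200)
    if abs(f(root)) > tol:
        raise NumericalFailureError(f"Euler-Lotka residual {f(root):.3g} above {tol}")
    return float(root)


def lifetable(census: CohortCensus) -> LifetableResult:
    """Full life-table analysis of one cohort census.

    Composes the schedules and the four scalars; undefined parameters
    (R0 == 0) are carried as flags, and R0 < 1 flags negative growth.
    """
    sched = schedules_from_census(census)
    r0 = net_reproductive_rate(sched)
    flags: dict = {}
    if r0 == 0:
        flags["undefined_T_r"] = True
        t = r_approx = r_exact = None
    else:
        t = generation_time(sched)
        r_approx = intrinsic_rate_approx(r0, t)
        r_exact = intrinsic_rate_exact(sched)
        if r0 < 1:
            flags["negative_growth"] = True
    return LifetableResult(
        cohort_id=census.cohort_id,
        generation=census.generation,
        treatment=census.treatment,
        feeding=census.feeding,
        replicate_id=census.replicate_id,
        schedules=sched,
        mean_lifespan=census.mean_lifespan(),
        R0=r0,
        T=t,
        r_approx=r_approx,
        r_exact=r_exact,
        flags=flags,
    )
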