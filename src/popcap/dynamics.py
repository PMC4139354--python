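"""Coupled population/carrying-capacity difference equations.

The state is a pair (P_t, K_t) of population and carrying capacity, both in
persons, advanced on an annual integer-year grid:

    dP_t = r_soc * P_t * (K_t - P_t)          (non-normalized logistic step)
    dK_t = law(P_t, K_t, dP_t; L, a, b)       (capacity-change law)

The capacity laws form a small registry.  ``verhulst`` freezes K.  ``oc``
couples the two with dK = (L/P) * dP, so that gained capacity is never lost.
The ``cc-*`` variants subtract a consumption-cost discount governed by
coefficients a (scale) and b (power); every variant reduces bit-for-bit to
``oc`` at a = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "RateParameters",
    "StructuralParameters",
    "InitialConditions",
    "ModelSpec",
    "TrajectoryPoint",
    "Trajectory",
    "CAPACITY_LAWS",
    "step_population",
    "elasticity_and_dK",
    "simulate",
    "verhulst_closed_form",
    "oc_conservation_gap",
]


class InvalidStateError(ValueError):
    """A dynamical quantity was non-finite or out of its domain."""


class ConfigurationError(ValueError):
    """A model specification is internally inconsistent."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateParameters:
    """Rates of the population recursion.

    ``r_soc`` (per person per year) is the only rate entering the dynamics.
    ``r_max`` is the natural per-capita ceiling; when given, the dilution
    factor ``m = r_max / r_soc`` is derived bookkeeping and must be >= 1.
    """

    r_soc: float
    r_max: Optional[float] = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.r_soc) and self.r_soc > 0):
            raise ConfigurationError(f"r_soc must be finite and > 0, got {self.r_soc}")
        if self.r_max is not None:
            if not (math.isfinite(self.r_max) and self.r_max > 0):
                raise ConfigurationError(f"r_max must be finite and > 0, got {self.r_max}")
            if self.m < 1:
                raise ConfigurationError(
                    f"m = r_max/r_soc = {self.m} < 1; r_soc may not exceed r_max"
                )

    @property
    def m(self) -> Optional[float]:
        """Dilution factor r_max / r_soc (None when r_max is unset)."""
        if self.r_max is None:
            return None
        return self.r_max / self.r_soc


@dataclass(frozen=True)
class StructuralParameters:
    """Structural constants of the capacity law.

    L : persons, limit to economies of scale (c = L/P in the ``oc`` law).
    a : consumption-cost discount coefficient, >= 0; a = 0 recovers ``oc``.
    b : dimensionless power of the cost term, 0 <= b <= 3.
    """

    L: float
    a: float = 0.0
    b: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.L) and self.L > 0):
            raise ConfigurationError(f"L must be finite and > 0, got {self.L}")
        if not (math.isfinite(self.a) and self.a >= 0):
            raise ConfigurationError(f"a must be finite and >= 0, got {self.a}")
        if not (math.isfinite(self.b) and 0 <= self.b <= 3):
            raise ConfigurationError(f"b must lie in [0, 3], got {self.b}")


@dataclass(frozen=True)
class InitialConditions:
    t0: int = 1
    P0: float = 2.25e8
    K0: float = 2.5e8

    def __post_init__(self) -> None:
        if not (math.isfinite(self.P0) and self.P0 > 0):
            raise ConfigurationError(f"P0 must be finite and > 0, got {self.P0}")
        if not (math.isfinite(self.K0) and self.K0 > self.P0):
            raise ConfigurationError(f"K0 must be finite and > P0, got K0={self.K0}, P0={self.P0}")


@dataclass(frozen=True)
class ModelSpec:
    """Everything needed to reproduce one run."""

    law: str
    rates: RateParameters
    structure: StructuralParameters
    init: InitialConditions = field(default_factory=InitialConditions)
    t_end: int = 2500

    def __post_init__(self) -> None:
        if self.law not in CAPACITY_LAWS:
            raise ConfigurationError(
                f"unknown law {self.law!r}; known: {sorted(CAPACITY_LAWS)}"
            )
        if self.t_end <= self.init.t0:
            raise ConfigurationError(f"t_end={self.t_end} must exceed t0={self.init.t0}")

    def with_K0(self, K0: float) -> "ModelSpec":
        return replace(self, init=replace(self.init, K0=K0))


@dataclass(frozen=True)
class TrajectoryPoint:
    t: int
    P: float
    K: float
    dP: float
    dK: float
    c_realized: Optional[float]  # dK/dP, None when dP == 0
    pct_growth: float            # 100 * dP / P


@dataclass(frozen=True)
class Trajectory:
    spec: ModelSpec
    years: np.ndarray       # consecutive integer years from t0
    P: np.ndarray
    K: np.ndarray
    dP: np.ndarray          # increment applied from t to t+1
    dK: np.ndarray
    collapse_event: Optional[tuple[int, str]] = None

    def __len__(self) -> int:
        return len(self.years)

    @property
    def collapsed(self) -> bool:
        return self.collapse_event is not None

    @property
    def c_realized(self) -> np.ndarray:
        """Realized elasticity dK/dP; NaN where dP == 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.where(self.dP != 0.0, self.dK / self.dP, np.nan)
        return c

    @property
    def pct_growth(self) -> np.ndarray:
        return 100.0 * self.dP / self.P

    def population_at(self, year: int) -> float:
        i = year - int(self.years[0])
        if i < 0 or i >= len(self.years):
            raise KeyError(f"year {year} not covered by trajectory")
        return float(self.P[i])

    def covers(self, year: int) -> bool:
        return int(self.years[0]) <= year <= int(self.years[-1])

    def point(self, year: int) -> TrajectoryPoint:
        i = year - int(self.years[0])
        if i < 0 or i >= len(self.years):
            raise KeyError(f"year {year} not covered by trajectory")
        dP = float(self.dP[i])
        dK = float(self.dK[i])
        return TrajectoryPoint(
            t=int(self.years[i]),
            P=float(self.P[i]),
            K=float(self.K[i]),
            dP=dP,
            dK=dK,
            c_realized=(dK / dP) if dP != 0.0 else None,
            pct_growth=100.0 * dP / float(self.P[i]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "P": self.P,
                "K": self.K,
                "dP": self.dP,
                "dK": self.dK,
                "c_realized": self.c_realized,
                "pct_growth": self.pct_growth,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# capacity-change laws
# ---------------------------------------------------------------------------

def _law_verhulst(P: float, K: float, dP: float, s: StructuralParameters) -> float:
    return 0.0


def _law_oc(P: float, K: float, dP: float, s: StructuralParameters) -> float:
    return (s.L / P) * dP


def _law_cc_mul_p(P: float, K: float, dP: float, s: StructuralParameters) -> float:
    # c_t = L/P - a*P^b, applied multiplicatively to dP
    if s.a == 0.0:
        return (s.L / P) * dP
    return (s.L / P - s.a * P ** s.b) * dP


def _law_cc_inner_p(P: float, K: float, dP: float, s: StructuralParameters) -> float:
    # c_t = (L - a*P^b) / P
    if s.a == 0.0:
        return (s.L / P) * dP
    return ((s.L - s.a * P ** s.b) / P) * dP


def _law_cc_abs_p(P: float, K: float, dP: float, s: StructuralParameters) -> float:
    # dK = (L/P)*dP - a*P^b  (absolute drag driven by population)
    if s.a == 0.0:
        return (s.L / P) * dP
    return (s.L / P) * dP - s.a * P ** s.b


def _law_cc_abs_k(P: float, K: float, dP: float, s: StructuralParameters) -> float:
    # dK = (L/P)*dP - a*K^b  (absolute drag driven by capacity)
    if s.a == 0.0:
        return (s.L / P) * dP
    return (s.L / P) * dP - s.a * K ** s.b


#: persons per "million-persons" unit used by the scaled multiplicative law
MEGA = 1e6


def _law_cc_mul_pmil(P: float, K: float, dP: float, s: StructuralParameters) -> float:
    # c_t = L/P - (a*1e6) * (P/1e6)^b, applied multiplicatively to dP.
    # Same structure as cc-mul-p but with the cost power evaluated on the
    # millions-of-persons scale and the coefficient carried along by 1e6,
    # i.e. an effective persons-scale coefficient a * 10^(6*(1-b)).
    if s.a == 0.0:
        return (s.L / P) * dP
    return (s.L / P - (s.a * MEGA) * (P / MEGA) ** s.b) * dP


CAPACITY_LAWS: dict[str, Callable[[float, float, float, StructuralParameters], float]] = {
    "verhulst": _law_verhulst,
    "oc": _law_oc,
    "cc-mul-p": _law_cc_mul_p,
    "cc-inner-p": _law_cc_inner_p,
    "cc-abs-p": _law_cc_abs_p,
    "cc-abs-k": _law_cc_abs_k,
    "cc-mul-pmil": _law_cc_mul_pmil,
}

#: CC variants participating in identification, in deterministic registry order.
CC_CANDIDATES: tuple[str, ...] = (
    "cc-mul-p",
    "cc-inner-p",
    "cc-abs-p",
    "cc-abs-k",
    "cc-mul-pmil",
)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def step_population(P: float, K: float, r_soc: float) -> float:
    """One-year population increment dP = r_soc * P * (K - P)."""
    if not (math.isfinite(P) and math.isfinite(K) and math.isfinite(r_soc)):
        raise InvalidStateError(f"non-finite inputs: P={P}, K={K}, r_soc={r_soc}")
    if P <= 0 or K <= 0:
        raise InvalidStateError(f"P and K must be > 0, got P={P}, K={K}")
    return r_soc * P * (K - P)


def elasticity_and_dK(
    law: str,
    P: float,
    K: float,
    dP: float,
    structure: StructuralParameters,
) -> float:
    """Capacity increment dK for one step of the named law.

    The realized elasticity is dK/dP whenever dP != 0.  With a = 0 every
    cc variant returns the ``oc`` value bit-for-bit.
    """
    try:
        fn = CAPACITY_LAWS[law]
    except KeyError:
        raise ConfigurationError(
            f"unknown law {law!r}; known: {sorted(CAPACITY_LAWS)}"
        ) from None
    if not (math.isfinite(P) and math.isfinite(K) and math.isfinite(dP)):
        raise InvalidStateError(f"non-finite inputs: P={P}, K={K}, dP={dP}")
    if P <= 0 or K <= 0:
        raise InvalidStateError(f"P and K must be > 0, got P={P}, K={K}")
    return fn(P, K, dP, structure)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate(spec: ModelSpec) -> Trajectory:
    """Run the annual-step recursion from t0 through t_end.

    Both increments are evaluated at the pre-step state (P_t, K_t); dP_t is
    computed first and fed to the capacity law.  If the next state would be
    non-positive or non-finite the trajectory is truncated at the last valid
    year and a collapse event is recorded -- collapse is a result, not an
    error.
    """
    law_fn = CAPACITY_LAWS[spec.law]
    r = spec.rates.r_soc
    s = spec.structure
    t0, t_end = spec.init.t0, spec.t_end
    n = t_end - t0 + 1

    P = np.empty(n)
    K = np.empty(n)
    dPs = np.empty(n)
    dKs = np.empty(n)

    p, k = spec.init.P0, spec.init.K0
    collapse: Optional[tuple[int, str]] = None
    i = 0
    while True:
        dp = r * p * (k - p)
        dk = law_fn(p, k, dp, s)
        P[i], K[i], dPs[i], dKs[i] = p, k, dp, dk
        if i == n - 1:
            break
        p_next, k_next = p + dp, k + dk
        if not (math.isfinite(p_next) and math.isfinite(k_next)):
            collapse = (t0 + i, "state became non-finite")
            break
        if p_next <= 0 or k_next <= 0:
            which = "P" if p_next <= 0 else "K"
            collapse = (t0 + i, f"{which} fell to or below zero")
            break
        p, k = p_next, k_next
        i += 1

    m = i + 1
    years = np.arange(t0, t0 + m, dtype=np.int64)
    return Trajectory(
        spec=spec,
        years=years,
        P=P[:m].copy(),
        K=K[:m].copy(),
        dP=dPs[:m].copy(),
        dK=dKs[:m].copy(),
        collapse_event=collapse,
    )


def simulate_population_at(spec: ModelSpec, years: tuple[int, ...]) -> dict[int, float]:
    """Fast path: run the recursion without storing the full trajectory.

    Returns {year: P} for the requested years.  Years past a collapse are
    absent from the result.  Identical arithmetic to :func:`simulate`.
    """
    law_fn = CAPACITY_LAWS[spec.law]
    r = spec.rates.r_soc
    s = spec.structure
    t0, t_end = spec.init.t0, spec.t_end
    want = set(years)
    out: dict[int, float] = {}

    p, k = spec.init.P0, spec.init.K0
    if t0 in want:
        out[t0] = p
    for t in range(t0, t_end):
        dp = r * p * (k - p)
        dk = law_fn(p, k, dp, s)
        p_next, k_next = p + dp, k + dk
        if not (
            math.isfinite(p_next) and math.isfinite(k_next)
            and p_next > 0 and k_next > 0
        ):
            break
        p, k = p_next, k_next
        if t + 1 in want:
            out[t + 1] = p
    return out


# ---------------------------------------------------------------------------
# batch (vectorized) engine
# ---------------------------------------------------------------------------
#
# Grid scans and Monte-Carlo recovery need thousands of runs; the batch
# engine advances a whole parameter vector in lockstep with numpy.  The
# arithmetic mirrors the scalar laws operation for operation.

def _blaw_verhulst(P, K, dP, L, a, b):
    return np.zeros_like(P)


def _blaw_oc(P, K, dP, L, a, b):
    return (L / P) * dP


def _blaw_cc_mul_p(P, K, dP, L, a, b):
    return (L / P - a * P ** b) * dP


def _blaw_cc_inner_p(P, K, dP, L, a, b):
    return ((L - a * P ** b) / P) * dP


def _blaw_cc_abs_p(P, K, dP, L, a, b):
    return (L / P) * dP - a * P ** b


def _blaw_cc_abs_k(P, K, dP, L, a, b):
    return (L / P) * dP - a * K ** b


def _blaw_cc_mul_pmil(P, K, dP, L, a, b):
    return (L / P - (a * MEGA) * (P / MEGA) ** b) * dP


_BATCH_LAWS = {
    "verhulst": _blaw_verhulst,
    "oc": _blaw_oc,
    "cc-mul-p": _blaw_cc_mul_p,
    "cc-inner-p": _blaw_cc_inner_p,
    "cc-abs-p": _blaw_cc_abs_p,
    "cc-abs-k": _blaw_cc_abs_k,
    "cc-mul-pmil": _blaw_cc_mul_pmil,
}


def simulate_batch_population_at(
    law: str,
    P0,
    K0,
    r_soc,
    L,
    a,
    b,
    years: tuple[int, ...],
    t0: int = 1,
    t_end: int = 2500,
):
    """Advance a vector of parameter points and sample P at given years.

    All parameter arguments broadcast against each other.  Returns
    ``(pop, last_P)`` where ``pop[year]`` is an array with NaN for points
    that collapsed before that year, and ``last_P`` holds the final valid
    population of every point (the pre-collapse value for collapsed ones).
    """
    if law not in _BATCH_LAWS:
        raise ConfigurationError(f"unknown law {law!r}")
    fn = _BATCH_LAWS[law]
    P0, K0, r_soc, L, a, b = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (P0, K0, r_soc, L, a, b))
    )
    P = P0.astype(float).copy()
    K = K0.astype(float).copy()
    r = r_soc
    alive = np.ones(P.shape, dtype=bool)
    want = set(int(y) for y in years)
    pop: dict[int, np.ndarray] = {}
    if t0 in want:
        pop[t0] = P.copy()
    for t in range(t0, t_end):
        dP = r * P * (K - P)
        dK = fn(P, K, dP, L, a, b)
        P_next = P + dP
        K_next = K + dK
        ok = alive & np.isfinite(P_next) & np.isfinite(K_next) & (P_next > 0) & (K_next > 0)
        P = np.where(ok, P_next, P)
        K = np.where(ok, K_next, K)
        alive = ok
        if t + 1 in want:
            out = P.copy()
            out[~alive] = np.nan
            pop[t + 1] = out
        if not alive.any():
            for y in want:
                if y > t + 1 and y not in pop:
                    pop[y] = np.full(P.shape, np.nan)
            break
    for y in want:
        pop.setdefault(y, np.full(P.shape, np.nan))
    return pop, P


# ---------------------------------------------------------------------------
# analytic oracles
# ---------------------------------------------------------------------------

def verhulst_closed_form(P0: float, K: float, r_soc: float, t: float) -> float:
    """Continuous-time logistic solution of dP/dt = r_soc * P * (K - P).

    The effective exponential rate is r_soc * K.  For P0 < K the curve rises
    monotonically to K; for P0 > K it decays monotonically to K (the
    decreasing branch of the same closed form).
    """
    if not (P0 > 0 and K > 0):
        raise InvalidStateError(f"P0 and K must be > 0, got P0={P0}, K={K}")
    A = (K - P0) / P0
    return K / (1.0 + A * math.exp(-r_soc * K * t))


def oc_conservation_gap(traj: Trajectory) -> float:
    """Max over t of |K_t - K0 - L*ln(P_t/P0)| for an ``oc`` trajectory.

    The quantity K - L*ln(P) is conserved by the continuous limit of the
    ``oc`` coupling; the discrete recursion drifts from it by at most
    L * sum((dP/P)^2) over the steps taken.  Used as a test oracle and for
    equilibrium prediction.  Raises for non-oc trajectories, where the
    invariant does not hold.
    """
    if traj.spec.law != "oc":
        raise ConfigurationError(
            f"conservation gap is defined for the 'oc' law, not {traj.spec.law!r}"
        )
    if traj.collapsed:
        raise InvalidStateError("trajectory collapsed; gap undefined")
    P0 = traj.P[0]
    K0 = traj.K[0]
    L = traj.spec.structure.L
    gap = np.abs(traj.K - K0 - L * np.log(traj.P / P0))
    return float(gap.max())


def oc_equilibrium(P0: float, K0: float, L: float, tol: float = 1e-12) -> float:
    """Solve P* = K0 + L*ln(P*/P0), the continuous-limit ``oc`` steady state.

    Fixed-point iteration on P -> K0 + L*ln(P/P0), which contracts for
    P > L; started from a bracket-safe Newton fallback.
    """
    # Newton on f(P) = P - K0 - L*ln(P/P0); f'(P) = 1 - L/P
    p = max(10.0 * L, K0 + L)
    for _ in range(200):
        f = p - K0 - L * math.log(p / P0)
        fp = 1.0 - L / p
        step = f / fp
        p_new = p - step
        if p_new <= L:
            p_new = 0.5 * (p + L)
        if abs(p_new - p) <= tol * p:
            return p_new
        p = p_new
    return p
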