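"""Availability-time distributions for single-vesicle release sites.

After a site releases its vesicle, the time until it again holds a
releasable vesicle is a non-negative random variable ``T_a`` with mean
``tau_a`` (seconds).  This module provides the two laws used throughout the
package — exponential (the classical memoryless assumption) and Rayleigh
(a non-memoryless alternative) — plus a hook for user-supplied laws, and
the Bayes conditional probability that a vesicle, still unavailable at one
observation time, becomes available by a later one:

    P(T_a <= b | T_a > a) = (F(b) - F(a)) / (1 - F(a)),   0 <= a < b.

All times are in seconds.  Samplers map a uniform variate on the open
interval (0, 1) to an availability time by inverse transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .exceptions import DegenerateConditioningError, ParameterError

__all__ = [
    "AvailabilityDistribution",
    "make_exponential",
    "make_rayleigh",
    "make_custom",
    "conditional_availability",
]

# Rayleigh mean = scale * sqrt(pi/2), hence scale = mean * sqrt(2/pi).
_RAYLEIGH_SCALE_PER_MEAN = math.sqrt(2.0 / math.pi)


@dataclass(frozen=True)
class AvailabilityDistribution:
    """The law of the time for a released vesicle to become available again.

    Attributes
    ----------
    mean_time:
        Mean availability time tau_a in seconds; strictly positive.
    family:
        One of ``"exponential"``, ``"rayleigh"``, ``"custom"``.
    cdf:
        Vectorised CDF, elapsed time (s, >= 0) -> probability.
    sampler:
        Inverse-transform sampler, uniform variate in (0, 1) -> time >= 0.
    """

    mean_time: float
    family: str
    cdf: Callable[[np.ndarray], np.ndarray]
    sampler: Callable[[np.ndarray], np.ndarray]

    def sample(self, rng: np.random.Generator, size: Optional[int] = None):
        """Draw availability times using uniforms from ``rng``.

        Uniforms are drawn on (0, 1): a draw of exactly 0.0 is redrawn as
        the smallest positive double so log(0) never occurs.
        """
        u = rng.random(size)
        u = np.where(u == 0.0, np.nextafter(0.0, 1.0), u)
        return self.sampler(u)


def _check_mean(mean_time: float) -> float:
    mean_time = float(mean_time)
    if not math.isfinite(mean_time) or mean_time <= 0.0:
        raise ParameterError(f"mean_time must be a positive finite number of "
                             f"seconds, got {mean_time!r}")
    return mean_time


def make_exponential(mean_time: float) -> AvailabilityDistribution:
    """Exponential availability times with mean ``mean_time`` (tau_a).

    CDF ``1 - exp(-y/tau_a)``; sampler ``-tau_a * log(U)``.
    """
    tau = _check_mean(mean_time)

    def cdf(y):
        y = np.asarray(y, dtype=float)
        out = -np.expm1(-np.maximum(y, 0.0) / tau)
        return out if out.ndim else float(out)

    def sampler(u):
        u = np.asarray(u, dtype=float)
        out = -tau * np.log(u)
        return out if out.ndim else float(out)

    return AvailabilityDistribution(tau, "exponential", cdf, sampler)


def make_rayleigh(mean_time: float) -> AvailabilityDistribution:
    """Rayleigh availability times parameterised by their MEAN.

    The Rayleigh law with scale sigma has mean sigma*sqrt(pi/2); the scale
    is therefore fixed at ``mean_time * sqrt(2/pi)`` so that the empirical
    mean of samples equals ``mean_time``.  CDF ``1 - exp(-y^2/(2 sigma^2))``.
    """
    mean = _check_mean(mean_time)
    sigma = mean * _RAYLEIGH_SCALE_PER_MEAN
    two_s2 = 2.0 * sigma * sigma

    def cdf(y):
        y = np.asarray(y, dtype=float)
        yy = np.maximum(y, 0.0)
        out = -np.expm1(-(yy * yy) / two_s2)
        return out if out.ndim else float(out)

    def sampler(u):
        # Inverse transform via the survival function: if U ~ Unif(0,1)
        # then sigma*sqrt(-2 ln U) is Rayleigh(sigma).
        u = np.asarray(u, dtype=float)
        out = sigma * np.sqrt(-2.0 * np.log(u))
        return out if out.ndim else float(out)

    return AvailabilityDistribution(mean, "rayleigh", cdf, sampler)


def make_custom(
    mean_time: float,
    cdf: Callable[[np.ndarray], np.ndarray],
    inverse_cdf: Optional[Callable[[float], float]] = None,
    tol: float = 1e-10,
) -> AvailabilityDistribution:
    """User-supplied availability-time law.

    Parameters
    ----------
    mean_time:
        The law's mean, in seconds (used for bookkeeping and sanity checks).
    cdf:
        CDF on elapsed time >= 0; must satisfy cdf(0) = 0 and -> 1.
    inverse_cdf:
        Optional exact inverse; when omitted the sampler inverts ``cdf``
        numerically by bisection (doubling upper bracket, tolerance ``tol``).
    """
    mean = _check_mean(mean_time)

    if inverse_cdf is not None:
        def sampler(u):
            u_arr = np.asarray(u, dtype=float)
            if u_arr.ndim == 0:
                return float(inverse_cdf(float(u_arr)))
            return np.array([inverse_cdf(float(v)) for v in u_arr.ravel()]
                            ).reshape(u_arr.shape)
    else:
        def _invert_one(p: float) -> float:
            hi = mean
            while float(cdf(hi)) < p:
                hi *= 2.0
                if hi > 1e12 * mean:  # pragma: no cover - pathological CDF
                    raise ParameterError("cdf does not reach the requested "
                                         "probability; cannot invert")
            lo = 0.0
            while hi - lo > tol:
                mid = 0.5 * (lo + hi)
                if float(cdf(mid)) < p:
                    lo = mid
                else:
                    hi = mid
            return 0.5 * (lo + hi)

        def sampler(u):
            u_arr = np.asarray(u, dtype=float)
            if u_arr.ndim == 0:
                return _invert_one(float(u_arr))
            return np.array([_invert_one(float(v)) for v in u_arr.ravel()]
                            ).reshape(u_arr.shape)

    return AvailabilityDistribution(mean, "custom", cdf, sampler)


def conditional_availability(
    dist: AvailabilityDistribution,
    elapsed_prev: float,
    elapsed_now: float,
) -> float:
    """P(available by ``elapsed_now`` | not available at ``elapsed_prev``).

    Both arguments are elapsed times since the release that emptied the
    site.  Returns ``(F(now) - F(prev)) / (1 - F(prev))``, clipped to [0, 1]
    against floating-point round-off.

    Raises
    ------
    ParameterError
        If ``elapsed_prev < 0`` or ``elapsed_now <= elapsed_prev``.
    DegenerateConditioningError
        If ``F(elapsed_prev) == 1`` (conditioning on a null event).
    """
    elapsed_prev = float(elapsed_prev)
    elapsed_now = float(elapsed_now)
    if elapsed_prev < 0.0:
        raise ParameterError("elapsed_prev must be >= 0")
    if elapsed_now <= elapsed_prev:
        raise ParameterError(
            f"elapsed_now ({elapsed_now}) must exceed elapsed_prev "
            f"({elapsed_prev})")
    f_prev = float(dist.cdf(elapsed_prev))
    f_now = float(dist.cdf(elapsed_now))
    if f_prev >= 1.0:
        raise DegenerateConditioningError(
            "the availability CDF is already 1 at elapsed_prev; the "
            "conditioning event has probability zero")
    return float(np.clip((f_now - f_prev) / (1.0 - f_prev), 0.0, 1.0))
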