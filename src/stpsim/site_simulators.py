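"""Single-trial, single-site event-driven simulators.

A release site holds at most one vesicle.  The site state sigma(t) is 1
(available) or 0 (not available); it switches 1 -> 0 only when an AP
releases the vesicle, and 0 -> 1 exactly once between releases, after a
random availability time T_a.  Two conceptual availability models are
implemented:

* **AM1** — T_a is drawn once, at the moment of release, and is unaffected
  by later spikes;
* **AM2** — while the vesicle is unavailable, the availability clock is
  re-anchored at every arriving spike.

For exponential T_a the two models coincide (memorylessness); otherwise
they differ.  Three statistically identical correct AM1 algorithms are
provided (one draw per release; a per-spike Bayes-conditional coin; a
pre-generated Poisson event stream), plus the known-flawed variants that
this package exists to expose and a discretised Delta-t/tau_a comparator.

All simulations start from a forced release at t = 0 (the vesicle is
unavailable at the start) unless ``start_available=True``.  A spike
arriving exactly at the scheduled availability time finds the vesicle
AVAILABLE (``>=`` comparison).  Each simulator reports how many uniform
variates it consumed, so algorithm efficiencies can be compared.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Union

import numpy as np

from .distributions import AvailabilityDistribution, conditional_availability
from .exceptions import ParameterError, TrajectoryInvariantError
from .release_models import ReleaseModel, release_prob_sequence
from .spike_trains import SpikeTrain

__all__ = [
    "SiteTrajectory",
    "simulate_am1",
    "simulate_am2",
    "simulate_incorrect",
    "simulate_time_stepped",
    "validate_trajectory",
    "is_valid_trajectory",
    "AM1_VARIANTS",
    "INCORRECT_VARIANTS",
]

AM1_VARIANTS = ("resample_at_release", "per_spike_conditional",
                "pregenerated_poisson")
INCORRECT_VARIANTS = ("am1_i11", "am1_i12", "am1_i2", "am2_i1")


@dataclass
class SiteTrajectory:
    """One trial's per-spike record of availability and release.

    ``available_before_decision[i]`` is sigma(t-) at spike i (after any
    refill that happened since the previous spike, before the release
    decision); ``released[i]`` is the binary release outcome R (alpha=1,
    beta=0).
    """

    spike_times: np.ndarray
    available_before_decision: np.ndarray
    released: np.ndarray
    release_times: np.ndarray
    last_release_time: float
    next_availability_time: float
    draws_used: int
    variant: str

    @property
    def n_releases(self) -> int:
        return int(self.release_times.size)

    def first_release_index(self) -> int:
        """1-based spike index of the first release; 0 if none occurred."""
        idx = np.flatnonzero(self.released)
        return int(idx[0]) + 1 if idx.size else 0

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({
            "spike_index": np.arange(1, self.spike_times.size + 1),
            "time_s": self.spike_times,
            "available": self.available_before_decision.astype(int),
            "released": self.released.astype(int),
        })


def _rng(seed: Union[int, np.random.Generator]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.Generator(np.random.PCG64(seed))


def validate_trajectory(traj: SiteTrajectory) -> None:
    """Check the single-vesicle state-machine contract.

    Raises :class:`TrajectoryInvariantError` if a release happened without
    availability, if availability was lost without a release, or if a
    release time is not a spike time.
    """
    avail = traj.available_before_decision
    rel = traj.released
    if np.any(rel & ~avail):
        raise TrajectoryInvariantError("release recorded without an "
                                       "available vesicle")
    for i in range(1, avail.size):
        if avail[i - 1] and not rel[i - 1] and not avail[i]:
            raise TrajectoryInvariantError(
                f"availability lost between spikes {i} and {i + 1} with no "
                "intervening release")
    spike_set = set(np.round(traj.spike_times, 12))
    for t in traj.release_times:
        if round(float(t), 12) not in spike_set:
            raise TrajectoryInvariantError(
                f"release time {t} is not a spike time")


def is_valid_trajectory(traj: SiteTrajectory) -> bool:
    try:
        validate_trajectory(traj)
    except TrajectoryInvariantError:
        return False
    return True


def _finish(times, avail, rel, last_release, next_avail, draws, variant):
    rel = np.asarray(rel, dtype=bool)
    return SiteTrajectory(
        spike_times=times,
        available_before_decision=np.asarray(avail, dtype=bool),
        released=rel,
        release_times=times[rel],
        last_release_time=last_release,
        next_availability_time=next_avail,
        draws_used=draws,
        variant=variant,
    )


def simulate_am1(
    train: SpikeTrain,
    dist: AvailabilityDistribution,
    release_model: ReleaseModel,
    seed: Union[int, np.random.Generator],
    variant: str = "resample_at_release",
    start_available: bool = False,
    stop_after_first_release: bool = False,
) -> SiteTrajectory:
    """Correct single-trial simulation of Availability Model 1.

    Variants (statistically identical for exponential T_a; the first works
    for any distribution):

    * ``resample_at_release`` — one availability time drawn per release;
    * ``per_spike_conditional`` — while unavailable, a uniform coin per
      spike against the Bayes conditional availability probability;
    * ``pregenerated_poisson`` — availability at the next event of a
      pre-generated Poisson stream with rate 1/tau_a (exponential only).
    """
    if variant not in AM1_VARIANTS:
        raise ParameterError(f"unknown AM1 variant {variant!r}; "
                             f"expected one of {AM1_VARIANTS}")
    rng = _rng(seed)
    times = train.times
    p_seq = release_prob_sequence(release_model, train)
    k = times.size
    avail = np.zeros(k, dtype=bool)
    rel = np.zeros(k, dtype=bool)
    draws = 0
    last_release = 0.0 if not start_available else -math.inf

    if variant == "pregenerated_poisson":
        if dist.family != "exponential":
            raise ParameterError("pregenerated_poisson requires an "
                                 "exponential availability distribution")
        # Poisson events with rate 1/tau_a covering the whole train.
        events = []
        t = 0.0
        horizon = times[-1]
        while t <= horizon:
            u = rng.random()
            draws += 1
            t += -dist.mean_time * math.log(max(u, np.nextafter(0.0, 1.0)))
            events.append(t)
        events = np.asarray(events)

        def next_poisson_time(x: float) -> float:
            j = int(np.searchsorted(events, x, side="right"))
            return float(events[j]) if j < events.size else math.inf

        next_avail = 0.0 if start_available else next_poisson_time(0.0)
        for i in range(k):
            if times[i] >= next_avail:
                avail[i] = True
                u = rng.random()
                draws += 1
                if u < p_seq[i]:
                    rel[i] = True
                    last_release = times[i]
                    next_avail = next_poisson_time(times[i])
                    if stop_after_first_release:
                        break
        return _finish(times, avail, rel, last_release, next_avail, draws,
                       f"am1:{variant}")

    if variant == "per_spike_conditional":
        is_avail = start_available
        t_s = 0.0                 # last release time (anchor)
        last_unavail_check = 0.0  # last time unavailability was observed
        next_avail = 0.0 if start_available else math.nan
        for i in range(k):
            t = times[i]
            if not is_avail:
                c = conditional_availability(
                    dist, last_unavail_check - t_s, t - t_s)
                u = rng.random()
                draws += 1
                if u < c:
                    is_avail = True
                else:
                    last_unavail_check = t
            if is_avail:
                avail[i] = True
                u = rng.random()
                draws += 1
                if u < p_seq[i]:
                    rel[i] = True
                    last_release = t
                    is_avail = False
                    t_s = t
                    last_unavail_check = t
                    if stop_after_first_release:
                        break
        return _finish(times, avail, rel, last_release, math.nan, draws,
                       f"am1:{variant}")

    # resample_at_release
    if start_available:
        next_avail = 0.0
    else:
        next_avail = float(dist.sample(rng))
        draws += 1
    for i in range(k):
        if times[i] >= next_avail:
            avail[i] = True
            u = rng.random()
            draws += 1
            if u < p_seq[i]:
                rel[i] = True
                last_release = times[i]
                next_avail = times[i] + float(dist.sample(rng))
                draws += 1
                if stop_after_first_release:
                    break
    return _finish(times, avail, rel, last_release, next_avail, draws,
                   f"am1:{variant}")


def simulate_am2(
    train: SpikeTrain,
    dist: AvailabilityDistribution,
    release_model: ReleaseModel,
    seed: Union[int, np.random.Generator],
    start_available: bool = False,
    stop_after_first_release: bool = False,
) -> SiteTrajectory:
    """Correct single-trial simulation of Availability Model 2.

    While the vesicle is unavailable, the next-availability time is redrawn
    at EVERY spike, anchored at that spike's time; once available, no
    re-draws occur until the next release.
    """
    rng = _rng(seed)
    times = train.times
    p_seq = release_prob_sequence(release_model, train)
    k = times.size
    avail = np.zeros(k, dtype=bool)
    rel = np.zeros(k, dtype=bool)
    draws = 0
    last_release = 0.0 if not start_available else -math.inf
    if start_available:
        next_avail = 0.0
    else:
        next_avail = float(dist.sample(rng))  # anchored at the t=0 release
        draws += 1
    for i in range(k):
        t = times[i]
        if t >= next_avail:
            avail[i] = True
            u = rng.random()
            draws += 1
            if u < p_seq[i]:
                rel[i] = True
                last_release = t
                next_avail = t + float(dist.sample(rng))
                draws += 1
                if stop_after_first_release:
                    break
        else:
            # unavailable: re-anchor the availability clock at this spike
            next_avail = t + float(dist.sample(rng))
            draws += 1
    return _finish(times, avail, rel, last_release, next_avail, draws, "am2")


def simulate_incorrect(
    train: SpikeTrain,
    dist: AvailabilityDistribution,
    release_model: ReleaseModel,
    seed: Union[int, np.random.Generator],
    variant: str,
    start_available: bool = False,
    stop_after_first_release: bool = False,
    warn: bool = True,
) -> SiteTrajectory:
    """Faithful reproductions of known-flawed simulation algorithms.

    These exist to quantify the statistical biases of published shortcuts
    and as regression tests against their silent reintroduction; they emit
    a ``UserWarning`` on use.

    * ``am1_i11`` — one coin per spike against P_a(t_i|t_s) * P_r|a, where
      P_a(t|t_s) = F(t - t_s) is anchored at the last release; no
      persistent availability state.  Implied availability is recorded as
      the coupled event U < P_a.
    * ``am1_i12`` — the same bias via two coins (availability, then
      release), again with no persistent availability state.
    * ``am1_i2`` — a persistent availability flag, but the refill coin uses
      the unconditional F(t_i - t_s) instead of the Bayes conditional, so
      too many vesicles become available after multi-spike gaps.
    * ``am2_i1`` — availability probability anchored at the previous spike
      (F(t_i - t_{i-1})), one combined coin, no persistent flag; the AM2
      analogue of i11, which under-counts releases.
    """
    if variant not in INCORRECT_VARIANTS:
        raise ParameterError(f"unknown incorrect variant {variant!r}; "
                             f"expected one of {INCORRECT_VARIANTS}")
    if warn:
        warnings.warn(
            f"simulate_incorrect({variant!r}) reproduces a known-flawed "
            "algorithm; its output is statistically biased by design",
            UserWarning, stacklevel=2)
    rng = _rng(seed)
    times = train.times
    p_seq = release_prob_sequence(release_model, train)
    k = times.size
    avail = np.zeros(k, dtype=bool)
    rel = np.zeros(k, dtype=bool)
    draws = 0
    t_s = 0.0  # last release time
    last_release = 0.0

    if variant == "am1_i11":
        for i in range(k):
            pa = float(dist.cdf(times[i] - t_s))
            u = rng.random()
            draws += 1
            avail[i] = u < pa  # implied availability, coupled to the coin
            if u < pa * p_seq[i]:
                rel[i] = True
                last_release = t_s = times[i]
                if stop_after_first_release:
                    break
    elif variant == "am1_i12":
        for i in range(k):
            pa = float(dist.cdf(times[i] - t_s))
            u1 = rng.random()
            draws += 1
            if u1 < pa:
                avail[i] = True
                u2 = rng.random()
                draws += 1
                if u2 < p_seq[i]:
                    rel[i] = True
                    last_release = t_s = times[i]
                    if stop_after_first_release:
                        break
    elif variant == "am1_i2":
        is_avail = start_available
        for i in range(k):
            if not is_avail:
                pa = float(dist.cdf(times[i] - t_s))  # bug: unconditional
                u1 = rng.random()
                draws += 1
                if u1 < pa:
                    is_avail = True
            if is_avail:
                avail[i] = True
                u2 = rng.random()
                draws += 1
                if u2 < p_seq[i]:
                    rel[i] = True
                    is_avail = False
                    last_release = t_s = times[i]
                    if stop_after_first_release:
                        break
    else:  # am2_i1
        t_prev = 0.0
        for i in range(k):
            pa = float(dist.cdf(times[i] - t_prev))
            u = rng.random()
            draws += 1
            avail[i] = u < pa
            if u < pa * p_seq[i]:
                rel[i] = True
                last_release = times[i]
                if stop_after_first_release:
                    break
            t_prev = times[i]
    return _finish(times, avail, rel, last_release, math.nan, draws,
                   f"incorrect:{variant}")


def simulate_time_stepped(
    train: SpikeTrain,
    tau_a: float,
    release_model: ReleaseModel,
    dt: float,
    seed: Union[int, np.random.Generator],
    start_available: bool = False,
    stop_after_first_release: bool = False,
) -> SiteTrajectory:
    """Discretised comparator: per-step refill coin with probability dt/tau_a.

    After each release, time advances in steps of ``dt``; each step flips
    the vesicle to available with probability dt/tau_a (the small-interval
    Poisson approximation, exponential availability only).  Converges in
    distribution to :func:`simulate_am1` as dt -> 0, at the cost of many
    more uniform draws.  ``dt >= tau_a`` is rejected and ``dt > tau_a/50``
    triggers a warning.
    """
    if not tau_a > 0:
        raise ParameterError("tau_a must be positive")
    if not dt > 0:
        raise ParameterError("dt must be positive")
    if dt >= tau_a:
        raise ParameterError(f"dt ({dt}) must be smaller than tau_a "
                             f"({tau_a})")
    if dt > tau_a / 50.0:
        warnings.warn(f"dt = {dt} is coarse relative to tau_a = {tau_a}; "
                      "the Delta-t/tau_a approximation degrades",
                      UserWarning, stacklevel=2)
    rng = _rng(seed)
    p_step = dt / tau_a
    times = train.times
    p_seq = release_prob_sequence(release_model, train)
    k = times.size
    avail = np.zeros(k, dtype=bool)
    rel = np.zeros(k, dtype=bool)
    draws = 0
    last_release = 0.0
    chunk = 512

    def refill_time(t0: float) -> float:
        """Step from t0 until a per-step coin succeeds; count the coins."""
        nonlocal draws
        steps_before = 0
        while True:
            u = rng.random(chunk)
            hits = np.flatnonzero(u < p_step)
            if hits.size:
                n = int(hits[0]) + 1
                draws += n
                return t0 + (steps_before + n) * dt
            draws += chunk
            steps_before += chunk

    next_avail = 0.0 if start_available else refill_time(0.0)
    for i in range(k):
        if times[i] >= next_avail:
            avail[i] = True
            u = rng.random()
            draws += 1
            if u < p_seq[i]:
                rel[i] = True
                last_release = times[i]
                next_avail = refill_time(times[i])
                if stop_after_first_release:
                    break
    return _finish(times, avail, rel, last_release, next_avail, draws,
                   "time_stepped")
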