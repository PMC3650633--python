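"""Efficient multi-trial simulation by binomial thinning.

Z independent trials of a single release site (equivalently, one trial of a
pool of Z independent single-vesicle sites) can be advanced with a handful
of binomial draws per spike instead of Z per-trial simulations:

* for exponential availability times the refill probability at spike i is
  the same ``1 - exp(-(t_i - t_{i-1})/tau_a)`` for every unavailable trial,
  whatever its release history (memorylessness), so ONE binomial draw moves
  the whole unavailable pool — followed by one binomial release draw on the
  available pool (:func:`simulate_binomial_exponential`);
* under AM2 the refill clock is re-anchored at every spike, so the refill
  probability ``F(t_i - t_{i-1})`` is again common to all unavailable
  trials for ANY distribution (:func:`simulate_binomial_am2_general`);
* under AM1 with non-exponential availability the refill probability
  depends on when each trial's vesicle was released, so the unavailable
  pool is partitioned into cohorts by release spike and one binomial draw
  is made per non-empty cohort, with the Bayes conditional probability
  (:func:`simulate_binomial_am1_cohorts`).

:func:`simulate_trials_loop` is the naive per-trial reference against which
all fast paths are validated.  Within a spike, refills are drawn first,
then releases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .distributions import AvailabilityDistribution
from .exceptions import ParameterError
from .release_models import ReleaseModel, release_prob_sequence
from .site_simulators import (simulate_am1, simulate_am2, simulate_incorrect,
                              simulate_time_stepped)
from .spike_trains import SpikeTrain

__all__ = [
    "EnsembleCounts",
    "simulate_binomial_exponential",
    "simulate_binomial_am2_general",
    "simulate_binomial_am1_cohorts",
    "simulate_trials_loop",
]

_COHORT_PRUNE = 1.0 - 1e-12


@dataclass
class EnsembleCounts:
    """Per-spike counts of availability and release across Z trials."""

    n_trials: int
    spike_times: np.ndarray
    n_unavailable_before: np.ndarray
    n_became_available: np.ndarray
    n_released: np.ndarray
    draws_used: int = 0
    method: str = ""
    per_trial_totals: Optional[np.ndarray] = None

    @property
    def n_available_before_decision(self) -> np.ndarray:
        """Trials with an available vesicle at each spike's decision point."""
        return (self.n_trials - self.n_unavailable_before
                + self.n_became_available)

    @property
    def fraction_released(self) -> np.ndarray:
        return self.n_released / self.n_trials

    def check_conservation(self) -> None:
        """Assert the unavailable-pool bookkeeping is conserved spike-to-spike."""
        z = self.n_trials
        unavail = self.n_unavailable_before
        became = self.n_became_available
        rel = self.n_released
        if np.any(became > unavail) or np.any(became < 0):
            raise AssertionError("more refills than unavailable trials")
        s = z - unavail + became
        if np.any(rel < 0) or np.any(rel > s) or np.any(s > z):
            raise AssertionError("release counts exceed the available pool")
        after = unavail - became + rel
        if unavail.size > 1 and not np.array_equal(after[:-1], unavail[1:]):
            raise AssertionError("unavailable-pool bookkeeping is not "
                                 "conserved between spikes")

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({
            "spike_index": np.arange(1, self.spike_times.size + 1),
            "time_s": self.spike_times,
            "n_unavailable_before": self.n_unavailable_before,
            "n_became_available": self.n_became_available,
            "n_released": self.n_released,
            "fraction_released": self.fraction_released,
        })


def _check_trials(n_trials: int) -> int:
    n_trials = int(n_trials)
    if n_trials < 1:
        raise ParameterError(f"n_trials must be >= 1, got {n_trials}")
    return n_trials


def _rng(seed: Union[int, np.random.Generator]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.Generator(np.random.PCG64(seed))


def simulate_binomial_exponential(
    train: SpikeTrain,
    tau_a: float,
    release_model: ReleaseModel,
    n_trials: int,
    seed: Union[int, np.random.Generator],
    start_available: bool = False,
) -> EnsembleCounts:
    """Two binomial draws per spike; exponential availability (AM1 = AM2).

    Refill probability per inter-spike interval is
    ``1 - exp(-(t_i - t_{i-1})/tau_a)`` with t_0 = 0.
    """
    if not tau_a > 0:
        raise ParameterError("tau_a must be positive")
    z = _check_trials(n_trials)
    rng = _rng(seed)
    times = train.times
    p_seq = release_prob_sequence(release_model, train)
    k = times.size
    unavail_before = np.empty(k, dtype=np.int64)
    became = np.empty(k, dtype=np.int64)
    released = np.empty(k, dtype=np.int64)
    unavail = 0 if start_available else z
    t_prev = 0.0
    draws = 0
    for i in range(k):
        pa = -math.expm1(-(times[i] - t_prev) / tau_a)
        unavail_before[i] = unavail
        w = int(rng.binomial(unavail, pa))
        draws += 1
        unavail -= w
        became[i] = w
        u = int(rng.binomial(z - unavail, p_seq[i]))
        draws += 1
        released[i] = u
        unavail += u
        t_prev = times[i]
    out = EnsembleCounts(z, times, unavail_before, became, released,
                         draws_used=draws, method="binomial_exponential")
    out.check_conservation()
    return out


def simulate_binomial_am2_general(
    train: SpikeTrain,
    dist: AvailabilityDistribution,
    release_model: ReleaseModel,
    n_trials: int,
    seed: Union[int, np.random.Generator],
    start_available: bool = False,
) -> EnsembleCounts:
    """Binomial multi-trial AM2 for an arbitrary availability distribution.

    AM2 re-anchors the availability clock at every spike, so the refill
    probability ``F(t_i - t_{i-1})`` is common to all unavailable trials.
    """
    z = _check_trials(n_trials)
    rng = _rng(seed)
    times = train.times
    p_seq = release_prob_sequence(release_model, train)
    k = times.size
    unavail_before = np.empty(k, dtype=np.int64)
    became = np.empty(k, dtype=np.int64)
    released = np.empty(k, dtype=np.int64)
    unavail = 0 if start_available else z
    t_prev = 0.0
    draws = 0
    for i in range(k):
        pa = float(dist.cdf(times[i] - t_prev))
        unavail_before[i] = unavail
        w = int(rng.binomial(unavail, pa))
        draws += 1
        unavail -= w
        became[i] = w
        u = int(rng.binomial(z - unavail, p_seq[i]))
        draws += 1
        released[i] = u
        unavail += u
        t_prev = times[i]
    out = EnsembleCounts(z, times, unavail_before, became, released,
                         draws_used=draws, method="binomial_am2_general")
    out.check_conservation()
    return out


def simulate_binomial_am1_cohorts(
    train: SpikeTrain,
    dist: AvailabilityDistribution,
    release_model: ReleaseModel,
    n_trials: int,
    seed: Union[int, np.random.Generator],
    start_available: bool = False,
) -> EnsembleCounts:
    """Cohort-tracking binomial AM1 for an arbitrary availability distribution.

    The unavailable pool is partitioned by the spike at which each trial's
    vesicle was released.  At every new spike, each cohort anchored at time
    t_j receives one binomial refill draw with the Bayes conditional
    probability ``(F(t_i - t_j) - F(t_{i-1} - t_j)) / (1 - F(t_{i-1} - t_j))``.
    A cohort whose conditional refill probability reaches 1 (to within
    1e-12) is refilled wholesale and pruned.  For exponential availability
    this reduces in distribution to :func:`simulate_binomial_exponential`.
    """
    z = _check_trials(n_trials)
    rng = _rng(seed)
    times = train.times
    p_seq = release_prob_sequence(release_model, train)
    k = times.size
    unavail_before = np.empty(k, dtype=np.int64)
    became = np.empty(k, dtype=np.int64)
    released = np.empty(k, dtype=np.int64)
    # cohorts: anchor (release) time -> trials still unavailable since it
    cohorts = {} if start_available else {0.0: z}
    n_avail = z if start_available else 0
    t_prev = 0.0
    draws = 0
    for i in range(k):
        t = times[i]
        unavail_before[i] = z - n_avail
        w_total = 0
        for anchor in list(cohorts):
            cnt = cohorts[anchor]
            f_prev = float(dist.cdf(t_prev - anchor))
            f_now = float(dist.cdf(t - anchor))
            if f_prev >= _COHORT_PRUNE:
                c = 1.0
            else:
                c = min(max((f_now - f_prev) / (1.0 - f_prev), 0.0), 1.0)
            if c >= _COHORT_PRUNE:
                w = cnt
            else:
                w = int(rng.binomial(cnt, c))
                draws += 1
            if w:
                cohorts[anchor] = cnt - w
                w_total += w
            if cohorts[anchor] == 0:
                del cohorts[anchor]
        n_avail += w_total
        became[i] = w_total
        u = int(rng.binomial(n_avail, p_seq[i]))
        draws += 1
        released[i] = u
        n_avail -= u
        if u:
            cohorts[t] = cohorts.get(t, 0) + u
        t_prev = t
    out = EnsembleCounts(z, times, unavail_before, became, released,
                         draws_used=draws, method="binomial_am1_cohorts")
    out.check_conservation()
    return out


_LOOP_MODELS = ("am1", "am2", "am1_i11", "am1_i12", "am1_i2", "am2_i1",
                "time_stepped")


def simulate_trials_loop(
    train: SpikeTrain,
    dist: Optional[AvailabilityDistribution],
    release_model: ReleaseModel,
    n_trials: int,
    seed: int,
    model: str = "am1",
    am1_variant: str = "resample_at_release",
    tau_a: Optional[float] = None,
    dt: Optional[float] = None,
    start_available: bool = False,
    warn_incorrect: bool = True,
) -> EnsembleCounts:
    """Reference multi-trial path: Z independent single-site simulations.

    Trial ``j`` uses its own RNG stream seeded ``seed + j``, so extending
    the trial count never re-randomises earlier trials.  ``model`` selects
    the single-site simulator: ``"am1"`` (with ``am1_variant``), ``"am2"``,
    an incorrect variant name, or ``"time_stepped"`` (needs ``tau_a``/``dt``).
    Per-trial total release counts are retained for min/max statistics.
    """
    if model not in _LOOP_MODELS:
        raise ParameterError(f"unknown model {model!r}; expected one of "
                             f"{_LOOP_MODELS}")
    z = _check_trials(n_trials)
    seed = int(seed)
    times = train.times
    k = times.size
    unavail_before = np.zeros(k, dtype=np.int64)
    became = np.zeros(k, dtype=np.int64)
    released = np.zeros(k, dtype=np.int64)
    totals = np.empty(z, dtype=np.int64)
    draws = 0

    if model in ("am1_i11", "am1_i12", "am2_i1") and warn_incorrect:
        import warnings
        warnings.warn(f"simulate_trials_loop(model={model!r}) aggregates a "
                      "known-flawed algorithm", UserWarning, stacklevel=2)
    if model == "am1_i2" and warn_incorrect:
        import warnings
        warnings.warn("simulate_trials_loop(model='am1_i2') aggregates a "
                      "known-flawed algorithm", UserWarning, stacklevel=2)

    for j in range(z):
        rng = np.random.Generator(np.random.PCG64(seed + j))
        if model == "am1":
            traj = simulate_am1(train, dist, release_model, rng,
                                variant=am1_variant,
                                start_available=start_available)
        elif model == "am2":
            traj = simulate_am2(train, dist, release_model, rng,
                                start_available=start_available)
        elif model == "time_stepped":
            if tau_a is None or dt is None:
                raise ParameterError("time_stepped needs tau_a and dt")
            traj = simulate_time_stepped(train, tau_a, release_model, dt,
                                         rng, start_available=start_available)
        else:
            traj = simulate_incorrect(train, dist, release_model, rng,
                                      variant=model,
                                      start_available=start_available,
                                      warn=False)
        a = traj.available_before_decision
        r = traj.released
        # availability after each spike; unavailable_before[i] refers to the
        # state just before spike i's refill opportunity
        avail_after = a & ~r
        prev_avail = np.empty(k, dtype=bool)
        prev_avail[0] = start_available
        prev_avail[1:] = avail_after[:-1]
        unavail_before += ~prev_avail
        became += (~prev_avail) & a
        released += r
        totals[j] = int(r.sum())
        draws += traj.draws_used

    out = EnsembleCounts(z, times, unavail_before, became, released,
                         draws_used=draws, method=f"loop:{model}",
                         per_trial_totals=totals)
    # i11/i12/am2_i1 have no coherent availability state; conservation of the
    # implied-availability bookkeeping is only guaranteed for correct models
    # and am1_i2.
    if model in ("am1", "am2", "am1_i2", "time_stepped"):
        out.check_conservation()
    return out
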