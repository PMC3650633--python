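"""Analytic oracles and error/summary statistics.

Every simulator in this package — correct or deliberately flawed — has an
exact analytic counterpart here, so the stochastic implementations can be
validated without external data:

* :func:`analytic_first_release` gives the exact probability that the FIRST
  release after the forced release at t = 0 happens at spike i, for each
  algorithm variant and any availability distribution;
* :func:`analytic_per_spike_release` gives the exact marginal release
  probability at every spike (no stopping) for exponential availability,
  via a renewal decomposition over the last-release spike;
* :func:`error_report` tabulates absolute and relative errors between a
  reference and a test probability surface;
* :func:`release_stats` summarises total releases per trial (mean/min/max).

The first-release law for each variant follows from chaining the per-spike
coin probabilities the algorithm actually uses.  With p_i = P_r|a(t_i) and
F the availability CDF (release anchor at t_0 = 0):

* correct AM1: refill hazard at spike i is the Bayes conditional
  (F(t_i) - F(t_{i-1})) / (1 - F(t_{i-1})); once available, the vesicle
  stays available until released;
* correct AM2: refill hazard F(t_i - t_{i-1}), availability persistent;
* i11/i12 (AM1): release coin p_i * F(t_i - t_s) each spike, no persistent
  availability — first release at i with probability
  prod_{j<i}(1 - p_j F(t_j)) * p_i F(t_i);
* i2 (AM1): persistent availability flag but unconditional refill coin
  F(t_i - t_s);
* i1 (AM2): release coin p_i * F(t_i - t_{i-1}), no persistent state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .distributions import AvailabilityDistribution, make_exponential
from .ensemble import EnsembleCounts
from .exceptions import ParameterError
from .release_models import ReleaseModel, constant_release, \
    release_prob_sequence
from .site_simulators import SiteTrajectory, simulate_am1, simulate_am2, \
    simulate_incorrect, simulate_time_stepped
from .spike_trains import SpikeTrain, periodic_train

__all__ = [
    "FirstReleaseDistribution",
    "ErrorReport",
    "ReleaseStats",
    "ANALYTIC_VARIANTS",
    "analytic_first_release",
    "analytic_per_spike_release",
    "error_report",
    "first_release_error_surface",
    "release_stats",
    "sample_first_release_indices",
    "empirical_first_release",
]

ANALYTIC_VARIANTS = ("am1_correct", "am2_correct", "am1_i11", "am1_i12",
                     "am1_i2", "am2_i1")


@dataclass(frozen=True)
class FirstReleaseDistribution:
    """Exact law of the spike index of the first release (1-based).

    ``probs[i-1]`` is P(first release at spike i); ``residual`` the mass of
    never releasing within the train.  probs.sum() + residual == 1.
    """

    variant: str
    probs: np.ndarray
    residual: float


@dataclass(frozen=True)
class ReleaseStats:
    """Mean/min/max of total vesicles released over the first H spikes."""

    mean: float
    min: int
    max: int
    n_trials: int
    h_spikes: int


@dataclass(frozen=True)
class ErrorReport:
    """Per-(frequency, spike) absolute and relative error surfaces.

    ``rel_error`` is |test - correct| / correct, left as NaN (and flagged
    ``rel_defined == False``) where the reference probability is zero.
    """

    table: pd.DataFrame

    def max_abs_error(self, frequency: Optional[float] = None) -> float:
        t = self._select(frequency)
        return float(t["abs_error"].max())

    def max_rel_error(self, frequency: Optional[float] = None) -> float:
        t = self._select(frequency)
        return float(t.loc[t["rel_defined"], "rel_error"].max())

    def _select(self, frequency):
        if frequency is None:
            return self.table
        sel = self.table[np.isclose(self.table["frequency"], frequency)]
        if sel.empty:
            raise ParameterError(f"frequency {frequency} not in the report")
        return sel


# ---------------------------------------------------------------------------
# exact first-release / next-release recursions
# ---------------------------------------------------------------------------

def _next_release_law(
    variant: str,
    times: np.ndarray,
    p_seq: np.ndarray,
    cdf: Callable[[float], float],
    j: int,
    anchor: float,
) -> np.ndarray:
    """P(next release at spike i | release at ``anchor`` = time of spike j).

    Returns an array g with g[i] for i in j+1..K (1-based spike indices;
    g[:j+1] is zero).  ``j = 0`` with ``anchor = 0.0`` is the initial forced
    release.
    """
    k = times.size
    g = np.zeros(k)
    if variant in ("am1_i11", "am1_i12"):
        surv = 1.0
        for i in range(j, k):
            q = p_seq[i] * float(cdf(times[i] - anchor))
            g[i] = surv * q
            surv *= 1.0 - q
        return g
    if variant == "am2_i1":
        surv = 1.0
        t_prev = anchor
        for i in range(j, k):
            q = p_seq[i] * float(cdf(times[i] - t_prev))
            g[i] = surv * q
            surv *= 1.0 - q
            t_prev = times[i]
        return g
    # state recursion over (unavailable, available-not-released)
    u, a = 1.0, 0.0
    t_prev = anchor
    for i in range(j, k):
        t = times[i]
        if variant == "am1_correct":
            f_prev = float(cdf(t_prev - anchor))
            f_now = float(cdf(t - anchor))
            c = 1.0 if f_prev >= 1.0 else \
                min(max((f_now - f_prev) / (1.0 - f_prev), 0.0), 1.0)
        elif variant == "am2_correct":
            c = float(cdf(t - t_prev))
        elif variant == "am1_i2":
            c = float(cdf(t - anchor))  # the bug: unconditional CDF
        else:
            raise ParameterError(f"unknown variant {variant!r}; expected one "
                                 f"of {ANALYTIC_VARIANTS}")
        avail = a + u * c
        g[i] = avail * p_seq[i]
        a = avail * (1.0 - p_seq[i])
        u = u * (1.0 - c)
        t_prev = t
    return g


def analytic_first_release(
    variant: str,
    train: SpikeTrain,
    dist: AvailabilityDistribution,
    release_model: ReleaseModel,
) -> FirstReleaseDistribution:
    """Exact first-release distribution after the forced release at t = 0.

    Valid for any availability distribution: until the first release there
    is a single release anchor (t = 0), so conditioning on the elapsed time
    since it is exact even under AM1 with non-exponential laws.
    """
    if variant not in ANALYTIC_VARIANTS:
        raise ParameterError(f"unknown variant {variant!r}; expected one of "
                             f"{ANALYTIC_VARIANTS}")
    p_seq = release_prob_sequence(release_model, train)
    probs = _next_release_law(variant, train.times, p_seq, dist.cdf,
                              j=0, anchor=0.0)
    residual = 1.0 - float(probs.sum())
    return FirstReleaseDistribution(variant, probs, residual)


def analytic_per_spike_release(
    variant: str,
    train: SpikeTrain,
    tau_a: float,
    release_model: ReleaseModel,
    start_available: bool = False,
) -> np.ndarray:
    """Exact marginal release probability at every spike (no stopping).

    Exponential availability only: the renewal decomposition over the
    last-release spike relies on the release anchoring the refill clock,
    and for the correct models on memorylessness.  For ``am1_correct`` and
    ``am2_correct`` (identical here) a forward Markov recursion is used,
    equal to the closed-form mean availability times P_r|a; the flawed
    variants use the renewal sum  r_i = sum_j rel_j * g(j -> i)  where
    g is each algorithm's exact next-release law.
    """
    if variant not in ANALYTIC_VARIANTS:
        raise ParameterError(f"unknown variant {variant!r}; expected one of "
                             f"{ANALYTIC_VARIANTS}")
    if not tau_a > 0:
        raise ParameterError("tau_a must be positive")
    times = train.times
    k = times.size
    p_seq = release_prob_sequence(release_model, train)
    dist = make_exponential(tau_a)

    if variant in ("am1_correct", "am2_correct"):
        r = np.empty(k)
        q = 1.0 if start_available else float(dist.cdf(times[0]))
        for i in range(k):
            r[i] = q * p_seq[i]
            a_after = q * (1.0 - p_seq[i])
            if i + 1 < k:
                gap = times[i + 1] - times[i]
                q = 1.0 - (1.0 - a_after) * math.exp(-gap / tau_a)
        return r

    if start_available:
        raise ParameterError("start_available is only supported for the "
                             "correct variants")
    # renewal over the last release epoch; rel[j] = marginal release prob
    r = np.zeros(k)
    g0 = _next_release_law(variant, times, p_seq, dist.cdf, j=0, anchor=0.0)
    r += g0
    for j in range(k):  # release at 0-based spike index j
        if r[j] <= 0.0:
            continue
        g = _next_release_law(variant, times, p_seq, dist.cdf,
                              j=j + 1, anchor=float(times[j]))
        r[j + 1:] += r[j] * g[j + 1:]
    return r


# ---------------------------------------------------------------------------
# error surfaces and summary statistics
# ---------------------------------------------------------------------------

def error_report(
    correct: np.ndarray,
    test: np.ndarray,
    frequencies: Optional[Sequence[float]] = None,
    spike_indices: Optional[Sequence[int]] = None,
) -> ErrorReport:
    """Tabulate |test - correct| and |test - correct| / correct.

    ``correct`` and ``test`` must have identical shape: 1-D (one frequency)
    or 2-D (n_frequencies x n_spikes).  Entries where the reference
    probability is zero have an undefined relative error (NaN, flagged).
    """
    c = np.asarray(correct, dtype=float)
    t = np.asarray(test, dtype=float)
    if c.shape != t.shape:
        raise ParameterError(f"shape mismatch: correct {c.shape} vs test "
                             f"{t.shape}")
    if c.ndim == 1:
        c = c[None, :]
        t = t[None, :]
    n_f, n_i = c.shape
    if frequencies is None:
        frequencies = [math.nan] * n_f
    if spike_indices is None:
        spike_indices = np.arange(1, n_i + 1)
    frequencies = np.asarray(frequencies, dtype=float)
    spike_indices = np.asarray(spike_indices)
    if frequencies.size != n_f or spike_indices.size != n_i:
        raise ParameterError("frequency / spike-index labels do not match "
                             "the error-surface shape")
    abs_err = np.abs(t - c)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_err = np.where(c > 0.0, abs_err / c, np.nan)
    table = pd.DataFrame({
        "frequency": np.repeat(frequencies, n_i),
        "spike_index": np.tile(spike_indices, n_f),
        "correct_prob": c.ravel(),
        "test_prob": t.ravel(),
        "abs_error": abs_err.ravel(),
        "rel_error": rel_err.ravel(),
        "rel_defined": (c > 0.0).ravel(),
    })
    return ErrorReport(table)


def first_release_error_surface(
    test_variant: str,
    ref_variant: str = "am1_correct",
    frequencies: Sequence[float] = tuple(range(5, 151, 5)),
    n_spikes: int = 20,
    tau_a: float = 0.5,
    release_model: Optional[ReleaseModel] = None,
    dist: Optional[AvailabilityDistribution] = None,
) -> ErrorReport:
    """Analytic first-release error surface over periodic-train frequencies.

    Defaults reproduce the standard comparison grid: f in {5, 10, ..., 150}
    Hz, spike indices 1..20, tau_a = 0.5 s, constant P_r|a = 0.6,
    exponential availability.
    """
    if release_model is None:
        release_model = constant_release(0.6)
    if dist is None:
        dist = make_exponential(tau_a)
    ref_rows, test_rows = [], []
    for f in frequencies:
        train = periodic_train(f, n_spikes)
        ref_rows.append(analytic_first_release(ref_variant, train, dist,
                                               release_model).probs)
        test_rows.append(analytic_first_release(test_variant, train, dist,
                                                release_model).probs)
    return error_report(np.vstack(ref_rows), np.vstack(test_rows),
                        frequencies=frequencies,
                        spike_indices=np.arange(1, n_spikes + 1))


def release_stats(
    source: Union[EnsembleCounts, Iterable[SiteTrajectory]],
    h_spikes: Optional[int] = None,
) -> ReleaseStats:
    """Mean/min/max total releases over the first ``h_spikes`` spikes.

    ``source`` is either an :class:`EnsembleCounts` from the per-trial loop
    (which retains per-trial totals over the full train) or an iterable of
    trajectories (any ``h_spikes`` <= train length).
    """
    if isinstance(source, EnsembleCounts):
        if source.per_trial_totals is None:
            raise ParameterError("this EnsembleCounts carries no per-trial "
                                 "totals; use the per-trial loop or pass "
                                 "trajectories")
        k = source.spike_times.size
        if h_spikes is not None and h_spikes != k:
            raise ParameterError("EnsembleCounts totals cover the whole "
                                 f"train (K = {k}); pass trajectories to "
                                 "truncate at an earlier spike")
        totals = source.per_trial_totals
        return ReleaseStats(float(totals.mean()), int(totals.min()),
                            int(totals.max()), source.n_trials, k)
    totals = []
    h = h_spikes
    for traj in source:
        k = traj.released.size
        hh = k if h is None else min(h, k)
        totals.append(int(traj.released[:hh].sum()))
    if not totals:
        raise ParameterError("release_stats needs at least one trial")
    arr = np.asarray(totals)
    return ReleaseStats(float(arr.mean()), int(arr.min()), int(arr.max()),
                        arr.size, hh)


# ---------------------------------------------------------------------------
# simulation-mode cross-validation
# ---------------------------------------------------------------------------

_SIM_MODELS = ("am1", "am2", "am1_i11", "am1_i12", "am1_i2", "am2_i1",
               "time_stepped")


def sample_first_release_indices(
    train: SpikeTrain,
    dist: Optional[AvailabilityDistribution],
    release_model: ReleaseModel,
    n_trials: int,
    seed: int,
    model: str = "am1",
    am1_variant: str = "resample_at_release",
    tau_a: Optional[float] = None,
    dt: Optional[float] = None,
    warn_incorrect: bool = False,
) -> np.ndarray:
    """First-release spike index (1-based; 0 = never) for Z stopped trials.

    Each trial runs its single-site simulator with early stopping at the
    first release, on its own RNG stream seeded ``seed + trial``.
    """
    if model not in _SIM_MODELS:
        raise ParameterError(f"unknown model {model!r}")
    n_trials = int(n_trials)
    if n_trials < 1:
        raise ParameterError("n_trials must be >= 1")
    out = np.empty(n_trials, dtype=np.int64)
    for j in range(n_trials):
        rng = np.random.Generator(np.random.PCG64(int(seed) + j))
        if model == "am1":
            traj = simulate_am1(train, dist, release_model, rng,
                                variant=am1_variant,
                                stop_after_first_release=True)
        elif model == "am2":
            traj = simulate_am2(train, dist, release_model, rng,
                                stop_after_first_release=True)
        elif model == "time_stepped":
            if tau_a is None or dt is None:
                raise ParameterError("time_stepped needs tau_a and dt")
            traj = simulate_time_stepped(train, tau_a, release_model, dt,
                                         rng, stop_after_first_release=True)
        else:
            traj = simulate_incorrect(train, dist, release_model, rng,
                                      variant=model,
                                      stop_after_first_release=True,
                                      warn=warn_incorrect and j == 0)
        out[j] = traj.first_release_index()
    return out


def empirical_first_release(indices: np.ndarray,
                            n_spikes: int) -> FirstReleaseDistribution:
    """Empirical first-release distribution from sampled indices."""
    indices = np.asarray(indices)
    n = indices.size
    if n == 0:
        raise ParameterError("no trials supplied")
    probs = np.bincount(indices[indices > 0], minlength=n_spikes + 1)[1:]
    probs = probs[:n_spikes].astype(float) / n
    residual = float(np.count_nonzero(indices == 0)) / n
    return FirstReleaseDistribution("empirical", probs, residual)
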