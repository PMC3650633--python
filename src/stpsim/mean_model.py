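"""Deterministic mean-field model of the available fraction N_a(t).

The ensemble-average fraction of trials with an available vesicle obeys,
for exponential availability with mean tau_a,

    dN_a/dt = (1 - N_a)/tau_a - N_r|a * N_a(t-) * sum_i delta(t - t_AP,i),

whose closed-form solution is: N_a = 1 before the first spike; a drop by
the factor (1 - N_r|a) at every spike; and exponential recovery toward 1
between spikes.  For a periodic drive at f Hz the pre-spike value converges
to the steady state

    N_ss- = (1 - e^{-1/(f tau_a)}) / (1 - e^{-1/(f tau_a)} (1 - N_r|a)).

This mean model is exact for AM2 generally and for AM1 with exponential
availability times; it does NOT describe AM1 with non-exponential
availability, where the refill hazard depends on each trial's release time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .exceptions import ParameterError
from .spike_trains import SpikeTrain

__all__ = ["MeanTrajectory", "mean_trajectory", "steady_state_availability"]


@dataclass(frozen=True)
class MeanTrajectory:
    """Closed-form mean availability along a spike train.

    ``na_pre[i]`` is N_a(t-_AP,i) just before spike i, ``na_post[i]`` the
    value just after the release drop, and ``release_frac[i]`` the mean
    fraction of trials releasing at spike i (N_r|a,i * N_a(t-)).
    """

    train: SpikeTrain
    tau_a: float
    release_sequence: np.ndarray
    na_pre: np.ndarray
    na_post: np.ndarray
    release_frac: np.ndarray
    initial_availability: float = 1.0

    def availability(self, t):
        """Evaluate N_a(t) at arbitrary times (post-drop at spike instants)."""
        t = np.asarray(t, dtype=float)
        times = self.train.times
        idx = np.searchsorted(times, t, side="right")  # spikes at or before t
        na = np.where(idx == 0, self.initial_availability,
                      self.na_post[np.maximum(idx - 1, 0)])
        t_anchor = np.where(idx == 0, 0.0, times[np.maximum(idx - 1, 0)])
        out = 1.0 - (1.0 - na) * np.exp(-(t - t_anchor) / self.tau_a)
        if self.initial_availability == 1.0:
            out = np.where(idx == 0, 1.0, out)
        return out if out.ndim else float(out)

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({
            "spike_index": np.arange(1, self.train.count + 1),
            "time_s": self.train.times,
            "Na_pre": self.na_pre,
            "Na_post": self.na_post,
            "mean_release_frac": self.release_frac,
        })


def mean_trajectory(
    train: SpikeTrain,
    tau_a: float,
    n_release_frac: float,
    release_sequence: Optional[Sequence[float]] = None,
    initial_availability: float = 1.0,
) -> MeanTrajectory:
    """Exact closed-form mean availability along ``train``.

    ``n_release_frac`` is the constant mean released fraction N_r|a; a
    per-spike ``release_sequence`` (e.g. a facilitation P_r|a sequence)
    overrides it spike-by-spike when given.  ``initial_availability`` is
    N_a(0): 1 (the default, matching the closed form, where N_a(t) = 1 for
    all t before the first spike) or 0 for an ensemble that starts from a
    forced release at t = 0.
    """
    if not tau_a > 0:
        raise ParameterError("tau_a must be positive")
    if not (0.0 <= n_release_frac <= 1.0):
        raise ParameterError("n_release_frac must lie in [0, 1]")
    times = train.times
    k = times.size
    if release_sequence is None:
        rel_seq = np.full(k, float(n_release_frac))
    else:
        rel_seq = np.asarray(release_sequence, dtype=float)
        if rel_seq.shape != (k,):
            raise ParameterError("release_sequence must have one entry per "
                                 "spike")
        if np.any((rel_seq < 0) | (rel_seq > 1)):
            raise ParameterError("release_sequence entries must lie in [0,1]")
    if not (0.0 <= initial_availability <= 1.0):
        raise ParameterError("initial_availability must lie in [0, 1]")
    na_pre = np.empty(k)
    na_post = np.empty(k)
    na = float(initial_availability)
    t_prev = 0.0 if initial_availability < 1.0 else None
    for i in range(k):
        if t_prev is not None:
            na = 1.0 - (1.0 - na) * math.exp(-(times[i] - t_prev) / tau_a)
        na_pre[i] = na
        na = (1.0 - rel_seq[i]) * na
        na_post[i] = na
        t_prev = times[i]
    return MeanTrajectory(train, float(tau_a), rel_seq, na_pre, na_post,
                          rel_seq * na_pre,
                          initial_availability=float(initial_availability))


def steady_state_availability(frequency: float, tau_a: float,
                              n_release_frac: float) -> float:
    """Pre-spike steady-state available fraction under periodic drive."""
    if not frequency > 0:
        raise ParameterError("frequency must be positive")
    if not tau_a > 0:
        raise ParameterError("tau_a must be positive")
    if not (0.0 <= n_release_frac <= 1.0):
        raise ParameterError("n_release_frac must lie in [0, 1]")
    x = math.exp(-1.0 / (frequency * tau_a))
    return (1.0 - x) / (1.0 - x * (1.0 - n_release_frac))
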