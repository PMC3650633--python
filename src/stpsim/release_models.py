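"""Release probability given availability, P_r|a(t).

Two release models are supported:

* **constant** — an available vesicle is released with a fixed probability
  P_r|a on every AP arrival (classical probabilistic release);
* **facilitation** — P_r|a(t) rests at Q, jumps by a fraction S of the
  remaining headroom at every AP, ``P -> P + S (1 - P)``, and decays
  exponentially back to Q with time constant tau_f between APs.

A facilitation-style **depression** variant (release-independent depression
with a static recovery time constant) is also provided: at each AP the
probability steps down by a fraction D of its distance to a floor,
``P -> P - D (P - floor)``, and relaxes back to Q between APs.

P_r|a(t) depends only on the AP times, never on availability or release
outcomes, so the per-spike sequence can be precomputed once per train and
shared across all trials.

Jump convention: the piecewise law assigns the jumped value AT the spike
time, which leaves open whether the spike that causes the jump is itself
decided with the jumped probability.  By default the release decision at
spike i uses the PRE-jump value (an isolated spike then releases with
probability Q, consistent with Q being the rest/steady-state probability);
set ``jump_applies_to_current_spike=True`` for the alternative convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import ParameterError
from .spike_trains import SpikeTrain

__all__ = [
    "ReleaseModel",
    "constant_release",
    "facilitation_release",
    "depression_release",
    "release_prob_sequence",
]


def _check_prob(name: str, value: float) -> float:
    value = float(value)
    if not (0.0 <= value <= 1.0):
        raise ParameterError(f"{name} must lie in [0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class ReleaseModel:
    """Time-varying release probability given availability.

    ``kind`` is one of ``"constant"``, ``"facilitation"``, ``"depression"``.
    For the constant model only ``p_const`` is meaningful; the dynamic kinds
    use the rest probability ``rest_prob`` (Q), the jump fraction
    ``increment`` (S, facilitation) or ``decrement`` (D, depression), the
    recovery time constant ``tau_f`` (s) and, for depression, ``floor``.
    """

    kind: str
    p_const: float = 0.0
    rest_prob: float = 0.0
    increment: float = 0.0
    decrement: float = 0.0
    tau_f: float = 1.0
    floor: float = 0.0
    jump_applies_to_current_spike: bool = False


def constant_release(p: float) -> ReleaseModel:
    """Release Model 1: constant P_r|a = p."""
    return ReleaseModel(kind="constant", p_const=_check_prob("p", p))


def facilitation_release(rest_prob: float, increment: float, tau_f: float,
                         jump_applies_to_current_spike: bool = False
                         ) -> ReleaseModel:
    """Release Model 2 (facilitation): rest Q, jump fraction S, decay tau_f."""
    q = _check_prob("rest_prob (Q)", rest_prob)
    s = _check_prob("increment (S)", increment)
    if not tau_f > 0:
        raise ParameterError(f"tau_f must be positive, got {tau_f!r}")
    return ReleaseModel(kind="facilitation", rest_prob=q, increment=s,
                        tau_f=float(tau_f),
                        jump_applies_to_current_spike=bool(
                            jump_applies_to_current_spike))


def depression_release(rest_prob: float, decrement: float, tau_f: float,
                       floor: float = 0.0,
                       jump_applies_to_current_spike: bool = False
                       ) -> ReleaseModel:
    """Release-independent depression with static recovery constant tau_f."""
    q = _check_prob("rest_prob (Q)", rest_prob)
    d = _check_prob("decrement (D)", decrement)
    fl = _check_prob("floor", floor)
    if fl > q:
        raise ParameterError("floor must not exceed the rest probability")
    if not tau_f > 0:
        raise ParameterError(f"tau_f must be positive, got {tau_f!r}")
    return ReleaseModel(kind="depression", rest_prob=q, decrement=d,
                        tau_f=float(tau_f), floor=fl,
                        jump_applies_to_current_spike=bool(
                            jump_applies_to_current_spike))


def release_prob_sequence(model: ReleaseModel,
                          train: SpikeTrain) -> np.ndarray:
    """P_r|a evaluated at each spike of ``train``.

    Returns the probability actually used for the release decision at each
    spike: the pre-jump value by default, the post-jump value when the model
    was built with ``jump_applies_to_current_spike=True``.  Deterministic
    given the train — independent of availability and release outcomes.
    """
    times = train.times
    k = times.size
    if model.kind == "constant":
        return np.full(k, model.p_const)
    if model.kind not in ("facilitation", "depression"):
        raise ParameterError(f"unknown release model kind {model.kind!r}")

    q = model.rest_prob
    out = np.empty(k)
    post_prev = q       # value holding before the first spike
    t_prev = 0.0
    for i in range(k):
        decay = math.exp(-(times[i] - t_prev) / model.tau_f)
        pre = q + (post_prev - q) * decay
        if model.kind == "facilitation":
            post = pre + model.increment * (1.0 - pre)
        else:
            post = pre - model.decrement * (pre - model.floor)
        out[i] = post if model.jump_applies_to_current_spike else pre
        post_prev = post
        t_prev = times[i]
    # The update maps [0,1] into [0,1]; clip only round-off.
    return np.clip(out, 0.0, 1.0)


def release_prob_at(model: ReleaseModel, train: SpikeTrain,
                    t: float) -> float:
    """P_r|a(t) at an arbitrary time (post-jump at spike instants)."""
    if model.kind == "constant":
        return model.p_const
    times = train.times
    q = model.rest_prob
    post_prev, t_prev = q, 0.0
    for ti in times:
        if ti > t:
            break
        pre = q + (post_prev - q) * math.exp(-(ti - t_prev) / model.tau_f)
        if model.kind == "facilitation":
            post_prev = pre + model.increment * (1.0 - pre)
        else:
            post_prev = pre - model.decrement * (pre - model.floor)
        t_prev = ti
    return q + (post_prev - q) * math.exp(-(t - t_prev) / model.tau_f)
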