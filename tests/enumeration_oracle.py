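"""Brute-force first-release oracle: exhaustive outcome-branch enumeration.

Independent of the package's survival-product / state recursions: each
algorithm's literal coin tree is walked branch by branch with exact
per-branch probabilities, stopping at the first release.  Feasible for
K <= ~10 spikes; used as the small-instance correctness anchor.
"""

from __future__ import annotations

import numpy as np

VARIANTS = ("am1_correct", "am2_correct", "am1_i11", "am1_i12", "am1_i2",
            "am2_i1")


def enumerate_first_release(variant, times, cdf, p_seq):
    """Exact P(first release at spike i) by exhaustive branching.

    Returns ``(probs, residual)``.  ``times`` are spike times (release
    anchor at t=0), ``cdf`` the availability CDF, ``p_seq`` the per-spike
    release probabilities.
    """
    times = np.asarray(times, dtype=float)
    p_seq = np.asarray(p_seq, dtype=float)
    k = times.size
    probs = np.zeros(k)

    if variant == "am1_correct":
        # Branch over the interval (t_{j-1}, t_j] in which the single
        # availability time T_a falls, then over the release coins.
        f = np.array([float(cdf(t)) for t in times])
        f_prev = np.concatenate([[0.0], f[:-1]])
        for j in range(k):
            w = f[j] - f_prev[j]          # T_a lands in interval j
            surv = w
            for i in range(j, k):
                probs[i] += surv * p_seq[i]
                surv *= 1.0 - p_seq[i]
        return probs, 1.0 - probs.sum()

    if variant in ("am1_i11", "am1_i12"):
        # One effective coin per spike: release with p_i * F(t_i).
        def release_coin(i):
            return p_seq[i] * float(cdf(times[i]))
    elif variant == "am2_i1":
        def release_coin(i):
            prev = times[i - 1] if i else 0.0
            return p_seq[i] * float(cdf(times[i] - prev))
    else:
        release_coin = None

    if release_coin is not None:
        def rec(i, weight):
            if i == k:
                return
            q = release_coin(i)
            probs[i] += weight * q
            rec(i + 1, weight * (1.0 - q))
        rec(0, 1.0)
        return probs, 1.0 - probs.sum()

    # stateful variants: explicit (spike, available?) branching
    if variant == "am2_correct":
        def refill_coin(i):
            prev = times[i - 1] if i else 0.0
            return float(cdf(times[i] - prev))
    elif variant == "am1_i2":
        def refill_coin(i):
            return float(cdf(times[i]))  # flawed: unconditional CDF
    else:
        raise ValueError(f"unknown variant {variant!r}")

    def rec(i, available, weight):
        if i == k:
            return
        if not available:
            c = refill_coin(i)
            if c > 0.0:
                decide(i, weight * c)
            rec(i + 1, False, weight * (1.0 - c))
        else:
            decide(i, weight)

    def decide(i, weight):
        probs[i] += weight * p_seq[i]
        rec(i + 1, True, weight * (1.0 - p_seq[i]))

    rec(0, False, 1.0)
    return probs, 1.0 - probs.sum()
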