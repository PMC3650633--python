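"""Pre-synaptic spike trains: generation and plain-text I/O.

A :class:`SpikeTrain` is a strictly increasing sequence of action-potential
(AP) times in seconds.  Time 0 is reserved for the initial forced release
that starts every simulation, so all AP times must be strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from .exceptions import FormatError, ParameterError

__all__ = [
    "SpikeTrain",
    "periodic_train",
    "poisson_train",
    "poisson_train_duration",
    "read_train",
    "write_train",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered pre-synaptic AP times t_AP,i (seconds), i = 1..K."""

    times: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size < 1:
            raise ParameterError("a spike train needs at least one AP time")
        if not np.all(t > 0.0):
            raise ParameterError("AP times must be strictly positive "
                                 "(t = 0 is the initial forced release)")
        if not np.all(np.diff(t) > 0.0):
            raise ParameterError("AP times must be strictly increasing")
        object.__setattr__(self, "times", t)

    @property
    def count(self) -> int:
        return int(self.times.size)

    @property
    def intervals(self) -> np.ndarray:
        """Inter-spike intervals including the leading interval from t = 0."""
        return np.diff(self.times, prepend=0.0)

    def __len__(self) -> int:  # convenience
        return self.count


def periodic_train(frequency: float, count: int) -> SpikeTrain:
    """Periodic train t_i = i / frequency, i = 1..count."""
    if not frequency > 0:
        raise ParameterError(f"frequency must be positive, got {frequency!r}")
    count = int(count)
    if count < 1:
        raise ParameterError(f"count must be >= 1, got {count!r}")
    return SpikeTrain(np.arange(1, count + 1, dtype=float) / float(frequency))


def poisson_train(rate: float, count: int, seed: int) -> SpikeTrain:
    """Homogeneous-Poisson train with exactly ``count`` spikes.

    Times are cumulative sums of i.i.d. exponential inter-arrival times with
    mean 1/rate; reproducible for a fixed ``seed``.
    """
    if not rate > 0:
        raise ParameterError(f"rate must be positive, got {rate!r}")
    count = int(count)
    if count < 1:
        raise ParameterError(f"count must be >= 1, got {count!r}")
    rng = np.random.Generator(np.random.PCG64(seed))
    gaps = rng.exponential(1.0 / rate, size=count)
    return SpikeTrain(np.cumsum(gaps))


def poisson_train_duration(rate: float, duration: float,
                           seed: int) -> SpikeTrain:
    """Homogeneous-Poisson train on (0, duration]; convenience generator."""
    if not rate > 0 or not duration > 0:
        raise ParameterError("rate and duration must be positive")
    rng = np.random.Generator(np.random.PCG64(seed))
    times = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / rate)
        if t > duration:
            break
        times.append(t)
    if not times:
        raise ParameterError("no spikes fell within the requested duration; "
                             "increase rate or duration")
    return SpikeTrain(np.asarray(times))


def write_train(train: SpikeTrain, path: Union[str, Path]) -> None:
    """Write one AP time per line, full double precision, seconds."""
    path = Path(path)
    with path.open("w") as fh:
        for t in train.times:
            fh.write(f"{float(t)!r}\n")


def read_train(path: Union[str, Path]) -> SpikeTrain:
    """Read a spike-time file.

    Accepts plain text with one time per line, or a single-column CSV whose
    header is ``time_s``.  Ordering and positivity are validated; the error
    message names the offending line.
    """
    path = Path(path)
    times = []
    with path.open() as fh:
        lines = [ln.strip() for ln in fh]
    start = 0
    if lines and lines[0].lower() == "time_s":
        start = 1
    for lineno, raw in enumerate(lines[start:], start=start + 1):
        if not raw:
            continue
        try:
            value = float(raw)
        except ValueError as exc:
            raise FormatError(
                f"{path}:{lineno}: not a spike time: {raw!r}") from exc
        if value <= 0.0:
            raise FormatError(
                f"{path}:{lineno}: spike times must be > 0, got {value}")
        if times and value <= times[-1]:
            raise FormatError(
                f"{path}:{lineno}: spike times must be strictly increasing "
                f"({value} after {times[-1]})")
        times.append(value)
    if not times:
        raise FormatError(f"{path}: empty spike-time file "
                          "(at least one spike required)")
    return SpikeTrain(np.asarray(times))
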