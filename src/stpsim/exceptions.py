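"""Exception types used across the package."""


class ParameterError(ValueError):
    """A model or run parameter is outside its valid range."""


class DegenerateConditioningError(ParameterError):
    """Conditioning on an event of probability zero (CDF already 1 at the
    earlier observation time)."""


class FormatError(ValueError):
    """A file being read does not satisfy the expected on-disk format."""


class TrajectoryInvariantError(AssertionError):
    """A simulated trajectory violates the single-vesicle state-machine
    contract (release without availability, or availability lost without a
    release)."""
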