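"""Exception hierarchy for ramplab."""


class RampLabError(Exception):
    """Base class for all ramplab errors."""


class SchemaError(RampLabError):
    """A tabular input is missing required columns or has a malformed layout."""


class ValidationError(RampLabError):
    """A record violates a domain invariant (e.g. non-ascending spike times)."""


class MetricError(RampLabError):
    """A waveform does not support the requested shape metric."""


class DegenerateUnitError(RampLabError):
    """A simulated unit's intensity function is zero everywhere."""


class DegenerateDataError(RampLabError):
    """A statistic is undefined on the given data (e.g. all paired differences zero)."""


class InsufficientDataError(RampLabError):
    """Too few trials/observations for the requested fit."""
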