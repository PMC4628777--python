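"""Exception hierarchy for the ocupulse pipeline."""


class OcupulseError(Exception):
    """Base class for all ocupulse errors."""


class ConfigurationError(OcupulseError):
    """An option, method name, zone or band definition is invalid."""


class MetadataError(OcupulseError):
    """Acquisition metadata (sidecar) is missing or invalid."""


class DimensionMismatchError(OcupulseError):
    """Frames in a sequence do not share identical dimensions."""


class BoundaryCrossingError(OcupulseError):
    """Displaced cornea/iris boundaries would cross (invalid motion)."""


class NoReliableRangeError(OcupulseError):
    """No contiguous column run is valid for both surfaces in all frames."""


class OrderingViolationError(OcupulseError):
    """Traced iris not strictly below cornea: non-positive gap depth."""


class InternalConsistencyError(OcupulseError):
    """A contract between pipeline stages was broken (internal bug)."""


class ContractError(OcupulseError):
    """An operation precondition on the data was violated (e.g. not detrended)."""
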