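"""Exception types raised by the analysis pipeline."""


class SwimrespError(ValueError):
    """Base class for all pipeline errors."""


class InvalidConfigError(SwimrespError):
    """A configuration or distribution parameter is out of its valid range."""


class TraceError(SwimrespError):
    """A trace violates sampling or bounds requirements."""


class InsufficientDataError(SwimrespError):
    """Too few samples or points to perform the requested fit."""


class ProtocolError(SwimrespError):
    """The trial record is incomplete with respect to the test protocol."""


class LeakError(SwimrespError):
    """PO2 rose during a closed phase beyond noise tolerance (leak or flush
    contamination)."""


class FishTooLargeError(SwimrespError):
    """Fish cross-section meets or exceeds the tunnel cross-section."""


class ProbeError(SwimrespError):
    """Flow signal is physically implausible (e.g. negative mean flow)."""


class DomainError(SwimrespError):
    """Input outside the physical domain of a formula."""
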