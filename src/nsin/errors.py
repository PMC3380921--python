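"""Exception hierarchy shared across the package."""


class NsinError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NsinError, ValueError):
    """A network or table file could not be parsed."""


class ConsistencyError(NsinError, ValueError):
    """Input is parseable but internally contradictory (e.g. conflicting edge signs)."""


class NetworkLookupError(NsinError, KeyError):
    """A referenced node or edge does not exist in the network."""


class ValidationError(NsinError, ValueError):
    """A configuration violates its invariants; message lists every failure."""


class DegenerateDataError(NsinError, ValueError):
    """Statistical input carries no information (zero variance, all-zero differences)."""


class JoinError(NsinError, ValueError):
    """Two tables share no keys to be joined on."""
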