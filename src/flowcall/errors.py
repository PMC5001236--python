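"""Exception hierarchy shared across the package."""


class FlowcallError(Exception):
    """Base class for all package-specific errors."""


class InputError(FlowcallError, ValueError):
    """Malformed or out-of-contract input (bad row, bad position, bad rate)."""


class FitError(FlowcallError, ValueError):
    """Prior fitting cannot proceed (e.g. no labeled candidates)."""


class FormatError(FlowcallError, ValueError):
    """A serialized artifact violates its schema."""


class ModelCoverageError(FlowcallError, KeyError):
    """The prior set has no parameters for a requested (nucleotide, zone)."""


class JoinError(FlowcallError, ValueError):
    """Calls and ground-truth records do not join one-to-one."""


class ConsistencyError(FlowcallError, ValueError):
    """Internally inconsistent artifacts (e.g. a call for a nonexistent run)."""
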