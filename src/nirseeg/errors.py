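"""Exception hierarchy used across the package.

Every stage raises a named subclass of :class:`NirseegError` so that the CLI
can map failures to diagnostics without string matching.
"""


class NirseegError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(NirseegError, ValueError):
    """A caller-supplied argument violates a precondition."""


class DataError(NirseegError):
    """Input data violate a contract (bad values, out-of-range windows)."""


class ConfigurationError(NirseegError):
    """An optics/analysis configuration is unusable (e.g. singular extinction)."""


class DegenerateModelError(NirseegError):
    """A classifier cannot be fitted (e.g. all feature vectors identical)."""


class StateError(NirseegError):
    """A stage was invoked before its prerequisites (e.g. missing baselines)."""


class ScheduleError(DataError):
    """An event schedule violates the block-design invariants."""


class BundleError(NirseegError):
    """Base class for recording-bundle I/O problems."""


class MissingFileError(BundleError):
    """A file referenced by a bundle manifest does not exist."""


class MalformedHeaderError(BundleError):
    """A CSV/TSV file does not carry the expected header columns."""


class ChannelCountError(BundleError):
    """A bundle declares or contains the wrong number of channels."""
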