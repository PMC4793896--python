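"""Exception hierarchy.

All package errors derive from :class:`MirnormError` so callers can catch one
type at the pipeline boundary; the subclasses mirror the failure surface of a
qPCR analysis run (malformed files, inconsistent metadata, bad configuration,
data that cannot support the requested computation).
"""


class MirnormError(Exception):
    """Base class for all mirnorm errors."""


class FormatError(MirnormError):
    """A file violates the expected tabular format."""


class ConsistencyError(MirnormError):
    """Companion tables disagree (e.g. a sample has no annotation)."""


class ConfigError(MirnormError):
    """The run configuration is invalid or incomplete."""


class DataError(MirnormError):
    """The data cannot support the requested computation."""


class InputError(MirnormError):
    """A function received arguments violating its contract."""


class SelectionError(MirnormError):
    """Not enough admissible candidates to select the requested references."""
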