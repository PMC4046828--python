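"""Exception hierarchy shared across the pipeline.

Input problems (bad files, malformed tags, impossible configurations) raise
:class:`InputError`; violations of internal contracts between pipeline stages
raise :class:`ConsistencyError`.  The CLI maps these to exit codes 2 and 3.
"""


class TagDGEError(Exception):
    """Base class for all package errors."""


class InputError(TagDGEError):
    """Invalid user input: files, parameters, malformed records."""

    exit_code = 2


class ConfigError(InputError):
    """Impossible or inconsistent configuration values."""


class UndefinedValueError(InputError):
    """A requested statistic is undefined (e.g. a zero denominator)."""


class ConsistencyError(TagDGEError):
    """Internal contract between pipeline stages was violated."""

    exit_code = 3
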