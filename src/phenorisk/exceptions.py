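"""Exception hierarchy.

All package errors derive from :class:`PhenoriskError` so callers can catch
one base class; validation and schema problems additionally derive from
``ValueError`` to behave naturally in generic code.
"""


class PhenoriskError(Exception):
    """Base class for all phenorisk errors."""


class SchemaError(PhenoriskError, ValueError):
    """An input table is missing required columns or is otherwise malformed."""


class ValidationError(PhenoriskError, ValueError):
    """Rows of an input table violate the documented contract.

    The message names the offending rows (1-based file line numbers,
    counting the header as line 1) whenever they are known.
    """


class ConfigError(PhenoriskError, ValueError):
    """A run configuration is inconsistent or references missing inputs."""
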