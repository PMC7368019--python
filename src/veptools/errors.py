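"""Exception hierarchy.

Configuration problems (bad parameter values, violated invariants) and data
problems (malformed files, missing channels) are kept distinct so the CLI can
map them to distinct exit codes.
"""


class VeptoolsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(VeptoolsError, ValueError):
    """A configuration value violates a documented invariant."""


class DataError(VeptoolsError, ValueError):
    """Input data is malformed, incomplete or inconsistent."""
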