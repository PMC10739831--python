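"""Exception hierarchy shared across the package.

Two broad classes matter to callers (and to the CLI's exit codes):
configuration/validation problems, and problems with the data itself.
"""


class ProbeAuditError(Exception):
    """Base class for all errors raised by probeaudit."""


class ValidationError(ProbeAuditError):
    """Bad configuration, arguments, or preconditions (CLI exit code 2)."""


class DataError(ProbeAuditError):
    """Malformed or inconsistent input data (CLI exit code 3)."""
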