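"""Exception hierarchy shared by all medax modules."""


class MedaxError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MedaxError):
    """A configuration problem: missing column mapping, bad threshold, etc."""


class ValidationError(MedaxError):
    """Input data violates a documented precondition or invariant."""
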