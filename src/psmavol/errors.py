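"""Exception hierarchy.

All package errors derive from :class:`PsmavolError` so callers can catch
one base class; the three leaves distinguish bad user input, inconsistent
configuration, and statistically degenerate models.
"""


class PsmavolError(Exception):
    """Base class for all errors raised by psmavol."""


class InputError(PsmavolError, ValueError):
    """A data input violates a precondition (wrong shape, empty mask, ...)."""


class ConfigurationError(PsmavolError, ValueError):
    """A spec/config object is internally inconsistent."""


class DegenerateModelError(PsmavolError, ValueError):
    """A statistical model cannot be fit (no events, constant covariate, ...)."""
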