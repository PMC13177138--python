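"""Exception hierarchy shared by all oildrop engines.

Every error raised by the library derives from :class:`OilDropError`, so
callers (including the CLI) can catch one base class and map it to a
diagnostic instead of a traceback.
"""


class OilDropError(Exception):
    """Base class for all oildrop errors."""


class InputError(OilDropError):
    """Invalid user-supplied value (bad chain, out-of-range parameter, ...)."""


class FormatError(OilDropError):
    """Unparseable or unrecognised input file."""


class GeometryError(OilDropError):
    """Degenerate point geometry (collinear, zero extent, identical points)."""


class ComputationError(OilDropError):
    """A numerical precondition failed at run time (no contacts, constant profile)."""


class ConfigError(OilDropError):
    """Inconsistent feedback-network configuration."""


class InfeasibleError(OilDropError):
    """No (p, k) plan can reach the requested target under the given cap."""
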