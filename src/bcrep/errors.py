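"""Exception hierarchy shared across the package."""


class BcrepError(Exception):
    """Base class for all package-specific errors."""


class GermlineError(BcrepError):
    """Invalid or inconsistent germline reference (duplicate names, bad anchors...)."""


class SimulationError(BcrepError):
    """Repertoire simulation could not proceed (e.g. productive rearrangement unreachable)."""


class FormatError(BcrepError):
    """A tabular input does not conform to the expected columns/format."""


class DialectError(FormatError):
    """External clonotype file matches none of the supported dialects."""
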