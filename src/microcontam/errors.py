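"""Exception hierarchy shared across the pipeline."""


class MicrocontamError(Exception):
    """Base class for all package errors."""


class ConfigError(MicrocontamError):
    """Infeasible or invalid configuration."""


class InputError(MicrocontamError):
    """Malformed or degenerate user input."""


class FormatError(InputError):
    """On-disk format inconsistency (dimension mismatches etc.)."""


class MarkerSelectionError(MicrocontamError):
    """Fewer usable marker genes than requested."""


class ReferenceError_(MicrocontamError):
    """Reference dataset lacks a required group or is degenerate."""


class DegenerateReferenceError(ReferenceError_):
    """Contaminant reference median does not exceed the neuronal median."""


class FitError(MicrocontamError):
    """Model fitting failed or a non-converged fit was used downstream."""
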