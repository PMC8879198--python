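"""Exception hierarchy shared across the toolkit."""


class EmfitError(Exception):
    """Base class for all toolkit errors."""


class EmptyModelError(EmfitError):
    """A structure file or model contained no usable atoms."""


class FormatError(EmfitError):
    """Malformed or unsupported input (PDB/MRC/FASTA/table)."""


class FormatOverflowError(FormatError):
    """A value does not fit the fixed-column field width of the format."""


class DegenerateInputError(EmfitError):
    """Input is mathematically degenerate for the requested operation
    (zero-variance column, all-zero map, collinear point set, ...)."""


class GridError(EmfitError):
    """Density-map grids are incompatible (geometry/spacing mismatch,
    out-of-bounds crop box, empty segmentation zone)."""


class ConfigError(EmfitError):
    """Invalid configuration value."""


class SearchFailureError(EmfitError):
    """A docking or fitting search produced no usable candidate."""
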