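"""Exception types shared across the package."""


class AlncompareError(Exception):
    """Base class for all package-specific errors."""


class SamParseError(AlncompareError):
    """A SAM/BAM record could not be interpreted (malformed CIGAR, etc.)."""


class SortOrderError(AlncompareError):
    """Input file is not grouped by read name.

    Raised when records for a read name reappear after records for a
    different name have been seen: single-pass grouping would then split
    the read across groups, so the comparison would be wrong.
    """


class UndefinedMetricError(AlncompareError):
    """A metric's denominator is zero, so the ratio is undefined."""


class GeometryError(AlncompareError):
    """Requested synthetic-alignment geometry does not fit the reference."""
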