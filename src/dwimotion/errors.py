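"""Exception hierarchy shared across the package.

All errors derive from :class:`DwiMotionError` so callers can catch the
package's failures with a single except clause; format vs. validation vs.
degenerate-input failures stay distinguishable for the CLI's exit codes.
"""


class DwiMotionError(Exception):
    """Base class for all dwimotion errors."""


class FormatError(DwiMotionError, ValueError):
    """A file does not conform to its expected text format (bad token
    counts, non-numeric fields, ragged rows, missing columns)."""


class ValidationError(DwiMotionError, ValueError):
    """Well-formed input that violates a semantic contract (negative RMS,
    row-count mismatch, duplicate keys, empty samples, rank-deficient
    designs)."""


class DegenerateInputError(DwiMotionError, ValueError):
    """Input on which the requested statistic is undefined (e.g. all
    paired differences exactly zero)."""
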