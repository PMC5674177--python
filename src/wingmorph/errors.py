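"""Exception hierarchy for wingmorph.

All package-specific failures derive from :class:`WingmorphError` so callers
(and the CLI) can distinguish analysis errors from programming errors.
"""


class WingmorphError(Exception):
    """Base class for all wingmorph errors."""


class TPSParseError(WingmorphError):
    """A TPS file violates the record contract (e.g. short coordinate block)."""


class SchemeError(WingmorphError):
    """Landmark schemes are inconsistent (different k, or unsupported 3-D records)."""


class ValidationError(WingmorphError):
    """A dataset or configuration violates a structural invariant."""


class DegenerateShapeError(WingmorphError):
    """A configuration has zero centroid size or coincident landmarks."""


class SingularCovarianceError(WingmorphError):
    """The pooled within-group covariance is not positive definite."""
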