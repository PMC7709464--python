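"""Exception hierarchy.

All errors raised by this package derive from :class:`BiotransparencyError`
so callers can catch everything from one place; the subclasses mirror the
distinct failure modes of the pipeline (bad inputs, bad files, degenerate
optics, impossible joins).
"""


class BiotransparencyError(Exception):
    """Base class for all package errors."""


class ValidationError(BiotransparencyError, ValueError):
    """A domain object violates one of its invariants."""


class FormatError(BiotransparencyError, ValueError):
    """A file on disk does not conform to the expected dialect."""


class BandRangeError(BiotransparencyError, ValueError):
    """A wavelength or band does not overlap the sampled grid."""


class CoverageError(BiotransparencyError, ValueError):
    """Egg regions plus guard margins cover the entire field of view."""


class DegenerateBackgroundError(BiotransparencyError, ValueError):
    """The background spectrum is nonpositive in at least one band."""


class DegenerateSpectrumError(BiotransparencyError, ValueError):
    """A transmittance/attenuation spectrum has no usable bands."""


class SceneError(BiotransparencyError, ValueError):
    """A synthetic scene specification is geometrically inconsistent."""


class TreeJoinError(BiotransparencyError, ValueError):
    """No tree tip could be matched to any trait-table species."""
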