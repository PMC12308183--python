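"""Exception hierarchy.

All errors raised by this package derive from :class:`RepeatGeomError` so
callers can catch everything with one clause while the pipeline can still
distinguish per-pair geometric degeneracies (recoverable, row flagged) from
input problems (fatal for the region).
"""


class RepeatGeomError(Exception):
    """Base class for all repeatgeom errors."""


class StructureParseError(RepeatGeomError):
    """Structure file could not be read or contains no usable records."""


class RegionValidationError(RepeatGeomError):
    """A repeat-region annotation violates the region invariants."""


class RegionResolutionError(RepeatGeomError):
    """A valid region does not resolve against the given structure."""


class UnitTooShortError(RegionResolutionError):
    """A repeat unit resolves to fewer Calpha atoms than superposition needs."""


class DegenerateGeometryError(RepeatGeomError):
    """Geometric construction is undefined for this input.

    Examples: identical centroids, zero-length radius vector, travel vector
    parallel to the pitch axis.  The pipeline catches this per unit pair and
    emits a flagged null row instead of aborting the region.
    """
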