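"""Exception hierarchy.

Everything raised on bad scientific input derives from :class:`DomainError`
(a ``ValueError``), so callers can catch one type for precondition
violations while I/O and schema problems stay distinguishable.
"""


class CapsuleCalibError(Exception):
    """Base class for all package-specific errors."""


class DomainError(CapsuleCalibError, ValueError):
    """An argument lies outside the physical/mathematical domain of an operation."""


class DegenerateDesignError(DomainError):
    """A fit was requested on data with no usable leverage (e.g. all x identical)."""


class NoCapsuleError(CapsuleCalibError):
    """Segmentation could not find a capsule in the image."""


class RegionSelectionError(CapsuleCalibError):
    """The centre region could not be placed inside the capsule mask."""


class GeometryError(DomainError):
    """A rendered capsule does not fit the requested canvas."""


class UnitError(DomainError):
    """A required physical scale (e.g. micrometres per pixel) is missing or invalid."""


class SchemaError(CapsuleCalibError):
    """An external table does not expose the expected columns."""


class PipelineError(CapsuleCalibError):
    """A fatal end-to-end pipeline failure (e.g. zero usable images)."""
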