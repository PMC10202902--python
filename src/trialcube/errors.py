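"""Exception hierarchy for trialcube.

Every error raised by the package derives from :class:`TrialCubeError`, so
callers (and the CLI) can distinguish domain validation problems from
programming errors with a single ``except``.
"""


class TrialCubeError(Exception):
    """Base class for all trialcube errors."""


# --- axis / space construction -------------------------------------------


class EmptyAxisError(TrialCubeError):
    """An axis was given no elements (or an amendment would empty it)."""


class DuplicateLabelError(TrialCubeError):
    """An axis contains the same element label twice."""


class InvalidControlError(TrialCubeError):
    """The control element is not a member of the axis, or the axis is not a
    treatment axis."""


class AxisOverlapError(TrialCubeError):
    """Two axes of one space share an element label, or a cohort merge would
    create a label collision.  Nominal dimensions must be mutually
    exclusive."""


class InvalidCellError(TrialCubeError):
    """A cell does not assign exactly one valid element per axis, or an
    active cell violates a treatment admissibility restriction."""


class UnknownFlagError(TrialCubeError):
    """An annotation flag outside the space's controlled vocabulary."""


class UnknownElementError(TrialCubeError):
    """A referenced axis or element does not exist in the space."""


# --- geometry -------------------------------------------------------------


class InvalidDimensionError(TrialCubeError):
    """A negative dimension, or a face dimension exceeding the cube's."""


class PoleProjectionError(TrialCubeError):
    """Stereographic projection requested at the projection pole itself."""


class OffSurfaceError(TrialCubeError):
    """A point handed to a surface map does not lie on the surface within
    tolerance."""


class InvalidPointError(TrialCubeError):
    """Non-finite or degenerate (zero) coordinates."""


# --- projection / adaptation ---------------------------------------------


class EmptySubgroupsError(TrialCubeError):
    """Subgroups requested for an undetermined design."""


class IncompatibleSpacesError(TrialCubeError):
    """Two spaces cannot be diffed because their axis names or roles
    disagree."""


# --- io / rendering -------------------------------------------------------


class SchemaError(TrialCubeError):
    """A design document violates the published schema.

    ``location`` is a dotted/indexed path into the document, e.g.
    ``space.axes[1].elements``.
    """

    def __init__(self, message: str, location: str = ""):
        self.location = location
        super().__init__(f"{location}: {message}" if location else message)


class VersionError(SchemaError):
    """Unknown ``schema_version`` in a design document."""


class UnknownFixtureError(TrialCubeError):
    """No packaged fixture by that name."""


class UnsupportedRenderError(TrialCubeError):
    """A render was requested for a space of dimension > 3; project first."""
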