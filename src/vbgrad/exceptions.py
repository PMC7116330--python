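"""Exception hierarchy.

All errors raised by the library derive from :class:`VBGradError` so callers
can catch one base class; most also derive from the matching builtin
(``ValueError``) so generic numeric code behaves as expected.
"""


class VBGradError(Exception):
    """Base class for all vbgrad errors."""


class ShapeError(VBGradError, ValueError):
    """Input arrays have incompatible or invalid shapes."""


class SymmetryError(VBGradError, ValueError):
    """An affinity matrix is asymmetric beyond tolerance."""


class DegenerateFeatureError(VBGradError, ValueError):
    """A feature vector is degenerate (zero norm or zero variance)."""


class DegenerateDegreeError(VBGradError, ValueError):
    """A node has degree zero where a normalized problem needs D > 0."""


class MeshError(VBGradError, ValueError):
    """A surface mesh violates its invariants."""


class AlignmentError(VBGradError, ValueError):
    """Per-vertex data does not align with the surface it accompanies."""


class ParameterError(VBGradError, ValueError):
    """A parameter is out of its documented range."""
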