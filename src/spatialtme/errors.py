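"""Exception hierarchy for spatialtme.

All errors derive from :class:`SpatialTMEError` so callers can catch the
package's failures with a single except clause; the subclasses mirror the
kinds of contract violations the pipeline distinguishes (file format vs
data validation vs configuration vs geometry).
"""


class SpatialTMEError(Exception):
    """Base class for all spatialtme errors."""


class FormatError(SpatialTMEError, ValueError):
    """A delimited input file does not match the expected layout."""


class ValidationError(SpatialTMEError, ValueError):
    """A table violates a data-model invariant (with a located message)."""


class ConfigurationError(SpatialTMEError, ValueError):
    """A parameter set or rule set is internally inconsistent."""


class GeometryError(SpatialTMEError, ValueError):
    """A tissue geometry is degenerate or unusable."""
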