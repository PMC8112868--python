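"""Exception hierarchy.

Every domain error derives from :class:`CytoClustError` so callers (and the
CLI) can distinguish expected failures from bugs.  Most also derive from
``ValueError`` so plain scripts behave sensibly.
"""


class CytoClustError(Exception):
    """Base class for all cytoclust domain errors."""


class AlignmentError(CytoClustError, ValueError):
    """Shapes of per-cell / per-channel structures disagree."""


class MetadataError(CytoClustError, ValueError):
    """Sample or panel metadata is inconsistent with the data."""


class ConfigurationError(CytoClustError, ValueError):
    """A configuration (e.g. marker use-flags) makes the request impossible."""


class EmptySelectionError(CytoClustError, ValueError):
    """A subset operation selected zero cells."""


class StateError(CytoClustError, RuntimeError):
    """A required layer (reduction, labels, ...) is absent."""


class FormatError(CytoClustError, ValueError):
    """A file violates the expected on-disk format."""


class TruncatedDataError(CytoClustError, IOError):
    """A binary segment ends before the declared number of bytes."""


class ParseError(CytoClustError, ValueError):
    """A text table could not be parsed."""


class PanelError(CytoClustError, KeyError):
    """A requested marker/channel is not in the panel."""


class DesignError(CytoClustError, ValueError):
    """The experimental design cannot support the requested test."""


class DegenerateDataError(CytoClustError, ValueError):
    """Data has no variation where variation is required."""


class CompletenessError(CytoClustError, ValueError):
    """A lookup table does not cover all required keys."""
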