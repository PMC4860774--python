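"""Exception hierarchy for radscreen.

All errors derive from :class:`RadScreenError` so callers can catch the
package's failures with one clause; domain errors also subclass
:class:`ValueError` so generic numeric code behaves sensibly.
"""


class RadScreenError(Exception):
    """Base class for all radscreen errors."""


class FormatError(RadScreenError, ValueError):
    """A file does not conform to the expected tabular schema."""


class ValidationError(RadScreenError, ValueError):
    """A parsed value violates a domain invariant (e.g. negative foci count)."""


class LayoutError(RadScreenError, ValueError):
    """Cells or wells are inconsistent with the plate layout."""


class GatingError(RadScreenError, ValueError):
    """Cell-cycle gating could not be performed."""


class QCError(RadScreenError, ValueError):
    """Control-separation QC could not be computed."""


class DecompositionError(RadScreenError, ValueError):
    """The median-polish decomposition is not defined for the input."""


class AssemblyError(RadScreenError, ValueError):
    """Well summaries could not be assembled into a screen cube."""


class MergeError(RadScreenError, ValueError):
    """Replicate score tables cannot be merged."""


class ConfigError(RadScreenError, ValueError):
    """A simulation or pipeline configuration is infeasible."""
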