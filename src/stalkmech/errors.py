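"""Exception hierarchy for stalkmech.

All package-specific errors derive from :class:`StalkmechError` so callers
can catch one base class at pipeline level.
"""


class StalkmechError(Exception):
    """Base class for all stalkmech errors."""


class FormatError(StalkmechError):
    """A coordinate file could not be parsed under the requested dialect."""


class EmptyStructureError(StalkmechError):
    """A structure contains no atoms after reading/filtering."""


class EmptySelectionError(StalkmechError):
    """A residue selection resolved to zero atoms."""


class MissingAtomError(StalkmechError):
    """A specifically named atom (marker, anchor, ring atom) is absent."""


class DegenerateInputError(StalkmechError):
    """Coordinate sets are too small or too degenerate to superpose."""


class ConvergenceError(StalkmechError):
    """Iterative core refinement failed (core shrank below 3 residues)."""


class ConfigError(StalkmechError):
    """Invalid configuration value (spec field, boundary list, hinge index...)."""


class IncompatibleTracesError(StalkmechError):
    """Two helical-axis traces share no residue labels."""


class TooShortError(StalkmechError):
    """An input series (base-pair list, profile) is too short to analyse."""
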