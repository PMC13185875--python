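"""Exception hierarchy for heliforge.

Every error raised by the public API derives from :class:`HeliforgeError`
so callers can catch the whole family with one clause.
"""


class HeliforgeError(Exception):
    """Base class for all heliforge errors."""


# --- chem_space -----------------------------------------------------------

class NameParseError(HeliforgeError, ValueError):
    """A Position-Substituent name string could not be parsed."""


class DuplicatePositionError(NameParseError):
    """The same scaffold position appears twice in a name."""


class UnknownSubstituentError(NameParseError):
    """A substituent code is not in the descriptor table."""


class PositionRangeError(NameParseError):
    """A position lies outside the 1..16 scaffold numbering."""


class DescriptorTableError(HeliforgeError, KeyError):
    """The sigma_p descriptor table is missing an entry."""


# --- chiroptics -----------------------------------------------------------

class DegenerateTransitionError(HeliforgeError, ValueError):
    """Both transition dipole magnitudes are zero; g is undefined."""


# --- dataset_io -----------------------------------------------------------

class SchemaError(HeliforgeError, ValueError):
    """A dataset file does not match the expected column schema."""


class DuplicateMoleculeError(HeliforgeError, ValueError):
    """Two rows share the same canonical molecule name."""


class ValidationError(HeliforgeError, ValueError):
    """A property record violates a physical invariant."""


# --- synthetic_oracle -----------------------------------------------------

class SpaceExhaustedError(HeliforgeError, ValueError):
    """More distinct molecules were requested than the space contains."""


# --- local_model ----------------------------------------------------------

class DimensionError(HeliforgeError, ValueError):
    """Two vectors or sequences have incompatible lengths."""


class InsufficientPoolError(HeliforgeError, ValueError):
    """Fewer candidate neighbours exist than were requested."""


# --- ga_design ------------------------------------------------------------

class InfeasibleConstraintError(HeliforgeError, ValueError):
    """The constraint set admits no valid molecule."""


class EmptyInputError(HeliforgeError, ValueError):
    """An operation that needs at least one element received none."""
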