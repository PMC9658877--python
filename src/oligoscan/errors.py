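"""Exception hierarchy shared across the package."""


class OligoscanError(Exception):
    """Base class for all package-specific errors."""


class StructureParseError(OligoscanError):
    """A structure file record could not be parsed; message names the line."""


class EmptyInputError(OligoscanError):
    """A file or model contained no atoms."""


class EmptySelectionError(OligoscanError):
    """An atom selection matched nothing."""


class DomainMapError(OligoscanError):
    """Invalid or inapplicable domain range table."""


class PaeFormatError(OligoscanError):
    """PAE data are not a valid square matrix."""


class PaeDialectError(PaeFormatError):
    """Unrecognized PAE JSON dialect; message lists the keys found."""


class StoichiometryError(OligoscanError):
    """Chain counts of two assemblies are incompatible."""


class NotSymmetricError(OligoscanError):
    """Chains are too dissimilar to support a cyclic-symmetry estimate."""


class TrajectoryFormatError(OligoscanError):
    """Inconsistent atom inventory across trajectory frames."""


class DimensionMismatchError(OligoscanError):
    """Structure residue count disagrees with the PAE matrix dimension."""


class SequenceError(OligoscanError):
    """Invalid residue characters in a sequence."""
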