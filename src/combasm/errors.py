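"""Exception hierarchy shared across the package."""


class CombasmError(Exception):
    """Base class for all package errors."""


class ConfigFormatError(CombasmError):
    """Malformed or invalid config / input record."""


class CapacityError(CombasmError):
    """Input exceeds the supported number of subunit copies."""


class SequenceIdentityError(CombasmError):
    """A chain in a predicted model matches no configured subunit sequence."""


class ScoreDialectError(CombasmError):
    """Confidence-score file inconsistent with the structure (shape/keys)."""


class RestraintReferenceError(CombasmError):
    """A restraint references an unknown subunit or out-of-range residue."""


class GeometryError(CombasmError):
    """Infeasible synthetic geometry (e.g. a ring too tight to close)."""


class ParameterError(CombasmError):
    """A parameter outside its documented domain."""


class CoverageError(CombasmError):
    """A subunit absent from every predicted model."""


class DegenerateAlignmentError(CombasmError):
    """Too few usable residues to define a superposition."""


class AssemblyError(CombasmError):
    """Assembly cannot proceed (e.g. empty transformation library)."""
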