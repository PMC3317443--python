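"""Exception hierarchy.

Every user-facing failure mode raises a subclass of :class:`PartForgeError`
so callers (and the CLI) can distinguish domain failures (exit 1) from
usage/I-O failures (exit 2) without string matching.
"""


class PartForgeError(Exception):
    """Base class for all partforge domain errors."""


class FormatError(PartForgeError):
    """A file failed to parse under its declared format."""


class InvalidSourceError(PartForgeError):
    """A source sequence is unusable (e.g. empty residues)."""


class AlphabetError(PartForgeError):
    """Residues contain characters outside the IUPAC DNA alphabet."""


class RangeError(PartForgeError):
    """A coordinate falls outside [1, source length]."""


class TopologyError(PartForgeError):
    """An origin-wrapping selection was requested on a linear sequence."""


class NamingError(PartForgeError):
    """A name is empty or contains prohibited characters."""


class UniquenessError(PartForgeError):
    """A part or rule name collides with an existing one."""


class StructureError(PartForgeError):
    """A structural precondition failed (empty bin, bad bin index, ...)."""


class OperandError(PartForgeError):
    """A rule operand does not resolve to a part on the canvas."""


class RuleValueError(PartForgeError):
    """A rule carries an invalid value (e.g. NOTMORETHAN count < 1)."""


class ValidationRefusedError(PartForgeError):
    """An export was refused because the design has error diagnostics."""

    def __init__(self, diagnostics):
        self.diagnostics = list(diagnostics)
        lines = "; ".join(str(d) for d in self.diagnostics)
        super().__init__(f"design has validation errors: {lines}")


class SchemaError(PartForgeError):
    """A design document violates the documented schema."""


class VersionError(SchemaError):
    """A design document declares an unsupported schema version."""


class ReferenceError_(PartForgeError):
    """A bundle entry references a source that cannot be resolved."""
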