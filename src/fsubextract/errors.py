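"""Typed exceptions shared across the package.

Every error class maps to a distinct CLI exit code (see ``cli.EXIT_CODES``)
so callers can distinguish malformed files from geometric mismatches from
bad parameters without parsing messages.
"""


class FsubError(Exception):
    """Base class for all package errors."""


class FormatError(FsubError):
    """File does not match the expected on-disk format (bad magic, bad header)."""


class UnsupportedDialectError(FormatError):
    """File is recognized but uses a dialect we deliberately refuse (e.g. rare TCK datatypes)."""


class CorruptFileError(FormatError):
    """File is structurally valid up to a point, then truncated or inconsistent."""


class SpaceMismatchError(FsubError):
    """Two objects do not share a voxel grid / coordinate space."""


class ParameterError(FsubError):
    """A numeric or enum parameter is outside its documented range."""


class ValidationError(FsubError):
    """Input object violates a structural invariant (bad face index, weight count...)."""


class EmptyInputError(FsubError):
    """An operation requires a non-empty mask, label, or tractogram."""
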