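"""Exception hierarchy.

Every error raised by the library derives from :class:`AssaySpecError` so the
CLI can map any domain failure to a single nonzero exit code.
"""


class AssaySpecError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(AssaySpecError):
    """Malformed input text (YAML syntax, newick syntax)."""


class SchemaError(AssaySpecError):
    """Structurally valid input missing or misusing a required key/field."""


class StructureError(AssaySpecError):
    """A tree shape that the requested operation cannot work on."""


class NotFoundError(AssaySpecError):
    """A named modality, region, or onlist does not exist."""


class GeometryError(AssaySpecError):
    """A read layout that a preprocessing-tool dialect cannot express,
    e.g. variable-length barcodes (inDropsv3-style designs)."""


class RenderError(AssaySpecError):
    """Diagram cannot be laid out under the requested constraints."""


class OnlistError(AssaySpecError):
    """Onlist file unreadable or unresolvable."""


class IntegrityError(OnlistError):
    """Onlist checksum mismatch."""


class ContentError(OnlistError):
    """Onlist file contains a non-nucleotide line."""


class ConfigError(AssaySpecError):
    """Contradictory fixture-generator configuration."""


class UpdateRejectedError(AssaySpecError):
    """A modify() update that would violate a document invariant.

    Carries the violation ``code`` (e.g. DUP_ID, FIXED_SEQ_LEN) so callers can
    react programmatically.
    """

    def __init__(self, code: str, message: str):
        super().__init__(message)
        self.code = code
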