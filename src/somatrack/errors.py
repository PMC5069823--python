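"""Exception hierarchy."""


class SomatrackError(Exception):
    """Base class for all package errors."""


class MalformedVariantError(SomatrackError):
    """Neither a genomic quadruple nor a (gene, protein-change) key is constructible."""


class ValidationError(SomatrackError):
    """An object violates its declared invariants."""


class FormatError(SomatrackError):
    """An input file does not conform to the documented dialect."""


class CaseMismatchError(SomatrackError):
    """An operation combined specimens belonging to different cases."""


class IncompleteCaseError(SomatrackError):
    """A case-level operation is missing data for one of the case's specimens."""


class DomainError(SomatrackError):
    """An operation was applied to a specimen of the wrong tissue type."""
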