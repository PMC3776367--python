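"""Exception hierarchy for adverank."""


class AdverankError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AdverankError):
    """A file does not conform to its expected dialect (bad header, wrong
    column count, non-numeric score field, ...)."""


class ValidationError(AdverankError):
    """Well-formed input carrying an invalid value (negative confidence
    score, similarity outside [0, 1], asymmetric similarity table, ...)."""


class StructureError(AdverankError):
    """A SMILES string could not be parsed into a molecule."""


class GenerationError(AdverankError):
    """A synthetic fixture specification could not be satisfied."""
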