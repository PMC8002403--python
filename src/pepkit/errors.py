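"""Exception hierarchy.

Every error raised by the package derives from :class:`PepkitError` so callers
can catch the whole family with one clause.
"""


class PepkitError(Exception):
    """Base class for all package errors."""


class EmptySequenceError(PepkitError):
    """The input sequence is empty after whitespace stripping."""


class InvalidMonomerError(PepkitError):
    """A token in the sequence is not a registered monomer.

    Attributes
    ----------
    token : str
        The offending token.
    position : int
        One-based residue position of the offending token.
    """

    def __init__(self, token: str, position: int):
        self.token = token
        self.position = position
        super().__init__(
            f"invalid monomer {token!r} at position {position}"
        )


class HelmSyntaxError(PepkitError):
    """A HELM string does not follow the simple-polymer grammar."""


class DomainError(PepkitError):
    """A numeric argument is outside its mathematical domain (e.g. pH)."""


class InstabilityUndefinedError(PepkitError):
    """The instability index needs at least one dipeptide (length >= 2)."""


class ChemistryError(PepkitError):
    """A SMILES string could not be parsed by the cheminformatics toolkit."""


class LengthMismatchError(PepkitError):
    """Sequences of unequal length where equal length is required."""


class AlphabetError(PepkitError):
    """A residue is not covered by the substitution-matrix alphabet."""


class MatrixFormatError(PepkitError):
    """A substitution-matrix file is not in the NCBI text layout."""


class EmbeddingError(PepkitError):
    """Distance-geometry embedding failed within the retry budget."""


class ChainNotFoundError(PepkitError):
    """The requested chain id is absent from the structure."""


class EmptyStructureError(PepkitError):
    """The PDB file contains no ATOM records."""


class AnnotationError(PepkitError):
    """Secondary-structure / ASA annotation failed."""


class DependencyError(PepkitError):
    """An optional runtime dependency is missing; the message says how to fix."""


class PatternError(PepkitError):
    """A library pattern contains characters outside the alphabet (plus X)."""


class LibraryTooLargeError(PepkitError):
    """Exhaustive expansion would exceed the configured size guard."""


class FrequencyError(PepkitError):
    """A per-position frequency row is degenerate or does not sum to one."""
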