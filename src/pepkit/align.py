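"""Gap-free, position-by-position pairwise peptide alignment.

Peptides of equal length are compared position by position under a symmetric
substitution matrix; the alignment score is the exact sum of the per-position
matrix scores. No gaps are ever introduced: gap-based alignment models
evolutionary events, which is the wrong prior for short synthetic peptides,
so unequal lengths are an error rather than a silent truncation.

Matrices are read from the standard NCBI text layout; BLOSUM62 ships with the
package. A pair is counted as *similar* when its matrix score is strictly
positive (the similarity cutoff is a documented convention of this module).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from . import core
from .core import Peptide
from .errors import AlphabetError, LengthMismatchError, MatrixFormatError

__all__ = [
    "SubstitutionMatrix",
    "AlignmentResult",
    "PositionScore",
    "load_matrix",
    "align_positionwise",
    "similarity_fraction",
    "format_blastp_query",
]


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric residue substitution matrix."""

    name: str
    alphabet: tuple[str, ...]
    _scores: dict[tuple[str, str], float]

    def __post_init__(self):
        for a in self.alphabet:
            for b in self.alphabet:
                if (a, b) not in self._scores:
                    raise MatrixFormatError(
                        f"{self.name}: pair ({a}, {b}) undefined")
                if self._scores[(a, b)] != self._scores[(b, a)]:
                    raise MatrixFormatError(
                        f"{self.name}: asymmetric at ({a}, {b})")

    def score(self, a: str, b: str) -> float:
        """Score of aligning residue ``a`` against residue ``b``."""
        try:
            return self._scores[(a, b)]
        except KeyError:
            missing = a if a not in self.alphabet else b
            raise AlphabetError(
                f"residue {missing!r} not in the {self.name} alphabet"
            ) from None

    def __contains__(self, residue: str) -> bool:
        return residue in self.alphabet

    @classmethod
    def from_ncbi_text(cls, text: str, name: str) -> "SubstitutionMatrix":
        """Parse a matrix in the NCBI text layout (# comments, header row)."""
        lines = [ln for ln in text.splitlines()
                 if ln.strip() and not ln.lstrip().startswith("#")]
        if not lines:
            raise MatrixFormatError("no data lines found")
        header = lines[0].split()
        scores: dict[tuple[str, str], float] = {}
        seen_rows = []
        for ln in lines[1:]:
            fields = ln.split()
            row = fields[0]
            values = fields[1:]
            if len(values) != len(header):
                raise MatrixFormatError(
                    f"row {row!r} has {len(values)} values for "
                    f"{len(header)} columns")
            seen_rows.append(row)
            for col, val in zip(header, values):
                try:
                    num = float(val)
                except ValueError as exc:
                    raise MatrixFormatError(
                        f"non-numeric score {val!r} at ({row}, {col})"
                    ) from exc
                scores[(row, col)] = int(num) if num.is_integer() else num
        if seen_rows != header:
            raise MatrixFormatError("row labels do not match the header")
        return cls(name, tuple(header), scores)

    @classmethod
    def from_ncbi_file(cls, path: str | Path,
                       name: str | None = None) -> "SubstitutionMatrix":
        path = Path(path)
        return cls.from_ncbi_text(path.read_text(),
                                  name or path.stem)

    @classmethod
    def from_biopython(cls, name: str) -> "SubstitutionMatrix":
        """Convert a matrix from Biopython's substitution-matrix catalogue."""
        from Bio.Align import substitution_matrices

        m = substitution_matrices.load(name)
        alphabet = tuple(m.alphabet)
        scores = {(a, b): float(m[a, b]) for a in alphabet for b in alphabet}
        scores = {k: int(v) if v.is_integer() else v
                  for k, v in scores.items()}
        return cls(name, alphabet, scores)


def load_matrix(name: str = "BLOSUM62") -> SubstitutionMatrix:
    """Load a named matrix shipped with the package (NCBI text layout)."""
    ref = resources.files("pepkit").joinpath(f"data/{name}.txt")
    if not ref.is_file():
        raise MatrixFormatError(f"no bundled matrix named {name!r}")
    return SubstitutionMatrix.from_ncbi_text(ref.read_text(), name)


@dataclass(frozen=True)
class PositionScore:
    residue_a: str
    residue_b: str
    score: float
    is_identity: bool


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of one gap-free pairwise alignment."""

    score: float
    per_position: tuple[PositionScore, ...]

    @property
    def length(self) -> int:
        return len(self.per_position)

    @property
    def n_identical(self) -> int:
        return sum(ps.is_identity for ps in self.per_position)

    @property
    def n_similar(self) -> int:
        """Positions whose matrix score is strictly positive."""
        return sum(ps.score > 0 for ps in self.per_position)


def align_positionwise(a: Peptide | str, b: Peptide | str,
                       matrix: SubstitutionMatrix) -> AlignmentResult:
    """Score two equal-length peptides position by position.

    Raises :class:`LengthMismatchError` for unequal lengths and
    :class:`AlphabetError` if a residue is not covered by the matrix.
    """
    a = core._as_peptide(a)
    b = core._as_peptide(b)
    if len(a) != len(b):
        raise LengthMismatchError(
            f"gap-free alignment needs equal lengths, got {len(a)} and "
            f"{len(b)}")
    per_position = []
    for ra, rb in zip(a.letters, b.letters):
        s = matrix.score(ra, rb)
        per_position.append(PositionScore(ra, rb, s, ra == rb))
    return AlignmentResult(
        score=sum(ps.score for ps in per_position),
        per_position=tuple(per_position),
    )


def similarity_fraction(result: AlignmentResult) -> float:
    """Fraction of positions with a strictly positive matrix score."""
    return result.n_similar / result.length


def format_blastp_query(p: Peptide | str, **params) -> dict:
    """Assemble (but never submit) an online blastp query for a peptide.

    Network submission is out of scope; this returns the parameter dictionary
    a short-peptide blastp search would use, so callers can submit it with
    their own client. Word size, expect threshold and matrix default to the
    short-query settings.
    """
    p = core._as_peptide(p)
    query = {
        "program": "blastp",
        "database": "nr",
        "sequence": p.letters,
        "word_size": 2,
        "expect": 200000,
        "matrix_name": "PAM30",
        "gapcosts": "9 1",
        "filter": "F",
    }
    query.update(params)
    return query
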