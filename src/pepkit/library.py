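"""Combinatorial peptide library design.

Four construction modes:

* **pattern** — exact Cartesian expansion of a pattern such as ``XRTEX``,
  where ``X`` ranges over the alphabet and fixed positions are preserved;
* **exhaustive** — all sequences of a given length (a pattern of all X);
* **scan** — every single-position substitution of a base sequence by every
  alphabet residue (the "uniform representation" design: each residue
  appears at each position exactly once across the pooled set);
* **frequency_sample** — seeded i.i.d. per-position sampling from explicit
  frequency rows.

Enumerated outputs are deduplicated and lexicographically sorted so runs are
diffable; sampled outputs are reproducible for a fixed seed. Exhaustive
expansion refuses to build more than ten million sequences and points the
caller at sampling mode instead. Libraries over alphabets containing
D-tokens can be rendered as HELM strings alongside the one-letter forms.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import core
from .errors import (
    FrequencyError,
    LengthMismatchError,
    LibraryTooLargeError,
    PatternError,
)
from .monomers import CANONICAL_ALPHABET

__all__ = [
    "LibrarySpec",
    "expand_pattern",
    "exhaustive_library",
    "scan_library",
    "sample_library",
    "frequency_matrix",
    "uniform_frequencies",
    "build_library",
    "to_fasta",
    "to_helm_lines",
]

MAX_EXHAUSTIVE = 10 ** 7
_FREQ_TOL = 1e-9


@dataclass(frozen=True)
class LibrarySpec:
    """Parameters of one library design."""

    mode: str                                   # pattern|exhaustive|scan|frequency_sample
    pattern: str | None = None
    length: int | None = None
    base: str | None = None
    frequencies: tuple[dict[str, float], ...] | None = None
    sample_size: int = 1
    seed: int = 0
    alphabet: tuple[str, ...] = CANONICAL_ALPHABET


def _tokenize_pattern(pattern: str,
                      alphabet: tuple[str, ...]) -> list[str]:
    tokens = []
    allowed = set(alphabet) | {"X"}
    for pos, match in enumerate(core._TOKEN_RE.finditer(pattern), start=1):
        tok = match.group(1) if match.group(1) is not None else match.group(2)
        if tok not in allowed:
            raise PatternError(
                f"pattern token {tok!r} at position {pos} is not X or an "
                f"alphabet residue")
        tokens.append(tok)
    if not tokens:
        raise PatternError("pattern is empty")
    return tokens


def _render(tokens: tuple[str, ...]) -> str:
    return "".join(t if len(t) == 1 else f"[{t}]" for t in tokens)


def expand_pattern(pattern: str,
                   alphabet: tuple[str, ...] = CANONICAL_ALPHABET,
                   max_size: int = MAX_EXHAUSTIVE) -> list[str]:
    """All sequences matching a pattern; X positions range over the alphabet.

    Output is deduplicated and lexicographically sorted. Raises
    :class:`LibraryTooLargeError` when the expansion would exceed
    ``max_size`` sequences (use :func:`sample_library` instead).
    """
    tokens = _tokenize_pattern(pattern, alphabet)
    n_x = sum(t == "X" for t in tokens)
    size = len(alphabet) ** n_x
    if size > max_size:
        raise LibraryTooLargeError(
            f"pattern {pattern!r} expands to {size} sequences "
            f"(> {max_size}); use frequency sampling instead")
    choices = [sorted(alphabet) if t == "X" else [t] for t in tokens]
    seqs = {_render(combo) for combo in itertools.product(*choices)}
    return sorted(seqs)


def exhaustive_library(length: int,
                       alphabet: tuple[str, ...] = CANONICAL_ALPHABET,
                       max_size: int = MAX_EXHAUSTIVE) -> list[str]:
    """All sequences of the given length over the alphabet."""
    if length < 1:
        raise PatternError("length must be >= 1")
    return expand_pattern("X" * length, alphabet, max_size)


def scan_library(base: "core.Peptide | str",
                 alphabet: tuple[str, ...] = CANONICAL_ALPHABET) -> list[str]:
    """Single-position scan: every substitution of every position.

    Across the pooled set every alphabet residue appears at every position
    at least once; the base sequence itself is kept exactly once
    (duplicates produced by substituting a position with its own residue
    are removed).
    """
    base = core._as_peptide(base)
    seqs = {base.sequence}
    for i in range(len(base)):
        for res in alphabet:
            tokens = list(base.monomers)
            tokens[i] = res
            seqs.add(_render(tuple(tokens)))
    return sorted(seqs)


def uniform_frequencies(length: int,
                        alphabet: tuple[str, ...] = CANONICAL_ALPHABET
                        ) -> tuple[dict[str, float], ...]:
    """Uniform per-position frequency rows."""
    row = {res: 1.0 / len(alphabet) for res in alphabet}
    return tuple(dict(row) for _ in range(length))


def sample_library(frequencies, n: int, seed: int = 0) -> list[str]:
    """Draw ``n`` sequences i.i.d. per position from frequency rows.

    Each row maps residue tokens to probabilities summing to one. Rows that
    are empty, carry negative weights, or sum to zero raise
    :class:`FrequencyError`. Reproducible for a fixed seed.
    """
    if n < 1:
        raise FrequencyError("sample size must be >= 1")
    rng = np.random.default_rng(seed)
    columns = []
    for pos, row in enumerate(frequencies, start=1):
        if not row:
            raise FrequencyError(f"position {pos}: empty frequency row")
        tokens = sorted(row)
        probs = np.array([row[t] for t in tokens], dtype=float)
        if (probs < 0).any():
            raise FrequencyError(f"position {pos}: negative frequency")
        total = probs.sum()
        if total <= 0:
            raise FrequencyError(f"position {pos}: frequencies sum to zero")
        if abs(total - 1.0) > _FREQ_TOL:
            raise FrequencyError(
                f"position {pos}: frequencies sum to {total}, not 1")
        columns.append(rng.choice(tokens, size=n, p=probs / total))
    return [_render(tuple(str(columns[j][i]) for j in range(len(columns))))
            for i in range(n)]


def frequency_matrix(sequences) -> pd.DataFrame:
    """Observed per-position residue fractions of an equal-length library.

    Rows are positions (1-based index), columns the tokens observed anywhere
    in the library; each row sums to one.
    """
    tokenized = []
    for seq in sequences:
        p = core._as_peptide(seq)
        tokenized.append(p.monomers)
    lengths = {len(t) for t in tokenized}
    if len(lengths) != 1:
        raise LengthMismatchError(
            f"sequences have mixed lengths: {sorted(lengths)}")
    length = lengths.pop()
    tokens = sorted({t for seq in tokenized for t in seq})
    counts = pd.DataFrame(0.0, index=range(1, length + 1), columns=tokens)
    for seq in tokenized:
        for pos, tok in enumerate(seq, start=1):
            counts.at[pos, tok] += 1
    return counts / len(tokenized)


def build_library(spec: LibrarySpec) -> list[str]:
    """Dispatch a :class:`LibrarySpec` to the matching construction mode."""
    if spec.mode == "pattern":
        return expand_pattern(spec.pattern, spec.alphabet)
    if spec.mode == "exhaustive":
        return exhaustive_library(spec.length, spec.alphabet)
    if spec.mode == "scan":
        return scan_library(spec.base, spec.alphabet)
    if spec.mode == "frequency_sample":
        freqs = spec.frequencies or uniform_frequencies(spec.length,
                                                        spec.alphabet)
        return sample_library(freqs, spec.sample_size, spec.seed)
    raise PatternError(f"unknown library mode {spec.mode!r}")


def to_fasta(sequences, prefix: str = "pep") -> str:
    """FASTA text for a library (ids ``prefix_1`` ...)."""
    lines = []
    for i, seq in enumerate(sequences, start=1):
        lines.append(f">{prefix}_{i}")
        lines.append(seq)
    return "\n".join(lines) + "\n"


def to_helm_lines(sequences) -> list[str]:
    """HELM rendering of each library member (D-tokens bracketed)."""
    return [core.to_helm(seq) for seq in sequences]
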