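"""Peptide data model, sequence parsing, HELM notation and SMILES construction.

A peptide is an ordered list of monomer codes: one-letter codes for the 20
canonical L-amino acids, ``[dX]`` bracket tokens for their D-counterparts
(lowercase ``d`` + the parent letter). Sequences are validated against the
registered monomer table; parsing upper-cases plain letters so ``gavl`` and
``GAVL`` are the same peptide, while D-residues must always be written with
brackets — this prevents silent L/D ambiguity.

SMILES strings are built residue by residue from N- to C-terminus so the atom
numbering follows the peptide bonds: each residue contributes N, CA, its side
chain, then the carbonyl C/O, and the chain ends with a free acid. Stereo tags
are emitted for every stereocenter (L by default, mirrored for D residues),
which lets :func:`sequence_from_smiles` walk the backbone of any peptide
SMILES produced here (or an equivalent one) and recover the sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from .errors import (
    ChemistryError,
    EmptySequenceError,
    HelmSyntaxError,
    InvalidMonomerError,
)
from .monomers import MONOMERS, MonomerRecord

__all__ = [
    "Peptide",
    "parse_sequence",
    "to_smiles",
    "build_mol",
    "to_helm",
    "from_helm",
    "sequence_from_smiles",
    "read_fasta",
]


@dataclass(frozen=True)
class Peptide:
    """A validated peptide: ordered monomer codes plus topology flag."""

    monomers: tuple[str, ...]
    is_cyclic: bool = False

    def __post_init__(self):
        if not self.monomers:
            raise EmptySequenceError("a peptide needs at least one residue")
        for pos, code in enumerate(self.monomers, start=1):
            if code not in MONOMERS:
                raise InvalidMonomerError(code, pos)

    def __len__(self) -> int:
        return len(self.monomers)

    def __iter__(self) -> Iterator[str]:
        return iter(self.monomers)

    @property
    def length(self) -> int:
        return len(self.monomers)

    @property
    def records(self) -> tuple[MonomerRecord, ...]:
        return tuple(MONOMERS[c] for c in self.monomers)

    @property
    def sequence(self) -> str:
        """Canonical rendering: plain letters, D residues bracketed."""
        return "".join(c if len(c) == 1 else f"[{c}]" for c in self.monomers)

    @property
    def letters(self) -> str:
        """One-letter sequence with D-residues mapped to their L-parent.

        Composition-level calculators (charge, hydrophobicity, ProtParam
        statistics) are stereochemistry-blind, so this view feeds them.
        """
        return "".join(MONOMERS[c].letter for c in self.monomers)

    @property
    def is_all_l(self) -> bool:
        return all(len(c) == 1 for c in self.monomers)

    def __str__(self) -> str:
        return self.sequence


_TOKEN_RE = re.compile(r"\[([^\]]*)\]|(.)", re.DOTALL)


def parse_sequence(text: str, is_cyclic: bool = False) -> Peptide:
    """Parse a one-letter (plus ``[dX]``) sequence string into a Peptide.

    Plain letters are upper-cased before validation; bracket tokens are
    normalised to lowercase-d + uppercase letter. Raises
    :class:`EmptySequenceError` on empty input and
    :class:`InvalidMonomerError` (with the one-based residue position) on any
    unregistered token.
    """
    if text is None:
        raise EmptySequenceError("sequence is None")
    stripped = "".join(text.split())
    if not stripped:
        raise EmptySequenceError("sequence is empty")
    monomers: list[str] = []
    for match in _TOKEN_RE.finditer(stripped):
        pos = len(monomers) + 1
        if match.group(1) is not None:
            tok = match.group(1)
            norm = tok[0].lower() + tok[1:].upper() if len(tok) == 2 else tok
            if norm not in MONOMERS:
                raise InvalidMonomerError(tok, pos)
            monomers.append(norm)
        else:
            ch = match.group(2).upper()
            if ch not in MONOMERS or len(ch) != 1:
                raise InvalidMonomerError(match.group(2), pos)
            monomers.append(ch)
    return Peptide(tuple(monomers), is_cyclic=is_cyclic)


def _as_peptide(p: "Peptide | str") -> Peptide:
    return p if isinstance(p, Peptide) else parse_sequence(p)


# --------------------------------------------------------------------------
# HELM (simple polymer section only)
# --------------------------------------------------------------------------

def to_helm(p: Peptide | str, polymer_id: int = 1) -> str:
    """Render the peptide as a HELM v2 simple-polymer string."""
    p = _as_peptide(p)
    body = ".".join(c if len(c) == 1 else f"[{c}]" for c in p.monomers)
    return f"PEPTIDE{polymer_id}{{{body}}}$$$$"


_HELM_RE = re.compile(r"^PEPTIDE\d+\{(?P<body>[^}]*)\}\$\$\$\$(V2\.0)?$")


def from_helm(helm: str) -> Peptide:
    """Parse a simple-polymer HELM string back into a Peptide."""
    m = _HELM_RE.match(helm.strip())
    if not m:
        raise HelmSyntaxError(f"not a simple-polymer HELM string: {helm!r}")
    body = m.group("body")
    if not body:
        raise EmptySequenceError("HELM polymer is empty")
    monomers = []
    for pos, tok in enumerate(body.split("."), start=1):
        tok = tok.strip()
        if tok.startswith("[") and tok.endswith("]"):
            tok = tok[1:-1]
        if tok not in MONOMERS:
            raise InvalidMonomerError(tok, pos)
        monomers.append(tok)
    return Peptide(tuple(monomers))


# --------------------------------------------------------------------------
# SMILES construction
# --------------------------------------------------------------------------

def _invert_stereo(smiles: str) -> str:
    """Swap @@ and @ tags (mirror all stereocenters in a fragment)."""
    return smiles.replace("@@", "\0").replace("@", "@@").replace("\0", "@")


@dataclass(frozen=True)
class AtomInfo:
    """Identity of one heavy atom in the built molecule."""

    residue_index: int   # 1-based
    residue_name3: str
    name: str            # PDB atom name (N, CA, CB, ..., OXT)


def _residue_fragment(code: str, last: bool) -> tuple[str, list[str]]:
    """SMILES fragment + heavy-atom names, in SMILES emission order."""
    rec = MONOMERS[code]
    letter, d = rec.letter, rec.is_d
    if letter == "P":
        ca = "[C@@H]" if d else "[C@H]"
        frag = f"N1CCC{ca}1C(=O)"
        names = ["N", "CD", "CG", "CB", "CA", "C", "O"]
    elif letter == "G":
        frag = "NCC(=O)"
        names = ["N", "CA", "C", "O"]
    else:
        side = rec.smiles_sidechain
        if d:
            side = _invert_stereo(side)
        ca = "[C@H]" if d else "[C@@H]"
        frag = f"N{ca}({side})C(=O)"
        names = ["N", "CA", *rec.sidechain_atom_names, "C", "O"]
    if last:
        frag += "O"
        names.append("OXT")
    return frag, names


def to_smiles(p: Peptide | str) -> str:
    """Linear peptide SMILES, atoms ordered N-terminus to C-terminus.

    Free amine at the N-terminus, free carboxylic acid at the C-terminus;
    stereo tags on every stereocenter. The output is deterministic (built by
    string concatenation of pinned per-residue fragments, not canonicalised).
    """
    p = _as_peptide(p)
    n = len(p)
    return "".join(
        _residue_fragment(code, last=(i == n - 1))[0]
        for i, code in enumerate(p.monomers)
    )


def build_mol(p: Peptide | str):
    """RDKit molecule plus per-heavy-atom :class:`AtomInfo` bookkeeping.

    The i-th entry of the returned list describes the i-th atom of the
    molecule (RDKit preserves SMILES atom order), which is what the conformer
    generator uses to write residue-annotated PDB files.
    """
    from rdkit import Chem

    p = _as_peptide(p)
    smiles = to_smiles(p)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:  # pragma: no cover - builder output is always valid
        raise ChemistryError(f"internal SMILES failed to parse: {smiles}")
    info: list[AtomInfo] = []
    n = len(p)
    for i, code in enumerate(p.monomers):
        rec = MONOMERS[code]
        _, names = _residue_fragment(code, last=(i == n - 1))
        info.extend(AtomInfo(i + 1, rec.name3, nm) for nm in names)
    assert len(info) == mol.GetNumAtoms()
    return mol, info


# --------------------------------------------------------------------------
# SMILES -> sequence decoding (backbone walk)
# --------------------------------------------------------------------------

def _is_carbonyl_carbon(atom) -> bool:
    from rdkit import Chem

    if atom.GetSymbol() != "C":
        return False
    return any(
        b.GetBondType() == Chem.BondType.DOUBLE
        and b.GetOtherAtom(atom).GetSymbol() == "O"
        for b in atom.GetBonds()
    )


def _sidechain_key(mol, ca_idx: int, exclude: set[int]) -> str:
    """Canonical, stereo-free fragment SMILES of CA + its side chain.

    CA carries atom-map 1 so the key is anchored — otherwise e.g. leucine and
    isoleucine side chains would both canonicalise to 2-methylbutane.
    """
    from rdkit import Chem

    seen = {ca_idx}
    stack = [
        nb.GetIdx()
        for nb in mol.GetAtomWithIdx(ca_idx).GetNeighbors()
        if nb.GetIdx() not in exclude
    ]
    while stack:
        idx = stack.pop()
        if idx in seen or idx in exclude:
            continue
        seen.add(idx)
        stack.extend(nb.GetIdx() for nb in mol.GetAtomWithIdx(idx).GetNeighbors())
    ca = mol.GetAtomWithIdx(ca_idx)
    ca.SetAtomMapNum(1)
    try:
        return Chem.MolFragmentToSmiles(
            mol, atomsToUse=sorted(seen), canonical=True, isomericSmiles=False
        )
    finally:
        ca.SetAtomMapNum(0)


_DECODE_REFS: dict[str, str] | None = None


def _decode_references() -> dict[str, str]:
    """Side-chain fragment keys for the 20 canonical residues.

    Built once from single-residue molecules produced by this module's own
    builder, so query and reference fragments go through the identical
    RDKit canonicalisation path.
    """
    global _DECODE_REFS
    if _DECODE_REFS is None:
        refs: dict[str, str] = {}
        for letter in sorted(set(c for c in MONOMERS if len(c) == 1)):
            mol, info = build_mol(parse_sequence(letter))
            idx_of = {ai.name: i for i, ai in enumerate(info)}
            ca = idx_of["CA"]
            exclude = {idx_of["C"]}
            if letter != "P":  # proline's ring nitrogen stays in the key
                exclude.add(idx_of["N"])
            key = _sidechain_key(mol, ca, exclude)
            refs[key] = letter
        _DECODE_REFS = refs
    return _DECODE_REFS


def sequence_from_smiles(smiles: str) -> Peptide:
    """Recover the residue sequence from a linear peptide SMILES.

    Walks the backbone from the free N-terminus through successive amide
    bonds to the free-acid C-terminus, identifies each residue by the
    constitution of its side chain, and assigns L/D from the CIP code of the
    alpha carbon (L is *S*, except cysteine where L is *R*).
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemistryError(f"unparseable SMILES: {smiles!r}")
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)

    # N-terminus: non-aromatic N with no carbonyl-carbon neighbour, attached
    # to a carbon that is itself bonded to a carbonyl carbon.
    start = None
    for atom in mol.GetAtoms():
        if atom.GetSymbol() != "N" or atom.GetIsAromatic():
            continue
        if any(_is_carbonyl_carbon(nb) for nb in atom.GetNeighbors()):
            continue
        for nb in atom.GetNeighbors():
            if nb.GetSymbol() == "C" and any(
                _is_carbonyl_carbon(x) for x in nb.GetNeighbors()
            ):
                start = atom.GetIdx()
                break
        if start is not None:
            break
    if start is None:
        raise ChemistryError("no free N-terminus found; not a linear peptide")

    refs = _decode_references()
    ring_info = mol.GetRingInfo()
    codes: list[str] = []
    n_idx = start
    prev_c = -1
    while True:
        n_atom = mol.GetAtomWithIdx(n_idx)
        ca_idx = c_idx = None
        for nb in n_atom.GetNeighbors():
            if nb.GetIdx() == prev_c or nb.GetSymbol() != "C":
                continue
            if _is_carbonyl_carbon(nb):
                continue
            carbonyls = [
                x.GetIdx() for x in nb.GetNeighbors()
                if x.GetIdx() != n_idx and _is_carbonyl_carbon(x)
            ]
            if carbonyls:
                ca_idx, c_idx = nb.GetIdx(), carbonyls[0]
                break
        if ca_idx is None:
            raise ChemistryError("backbone walk broke: no alpha carbon found")

        is_pro = ring_info.AreAtomsInSameRing(n_idx, ca_idx)
        # prev_c blocks the flood fill from escaping through proline's ring
        # nitrogen (an amide N mid-chain) into the previous residue
        exclude = {c_idx, prev_c}
        if not is_pro:
            exclude.add(n_idx)
        key = _sidechain_key(mol, ca_idx, exclude)
        letter = refs.get(key)
        if letter is None:
            raise ChemistryError(f"unrecognised side chain at residue "
                                 f"{len(codes) + 1}")

        ca_atom = mol.GetAtomWithIdx(ca_idx)
        if letter == "G":
            codes.append("G")
        else:
            cip = (ca_atom.GetPropsAsDict().get("_CIPCode")
                   if ca_atom.HasProp("_CIPCode") else None)
            if cip is None:
                raise ChemistryError(
                    f"alpha carbon of residue {len(codes) + 1} has no "
                    f"stereo assignment")
            l_cip = "R" if letter == "C" else "S"
            codes.append(letter if cip == l_cip else "d" + letter)

        # follow the backbone: amide N continues the chain, O-H terminates
        c_atom = mol.GetAtomWithIdx(c_idx)
        next_n = None
        terminal = False
        for nb in c_atom.GetNeighbors():
            if nb.GetIdx() == ca_idx:
                continue
            bond = mol.GetBondBetweenAtoms(c_idx, nb.GetIdx())
            from rdkit import Chem as _C
            if nb.GetSymbol() == "N" and bond.GetBondType() == _C.BondType.SINGLE:
                next_n = nb.GetIdx()
            elif nb.GetSymbol() == "O" and bond.GetBondType() == _C.BondType.SINGLE:
                terminal = True
        if next_n is not None:
            n_idx, prev_c = next_n, c_idx
        elif terminal:
            break
        else:
            raise ChemistryError("backbone walk broke: carbonyl carbon has "
                                 "neither amide N nor acid O")
    return Peptide(tuple(codes))


# --------------------------------------------------------------------------
# FASTA batch input
# --------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read ``(record_id, sequence_text)`` pairs from a FASTA file.

    Only the record id of each description line is kept. Sequences are
    returned as raw text; validate them with :func:`parse_sequence`.
    """
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
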