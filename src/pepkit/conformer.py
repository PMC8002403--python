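"""Single-conformer 3D structure prediction by distance geometry.

The peptide SMILES from :mod:`pepkit.core` (atoms emitted N→C along the
backbone) is embedded with RDKit's distance-geometry implementation — a
distance-bounds matrix is triangle-smoothed, a random distance matrix drawn
inside the bounds, embedded in 3D — and the raw coordinates are cleaned up
with the MMFF94 force field (the static variant; recorded in the result).
Hydrogens are added for embedding and minimisation and stripped from the
output by default, giving X-ray-like heavy-atom PDB files.

Embedding is deterministic for a fixed seed. A failed embedding is retried
with derived seeds up to a configurable budget (default 10) before
:class:`EmbeddingError` is raised.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from . import core
from .core import Peptide
from .errors import EmbeddingError
from .pdbio import format_atom_line, format_ter_line

__all__ = ["AtomRecord", "ConformerResult", "generate_conformer", "write_pdb"]

#: MMFF variant passed to RDKit, recorded in every result
MMFF_VARIANT = "MMFF94"
DEFAULT_RETRY_BUDGET = 10


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a generated conformer."""

    serial: int
    name: str
    element: str
    residue_index: int    # 1-based, contiguous N→C
    residue_name3: str
    x: float
    y: float
    z: float


@dataclass(frozen=True)
class ConformerResult:
    """A minimised 3D conformer plus generation metadata."""

    atoms: tuple[AtomRecord, ...]
    sequence: str
    seed: int
    energy: float          # MMFF94 energy after minimisation, kcal/mol
    converged: bool
    force_field: str = MMFF_VARIANT

    @property
    def n_residues(self) -> int:
        return self.atoms[-1].residue_index if self.atoms else 0

    def residue_atoms(self, index: int) -> tuple[AtomRecord, ...]:
        return tuple(a for a in self.atoms if a.residue_index == index)


def generate_conformer(p: Peptide | str, seed: int = 1,
                       retry_budget: int = DEFAULT_RETRY_BUDGET,
                       keep_hydrogens: bool = False) -> ConformerResult:
    """Embed and minimise one conformer of the peptide.

    The distance-geometry embedding uses ``seed`` directly on the first
    attempt; each retry derives a new seed deterministically, so the whole
    procedure is reproducible. Raises :class:`EmbeddingError` once the retry
    budget is exhausted.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    p = core._as_peptide(p)
    mol, info = core.build_mol(p)
    molh = Chem.AddHs(mol)

    conf_id = -1
    for attempt in range(retry_budget):
        params = AllChem.ETKDGv3()
        params.randomSeed = (seed + 7919 * attempt) % (2 ** 31)
        conf_id = AllChem.EmbedMolecule(molh, params)
        if conf_id >= 0:
            break
    if conf_id < 0:
        raise EmbeddingError(
            f"distance-geometry embedding failed after {retry_budget} "
            f"attempts for {p.sequence!r}")

    status = AllChem.MMFFOptimizeMolecule(molh, mmffVariant=MMFF_VARIANT,
                                          maxIters=2000)
    props = AllChem.MMFFGetMoleculeProperties(molh, mmffVariant=MMFF_VARIANT)
    ff = AllChem.MMFFGetMoleculeForceField(molh, props)
    energy = ff.CalcEnergy()

    conf = molh.GetConformer()
    atoms: list[AtomRecord] = []
    serial = 1
    # heavy atoms first, in builder order (AddHs appends hydrogens at the end)
    for idx, ai in enumerate(info):
        pos = conf.GetAtomPosition(idx)
        element = molh.GetAtomWithIdx(idx).GetSymbol()
        atoms.append(AtomRecord(serial, ai.name, element, ai.residue_index,
                                ai.residue_name3, pos.x, pos.y, pos.z))
        serial += 1
    if keep_hydrogens:
        h_counter: dict[int, int] = {}
        for idx in range(len(info), molh.GetNumAtoms()):
            atom = molh.GetAtomWithIdx(idx)
            heavy = atom.GetNeighbors()[0].GetIdx()
            res = info[heavy].residue_index
            h_counter[res] = h_counter.get(res, 0) + 1
            atoms.append(AtomRecord(
                serial, f"H{h_counter[res]}", "H", res,
                info[heavy].residue_name3,
                conf.GetAtomPosition(idx).x, conf.GetAtomPosition(idx).y,
                conf.GetAtomPosition(idx).z))
            serial += 1

    return ConformerResult(tuple(atoms), p.sequence, seed, energy,
                           converged=(status == 0))


def write_pdb(result: ConformerResult, path: str | Path,
              chain_id: str = "A") -> Path:
    """Write the conformer as PDB v3.3 ATOM records (serials 1..N, TER)."""
    path = Path(path)
    lines = []
    serial = 0
    for atom in result.atoms:
        serial += 1
        lines.append(format_atom_line(
            serial, atom.name, atom.residue_name3, chain_id,
            atom.residue_index, atom.x, atom.y, atom.z, atom.element))
    last = result.atoms[-1]
    lines.append(format_ter_line(serial + 1, last.residue_name3, chain_id,
                                 last.residue_index))
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
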