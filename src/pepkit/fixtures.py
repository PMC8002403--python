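"""Deterministic synthetic protein–peptide complexes for download-free tests.

Backbones are built from ideal internal coordinates (N–CA 1.458 Å, CA–C
1.525 Å, C–N 1.329 Å, standard angles, ω = 180°) by natural-extension
(NeRF) placement, with φ/ψ set per fixture kind:

* ``helix`` — a 16-residue α-helical receptor chain A (φ=−57°, ψ=−47°) and a
  12-residue α-helical peptide chain B offset 20 Å;
* ``extended`` — the same receptor with a fully extended (β-like, φ=−140°,
  ψ=135°) tripeptide chain B;
* ``two_atom`` — two single-glycine chains laid out on the x-axis so that
  exactly one peptide/protein atom pair sits at 3.5 Å (the next-nearest
  pairs are at 5.0 Å); three water HETATM records sit near the interface to
  exercise solvent exclusion;
* ``far_apart`` — helix receptor and helical peptide 60 Å apart (no
  interface);
* ``random`` — seeded uniformly scattered pseudo-atoms (30 + 20 glycine
  residues, 200 atoms) in overlapping boxes, for brute-force contact
  oracles;
* ``multi_model`` — the helix complex as MODEL 1 plus a translated MODEL 2,
  for first-model-only parsing tests.

All chains are polyglycine (backbone N, CA, C, O only): secondary structure
and hydrogen bonds depend on backbone geometry, not side chains. Output is
byte-deterministic for a fixed (kind, seed).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import PepkitError
from .pdbio import format_atom_line, format_ter_line

__all__ = ["make_fixture_complex", "FIXTURE_KINDS", "TWO_ATOM_GAP"]

FIXTURE_KINDS = ("helix", "extended", "two_atom", "far_apart", "random",
                 "multi_model")

#: the stated closest peptide/protein distance in the two_atom fixture (Å)
TWO_ATOM_GAP = 3.5

_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231

HELIX_PHI_PSI = (-57.0, -47.0)
EXTENDED_PHI_PSI = (-140.0, 135.0)


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF: position of the atom bonded to ``c`` given a-b-c and internal
    coordinates (degrees)."""
    angle = np.deg2rad(angle)
    torsion = np.deg2rad(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(angle),
                  bond * np.cos(torsion) * np.sin(angle),
                  bond * np.sin(torsion) * np.sin(angle)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def ideal_backbone(n_res: int, phi: float, psi: float,
                   omega: float = 180.0) -> list[dict[str, np.ndarray]]:
    """Backbone (N, CA, C, O) coordinates for an ideal-geometry chain."""
    first_n = np.array([0.0, 0.0, 0.0])
    first_ca = np.array([_BOND_N_CA, 0.0, 0.0])
    first_c = _place(np.array([0.0, 1.0, 0.0]), first_n, first_ca,
                     _BOND_CA_C, 111.0, 0.0)
    residues = [{"N": first_n, "CA": first_ca, "C": first_c}]
    for _ in range(1, n_res):
        prev = residues[-1]
        n = _place(prev["N"], prev["CA"], prev["C"], _BOND_C_N, 116.2, psi)
        ca = _place(prev["CA"], prev["C"], n, _BOND_N_CA, 121.7, omega)
        c = _place(prev["C"], n, ca, _BOND_CA_C, 111.0, phi)
        residues.append({"N": n, "CA": ca, "C": c})
    for i, res in enumerate(residues):
        if i + 1 < len(residues):
            res["O"] = _place(residues[i + 1]["N"], res["CA"], res["C"],
                              _BOND_C_O, 120.5, 180.0)
        else:
            res["O"] = _place(res["N"], res["CA"], res["C"],
                              _BOND_C_O, 120.5, -45.0)
    return residues


def _shift(residues, offset):
    offset = np.asarray(offset, dtype=float)
    return [{k: v + offset for k, v in res.items()} for res in residues]


def _chain_lines(chain_id: str, residues, serial: int,
                 res_name: str = "GLY") -> tuple[list[str], int]:
    lines = []
    for i, res in enumerate(residues, start=1):
        for name in ("N", "CA", "C", "O"):
            x, y, z = res[name]
            lines.append(format_atom_line(serial, name, res_name, chain_id,
                                          i, x, y, z, name[0]))
            serial += 1
    lines.append(format_ter_line(serial, res_name, chain_id, len(residues)))
    return lines, serial + 1


def _helix_chains(peptide_offset_z: float):
    receptor = ideal_backbone(16, *HELIX_PHI_PSI)
    peptide = _shift(ideal_backbone(12, *HELIX_PHI_PSI),
                     (0.0, 0.0, peptide_offset_z))
    return receptor, peptide


def _axis_residue(xs: tuple[float, ...]) -> dict[str, np.ndarray]:
    names = ("N", "CA", "C", "O")
    return {nm: np.array([x, 0.0, 0.0]) for nm, x in zip(names, xs)}


def make_fixture_complex(kind: str, seed: int = 0,
                         path: str | Path = "fixture.pdb") -> Path:
    """Write one synthetic complex PDB; returns the path written."""
    if kind not in FIXTURE_KINDS:
        raise PepkitError(
            f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    path = Path(path)
    lines: list[str] = []
    serial = 1

    if kind in ("helix", "extended", "far_apart", "multi_model"):
        if kind == "extended":
            receptor = ideal_backbone(16, *HELIX_PHI_PSI)
            peptide = _shift(ideal_backbone(3, *EXTENDED_PHI_PSI),
                             (0.0, 0.0, 20.0))
        else:
            offset = 60.0 if kind == "far_apart" else 20.0
            receptor, peptide = _helix_chains(offset)
        if kind == "multi_model":
            for imodel, shift in enumerate(((0.0, 0.0, 0.0),
                                            (100.0, 0.0, 0.0)), start=1):
                lines.append(f"MODEL     {imodel:4d}")
                serial = 1
                ch_a, serial = _chain_lines("A", _shift(receptor, shift),
                                            serial)
                ch_b, serial = _chain_lines("B", _shift(peptide, shift),
                                            serial)
                lines.extend(ch_a + ch_b)
                lines.append("ENDMDL")
        else:
            ch_a, serial = _chain_lines("A", receptor, serial)
            ch_b, serial = _chain_lines("B", peptide, serial)
            lines.extend(ch_a + ch_b)

    elif kind == "two_atom":
        receptor = [_axis_residue((0.0, -1.5, -3.0, -4.5))]
        peptide = [_axis_residue((TWO_ATOM_GAP, TWO_ATOM_GAP + 1.5,
                                  TWO_ATOM_GAP + 3.0, TWO_ATOM_GAP + 4.5))]
        ch_a, serial = _chain_lines("A", receptor, serial)
        ch_b, serial = _chain_lines("B", peptide, serial)
        lines.extend(ch_a + ch_b)
        # interface waters: would add contacts if solvent were not excluded
        for i, x in enumerate((1.0, 2.0, 4.5), start=1):
            lines.append(format_atom_line(serial, "O", "HOH", "W", i,
                                          x, 1.0, 0.0, "O",
                                          record="HETATM"))
            serial += 1

    elif kind == "random":
        rng = np.random.default_rng(seed)
        lines_a: list[str] = []
        for chain_id, n_res, lo, hi in (("A", 30, 0.0, 20.0),
                                        ("B", 20, 10.0, 30.0)):
            for i in range(1, n_res + 1):
                for name in ("N", "CA", "C", "O"):
                    x, y, z = rng.uniform(lo, hi, size=3)
                    lines_a.append(format_atom_line(
                        serial, name, "GLY", chain_id, i,
                        round(x, 3), round(y, 3), round(z, 3), name[0]))
                    serial += 1
            lines_a.append(format_ter_line(serial, "GLY", chain_id, n_res))
            serial += 1
        lines.extend(lines_a)

    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
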