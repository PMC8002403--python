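"""Pinned per-monomer constants: the single source of truth.

Every number used by the sequence-level calculators lives here so that tests
can pin exact values and reports can cite one provenance string per table:

* average molecular masses of the free amino acids (IUPAC atomic weights);
* side-chain pKa values from the Lehninger table, with the charge sign the
  group carries when ionized (+1 for bases, -1 for acids); free-termini pKa
  are pinned at 9.0 (alpha-amino) and 2.0 (alpha-carboxyl);
* Eisenberg consensus hydrophobicity values;
* categorical flags: charged = {D, E, K, R, H}, hydrophobic =
  {A, I, L, M, F, W, V, Y}, aromatic = {F, W, Y};
* side-chain SMILES fragments (attached at the alpha carbon) together with
  their heavy-atom PDB names in fragment order, used by the SMILES builder
  and the PDB writer;
* maximum accessible surface areas (theoretical values of Tien et al. 2013)
  used to normalise raw ASA to relative ASA.

D-amino acids are registered as ``dX`` counterparts of the 20 canonical
L-entries: identical composition-level constants, mirrored stereochemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: provenance identifiers recorded in report metadata
PKA_TABLE_ID = "lehninger"
HYDROPHOBICITY_SCALE_ID = "eisenberg-consensus"
MAX_ASA_TABLE_ID = "tien-2013-theoretical"

#: free-termini ionization constants (pKa, sign when ionized)
N_TERM_PKA = 9.0
C_TERM_PKA = 2.0


@dataclass(frozen=True)
class MonomerRecord:
    """Constants for one registered monomer."""

    code: str                  # "A" for L-Ala, "dA" for D-Ala
    name3: str                 # three-letter residue name (PDB style)
    mass: float                # average mass of the free amino acid, g/mol
    eisenberg: float           # consensus hydrophobicity (dimensionless)
    pka: float | None          # side-chain pKa, None if not ionizable
    charge_sign: int | None    # +1 (base) / -1 (acid) when ionized
    charged: bool
    hydrophobic: bool
    aromatic: bool
    smiles_sidechain: str      # fragment attached at CA ("" for Gly)
    sidechain_atom_names: tuple[str, ...] = field(default=())

    @property
    def is_d(self) -> bool:
        return self.code.startswith("d")

    @property
    def letter(self) -> str:
        """Canonical one-letter code of the L-parent."""
        return self.code[-1]


# code: (name3, mass, eisenberg, pka, sign, charged, hydrophobic, aromatic,
#        sidechain smiles, sidechain atom names)
_CANONICAL = {
    "A": ("ALA",  89.09,  0.62, None,  None, False, True,  False,
          "C", ("CB",)),
    "R": ("ARG", 174.20, -2.53, 12.48, +1,   True,  False, False,
          "CCCNC(=N)N", ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2")),
    "N": ("ASN", 132.12, -0.78, None,  None, False, False, False,
          "CC(N)=O", ("CB", "CG", "ND2", "OD1")),
    "D": ("ASP", 133.10, -0.90, 3.65,  -1,   True,  False, False,
          "CC(=O)O", ("CB", "CG", "OD1", "OD2")),
    "C": ("CYS", 121.16,  0.29, 8.18,  -1,   False, False, False,
          "CS", ("CB", "SG")),
    "Q": ("GLN", 146.15, -0.85, None,  None, False, False, False,
          "CCC(N)=O", ("CB", "CG", "CD", "NE2", "OE1")),
    "E": ("GLU", 147.13, -0.74, 4.25,  -1,   True,  False, False,
          "CCC(=O)O", ("CB", "CG", "CD", "OE1", "OE2")),
    "G": ("GLY",  75.07,  0.48, None,  None, False, False, False,
          "", ()),
    "H": ("HIS", 155.15, -0.40, 6.00,  +1,   True,  False, False,
          "Cc1c[nH]cn1", ("CB", "CG", "CD2", "NE2", "CE1", "ND1")),
    "I": ("ILE", 131.17,  1.38, None,  None, False, True,  False,
          "[C@@H](C)CC", ("CB", "CG2", "CG1", "CD1")),
    "L": ("LEU", 131.17,  1.06, None,  None, False, True,  False,
          "CC(C)C", ("CB", "CG", "CD1", "CD2")),
    "K": ("LYS", 146.19, -1.50, 10.53, +1,   True,  False, False,
          "CCCCN", ("CB", "CG", "CD", "CE", "NZ")),
    "M": ("MET", 149.21,  0.64, None,  None, False, True,  False,
          "CCSC", ("CB", "CG", "SD", "CE")),
    "F": ("PHE", 165.19,  1.19, None,  None, False, True,  True,
          "Cc1ccccc1", ("CB", "CG", "CD1", "CE1", "CZ", "CE2", "CD2")),
    "P": ("PRO", 115.13,  0.12, None,  None, False, False, False,
          # proline's "side chain" closes onto the backbone nitrogen; the
          # SMILES builder handles the ring, these are the ring carbons
          "CCC", ("CB", "CG", "CD")),
    "S": ("SER", 105.09, -0.18, None,  None, False, False, False,
          "CO", ("CB", "OG")),
    "T": ("THR", 119.12, -0.05, None,  None, False, False, False,
          "[C@H](O)C", ("CB", "OG1", "CG2")),
    "W": ("TRP", 204.23,  0.81, None,  None, False, True,  True,
          "Cc1c[nH]c2ccccc12",
          ("CB", "CG", "CD1", "NE1", "CE2", "CZ2", "CH2", "CZ3", "CE3",
           "CD2")),
    "Y": ("TYR", 181.19,  0.26, 10.07, -1,   False, True,  True,
          "Cc1ccc(O)cc1", ("CB", "CG", "CD1", "CE1", "CZ", "OH", "CE2",
                           "CD2")),
    "V": ("VAL", 117.15,  1.08, None,  None, False, True,  False,
          "C(C)C", ("CB", "CG1", "CG2")),
}


def _build_table() -> dict[str, MonomerRecord]:
    table: dict[str, MonomerRecord] = {}
    for code, (name3, mass, eis, pka, sign, chg, hyd, aro, smi,
               names) in _CANONICAL.items():
        table[code] = MonomerRecord(code, name3, mass, eis, pka, sign,
                                    chg, hyd, aro, smi, tuple(names))
        # D-counterpart: same scalar constants, D-prefixed three-letter name
        table["d" + code] = MonomerRecord(
            "d" + code, "D" + name3[:2], mass, eis, pka, sign,
            chg, hyd, aro, smi, tuple(names))
    return table


#: the registered monomer table (20 canonical L entries + 20 D counterparts)
MONOMERS: dict[str, MonomerRecord] = _build_table()

#: canonical one-letter alphabet, alphabetically sorted
CANONICAL_ALPHABET: tuple[str, ...] = tuple(sorted(_CANONICAL))

#: three-letter -> one-letter lookup for the canonical entries
NAME3_TO_CODE: dict[str, str] = {
    rec.name3: code for code, rec in MONOMERS.items() if not rec.is_d
}

# Maximum ASA per residue (A^2), theoretical values; used for rASA.
MAX_ASA: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}
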