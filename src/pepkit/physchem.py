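"""Sequence- and SMILES-derived physico-chemical descriptors.

Two families of descriptors are computed:

* **sequence-based** — Henderson–Hasselbalch net charge (summed fractional
  charges of ionizable side chains plus the free termini), summed Eisenberg
  hydrophobicity, and the ProtParam statistics (aromaticity, instability
  index, isoelectric point). The isoelectric point is found by bisection on
  this module's own net-charge function, so ``net_charge(p, pI(p)) ~ 0`` holds
  by construction.
* **SMILES-based** — average molecular weight, Crippen/Wildman logP and
  Lipinski hydrogen-bond donor/acceptor counts, computed with RDKit on the
  peptide SMILES built by :mod:`pepkit.core`.

All composition-level descriptors see D-residues as their L-parent (they are
stereochemistry-blind).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

from . import core
from .core import Peptide
from .errors import ChemistryError, DomainError, InstabilityUndefinedError
from .monomers import (
    C_TERM_PKA,
    HYDROPHOBICITY_SCALE_ID,
    N_TERM_PKA,
    PKA_TABLE_ID,
)

__all__ = [
    "PropertyReport",
    "net_charge",
    "hydrophobicity",
    "isoelectric_point",
    "instability_index",
    "aromaticity",
    "protparam_properties",
    "smiles_descriptors",
    "compute_report",
]

#: donor/acceptor counting convention recorded in report metadata
HBOND_CONVENTION = "rdkit-lipinski"

#: bisection settings for the isoelectric point
_PI_TOL = 1e-4
_PI_MAX_ITER = 64


def net_charge(p: Peptide | str, pH: float = 7.0) -> float:
    """Henderson–Hasselbalch net charge at the given pH.

    Each basic group (Arg, Lys, His side chains; the free alpha-amino
    terminus) contributes ``+1 / (1 + 10**(pH - pKa))``; each acidic group
    (Asp, Glu, Cys, Tyr side chains; the free alpha-carboxyl terminus)
    contributes ``-1 / (1 + 10**(pKa - pH))``.
    """
    if not 0.0 <= pH <= 14.0:
        raise DomainError(f"pH must be in [0, 14], got {pH}")
    p = core._as_peptide(p)
    charge = 1.0 / (1.0 + 10.0 ** (pH - N_TERM_PKA))
    charge -= 1.0 / (1.0 + 10.0 ** (C_TERM_PKA - pH))
    for rec in p.records:
        if rec.pka is None:
            continue
        if rec.charge_sign > 0:
            charge += 1.0 / (1.0 + 10.0 ** (pH - rec.pka))
        else:
            charge -= 1.0 / (1.0 + 10.0 ** (rec.pka - pH))
    return charge


def hydrophobicity(p: Peptide | str) -> float:
    """Summed Eisenberg consensus hydrophobicity over all residues."""
    p = core._as_peptide(p)
    return sum(rec.eisenberg for rec in p.records)


def aromaticity(p: Peptide | str) -> float:
    """Fraction of aromatic residues (Phe, Trp, Tyr), in [0, 1]."""
    p = core._as_peptide(p)
    return sum(rec.aromatic for rec in p.records) / len(p)


def instability_index(p: Peptide | str) -> float:
    """ProtParam instability index: ``(10/L) * sum DIWV(x_i, x_{i+1})``.

    Delegates the DIWV dipeptide-weight lookup to Biopython's ProtParam
    implementation. Peptides shorter than two residues have no dipeptide and
    raise :class:`InstabilityUndefinedError`.
    """
    from Bio.SeqUtils.ProtParam import ProteinAnalysis

    p = core._as_peptide(p)
    if len(p) < 2:
        raise InstabilityUndefinedError(
            "instability index needs at least 2 residues")
    return ProteinAnalysis(p.letters).instability_index()


def isoelectric_point(p: Peptide | str) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    The net charge is monotonically non-increasing in pH and is positive at
    pH 0 (full protonation) and negative at pH 14 (the termini guarantee
    both signs), so a root always exists. Bisection runs until
    ``|charge| < 1e-4`` or 64 iterations.
    """
    p = core._as_peptide(p)
    lo, hi = 0.0, 14.0
    mid = 7.0
    for _ in range(_PI_MAX_ITER):
        mid = 0.5 * (lo + hi)
        q = net_charge(p, mid)
        if abs(q) < _PI_TOL:
            break
        if q > 0:
            lo = mid
        else:
            hi = mid
    return mid


def protparam_properties(p: Peptide | str) -> dict:
    """The three ProtParam-style statistics as one dictionary.

    For single-residue peptides the instability index is undefined and
    reported as ``None``; the other two fields are still returned.
    """
    p = core._as_peptide(p)
    try:
        ii = instability_index(p)
    except InstabilityUndefinedError:
        ii = None
    return {
        "aromaticity": aromaticity(p),
        "instability_index": ii,
        "isoelectric_point": isoelectric_point(p),
    }


def smiles_descriptors(smiles: str) -> dict:
    """Molecular weight, Crippen logP and H-bond donor/acceptor counts.

    Uses RDKit: average molecular weight (implicit hydrogens included),
    Wildman–Crippen atom-contribution logP, and the Lipinski donor/acceptor
    definitions (recorded as ``rdkit-lipinski`` in report metadata).
    """
    from rdkit import Chem
    from rdkit.Chem import Crippen, Descriptors, Lipinski

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemistryError(f"unparseable SMILES: {smiles!r}")
    return {
        "molecular_weight": Descriptors.MolWt(mol),
        "crippen_logp": Crippen.MolLogP(mol),
        "n_hbond_donors": Lipinski.NumHDonors(mol),
        "n_hbond_acceptors": Lipinski.NumHAcceptors(mol),
    }


@dataclass(frozen=True)
class PropertyReport:
    """The full per-peptide descriptor roster plus rule-failure counts."""

    sequence: str
    net_charge: float
    molecular_weight: float
    crippen_logp: float
    hydrophobicity_eisenberg: float
    aromaticity: float
    instability_index: float | None
    isoelectric_point: float
    n_hbond_donors: int
    n_hbond_acceptors: int
    n_solubility_rules_failed: int
    n_synthesis_rules_failed: int

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def metadata() -> dict:
        """Provenance of the pinned constants behind the numbers."""
        return {
            "pka_table": PKA_TABLE_ID,
            "n_term_pka": N_TERM_PKA,
            "c_term_pka": C_TERM_PKA,
            "hydrophobicity_scale": HYDROPHOBICITY_SCALE_ID,
            "hbond_convention": HBOND_CONVENTION,
            "charge_pH": 7.0,
        }


def compute_report(p: Peptide | str, pH: float = 7.0) -> PropertyReport:
    """Compute the full :class:`PropertyReport` for one peptide."""
    from . import rules  # local import: rules also uses net_charge

    p = core._as_peptide(p)
    smi = core.to_smiles(p)
    desc = smiles_descriptors(smi)
    pp = protparam_properties(p)
    rule_report = rules.check_all_rules(p)
    return PropertyReport(
        sequence=p.sequence,
        net_charge=net_charge(p, pH),
        molecular_weight=desc["molecular_weight"],
        crippen_logp=desc["crippen_logp"],
        hydrophobicity_eisenberg=hydrophobicity(p),
        aromaticity=pp["aromaticity"],
        instability_index=pp["instability_index"],
        isoelectric_point=pp["isoelectric_point"],
        n_hbond_donors=desc["n_hbond_donors"],
        n_hbond_acceptors=desc["n_hbond_acceptors"],
        n_solubility_rules_failed=rule_report.n_solubility_failed,
        n_synthesis_rules_failed=rule_report.n_synthesis_failed,
    )
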