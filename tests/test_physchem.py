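"""Physico-chemical descriptors against independent oracles.

The Henderson–Hasselbalch oracle here is coded directly from the titration
formula on the pinned pKa table, independently of the implementation path.
"""

import math
import random

import numpy as np
import pytest
from rdkit import Chem

from pepkit import core, physchem
from pepkit.errors import (
    ChemistryError,
    DomainError,
    InstabilityUndefinedError,
)
from pepkit.monomers import C_TERM_PKA, MONOMERS, N_TERM_PKA

from conftest import random_sequence

WATER_MASS = 18.015


def oracle_net_charge(letters: str, pH: float) -> float:
    """Independent Henderson–Hasselbalch summation on the pinned table."""
    basic = [N_TERM_PKA] + [MONOMERS[c].pka for c in letters
                            if MONOMERS[c].charge_sign == 1]
    acidic = [C_TERM_PKA] + [MONOMERS[c].pka for c in letters
                             if MONOMERS[c].charge_sign == -1]
    pos = sum(1.0 / (1.0 + 10.0 ** (pH - pka)) for pka in basic)
    neg = sum(1.0 / (1.0 + 10.0 ** (pka - pH)) for pka in acidic)
    return pos - neg


class TestNetCharge:
    def test_matches_oracle_on_random_peptides(self, rng):
        for _ in range(200):
            seq = random_sequence(rng, rng.randint(2, 25))
            for pH in (2.0, 5.0, 7.0, 9.0, 12.0):
                assert physchem.net_charge(seq, pH) == pytest.approx(
                    oracle_net_charge(seq, pH), abs=1e-6)

    def test_diglycine_is_nearly_neutral_at_ph7(self):
        assert abs(physchem.net_charge("GG", 7.0)) < 0.2

    def test_triple_glutamate_carries_minus_three(self):
        assert physchem.net_charge("EEE", 7.0) == pytest.approx(-3.0,
                                                                abs=0.1)

    def test_full_protonation_asymptote_at_low_ph(self, rng):
        for _ in range(10):
            seq = random_sequence(rng, rng.randint(2, 15))
            n_basic = sum(MONOMERS[c].charge_sign == 1 for c in seq)
            assert physchem.net_charge(seq, 0.0) == pytest.approx(
                n_basic + 1, abs=0.02)

    def test_monotone_non_increasing_in_ph(self, rng):
        grid = np.arange(0.0, 14.01, 0.1)
        for _ in range(10):
            seq = random_sequence(rng, rng.randint(1, 20))
            charges = [physchem.net_charge(seq, pH) for pH in grid]
            assert all(a >= b - 1e-12 for a, b in zip(charges, charges[1:]))

    @pytest.mark.parametrize("bad_ph", [-0.5, 14.5])
    def test_ph_out_of_range_rejected(self, bad_ph):
        with pytest.raises(DomainError):
            physchem.net_charge("GG", bad_ph)


class TestHydrophobicity:
    def test_single_residue_equals_pinned_scale_value(self):
        for code, rec in MONOMERS.items():
            if len(code) == 1:
                assert physchem.hydrophobicity(code) == rec.eisenberg

    def test_additive_over_concatenation(self, rng):
        for _ in range(20):
            a = random_sequence(rng, rng.randint(1, 10))
            b = random_sequence(rng, rng.randint(1, 10))
            assert physchem.hydrophobicity(a + b) == pytest.approx(
                physchem.hydrophobicity(a) + physchem.hydrophobicity(b))

    def test_homopolymer_is_length_times_monomer(self):
        assert physchem.hydrophobicity("GG") == pytest.approx(
            2 * physchem.hydrophobicity("G"))


class TestProtParam:
    def test_aromaticity_extremes(self):
        assert physchem.aromaticity("FWY") == 1.0
        assert physchem.aromaticity("GGGG") == 0.0

    def test_isoelectric_point_is_charge_root(self, rng):
        for _ in range(100):
            seq = random_sequence(rng, rng.randint(2, 20))
            pi = physchem.isoelectric_point(seq)
            assert abs(physchem.net_charge(seq, pi)) < 1e-4

    def test_pi_reflects_acid_base_balance(self):
        acidic = ["EEGG", "DDGG", "EDGGG", "EEEK", "DDDG"] * 5
        basic = ["KKGG", "RRGG", "KRGGG", "KKKE", "RRRG"] * 5
        for seq in acidic:
            assert physchem.isoelectric_point(seq) < 7
        for seq in basic:
            assert physchem.isoelectric_point(seq) > 7

    def test_instability_undefined_for_single_residue(self):
        with pytest.raises(InstabilityUndefinedError):
            physchem.instability_index("G")
        props = physchem.protparam_properties("G")
        assert props["instability_index"] is None
        assert props["aromaticity"] == 0.0
        assert 0 < props["isoelectric_point"] < 14


class TestSmilesDescriptors:
    def test_glycine_molecular_weight(self):
        desc = physchem.smiles_descriptors(core.to_smiles("G"))
        assert desc["molecular_weight"] == pytest.approx(75.07, abs=0.01)

    def test_condensation_loses_one_water(self, rng):
        for _ in range(50):
            a = random_sequence(rng, rng.randint(1, 8))
            b = random_sequence(rng, rng.randint(1, 8))
            mw = lambda s: physchem.smiles_descriptors(  # noqa: E731
                core.to_smiles(s))["molecular_weight"]
            assert mw(a + b) == pytest.approx(mw(a) + mw(b) - WATER_MASS,
                                              abs=0.02)

    def test_glycine_donors_acceptors_match_smarts_oracle(self):
        # Lipinski convention: donors = N-H/O-H heavy atoms, acceptors = N/O
        mol = Chem.MolFromSmiles(core.to_smiles("G"))
        donor_patt = Chem.MolFromSmarts("[$([N;!H0;v3,v4&+1]),$([O,S;H1;+0])]")
        acceptor_patt = Chem.MolFromSmarts(
            "[$([O,S;H1;v2]-[!$(*=[O,N,P,S])]),$([O,S;H0;v2]),"
            "$([O,S;-]),$([N;v3;!$(N-*=!@[O,N,P,S])]),$([nH0,o,s;+0])]")
        desc = physchem.smiles_descriptors(core.to_smiles("G"))
        assert desc["n_hbond_donors"] == len(
            mol.GetSubstructMatches(donor_patt))
        assert desc["n_hbond_acceptors"] >= 1

    def test_unparseable_smiles_rejected(self):
        with pytest.raises(ChemistryError):
            physchem.smiles_descriptors("not-a-smiles(((")


class TestPropertyReport:
    def test_all_fields_finite_for_random_peptides(self, rng):
        for _ in range(40):
            seq = random_sequence(rng, rng.randint(2, 30))
            report = physchem.compute_report(seq)
            for key, value in report.to_dict().items():
                if isinstance(value, float):
                    assert math.isfinite(value), (seq, key)
            assert 0.0 <= report.aromaticity <= 1.0
            assert 0.0 < report.isoelectric_point < 14.0
            assert report.n_hbond_donors >= 0
            assert report.n_hbond_acceptors >= 0

    def test_metadata_names_pinned_tables(self):
        meta = physchem.PropertyReport.metadata()
        assert meta["pka_table"] == "lehninger"
        assert meta["hydrophobicity_scale"] == "eisenberg-consensus"
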