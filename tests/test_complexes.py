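"""Complex parsing, contacts, DSSP-style annotation and hydrogen-bond
graphs — all on generated synthetic fixtures."""

import numpy as np
import pytest

from pepkit import complexes
from pepkit.errors import ChainNotFoundError, DomainError
from pepkit.fixtures import TWO_ATOM_GAP, make_fixture_complex


def brute_force_total(model, threshold):
    pep = np.concatenate([r.coords for r in model.peptide_residues])
    prot = np.concatenate([r.coords for r in model.protein_residues])
    d = np.linalg.norm(pep[:, None] - prot[None, :], axis=2)
    return int((d <= threshold).sum())


def brute_force_profile(model, threshold):
    prot = np.concatenate([r.coords for r in model.protein_residues])
    counts = []
    for res in model.peptide_residues:
        d = np.linalg.norm(res.coords[:, None] - prot[None, :], axis=2)
        counts.append(int((d <= threshold).sum()))
    return tuple(counts)


class TestLoading:
    def test_chain_roles_assigned(self, helix_pdb):
        model = complexes.load_complex(helix_pdb, "B")
        assert sorted(model.chains) == ["A", "B"]
        assert model.peptide_chain_id == "B"
        assert len(model.peptide_residues) == 12
        assert len(model.protein_residues) == 16

    def test_missing_chain_rejected(self, helix_pdb):
        with pytest.raises(ChainNotFoundError):
            complexes.load_complex(helix_pdb, "Z")

    def test_multi_model_keeps_first_model_only(self, tmp_path):
        path = make_fixture_complex("multi_model", 0, tmp_path / "mm.pdb")
        model = complexes.load_complex(path, "B")
        assert len(model.peptide_residues) == 12
        assert len(model.protein_residues) == 16
        # model 2 is translated by +100 Å in x; model 1 stays near origin
        assert model.peptide_residues[0].coords[:, 0].max() < 50.0

    def test_waters_excluded_from_model(self, two_atom_pdb):
        model = complexes.load_complex(two_atom_pdb, "B")
        assert "W" not in model.chains


class TestContacts:
    def test_two_atom_fixture_thresholds(self, two_atom_pdb):
        model = complexes.load_complex(two_atom_pdb, "B")
        assert complexes.count_contacts(model, 4.0).total == 1
        assert complexes.count_contacts(model, 3.0).total == 0
        # the interface waters sit ~2.5 Å from peptide atoms but never count
        assert complexes.count_contacts(model, TWO_ATOM_GAP).total == 1

    def test_profile_matches_brute_force_oracle(self):
        import tempfile
        from pathlib import Path

        with tempfile.TemporaryDirectory() as tmp:
            for seed in range(20):
                path = make_fixture_complex("random", seed,
                                            Path(tmp) / f"r{seed}.pdb")
                model = complexes.load_complex(path, "B")
                for t in (3.0, 4.0, 5.0):
                    profile = complexes.count_contacts(model, t)
                    assert profile.counts == brute_force_profile(model, t)

    def test_monotone_in_threshold(self, helix_pdb):
        model = complexes.load_complex(helix_pdb, "B")
        totals = [complexes.count_contacts(model, t).total
                  for t in (2.0, 3.0, 4.0, 5.0, 6.0)]
        assert totals == sorted(totals)

    def test_symmetry_of_pair_counts(self, tmp_path):
        # pairs counted peptide→protein equal protein→peptide
        path = make_fixture_complex("random", 3, tmp_path / "r.pdb")
        model = complexes.load_complex(path, "B")
        profile = complexes.count_contacts(model, 4.0)
        swapped = complexes.ComplexModel(model.path, model.chains, "A")
        reverse = complexes.count_contacts(swapped, 4.0)
        assert profile.total == reverse.total == brute_force_total(model, 4.0)

    def test_nonpositive_threshold_rejected(self, helix_pdb):
        model = complexes.load_complex(helix_pdb, "B")
        with pytest.raises(DomainError):
            complexes.count_contacts(model, 0.0)

    def test_contacting_atom_mode_bounded_by_pair_mode(self, tmp_path):
        path = make_fixture_complex("random", 9, tmp_path / "r.pdb")
        model = complexes.load_complex(path, "B")
        pairs = complexes.count_contacts(model, 5.0)
        atoms = complexes.count_contacts(model, 5.0, count_atoms=True)
        for n_atoms, n_pairs in zip(atoms.counts, pairs.counts):
            assert n_atoms <= n_pairs


class TestAnnotation:
    def test_helical_peptide_core_coded_h(self, helix_pdb):
        model = complexes.load_complex(helix_pdb, "B")
        annotation = complexes.annotate_structure(model)["B"]
        assert len(annotation) == 12
        core_codes = [a.ss_code for a in annotation[2:10]]
        assert sum(c == "H" for c in core_codes) >= 6

    def test_extended_tripeptide_has_no_helix_codes(self, extended_pdb):
        model = complexes.load_complex(extended_pdb, "B")
        annotation = complexes.annotate_structure(model)["B"]
        assert len(annotation) == 3
        assert all(a.ss_code != "H" for a in annotation)

    def test_relative_asa_is_clamped_fraction(self, helix_pdb):
        model = complexes.load_complex(helix_pdb, "B")
        for chain in complexes.annotate_structure(model).values():
            for ann in chain:
                assert 0.0 <= ann.rel_asa <= 1.0
                assert ann.raw_asa >= 0.0

    def test_ss_codes_in_dssp_alphabet(self, helix_pdb):
        model = complexes.load_complex(helix_pdb, "B")
        for chain in complexes.annotate_structure(model).values():
            assert all(a.ss_code in set("HBEGITS-") for a in chain)


class TestHydrogenBondGraph:
    def test_far_apart_peptide_gives_isolated_peptide_nodes(
            self, far_apart_pdb):
        model = complexes.load_complex(far_apart_pdb, "B")
        ig = complexes.hydrogen_bond_graph(model)
        roles = {d["role"] for _, d in ig.graph.nodes(data=True)}
        assert ig.graph.number_of_edges() == 0
        assert roles == {"peptide"}
        assert ig.graph.number_of_nodes() == 12

    def test_helix_intra_peptide_bonds_are_i_to_i_plus_4(self, helix_pdb):
        model = complexes.load_complex(helix_pdb, "B")
        ig = complexes.hydrogen_bond_graph(model, include_intra_peptide=True)
        separations = set()
        for a, b in ig.graph.edges:
            na = ig.graph.nodes[a]
            nb = ig.graph.nodes[b]
            if na["chain"] == nb["chain"] == "B":
                separations.add(abs(na["number"] - nb["number"]))
        assert separations == {4}

    def test_edge_weights_count_bonds_per_pair(self, helix_pdb):
        model = complexes.load_complex(helix_pdb, "B")
        ig = complexes.hydrogen_bond_graph(model, include_intra_peptide=True)
        assert all(d["weight"] >= 1 for _, _, d in
                   ig.graph.edges(data=True))
        assert ig.n_bonds == sum(
            d["weight"] for _, _, d in ig.graph.edges(data=True))

    def test_layout_hint_follows_topology_flag(self, helix_pdb):
        model = complexes.load_complex(helix_pdb, "B")
        assert complexes.hydrogen_bond_graph(model).layout_hint == "linear"
        assert complexes.hydrogen_bond_graph(
            model, cyclic=True).layout_hint == "spring"

    def test_graph_exports(self, helix_pdb, tmp_path):
        import networkx as nx

        model = complexes.load_complex(helix_pdb, "B")
        ig = complexes.hydrogen_bond_graph(model, include_intra_peptide=True)
        gml = ig.to_graphml(tmp_path / "g.graphml")
        back = nx.read_graphml(str(gml))
        assert back.number_of_edges() == ig.graph.number_of_edges()
        dot = ig.to_dot(tmp_path / "g.dot")
        assert "--" in dot.read_text()


class TestRenderGraph:
    def test_empty_edge_graph_renders(self, far_apart_pdb, tmp_path):
        model = complexes.load_complex(far_apart_pdb, "B")
        ig = complexes.hydrogen_bond_graph(model)
        out = complexes.render_graph(ig, tmp_path / "empty.png")
        assert out.exists() and out.stat().st_size > 0

    def test_width_proportional_to_weight(self, helix_pdb, tmp_path):
        model = complexes.load_complex(helix_pdb, "B")
        ig = complexes.hydrogen_bond_graph(model, include_intra_peptide=True)
        complexes.render_graph(ig, tmp_path / "g.png")
        for _, _, d in ig.graph.edges(data=True):
            assert d["drawn_width"] == pytest.approx(1.5 * d["weight"])

    def test_layout_deterministic_for_fixed_seed(self, helix_pdb, tmp_path):
        model = complexes.load_complex(helix_pdb, "B")
        ig1 = complexes.hydrogen_bond_graph(model, cyclic=True,
                                            include_intra_peptide=True)
        complexes.render_graph(ig1, tmp_path / "a.png", layout_seed=5)
        pos1 = {n: (d["layout_x"], d["layout_y"])
                for n, d in ig1.graph.nodes(data=True)}
        ig2 = complexes.hydrogen_bond_graph(model, cyclic=True,
                                            include_intra_peptide=True)
        complexes.render_graph(ig2, tmp_path / "b.png", layout_seed=5)
        pos2 = {n: (d["layout_x"], d["layout_y"])
                for n, d in ig2.graph.nodes(data=True)}
        assert pos1 == pos2
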