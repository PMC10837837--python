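"""Solvent accessibility, secondary structure and interaction detection."""

import math

import numpy as np
import pandas as pd
import pytest

from ecosig.io_core import Atom, Residue, StructureModel
from ecosig.structure_features import (
    InteractionContact,
    aggregate_stability,
    assign_secondary_structure,
    annotate_structure,
    compute_sasa,
    detect_interactions,
    interaction_density,
    max_asa,
    percent_change,
    relative_accessibility,
    stratified_composition,
    vdw_radius,
)
from ecosig.synthetic_data import build_peptide, make_contact_fixture

from .oracles import brute_force_contacts


def single_atom_model(element="C"):
    return StructureModel("one", [Residue(1, "ALA", [Atom("CB", element, [0, 0, 0])])])


class TestSasa:
    def test_isolated_atom_closed_form(self):
        _, per_atom, _ = compute_sasa(single_atom_model())
        assert per_atom[0] == pytest.approx(4 * math.pi * (1.70 + 1.4) ** 2, rel=1e-9)

    def test_two_distant_atoms_unoccluded(self):
        d = 2 * (1.70 + 1.4) + 0.01
        m = StructureModel(
            "two",
            [
                Residue(1, "ALA", [Atom("CB", "C", [0, 0, 0])]),
                Residue(2, "ALA", [Atom("CB", "C", [d, 0, 0])]),
            ],
        )
        _, per_atom, _ = compute_sasa(m)
        full = 4 * math.pi * (1.70 + 1.4) ** 2
        np.testing.assert_allclose(per_atom, full, rtol=1e-9)

    def test_unknown_element_errors(self):
        with pytest.raises(ValueError, match="(?i)fe"):
            compute_sasa(single_atom_model("Fe"))

    def test_rigid_motion_invariance(self, rng):
        # total SASA within 0.5 %, per-residue within 2 % under random
        # rigid motions (point sampling is orientation-dependent at the
        # single-atom level)
        pep = build_peptide("MKVYAW", "helix")
        ref, _, _ = compute_sasa(pep, n_points=960)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = rng.uniform(-20, 20, 3)
        moved = StructureModel(
            pep.protein_id,
            [
                Residue(r.index, r.name, [Atom(a.name, a.element, q @ a.coord + t) for a in r.atoms])
                for r in pep.residues
            ],
        )
        rot, _, _ = compute_sasa(moved, n_points=960)
        assert abs(sum(rot.values()) - sum(ref.values())) / sum(ref.values()) < 0.005
        for idx in ref:
            assert abs(rot[idx] - ref[idx]) / max(ref[idx], 1.0) < 0.02

    def test_point_density_convergence(self):
        pep = build_peptide("MKVYAW", "strand")
        coarse, _, _ = compute_sasa(pep, n_points=240)
        fine, _, _ = compute_sasa(pep, n_points=960)
        for idx in coarse:
            assert abs(coarse[idx] - fine[idx]) / fine[idx] < 0.03

    def test_hydrogens_ignored(self):
        m1 = single_atom_model()
        m2 = StructureModel(
            "h", [Residue(1, "ALA", [Atom("CB", "C", [0, 0, 0]), Atom("HB1", "H", [1, 0, 0])])]
        )
        _, a1, _ = compute_sasa(m1)
        _, a2, _ = compute_sasa(m2)
        assert a1[0] == a2[0]


class TestRSA:
    def test_reference_conformation_is_one(self):
        for res in ("ALA", "GLY", "TRP", "ASP"):
            rsa, _ = relative_accessibility(max_asa(res), res)
            assert rsa == pytest.approx(1.0)

    def test_core_boundary_inclusive(self):
        ref = max_asa("ALA")
        assert relative_accessibility(0.20 * ref, "ALA")[1] == "core"
        assert relative_accessibility(0.21 * ref, "ALA")[1] == "surface"

    def test_unknown_residue_errors(self):
        with pytest.raises(ValueError):
            relative_accessibility(10.0, "XXX")

    def test_partition_is_exhaustive(self):
        pep = build_peptide("MKVYAWDE", "helix")
        ann = annotate_structure(pep, n_points=240)
        regions = [a.region for a in ann.values()]
        assert all(r in ("core", "surface") for r in regions)
        assert len(regions) == pep.n_residues


class TestSecondaryStructure:
    def test_ideal_helix(self):
        ss = assign_secondary_structure(build_peptide("A" * 30, "helix"))
        assert sum(1 for v in ss.values() if v == "H") >= 26

    def test_ideal_strand(self):
        ss = assign_secondary_structure(build_peptide("A" * 12, "strand"))
        assert sum(1 for v in ss.values() if v == "E") >= 8

    def test_short_peptide_all_loop(self):
        ss = assign_secondary_structure(build_peptide("AAA", "extended"))
        assert list(ss.values()) == ["C", "C", "C"]

    def test_chain_break_splits_runs(self):
        pep = build_peptide("A" * 10, "helix")
        # pull the second half 50 A away: torsions across the break are void
        for r in pep.residues[5:]:
            for a in r.atoms:
                a.coord = a.coord + np.array([50.0, 0.0, 0.0])
        ss = assign_secondary_structure(pep)
        assert sum(1 for v in ss.values() if v == "H") <= 8


class TestInteractions:
    @pytest.mark.parametrize(
        "itype,dist,expected",
        [
            ("disulfide", 2.0, True),
            ("disulfide", 2.2, True),
            ("disulfide", 2.3, False),
            ("ionic", 6.0, True),
            ("ionic", 6.1, False),
            ("aromatic_aromatic", 4.4, False),
            ("aromatic_aromatic", 4.5, True),
            ("aromatic_aromatic", 7.0, True),
            ("aromatic_aromatic", 7.1, False),
            ("aromatic_sulfur", 5.3, True),
            ("cation_pi", 6.0, True),
            ("hydrophobic", 5.0, True),
            ("hydrophobic", 5.1, False),
        ],
    )
    def test_fixture_truths(self, itype, dist, expected):
        model, truth = make_contact_fixture(itype, dist)
        assert truth is expected
        found = any(c.type == itype for c in detect_interactions(model))
        assert found is expected

    def test_matches_brute_force_on_peptides(self, rng):
        aa = list("AVLIMFWPYCDEKRHNQST")
        for _ in range(10):
            seq = "".join(rng.choice(aa, 12))
            pep = build_peptide(seq, "helix")
            ours = {(c.type, c.res_i, c.res_j) for c in detect_interactions(pep)}
            assert ours == brute_force_contacts(pep)

    def test_symmetric_under_atom_order(self, rng):
        pep = build_peptide("FKDCEMFYW", "helix")
        ref = {(c.type, c.res_i, c.res_j) for c in detect_interactions(pep)}
        shuffled = StructureModel(
            pep.protein_id,
            [
                Residue(r.index, r.name, [r.atoms[k] for k in rng.permutation(len(r.atoms))])
                for r in pep.residues
            ],
        )
        out = {(c.type, c.res_i, c.res_j) for c in detect_interactions(shuffled)}
        assert out == ref

    def test_one_contact_per_pair_per_type(self):
        pep = build_peptide("LALAL", "helix")
        contacts = detect_interactions(pep)
        keys = [(c.type, c.res_i, c.res_j) for c in contacts]
        assert len(keys) == len(set(keys))


class TestDensities:
    def test_density(self):
        contacts = [InteractionContact("ionic", i, i + 5, 4.0) for i in range(9)]
        assert interaction_density(contacts, 100)["ionic"] == pytest.approx(0.09)

    def test_zero_contacts(self):
        d = interaction_density([], 50)
        assert all(v == 0.0 for v in d.values())

    def test_invalid_length(self):
        with pytest.raises(ValueError):
            interaction_density([], 0)


class TestStratifiedComposition:
    def test_rows_sum_to_one(self):
        pep = build_peptide("MKVYAWDEKR", "helix")
        ann = annotate_structure(pep, n_points=240)
        freq, fractions, low = stratified_composition([(pep, ann)], low_support=5)
        for _, row in freq.iterrows():
            if not row.isna().all():
                assert row.sum() == pytest.approx(1.0)
        assert sum(fractions.values()) == pytest.approx(1.0)

    def test_single_stratum(self):
        # one residue, forced annotation: surface helix only
        from ecosig.structure_features import ResidueAnnotation

        pep = build_peptide("AAAA", "extended")
        ann = {
            r.index: ResidueAnnotation(r.index, 100.0, 0.9, "surface", "H")
            for r in pep.residues
        }
        freq, fractions, _ = stratified_composition([(pep, ann)], low_support=1)
        assert freq.loc["surface_H", "A"] == pytest.approx(1.0)
        assert freq.loc["core_H"].isna().all()
        assert fractions["H"] == 1.0


class TestStability:
    def test_mean(self):
        df = pd.DataFrame(
            {"protein_id": ["p", "p"], "residue_index": [1, 2], "S": [-0.1, -0.06]}
        )
        per_protein, _ = aggregate_stability(df)
        assert per_protein["p"] == pytest.approx(-0.08)

    def test_empty_table(self):
        df = pd.DataFrame(columns=["protein_id", "residue_index", "S"])
        per_protein, per_clade = aggregate_stability(df, protein_clades={})
        assert per_protein.empty and per_clade is None

    def test_unknown_residues_dropped(self, caplog):
        df = pd.DataFrame(
            {"protein_id": ["p"] * 3, "residue_index": [1, 2, 99], "S": [-0.1, -0.06, 5.0]}
        )
        with caplog.at_level("WARNING"):
            per_protein, _ = aggregate_stability(df, known_residues={"p": {1, 2}})
        assert per_protein["p"] == pytest.approx(-0.08)
        assert "1 score rows" in caplog.text

    def test_percent_change_direction(self):
        # stability score moving toward zero reads as a positive (destabilizing) change
        assert percent_change(-0.085, -0.090) == pytest.approx(5.56, abs=0.01)
        assert percent_change(-0.081, -0.071) == pytest.approx(-14.08, abs=0.01)


def test_vdw_table():
    assert vdw_radius("C") == 1.70
    assert vdw_radius("s") == 1.80
    with pytest.raises(ValueError):
        vdw_radius("Zn")
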