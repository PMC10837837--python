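"""Generators: determinism, format validity, planted-truth recovery."""

import warnings

import numpy as np
import pytest

from ecosig.genome_features import gc_content
from ecosig.io_core import read_fasta, read_gff3, read_pdb, read_newick, write_fasta, write_gff3, write_pdb
from ecosig.protein_sequence import mean_pairwise_identity
from ecosig.synthetic_data import (
    GenomeSimConfig,
    ProteomeSimConfig,
    build_peptide,
    make_aai_fixture,
    make_clade_genomes,
    make_clade_tree,
    make_contact_fixture,
    make_core_surface_fixture,
    make_protein_families,
    make_qc_metrics_fixture,
    per_protein_frequencies,
)
from .conftest import SMALL_CLADES


class TestDeterminism:
    def test_genomes_identical_across_calls(self, small_genome_config):
        g1 = make_clade_genomes(small_genome_config, seed=5)
        g2 = make_clade_genomes(small_genome_config, seed=5)
        assert g1.truth == g2.truth
        for iso in g1.genomes:
            assert g1.genomes[iso].contigs == g2.genomes[iso].contigs
            assert [
                (f.feature_type, f.contig_id, f.start, f.end, f.strand)
                for f in g1.annotations[iso].features
            ] == [
                (f.feature_type, f.contig_id, f.start, f.end, f.strand)
                for f in g2.annotations[iso].features
            ]

    def test_proteins_identical_across_calls(self, small_proteome_config):
        p1 = make_protein_families(small_proteome_config, seed=5)
        p2 = make_protein_families(small_proteome_config, seed=5)
        assert p1.proteins == p2.proteins
        for f in p1.surface_masks:
            assert (p1.surface_masks[f] == p2.surface_masks[f]).all()

    def test_seed_changes_output(self, small_proteome_config):
        p1 = make_protein_families(small_proteome_config, seed=5)
        p2 = make_protein_families(small_proteome_config, seed=6)
        assert p1.proteins != p2.proteins

    def test_peptide_builder_deterministic(self):
        a = build_peptide("MKWDE", "helix")
        b = build_peptide("MKWDE", "helix")
        for ra, rb in zip(a.residues, b.residues):
            for x, y in zip(ra.atoms, rb.atoms):
                assert (x.coord == y.coord).all()


class TestFormatValidity:
    def test_generated_files_pass_readers_without_warnings(self, small_genome_set, tmp_path):
        gs = small_genome_set
        iso = next(iter(gs.genomes))
        fa = tmp_path / f"{iso}.fa"
        gff = tmp_path / f"{iso}.gff"
        write_fasta(fa, gs.genomes[iso].contigs)
        write_gff3(gff, gs.annotations[iso])
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            records = read_fasta(fa)
            ann = read_gff3(gff, gs.genomes[iso])
        assert [r[0] for r in records] == [c[0] for c in gs.genomes[iso].contigs]
        assert len(ann) == len(gs.annotations[iso])

    def test_generated_pdb_round_trips(self, tmp_path):
        pep = build_peptide("MKVW", "strand")
        p = tmp_path / "pep.pdb"
        write_pdb(p, pep)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            model = read_pdb(p)
        assert model.n_residues == 4
        assert model.missing_backbone() == []

    def test_clade_tree_parses(self, tmp_path):
        nwk = make_clade_tree(
            {c: [f"{c}_{k}" for k in range(4)] for c in ("Ia", "Ib", "IIa", "IIb")},
            seed=3,
        )
        p = tmp_path / "t.nwk"
        p.write_text(nwk + "\n")
        tree = read_newick(p)
        assert len(tree.leaf_labels) == 16
        assert max(tree.leaf_depths().values()) < 0.5


class TestGenomeTruth:
    def test_realized_gc_concentrates(self):
        cfg = GenomeSimConfig(
            clades={"X": SMALL_CLADES["Ia"].__class__(
                1, 0.50, 10.0, 0.5, 0.3, 5.0, 20.0, 0.2, 0.0, 0.05, 0.60
            )},
            genome_length=100_000,
            n_cds=30,
        )
        gs = make_clade_genomes(cfg, seed=9)
        seq = "".join(s for _, s in gs.genomes["X_000"].contigs)
        assert 0.49 <= gc_content(seq) <= 0.51

    def test_counts_match_truth(self, small_genome_set):
        gs = small_genome_set
        for iso, ann in gs.annotations.items():
            c = ann.counts()
            t = gs.truth["isolates"][iso]
            assert c["sRNA"] == t["n_srna"]
            assert c["insertion_sequence"] == t["n_is"]
            assert c["CRISPR"] == t["n_crispr"]
            assert c["operon"] == t["n_operons"]
            assert c["CDS"] == t["n_cds"]

    def test_infeasible_packing_errors(self):
        cfg = GenomeSimConfig(clades=SMALL_CLADES, genome_length=5_000, n_cds=60)
        with pytest.raises(ValueError, match="infeasible packing"):
            make_clade_genomes(cfg, seed=0)

    def test_metadata_reflects_clade_habitat(self, small_genome_set):
        gs = small_genome_set
        by_clade = {}
        for m in gs.metadata:
            by_clade.setdefault(m.clade_label, []).append(m)
        assert np.mean([m.mat for m in by_clade["IIb"]]) > 40
        assert np.mean([m.mat for m in by_clade["Ib"]]) < 2
        assert np.mean([m.salinity for m in by_clade["Ia"]]) < 1
        assert np.mean([m.salinity for m in by_clade["IIa"]]) > 5


class TestProteomeTruth:
    def test_planted_identity_within_binomial_interval(self):
        cfg = ProteomeSimConfig(
            clades={"X": 5, "Y": 5},
            n_families=4,
            protein_length=300,
            length_jitter=0.0,
            identity_sd=0.0,
            shifts={"X": {}, "Y": {}},
        )
        ps = make_protein_families(cfg, seed=21)
        fams: dict[str, list[str]] = {}
        for pid, _iso, _clade, seq in ps.proteins:
            fams.setdefault(ps.protein_family[pid], []).append(seq)
        for seqs in fams.values():
            mean_id, _ = mean_pairwise_identity(seqs)
            assert 74.0 <= mean_id <= 86.0

    def test_zero_shift_compositions_match(self):
        cfg = ProteomeSimConfig(
            clades={"X": 100, "Y": 100},
            n_families=2,
            protein_length=300,
            length_jitter=0.0,
            shifts={"X": {}, "Y": {}},
        )
        ps = make_protein_families(cfg, seed=13)
        freq, clades = per_protein_frequencies(ps)
        fx = freq[clades == "X"].mean()
        fy = freq[clades == "Y"].mean()
        d = 100 * (fx - fy) / fy
        assert d.abs().max() < 3.0

    def test_negative_shift_frequency_rejected(self):
        cfg = ProteomeSimConfig(shifts={"Ia": {}, "Ib": {"W": -99.9}})
        with pytest.raises(ValueError, match="negative"):
            cfg.validate()

    def test_surface_restriction(self):
        cfg = ProteomeSimConfig(
            clades={"R": 50, "T": 50},
            n_families=2,
            protein_length=2000,
            length_jitter=0.0,
            surface_fraction=0.5,
            surface_only=True,
            shifts={"R": {}, "T": {"D": 10.0}},
        )
        ps = make_protein_families(cfg, seed=17)
        surf, clades = per_protein_frequencies(ps, region="surface")
        core, _ = per_protein_frequencies(ps, region="core")
        d_surf = 100 * (surf[clades == "T"]["D"].mean() - surf[clades == "R"]["D"].mean()) / surf[clades == "R"]["D"].mean()
        d_core = 100 * (core[clades == "T"]["D"].mean() - core[clades == "R"]["D"].mean()) / core[clades == "R"]["D"].mean()
        assert 8.0 <= d_surf <= 12.0
        assert abs(d_core) < 3.0


class TestStructureFixtures:
    @pytest.mark.parametrize(
        "itype,dist,expected",
        [
            ("disulfide", 2.0, True),
            ("aromatic_aromatic", 7.1, False),
            ("ionic", 6.0, True),
        ],
    )
    def test_contact_fixture_truth(self, itype, dist, expected):
        _, flag = make_contact_fixture(itype, dist)
        assert flag is expected

    def test_contact_fixture_invalid(self):
        with pytest.raises(ValueError):
            make_contact_fixture("disulfide", -1.0)
        with pytest.raises(ValueError):
            make_contact_fixture("magnetic", 3.0)

    def test_core_surface_requires_counts(self):
        with pytest.raises(ValueError):
            make_core_surface_fixture(0, 20)

    def test_core_surface_deterministic(self):
        a, _ = make_core_surface_fixture(3, 18)
        b, _ = make_core_surface_fixture(3, 18)
        for ra, rb in zip(a.residues, b.residues):
            for x, y in zip(ra.atoms, rb.atoms):
                assert (x.coord == y.coord).all()

    def test_gly_x_gly_self_consistency(self):
        # the extended reference build reproduces the maxASA values
        from ecosig.structure_features import compute_sasa, max_asa

        tri = build_peptide("GVG", "extended")
        per_res, _, _ = compute_sasa(tri)
        assert per_res[tri.residues[1].index] == pytest.approx(max_asa("VAL"))


class TestQCAndAAIFixtures:
    def test_qc_fixture_truth(self):
        from ecosig.genome_features import qc_filter

        metrics, passing = make_qc_metrics_fixture(50, 35, seed=3)
        assert len(passing) == 35
        recovered = {m.isolate_id for m in metrics if qc_filter(m)[0]}
        assert recovered == passing

    def test_aai_fixture_components(self):
        ids = [f"g{i}" for i in range(20)]
        aai, components = make_aai_fixture(ids, n_components=3, seed=4)
        assert len(components) == 3
        m = aai.to_numpy()
        assert np.allclose(m, m.T)
        for comp in components:
            idx = [ids.index(i) for i in comp]
            for a in idx:
                for b in idx:
                    if a != b:
                        assert m[a, b] >= 99.5
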