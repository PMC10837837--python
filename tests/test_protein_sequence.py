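"""Proteome composition, family clustering and signature arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecosig.protein_sequence import (
    AMINO_ACIDS,
    aa_frequencies,
    aa_ratio,
    alignment_identity_coverage,
    cluster_families,
    composition_signature,
    filter_families,
    gravy,
    isoelectric_point,
    ks_contrast,
    kyte_doolittle_scale,
    mean_pairwise_identity,
    net_charge,
)

AA_IDX = {a: i for i, a in enumerate(AMINO_ACIDS)}
peptides = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=60)


class TestFrequencies:
    def test_single_residue_type(self):
        f, skipped = aa_frequencies(["AAAA"])
        assert f[AA_IDX["A"]] == 1.0 and skipped == 0

    def test_pooled(self):
        f, _ = aa_frequencies(["AR", "AR"])
        assert f[AA_IDX["A"]] == pytest.approx(0.5)
        assert f[AA_IDX["R"]] == pytest.approx(0.5)

    def test_nonstandard_skipped(self):
        f, skipped = aa_frequencies(["AX"])
        assert f[AA_IDX["A"]] == 1.0 and skipped == 1

    @settings(max_examples=30, deadline=None)
    @given(st.lists(peptides, min_size=1, max_size=5))
    def test_pooling_equals_length_weighted_mean(self, seqs):
        pooled, _ = aa_frequencies(seqs)
        weighted = np.zeros(20)
        for s in seqs:
            f, _ = aa_frequencies([s])
            weighted += f * len(s)
        weighted /= sum(len(s) for s in seqs)
        np.testing.assert_allclose(pooled, weighted, atol=1e-12)


class TestGravy:
    @pytest.mark.parametrize("seq,expected", [("A", 1.8), ("R", -4.5), ("AR", -1.35)])
    def test_table_lookups(self, seq, expected):
        assert gravy(seq) == pytest.approx(expected)

    def test_equals_table_mean(self, rng):
        scale = kyte_doolittle_scale()
        for _ in range(20):
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(1, 50)))
            assert gravy(seq) == pytest.approx(np.mean([scale[c] for c in seq]))


class TestIsoelectricPoint:
    def test_defining_property(self):
        for seq in ("ACDEFGHIKLMNPQRSTVWY", "MKKLLE", "GGG"):
            assert abs(net_charge(seq, isoelectric_point(seq))) < 1e-4

    def test_acidic_and_basic_extremes(self):
        assert isoelectric_point("DDDDDD") < 4.5
        assert isoelectric_point("KKKKKK") > 9.0

    @settings(max_examples=30, deadline=None)
    @given(peptides, st.integers(0, 59))
    def test_monotone_under_substitution(self, seq, pos):
        # replacing any residue by Asp never raises pI; replacing any
        # residue except Arg by Lys never lowers it (Arg is the stronger
        # base, pKa 12.5 vs 10.8, so Arg -> Lys legitimately lowers pI)
        pos = pos % len(seq)
        base = isoelectric_point(seq)
        acid = isoelectric_point(seq[:pos] + "D" + seq[pos + 1 :])
        assert acid <= base + 1e-3
        if seq[pos] != "R":
            basic = isoelectric_point(seq[:pos] + "K" + seq[pos + 1 :])
            assert basic >= base - 1e-3


class TestRatios:
    def test_lys_arg(self):
        f = np.zeros(20)
        f[AA_IDX["K"]], f[AA_IDX["R"]] = 0.06, 0.05
        assert aa_ratio(f, "K", "R") == pytest.approx(1.2)

    def test_equal_is_one(self):
        f = np.full(20, 0.05)
        assert aa_ratio(f, "E", "D") == pytest.approx(1.0)

    def test_zero_denominator_missing(self):
        f = np.zeros(20)
        f[AA_IDX["K"]] = 0.06
        assert math.isnan(aa_ratio(f, "K", "R"))


class TestClustering:
    def test_identity_examples(self):
        assert alignment_identity_coverage("AAAA", "AAAT")[0] == pytest.approx(0.75)
        assert alignment_identity_coverage("MKV", "MKV") == (1.0, 1.0)

    def test_identical_pair_one_family(self):
        fams = cluster_families([("p1", "i1", "MKVLAT"), ("p2", "i2", "MKVLAT")])
        assert len(fams) == 1 and len(fams[0].members) == 2

    def test_random_sequences_split(self, rng):
        aa = list(AMINO_ACIDS)
        s1 = "".join(rng.choice(aa, 100))
        s2 = "".join(rng.choice(aa, 100))
        identity, _ = alignment_identity_coverage(s1, s2)
        assert identity < 0.5  # ~5 % expected for random 20-letter strings
        assert len(cluster_families([("p1", "i1", s1), ("p2", "i2", s2)])) == 2

    def test_sixty_percent_mutant_joins(self, rng):
        aa = list(AMINO_ACIDS)
        s1 = "".join(rng.choice(aa, 120))
        mutant = list(s1)
        for pos in rng.choice(120, size=48, replace=False):  # 40 % mutated
            mutant[pos] = str(rng.choice([a for a in aa if a != s1[pos]]))
        s2 = "".join(mutant)
        assert alignment_identity_coverage(s1, s2)[0] == pytest.approx(0.6, abs=0.01)
        assert len(cluster_families([("p1", "i1", s1), ("p2", "i2", s2)])) == 1

    def test_deterministic_under_permutation(self, rng):
        aa = list(AMINO_ACIDS)
        prots = [
            (f"p{i}", f"i{i}", "".join(rng.choice(aa, int(rng.integers(50, 80)))))
            for i in range(8)
        ]
        ref = [sorted(m[0] for m in f.members) for f in cluster_families(prots)]
        perm = [prots[i] for i in rng.permutation(len(prots))]
        out = [sorted(m[0] for m in f.members) for f in cluster_families(perm)]
        assert sorted(map(tuple, ref)) == sorted(map(tuple, out))


class TestFamilyFilter:
    def test_half_genome_threshold(self):
        fams = cluster_families([("p1", "i1", "MKVLAT"), ("p2", "i2", "MKVLAT")])
        # 78 genomes -> threshold 39; a 2-member family is removed
        assert filter_families(fams, n_genomes=78) == []
        assert filter_families(fams, min_members=2) == fams

    def test_boundary(self):
        fam = cluster_families([(f"p{i}", f"i{i}", "MKVLAT") for i in range(38)])
        assert filter_families(fam, min_members=39) == []
        fam = cluster_families([(f"p{i}", f"i{i}", "MKVLAT") for i in range(39)])
        assert len(filter_families(fam, min_members=39)) == 1

    def test_empty(self):
        assert filter_families([], min_members=5) == []


class TestPairwiseIdentity:
    def test_identical_pair(self):
        m, sd = mean_pairwise_identity(["MKVL", "MKVL"])
        assert m == pytest.approx(100.0)

    def test_three_quarters(self):
        m, _ = mean_pairwise_identity(["AAAA", "AAAT"])
        assert m == pytest.approx(75.0)

    def test_three_identical(self):
        m, sd = mean_pairwise_identity(["MKVL"] * 3)
        assert m == pytest.approx(100.0) and sd == pytest.approx(0.0)

    def test_singleton_missing(self):
        m, sd = mean_pairwise_identity(["MKVL"])
        assert math.isnan(m) and math.isnan(sd)


class TestSignature:
    def test_arithmetic(self):
        f_t = np.full(20, 0.05)
        f_r = np.full(20, 0.05)
        f_t[0], f_r[0] = 0.055, 0.050
        f_t[1:] = (1 - 0.055) / 19
        f_r[1:] = (1 - 0.050) / 19
        d = composition_signature(f_t, f_r)
        assert d[0] == pytest.approx(10.0)

    def test_self_contrast_zero(self, rng):
        f = rng.dirichlet(np.ones(20))
        np.testing.assert_allclose(composition_signature(f, f), 0.0, atol=1e-12)

    def test_zero_reference_missing(self):
        f_r = np.full(20, 0.05)
        f_r[3] = 0.0
        d = composition_signature(np.full(20, 0.05), f_r)
        assert math.isnan(d[3])


class TestKSContrast:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        d, p = ks_contrast(x, x)
        assert d == 0.0 and p == 1.0

    def test_shifted_distributions(self, rng):
        a = rng.normal(0, 1, 100)
        b = rng.normal(5, 1, 100)
        d, p = ks_contrast(a, b)
        assert p < 0.001
        assert 0 <= d <= 1

    def test_small_sample_errors(self):
        with pytest.raises(ValueError):
            ks_contrast([1, 2, 3], [1, 2, 3, 4, 5])
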