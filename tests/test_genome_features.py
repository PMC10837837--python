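"""Genome-scale features, QC gate, deduplication and rank contrasts."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecosig.genome_features import (
    CODONS,
    GenomeQCMetrics,
    QCThresholds,
    at_content,
    clade_summary,
    codon_usage,
    coding_density,
    dedup_aai,
    gc_content,
    n50,
    positional_gc,
    qc_filter,
    rank_contrast,
    star_class,
)
from ecosig.io_core import IsolateMetadata


class TestGC:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ATGC", 0.5), ("GGCC", 1.0), ("ATGCNN", 0.5), ("atgc", 0.5)],
    )
    def test_examples(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_all_ambiguous_is_missing(self):
        assert math.isnan(gc_content("NNNN"))

    @settings(max_examples=50, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=100))
    def test_gc_plus_at_is_one(self, seq):
        assert gc_content(seq) + at_content(seq) == pytest.approx(1.0)


class TestPositionalGC:
    def test_all_gc_cds(self):
        assert positional_gc(["GGGGGG"]) == pytest.approx((1.0, 1.0, 1.0))

    def test_hand_enumerated(self):
        # ATG GCA TAA: pos1 = A,G,T -> 1/3; pos2 = T,C,A -> 1/3; pos3 = G,A,A -> 1/3
        assert positional_gc(["ATGGCATAA"]) == pytest.approx((1 / 3, 1 / 3, 1 / 3))

    def test_trailing_partial_codon_dropped(self, caplog):
        with caplog.at_level("WARNING"):
            g1, g2, g3 = positional_gc(["GGGGGGGGGG"])  # length 10
        assert (g1, g2, g3) == (1.0, 1.0, 1.0)
        assert "dropped" in caplog.text

    def test_empty_set_missing(self):
        assert all(math.isnan(v) for v in positional_gc([]))


class TestCodonUsage:
    def test_frequency(self):
        v = codon_usage(["ATGTGG"])
        assert v[CODONS.index("ATG")] == pytest.approx(0.5)
        assert v[CODONS.index("TGG")] == pytest.approx(0.5)
        assert v.sum() == pytest.approx(1.0)

    def test_rscu_equal_family(self):
        # equal usage of the 4 Gly codons -> RSCU 1 each
        v = codon_usage(["GGTGGCGGAGGG"], mode="RSCU")
        for c in ("GGT", "GGC", "GGA", "GGG"):
            assert v[CODONS.index(c)] == pytest.approx(1.0)

    def test_rscu_phe_family(self):
        v = codon_usage(["TTTTTTTTC"], mode="RSCU")  # TTT TTT TTC
        assert v[CODONS.index("TTT")] == pytest.approx(4 / 3)
        assert v[CODONS.index("TTC")] == pytest.approx(2 / 3)

    def test_single_codon_families_rscu_one(self):
        v = codon_usage(["ATGTGG"], mode="RSCU")
        assert v[CODONS.index("ATG")] == pytest.approx(1.0)
        assert v[CODONS.index("TGG")] == pytest.approx(1.0)

    def test_empty_missing(self):
        assert np.isnan(codon_usage([])).all()


def brute_force_n50(lengths):
    lengths = sorted(lengths, reverse=True)
    total = sum(lengths)
    for k in range(1, len(lengths) + 1):
        if sum(lengths[:k]) >= total / 2:
            return lengths[k - 1]


class TestN50:
    @pytest.mark.parametrize("lengths,expected", [([100], 100), ([100, 200, 300, 400], 300)])
    def test_examples(self, lengths, expected):
        assert n50(lengths) == expected

    def test_order_invariance(self, rng):
        lengths = list(rng.integers(1, 10_000, size=30))
        assert n50(lengths) == n50(sorted(lengths)) == n50(sorted(lengths, reverse=True))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            n50([])

    def test_matches_brute_force(self, rng):
        for _ in range(100):
            lengths = rng.integers(1, 100_000, size=rng.integers(1, 50)).tolist()
            assert n50(lengths) == brute_force_n50(lengths)


class TestQCFilter:
    def test_pass(self):
        ok, reasons = qc_filter(GenomeQCMetrics("g", 120, 50_000, 98, 1))
        assert ok and reasons == []

    def test_contig_violation(self):
        ok, reasons = qc_filter(GenomeQCMetrics("g", 301, 50_000, 98, 1))
        assert not ok and reasons == ["contigs>300"]

    def test_n50_violation(self):
        ok, reasons = qc_filter(GenomeQCMetrics("g", 120, 19_999, 98, 1))
        assert not ok and reasons == ["N50<20kb"]

    def test_all_violations_reported(self):
        ok, reasons = qc_filter(GenomeQCMetrics("g", 500, 1_000, 50, 50))
        assert not ok and len(reasons) == 4

    def test_missing_metric(self):
        ok, reasons = qc_filter(GenomeQCMetrics("g", None, 50_000, 98, 1))
        assert not ok and reasons == ["missing metric"]

    def test_monotone_in_thresholds(self, rng):
        # relaxing any threshold never turns a pass into a fail
        base = QCThresholds()
        relaxed = QCThresholds(
            max_contigs=400, min_n50=10_000, min_completeness=90, max_contamination=10
        )
        for _ in range(200):
            m = GenomeQCMetrics(
                "g",
                int(rng.integers(1, 600)),
                float(rng.uniform(0, 100_000)),
                float(rng.uniform(0, 100)),
                float(rng.uniform(0, 20)),
            )
            if qc_filter(m, base)[0]:
                assert qc_filter(m, relaxed)[0]


def _aai_frame(ids, pairs, background=90.0):
    n = len(ids)
    m = np.full((n, n), background)
    np.fill_diagonal(m, 100.0)
    for a, b, v in pairs:
        i, j = ids.index(a), ids.index(b)
        m[i, j] = m[j, i] = v
    return pd.DataFrame(m, index=ids, columns=ids)


class TestDedupAAI:
    def test_no_duplicates_keeps_all(self):
        aai = _aai_frame(["a", "b", "c"], [])
        assert dedup_aai(aai) == ["a", "b", "c"]

    def test_higher_completeness_kept(self):
        aai = _aai_frame(["a", "b"], [("a", "b", 99.6)])
        meta = {
            "a": IsolateMetadata("a", "X", completeness=96.0),
            "b": IsolateMetadata("b", "X", completeness=99.0),
        }
        assert dedup_aai(aai, meta) == ["b"]

    def test_chain_is_one_component(self):
        aai = _aai_frame(["a", "b", "c"], [("a", "b", 99.6), ("b", "c", 99.6), ("a", "c", 99.0)])
        assert len(dedup_aai(aai)) == 1

    def test_retained_set_has_no_close_pair_and_is_idempotent(self, rng):
        ids = [f"g{i}" for i in range(12)]
        pairs = [("g0", "g1", 99.7), ("g2", "g3", 99.9), ("g3", "g4", 99.6)]
        aai = _aai_frame(ids, pairs)
        kept = dedup_aai(aai)
        sub = aai.loc[kept, kept].to_numpy()
        np.fill_diagonal(sub, 0)
        assert (sub < 99.5).all()
        assert dedup_aai(aai.loc[kept, kept]) == kept

    def test_asymmetric_errors(self):
        aai = _aai_frame(["a", "b"], [])
        aai.iloc[0, 1] = 95.0
        with pytest.raises(ValueError, match="asymmetric"):
            dedup_aai(aai)


class TestCodingDensityAndSummary:
    @pytest.mark.parametrize("n,mb,expected", [(3000, 3.0, 1.0), (900, 1.0, 0.9), (0, 2.0, 0.0)])
    def test_coding_density(self, n, mb, expected):
        assert coding_density(n, mb) == pytest.approx(expected)

    def test_clade_summary(self):
        df = pd.DataFrame({"f": [2.0, 4.0, 7.0]}, index=["a", "b", "c"])
        out = clade_summary(df, {"a": "X", "b": "X", "c": "Y"})
        assert out.loc[("X", "f"), "mean"] == pytest.approx(3.0)
        assert out.loc[("X", "f"), "sd"] == pytest.approx(math.sqrt(2), rel=1e-6)
        assert math.isnan(out.loc[("Y", "f"), "sd"])  # singleton clade
        assert out.loc[("X", "f"), "n"] == 2

    def test_missing_excluded_pairwise(self):
        df = pd.DataFrame({"f": [1.0, float("nan"), 3.0]}, index=["a", "b", "c"])
        out = clade_summary(df, {"a": "X", "b": "X", "c": "X"})
        assert out.loc[("X", "f"), "n"] == 2
        assert out.loc[("X", "f"), "mean"] == pytest.approx(2.0)


class TestRankContrast:
    def test_identical_groups(self):
        _, p, star = rank_contrast([1, 2, 3, 4], [1, 2, 3, 4])
        assert p == pytest.approx(1.0)
        assert star == "ns"

    def test_exact_small_sample(self):
        # smallest attainable two-sided p at 3 vs 3 is 2/20 = 0.1
        _, p, star = rank_contrast([1, 2, 3], [10, 11, 12])
        assert p == pytest.approx(0.1)
        assert star == "ns"

    @pytest.mark.parametrize(
        "p,star", [(0.2, "ns"), (0.05, "*"), (0.009, "**"), (0.0009, "***")]
    )
    def test_star_mapping(self, p, star):
        assert star_class(p) == star

    def test_small_group_errors(self):
        with pytest.raises(ValueError):
            rank_contrast([1], [2, 3])
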