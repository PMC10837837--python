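"""Per-isolate genome-scale features, the QC/dedup gate, clade summaries.

Covers assembly statistics (N50), nucleotide composition (genome GC,
codon-position GC1/GC2/GC3), codon usage (frequencies and RSCU), coding
density, the quality-control filter used to select analysis-grade
genomes, AAI-based deduplication, and the rank-sum contrast with the
star annotation used throughout the box-plot style comparisons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse
import scipy.sparse.csgraph
from scipy import stats

from .io_core import GenomeRecord, IsolateMetadata

__all__ = [
    "GenomeQCMetrics",
    "QCThresholds",
    "gc_content",
    "at_content",
    "positional_gc",
    "codon_usage",
    "CODONS",
    "SYNONYM_FAMILIES",
    "n50",
    "qc_filter",
    "dedup_aai",
    "coding_density",
    "clade_summary",
    "rank_contrast",
    "star_class",
]

logger = logging.getLogger(__name__)

_UNAMBIGUOUS = set("ACGT")

#: The 64 codons in fixed lexicographic (T, C, A, G per position is the
#: classical table order, but plain A/C/G/T sorting is used here) order.
CODONS: list[str] = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_CODON_INDEX = {c: i for i, c in enumerate(CODONS)}


def _synonym_families(table_id: int = 11) -> dict[str, list[str]]:
    """Synonym families of the given NCBI translation table (stops excluded)."""
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[table_id]
    fams: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        fams.setdefault(aa, []).append(codon)
    return {aa: sorted(cs) for aa, cs in fams.items()}


#: Synonym families of the bacterial code (NCBI translation table 11).
SYNONYM_FAMILIES: dict[str, list[str]] = _synonym_families(11)


@dataclass
class GenomeQCMetrics:
    isolate_id: str
    n_contigs: int | None
    n50: float | None  # bp
    completeness: float | None  # %
    contamination: float | None  # %


@dataclass
class QCThresholds:
    """Removal criteria: a genome fails if ANY criterion is violated."""

    max_contigs: int = 300
    min_n50: float = 20_000.0
    min_completeness: float = 95.0
    max_contamination: float = 5.0


# ---------------------------------------------------------------------------
# nucleotide composition
# ---------------------------------------------------------------------------


def gc_content(sequence: str) -> float:
    """(G+C) / (A+C+G+T), case-insensitive; ambiguity codes excluded.

    Returns NaN (with a warning) when no unambiguous base is present.
    """
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    total = gc + s.count("A") + s.count("T")
    if total == 0:
        logger.warning("no unambiguous bases; GC content undefined")
        return float("nan")
    return gc / total


def at_content(sequence: str) -> float:
    """(A+T) / (A+C+G+T) over unambiguous bases; NaN when undefined."""
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    at = s.count("A") + s.count("T")
    total = at + s.count("G") + s.count("C")
    if total == 0:
        logger.warning("no unambiguous bases; AT content undefined")
        return float("nan")
    return at / total


def _codon_positions(cds_sequences: Iterable[str]) -> list[str]:
    """Concatenate strand-resolved CDS, dropping trailing partial codons."""
    out = []
    for seq in cds_sequences:
        s = seq.upper()
        if len(s) % 3 != 0:
            logger.warning(
                "CDS length %d not a multiple of 3; trailing %d base(s) dropped",
                len(s),
                len(s) % 3,
            )
            s = s[: len(s) - len(s) % 3]
        out.append(s)
    return out


def positional_gc(cds_sequences: Iterable[str]) -> tuple[float, float, float]:
    """Pooled GC at codon positions 1..3 over all CDS of an isolate.

    Stop codons are included; ambiguity codes are excluded position-wise
    as in :func:`gc_content`.  An empty CDS set yields NaNs.
    """
    seqs = _codon_positions(cds_sequences)
    gc = [0, 0, 0]
    total = [0, 0, 0]
    for s in seqs:
        for pos in range(3):
            sub = s[pos::3]
            gc[pos] += sub.count("G") + sub.count("C")
            total[pos] += (
                sub.count("G") + sub.count("C") + sub.count("A") + sub.count("T")
            )
    return tuple(g / t if t else float("nan") for g, t in zip(gc, total))  # type: ignore[return-value]


def codon_usage(cds_sequences: Iterable[str], mode: str = "frequency") -> np.ndarray:
    """64-long codon usage vector, pooled over all CDS of an isolate.

    ``frequency``: counts normalised to sum to 1 over counted codons.
    ``RSCU``: observed count divided by the mean count of its synonym
    family (bacterial code); the single-codon families ATG and TGG get
    RSCU 1 when present.  Codons containing ambiguity codes are skipped.
    Empty input yields an all-NaN vector.
    """
    if mode not in {"frequency", "RSCU"}:
        raise ValueError(f"unknown mode {mode!r}")
    counts = np.zeros(64)
    for s in _codon_positions(cds_sequences):
        for i in range(0, len(s), 3):
            codon = s[i : i + 3]
            idx = _CODON_INDEX.get(codon)
            if idx is not None:
                counts[idx] += 1
    if counts.sum() == 0:
        return np.full(64, np.nan)
    if mode == "frequency":
        return counts / counts.sum()
    rscu = np.full(64, np.nan)
    for _aa, family in SYNONYM_FAMILIES.items():
        fam_idx = [_CODON_INDEX[c] for c in family]
        fam_counts = counts[fam_idx]
        mean = fam_counts.mean()
        if mean > 0:
            rscu[fam_idx] = fam_counts / mean
    return rscu


# ---------------------------------------------------------------------------
# assembly statistics and QC
# ---------------------------------------------------------------------------


def n50(contig_lengths: Sequence[int]) -> int:
    """Smallest contig length L such that contigs >= L sum to at least
    half the assembly length.  Order-invariant; always the length of one
    of the contigs."""
    if len(contig_lengths) == 0:
        raise ValueError("empty contig length list")
    if any(l <= 0 for l in contig_lengths):
        raise ValueError("contig lengths must be positive")
    lengths = sorted(contig_lengths, reverse=True)
    half = sum(lengths) / 2.0
    acc = 0
    for l in lengths:
        acc += l
        if acc >= half:
            return l
    raise AssertionError("unreachable")


def qc_filter(
    metrics: GenomeQCMetrics, thresholds: QCThresholds | None = None
) -> tuple[bool, list[str]]:
    """Apply the genome quality gate; returns (passed, violated criteria).

    A genome fails if ANY criterion is violated: more than
    ``max_contigs`` contigs, N50 below ``min_n50``, completeness below
    ``min_completeness``, or contamination above ``max_contamination``.
    A missing metric fails with reason ``"missing metric"``.
    """
    t = thresholds or QCThresholds()
    reasons: list[str] = []
    if any(
        v is None
        for v in (metrics.n_contigs, metrics.n50, metrics.completeness, metrics.contamination)
    ):
        return False, ["missing metric"]
    if metrics.n_contigs > t.max_contigs:
        reasons.append(f"contigs>{t.max_contigs}")
    if metrics.n50 < t.min_n50:
        reasons.append(f"N50<{t.min_n50 / 1000:g}kb")
    if metrics.completeness < t.min_completeness:
        reasons.append(f"completeness<{t.min_completeness:g}%")
    if metrics.contamination > t.max_contamination:
        reasons.append(f"contamination>{t.max_contamination:g}%")
    return (not reasons), reasons


def dedup_aai(
    aai: pd.DataFrame,
    metadata: Mapping[str, IsolateMetadata] | None = None,
    threshold: float = 99.5,
) -> list[str]:
    """Deduplicate isolates whose pairwise AAI is at or above ``threshold`` %.

    Builds a graph with an edge for every pair with AAI >= threshold and
    keeps exactly one representative per connected component, preferring
    higher completeness, then lower contamination, then the
    lexicographically smallest id.  The matrix must be symmetric (within
    1e-6) with diagonal 100.
    """
    ids = list(aai.index)
    if list(aai.columns) != ids:
        raise ValueError("AAI matrix rows and columns must match")
    m = aai.to_numpy(dtype=float)
    if not np.allclose(m, m.T, atol=1e-6):
        raise ValueError("AAI matrix is asymmetric beyond tolerance 1e-6")
    if not np.allclose(np.diag(m), 100.0, atol=1e-6):
        raise ValueError("AAI matrix diagonal must be 100")

    adj = (m >= threshold).astype(np.int8)
    np.fill_diagonal(adj, 0)
    n_comp, labels = scipy.sparse.csgraph.connected_components(
        scipy.sparse.csr_matrix(adj), directed=False
    )

    def sort_key(isolate_id: str) -> tuple:
        meta = metadata.get(isolate_id) if metadata else None
        completeness = meta.completeness if meta and meta.completeness is not None else -math.inf
        contamination = meta.contamination if meta and meta.contamination is not None else math.inf
        return (-completeness, contamination, isolate_id)

    retained: list[str] = []
    for comp in range(n_comp):
        members = [ids[i] for i in np.flatnonzero(labels == comp)]
        retained.append(min(members, key=sort_key))
    return sorted(retained, key=ids.index)


def coding_density(n_cds: int, genome_size_mb: float) -> float:
    """Coding density in genes per kb: n_CDS / genome size in kb."""
    if genome_size_mb <= 0:
        raise ValueError("genome size must be positive")
    return n_cds / (genome_size_mb * 1000.0)


# ---------------------------------------------------------------------------
# clade summaries and contrasts
# ---------------------------------------------------------------------------


def clade_summary(
    features: pd.DataFrame, clades: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Per-clade mean, sample SD (n-1) and n for every numeric feature.

    Missing values are excluded pairwise and the per-cell n reports how
    many isolates actually contributed.  Clades with zero isolates in the
    table are omitted with a warning; a single-isolate clade reports a
    missing SD.
    """
    clades = pd.Series(dict(clades) if not isinstance(clades, pd.Series) else clades)
    missing_clades = set(clades.unique()) - set(clades[clades.index.isin(features.index)].unique())
    for c in sorted(missing_clades):
        logger.warning("clade %r has no isolates in the feature table; omitted", c)
    df = features.join(clades.rename("clade"), how="inner")
    grouped = df.groupby("clade")
    rows = []
    for clade, sub in grouped:
        for col in features.columns:
            vals = sub[col].dropna()
            rows.append(
                {
                    "clade": clade,
                    "feature": col,
                    "mean": vals.mean() if len(vals) else float("nan"),
                    "sd": vals.std(ddof=1) if len(vals) >= 2 else float("nan"),
                    "n": len(vals),
                }
            )
    return pd.DataFrame(rows).set_index(["clade", "feature"])


def star_class(p: float) -> str:
    """Significance star annotation: ns / * / ** / ***."""
    if math.isnan(p):
        return "ns"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def rank_contrast(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float, str]:
    """Two-sided unpaired rank-sum (Mann-Whitney U) contrast with stars.

    Exact enumeration for group sizes up to 8 on both sides, otherwise
    the tie-corrected normal approximation.  Each group must have n >= 2.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group must have at least 2 observations")
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and
                         len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(min(res.pvalue, 1.0))
    return float(res.statistic), p, star_class(p)
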