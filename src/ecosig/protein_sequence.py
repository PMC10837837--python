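"""Proteome composition indices, family clustering and signature arithmetic.

Amino-acid composition differences between clades living in cold, hot
or hypersaline habitats are the central sequence-level adaptation
signal: e.g. Lys replacing Arg at the surface of cold-adapted proteins,
Asp/Glu enrichment in halophiles, a raised Glu/Asp ratio in
thermophiles.  This module computes the per-isolate composition vectors
(with GRAVY and isoelectric point), clusters proteins into homologous
families by greedy centroid clustering, measures within-family
conservation, and turns clade-mean composition vectors into
percentage-difference signatures with Kolmogorov-Smirnov support.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats

__all__ = [
    "AMINO_ACIDS",
    "ProteomeCompositionVector",
    "ProteinFamily",
    "aa_frequencies",
    "gravy",
    "kyte_doolittle_scale",
    "isoelectric_point",
    "net_charge",
    "pka_table",
    "aa_ratio",
    "cluster_families",
    "filter_families",
    "alignment_identity_coverage",
    "mean_pairwise_identity",
    "composition_signature",
    "ks_contrast",
]

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical one-letter codes.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def _load_data_table(name: str) -> list[list[str]]:
    text = (importlib.resources.files("ecosig.data") / name).read_text()
    rows = []
    for line in text.splitlines():
        if line.startswith("#") or not line.strip():
            continue
        rows.append(line.split("\t"))
    return rows


@lru_cache(maxsize=None)
def kyte_doolittle_scale() -> Mapping[str, float]:
    """The shipped Kyte-Doolittle hydropathy table (residue -> value)."""
    return {aa: float(v) for aa, v in _load_data_table("kyte_doolittle.tsv")}


@lru_cache(maxsize=None)
def pka_table(name: str = "emboss-1.0") -> Mapping[str, tuple[float, int]]:
    """Shipped pKa set: group -> (pKa, charge sign of the ionized form)."""
    if name != "emboss-1.0":
        raise ValueError(f"unknown pKa set {name!r}")
    return {g: (float(p), int(s)) for g, p, s in _load_data_table("pka_emboss.tsv")}


@dataclass
class ProteomeCompositionVector:
    """Genome-wide composition summary of one isolate's proteome."""

    isolate_id: str
    frequencies: np.ndarray  # 20-vector over AMINO_ACIDS, sums to 1
    gravy: float
    pi: float
    ratios: dict[str, float] = field(default_factory=dict)


@dataclass
class ProteinFamily:
    """A cluster of homologous proteins."""

    family_id: str
    members: list[tuple[str, str]]  # (protein_id, isolate_id)
    representative: str
    mean_pairwise_identity: float | None = None  # %, None until computed


# ---------------------------------------------------------------------------
# composition indices
# ---------------------------------------------------------------------------


def aa_frequencies(sequences: Iterable[str]) -> tuple[np.ndarray, int]:
    """Pooled 20-vector of amino-acid frequencies over all proteins.

    Non-standard letters (X, B, Z, U, ...) are skipped; the number of
    skipped residues is returned alongside.  Zero countable residues
    yields an all-NaN vector.
    """
    counts = np.zeros(20)
    skipped = 0
    for seq in sequences:
        for ch in seq.upper():
            idx = _AA_INDEX.get(ch)
            if idx is None:
                skipped += 1
            else:
                counts[idx] += 1
    if skipped:
        logger.info("skipped %d non-standard residues", skipped)
    total = counts.sum()
    if total == 0:
        return np.full(20, np.nan), skipped
    return counts / total, skipped


def gravy(sequence: str) -> float:
    """Grand average of hydropathicity: mean Kyte-Doolittle value.

    Non-standard letters are skipped; NaN when nothing is countable.
    """
    if not sequence:
        raise ValueError("empty sequence")
    scale = kyte_doolittle_scale()
    vals = [scale[ch] for ch in sequence.upper() if ch in scale]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def net_charge(sequence: str, ph: float, pka_set: str = "emboss-1.0") -> float:
    """Net charge at the given pH from Henderson-Hasselbalch terms.

    Positive groups (N-terminus, Lys, Arg, His) contribute
    ``1 / (1 + 10^(pH - pKa))`` each; negative groups (C-terminus, Asp,
    Glu, Cys, Tyr) contribute ``-1 / (1 + 10^(pKa - pH))``.
    """
    table = pka_table(pka_set)
    s = sequence.upper()
    q = 0.0
    for group, (pka, sign) in table.items():
        if group == "Nterm":
            n = 1
        elif group == "Cterm":
            n = 1
        else:
            n = s.count(group)
        if n == 0:
            continue
        if sign > 0:
            q += n / (1.0 + 10.0 ** (ph - pka))
        else:
            q -= n / (1.0 + 10.0 ** (pka - ph))
    return q


def isoelectric_point(
    sequence: str, pka_set: str = "emboss-1.0", tol: float = 1e-4, max_iter: int = 200
) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    The net charge is strictly decreasing in pH, so bisection converges.
    The interval is narrowed below 1e-7 pH units (the charge curve is
    nearly flat between well-separated pKa values, so stopping on the
    charge alone would leave the root poorly located); failure to reach
    ``|Q| < tol`` within ``max_iter`` raises (should be unreachable).
    """
    if not sequence:
        raise ValueError("empty sequence")
    lo, hi = 0.0, 14.0
    mid = 7.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        q = net_charge(sequence, mid, pka_set)
        if hi - lo < 1e-7 and abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    if abs(net_charge(sequence, mid, pka_set)) < tol:
        return mid
    raise RuntimeError("isoelectric point bisection did not converge")


def aa_ratio(
    frequencies: np.ndarray,
    numerator: Sequence[str],
    denominator: Sequence[str],
) -> float:
    """Ratio of summed frequencies, e.g. Lys/Arg or Glu/Asp.

    NaN (with a warning) when the denominator frequency is zero.
    """
    num = sum(frequencies[_AA_INDEX[a]] for a in numerator)
    den = sum(frequencies[_AA_INDEX[a]] for a in denominator)
    if den == 0:
        logger.warning("zero denominator frequency for ratio %s/%s", numerator, denominator)
        return float("nan")
    return float(num / den)


# ---------------------------------------------------------------------------
# family clustering
# ---------------------------------------------------------------------------


def _make_aligner(match: float = 1.0, mismatch: float = 0.0,
                  gap_open: float = -10.0, gap_extend: float = -0.5) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def alignment_identity_coverage(
    seq_a: str, seq_b: str, aligner: Align.PairwiseAligner | None = None
) -> tuple[float, float]:
    """Global-alignment identity and coverage of two sequences.

    Identity = identical columns / alignment length excluding terminal
    gaps.  Coverage = span of non-terminal-gap columns / length of the
    shorter sequence.  Scoring: match +1, mismatch 0, gap open -10, gap
    extend -0.5 (configurable through a custom aligner).
    """
    if aligner is None:
        aligner = _make_aligner()
    aln = aligner.align(seq_a, seq_b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    # strip terminal-gap columns (leading/trailing gap in either row)
    start = 0
    end = len(ga)
    while start < end and (ga[start] == "-" or gb[start] == "-"):
        # a leading gap run belongs to exactly one row in a global alignment
        if ga[start] != "-" and gb[start] != "-":
            break
        start += 1
    while end > start and (ga[end - 1] == "-" or gb[end - 1] == "-"):
        if ga[end - 1] != "-" and gb[end - 1] != "-":
            break
        end -= 1
    span = end - start
    if span <= 0:
        return 0.0, 0.0
    identical = sum(1 for i in range(start, end) if ga[i] == gb[i] and ga[i] != "-")
    identity = identical / span
    coverage = span / min(len(seq_a), len(seq_b))
    return identity, coverage


def cluster_families(
    proteins: Sequence[tuple[str, str, str]],
    min_identity: float = 0.50,
    min_coverage: float = 0.80,
    aligner: Align.PairwiseAligner | None = None,
) -> list[ProteinFamily]:
    """Greedy centroid clustering of proteins into homologous families.

    ``proteins`` is a sequence of ``(protein_id, isolate_id, sequence)``.
    Proteins are visited in order of decreasing length (ties broken by
    lexicographic protein id, making the result deterministic under
    permutation of the input); each protein joins the first existing
    representative for which both the identity and coverage cut-offs are
    met, otherwise it founds a new family with itself as representative.
    """
    if not proteins:
        raise ValueError("no proteins to cluster")
    if aligner is None:
        aligner = _make_aligner()
    order = sorted(proteins, key=lambda p: (-len(p[2]), p[0]))
    reps: list[tuple[str, str]] = []  # (protein_id, sequence)
    families: list[ProteinFamily] = []
    for pid, iso, seq in order:
        placed = False
        for fam, (rep_id, rep_seq) in zip(families, reps):
            identity, coverage = alignment_identity_coverage(seq, rep_seq, aligner)
            if identity >= min_identity and coverage >= min_coverage:
                fam.members.append((pid, iso))
                placed = True
                break
        if not placed:
            fam = ProteinFamily(
                family_id=f"F{len(families):05d}",
                members=[(pid, iso)],
                representative=pid,
            )
            families.append(fam)
            reps.append((pid, seq))
    return families


def filter_families(
    families: Sequence[ProteinFamily],
    n_genomes: int | None = None,
    min_members: int | None = None,
) -> list[ProteinFamily]:
    """Keep families with at least ``min_members`` members.

    By default the threshold is half the number of genomes, rounded up
    (e.g. 39 for 78 genomes) — families present in at least half of the
    isolates are considered pangenome-wide.
    """
    if min_members is None:
        if n_genomes is None:
            raise ValueError("provide either n_genomes or min_members")
        min_members = math.ceil(n_genomes / 2)
    return [f for f in families if len(f.members) >= min_members]


def mean_pairwise_identity(
    sequences: Sequence[str], aligner: Align.PairwiseAligner | None = None
) -> tuple[float, float]:
    """Mean and SD (in %) of global-alignment identity over all pairs.

    A singleton family has no pairs: returns (NaN, NaN).  The SD is NaN
    for a single pair.
    """
    if len(sequences) < 2:
        return float("nan"), float("nan")
    if aligner is None:
        aligner = _make_aligner()
    idents = []
    for i in range(len(sequences)):
        for j in range(i + 1, len(sequences)):
            identity, _ = alignment_identity_coverage(sequences[i], sequences[j], aligner)
            idents.append(identity * 100.0)
    arr = np.asarray(idents)
    sd = float(arr.std(ddof=1)) if len(arr) >= 2 else float("nan")
    return float(arr.mean()), sd


# ---------------------------------------------------------------------------
# signatures
# ---------------------------------------------------------------------------


def composition_signature(
    f_target: np.ndarray, f_reference: np.ndarray
) -> np.ndarray:
    """Per-amino-acid percentage difference of target vs reference clade:
    ``100 * (f_t - f_r) / f_r``; NaN where the reference frequency is 0."""
    f_target = np.asarray(f_target, dtype=float)
    f_reference = np.asarray(f_reference, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 100.0 * (f_target - f_reference) / f_reference
    d[f_reference == 0] = np.nan
    return d


def ks_contrast(
    values_target: Sequence[float],
    values_reference: Sequence[float],
    asymptotic_min_n: int = 50,
) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov contrast.

    Exact p-value when either sample is below ``asymptotic_min_n``
    observations, asymptotic otherwise; each sample must have n >= 5.
    """
    a = np.asarray(values_target, dtype=float)
    b = np.asarray(values_reference, dtype=float)
    if len(a) < 5 or len(b) < 5:
        raise ValueError("each sample must have at least 5 observations")
    method = "exact" if min(len(a), len(b)) < asymptotic_min_n else "asymp"
    res = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))
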