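"""Seeded generators of genomes, annotations, proteomes and toy structures
with planted extremophile signatures and machine-readable truth.

Every pipeline stage can be exercised end-to-end without downloads:

* :func:`make_clade_genomes` draws multi-clade genome sets with per-clade
  GC targets, regulatory elements carved with planted composition
  offsets, and metadata reflecting each clade's habitat (mean annual
  temperature, salinity).
* :func:`make_protein_families` plants families of homologous proteins
  at a controlled within-family identity, with clade-specific amino-acid
  shifts that can be restricted to designated surface positions.
* :func:`build_peptide`, :func:`make_contact_fixture` and
  :func:`make_core_surface_fixture` build idealized structures with
  known geometry for the structure-analysis stages.

All generators are pure functions of (config, seed): repeated calls are
identical.  Truth objects record every planted quantity so recovery
tests never need to regenerate.

The i.i.d. nucleotide and substitution models are deliberate: the
statistics under test are composition-level, so independent draws
suffice and keep the recovery intervals in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_features import GenomeQCMetrics
from .io_core import (
    AnnotationSet,
    Atom,
    GenomeFeature,
    GenomeRecord,
    IsolateMetadata,
    Residue,
    StructureModel,
)
from .protein_sequence import AMINO_ACIDS
from .structure_features import (
    ANION_ATOMS,
    CATION_ATOMS,
    CATION_PI_ATOMS,
    InteractionCriteria,
    RING_ATOMS,
    SULFUR_ATOMS,
    fibonacci_sphere,
)

__all__ = [
    "CladeParams",
    "GenomeSimConfig",
    "ProteomeSimConfig",
    "SyntheticGenomeSet",
    "SyntheticProteomeSet",
    "DEFAULT_CLADES",
    "DEFAULT_SHIFTS",
    "make_clade_genomes",
    "make_protein_families",
    "per_protein_frequencies",
    "build_peptide",
    "make_contact_fixture",
    "make_core_surface_fixture",
    "make_clade_tree",
    "make_qc_metrics_fixture",
    "make_aai_fixture",
]


# ---------------------------------------------------------------------------
# study conditions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CladeParams:
    """Planted per-clade genome parameters.

    GC targets and CRISPR means follow the observed subclade averages of
    the study system; the regulatory-element means encode the qualitative
    effect directions (tmRNA GC lowered in every extremophilic clade,
    promoter AT highest in the nonsaline clades, more insertion
    sequences and operons in extremophiles, extra sRNA only in the
    psychrophilic clade).
    """

    n_isolates: int
    gc: float
    mat: float  # degC, mean annual temperature of the isolation source
    salinity: float  # % NaCl m/v
    crispr_mean: float
    is_mean: float
    srna_mean: float
    operons_per_cds: float
    tmrna_gc_offset: float
    rrna_gc_offset: float
    promoter_at: float


#: Default clade scheme: nonsaline mesophilic Ia, nonsaline psychrophilic
#: Ib, saline mesophilic IIa, saline thermophilic IIb.
DEFAULT_CLADES: dict[str, CladeParams] = {
    "Ia": CladeParams(23, 0.470, 8.9, 0.5, 0.26, 5.0, 20.0, 0.18, 0.00, 0.05, 0.62),
    "Ib": CladeParams(15, 0.473, -1.6, 0.5, 0.47, 9.0, 30.0, 0.21, -0.05, 0.05, 0.64),
    "IIa": CladeParams(29, 0.521, 12.1, 6.0, 0.97, 9.0, 20.0, 0.21, -0.05, 0.04, 0.55),
    "IIb": CladeParams(10, 0.481, 45.5, 8.0, 0.80, 7.0, 20.0, 0.20, -0.05, 0.05, 0.58),
}

#: Planted per-clade amino-acid shifts (percent change of the realized
#: frequency relative to the base composition), restricted to surface
#: positions by default.  Directions and headline magnitudes follow the
#: adaptation signatures of the study system: Lys-for-Arg exchange in the
#: cold-adapted clade (Lys/Arg ratio about +8 %), Asp/Glu enrichment with
#: Lys/Gln/Ile/Leu depletion in the halophilic clade, and a Glu-over-Asp
#: preference (ratio about +10 %) in the thermophilic clade.
DEFAULT_SHIFTS: dict[str, dict[str, float]] = {
    "Ia": {},
    "Ib": {"K": 3.9, "R": -3.9, "Y": -3.0, "W": -3.0, "H": -3.0, "N": 4.0, "T": 4.0, "Q": 2.0},
    "IIa": {"D": 10.0, "E": 6.0, "W": 7.0, "K": -6.0, "N": 6.0, "Q": -6.0,
            "V": 4.0, "I": -4.0, "L": -4.0, "M": 4.0},
    # IIb composes the halophilic background with the thermophilic deltas
    # so that the IIb-vs-IIa contrast shows Glu up / Asp down, Lys up /
    # Arg down, Gln and Ser up, Ala down.
    "IIb": {"D": 4.6, "E": 11.2, "W": 7.0, "K": -3.2, "N": 6.0, "Q": -2.2,
            "V": 4.0, "I": -4.0, "L": -4.0, "M": 4.0, "R": -3.0, "S": 4.0, "A": -5.0},
}

#: Base proteome amino-acid composition (bacterial averages, normalized).
_RAW_COMPOSITION = {
    "A": 0.088, "R": 0.055, "N": 0.040, "D": 0.054, "C": 0.012,
    "Q": 0.039, "E": 0.066, "G": 0.071, "H": 0.022, "I": 0.060,
    "L": 0.101, "K": 0.058, "M": 0.025, "F": 0.040, "P": 0.046,
    "S": 0.066, "T": 0.054, "W": 0.012, "Y": 0.030, "V": 0.069,
}
BASE_COMPOSITION: dict[str, float] = {
    a: v / sum(_RAW_COMPOSITION.values()) for a, v in _RAW_COMPOSITION.items()
}


@dataclass(frozen=True)
class GenomeSimConfig:
    """Configuration of the genome generator (desk-scale defaults)."""

    clades: Mapping[str, CladeParams] = field(default_factory=lambda: dict(DEFAULT_CLADES))
    genome_length: int = 100_000
    n_contigs: int = 3
    n_cds: int = 60
    cds_length: int = 900  # multiple of 3
    n_rrna: int = 2
    rrna_length: int = 1500
    tmrna_length: int = 350
    n_promoters: int = 30
    promoter_length: int = 40
    srna_length: int = 100
    is_length: int = 800
    crispr_length: int = 600
    mat_sd: float = 1.5
    salinity_sd: float = 0.3

    def validate(self) -> None:
        if self.cds_length % 3 != 0:
            raise ValueError("cds_length must be a multiple of 3")
        for name, clade in self.clades.items():
            if not 0 < clade.gc < 1:
                raise ValueError(f"clade {name}: GC target must be in (0, 1)")
            if not 0 < clade.promoter_at < 1:
                raise ValueError(f"clade {name}: promoter AT must be in (0, 1)")


@dataclass
class SyntheticGenomeSet:
    genomes: dict[str, GenomeRecord]
    annotations: dict[str, AnnotationSet]
    metadata: list[IsolateMetadata]
    truth: dict


def _draw_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.array(list("ACGT")), size=n, p=p)


def make_clade_genomes(
    config: GenomeSimConfig | None = None, seed: int = 0
) -> SyntheticGenomeSet:
    """Generate genomes + annotations + metadata with planted truth.

    Nucleotides are drawn i.i.d. at each clade's GC target; regulatory
    elements (tmRNA, rRNA, promoters) are carved with their planted
    composition offsets; sRNA / insertion-sequence / CRISPR counts are
    Poisson at the planted clade means; operons are intervals spanning
    consecutive CDS at the planted operon-per-CDS rate.  Raises when the
    requested features cannot be packed into the genome.
    """
    config = config or GenomeSimConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    genomes: dict[str, GenomeRecord] = {}
    annotations: dict[str, AnnotationSet] = {}
    metadata: list[IsolateMetadata] = []
    truth: dict = {"seed": seed, "isolates": {}, "clades": {}}
    for name, clade in config.clades.items():
        truth["clades"][name] = {
            "gc": clade.gc,
            "tmrna_gc_offset": clade.tmrna_gc_offset,
            "rrna_gc_offset": clade.rrna_gc_offset,
            "promoter_at": clade.promoter_at,
            "mat": clade.mat,
            "salinity": clade.salinity,
        }

    for clade_name in config.clades:
        clade = config.clades[clade_name]
        for k in range(clade.n_isolates):
            iso = f"{clade_name}_{k:03d}"
            genome, ann, counts = _simulate_genome(rng, config, clade)
            genomes[iso] = GenomeRecord(
                isolate_id=iso,
                contigs=genome,
                source=f"synthetic clade {clade_name}",
            )
            annotations[iso] = ann
            annotations[iso].validate_against(genomes[iso])
            metadata.append(
                IsolateMetadata(
                    isolate_id=iso,
                    clade_label=clade_name,
                    habitat="synthetic",
                    mat=float(rng.normal(clade.mat, config.mat_sd)),
                    salinity=float(max(0.0, rng.normal(clade.salinity, config.salinity_sd))),
                    completeness=float(rng.uniform(96.0, 100.0)),
                    contamination=float(rng.uniform(0.0, 2.0)),
                    n_contigs=config.n_contigs,
                )
            )
            truth["isolates"][iso] = {"clade": clade_name, **counts}
    return SyntheticGenomeSet(genomes, annotations, metadata, truth)


def _simulate_genome(
    rng: np.random.Generator, config: GenomeSimConfig, clade: CladeParams
) -> tuple[list[tuple[str, str]], AnnotationSet, dict]:
    # contig lengths: even split with +-10% jitter
    base = config.genome_length // config.n_contigs
    lengths = [
        int(base * rng.uniform(0.9, 1.1)) for _ in range(config.n_contigs - 1)
    ]
    lengths.append(config.genome_length - sum(lengths))
    if min(lengths) <= 0:
        raise ValueError("infeasible contig length configuration")

    contigs = [
        (f"c{ci:02d}", _draw_bases(rng, L, clade.gc)) for ci, L in enumerate(lengths)
    ]

    n_srna = int(rng.poisson(clade.srna_mean))
    n_is = int(rng.poisson(clade.is_mean))
    n_crispr = int(rng.poisson(clade.crispr_mean))
    n_operons = int(rng.poisson(clade.operons_per_cds * config.n_cds))

    requests: list[tuple[str, int, float | None]] = []  # (type, length, gc or None)
    requests += [("CDS", config.cds_length, None)] * config.n_cds
    requests += [("rRNA", config.rrna_length, clade.gc + clade.rrna_gc_offset)] * config.n_rrna
    requests += [("tmRNA", config.tmrna_length, clade.gc + clade.tmrna_gc_offset)]
    requests += [("promoter", config.promoter_length, 1.0 - clade.promoter_at)] * config.n_promoters
    requests += [("sRNA", config.srna_length, None)] * n_srna
    requests += [("insertion_sequence", config.is_length, None)] * n_is
    requests += [("CRISPR", config.crispr_length, None)] * n_crispr

    total_needed = sum(L for _, L, _ in requests)
    if total_needed > config.genome_length:
        raise ValueError(
            f"infeasible packing: {total_needed} bp of features in a "
            f"{config.genome_length} bp genome"
        )

    order = rng.permutation(len(requests))
    # sequential packing across contigs with random small gaps
    cursors = [0] * config.n_contigs
    slack = config.genome_length - total_needed
    mean_gap = max(1, slack // (len(requests) + config.n_contigs))
    features: list[GenomeFeature] = []
    cds_by_contig: dict[int, list[tuple[int, int]]] = {i: [] for i in range(config.n_contigs)}
    ci = 0
    for ri in order:
        ftype, L, gc_target = requests[ri]
        placed = False
        for _ in range(config.n_contigs):
            gap = int(rng.integers(1, mean_gap + 1))
            start = cursors[ci] + gap
            if start + L <= lengths[ci]:
                placed = True
                break
            ci = (ci + 1) % config.n_contigs
        if not placed:
            # fall back to zero-gap placement anywhere
            for ci2 in range(config.n_contigs):
                if cursors[ci2] + L <= lengths[ci2]:
                    ci, start = ci2, cursors[ci2]
                    placed = True
                    break
        if not placed:
            raise ValueError("infeasible packing: no contig can hold a feature")
        strand = "+" if rng.random() < 0.5 else "-"
        seq_arr = contigs[ci][1]
        if ftype == "CDS":
            codons = _draw_bases(rng, L - 6, clade.gc)
            cds = np.concatenate([np.array(list("ATG")), codons, np.array(list("TAA"))])
            if strand == "-":
                cds = _revcomp_array(cds)
            seq_arr[start : start + L] = cds
            cds_by_contig[ci].append((start, start + L))
        elif gc_target is not None:
            seq_arr[start : start + L] = _draw_bases(rng, L, min(max(gc_target, 0.01), 0.99))
        features.append(
            GenomeFeature(
                feature_type=ftype,
                contig_id=contigs[ci][0],
                start=start,
                end=start + L,
                strand=strand,
            )
        )
        cursors[ci] = start + L
        ci = (ci + 1) % config.n_contigs

    # operons: intervals spanning 2-4 consecutive CDS on one contig
    placed_operons = 0
    for _ in range(n_operons):
        candidates = [ci for ci, lst in cds_by_contig.items() if len(lst) >= 2]
        if not candidates:
            break
        ci = int(rng.choice(candidates))
        lst = sorted(cds_by_contig[ci])
        i0 = int(rng.integers(0, len(lst) - 1))
        span = int(rng.integers(2, min(4, len(lst) - i0) + 1))
        start = lst[i0][0]
        end = lst[i0 + span - 1][1]
        features.append(
            GenomeFeature(
                feature_type="operon",
                contig_id=contigs[ci][0],
                start=start,
                end=end,
                strand="+",
            )
        )
        placed_operons += 1

    genome = [(cid, "".join(arr)) for cid, arr in contigs]
    counts = {
        "n_srna": n_srna,
        "n_is": n_is,
        "n_crispr": n_crispr,
        "n_operons": placed_operons,
        "n_cds": config.n_cds,
    }
    return genome, AnnotationSet(features), counts


_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp_array(arr: np.ndarray) -> np.ndarray:
    return np.array([_RC[b] for b in arr[::-1]])


# ---------------------------------------------------------------------------
# proteome generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteomeSimConfig:
    """Configuration of the protein-family generator.

    ``target_identity``/``identity_sd`` control the planted mean
    pairwise identity within each family; ``shifts`` plants per-clade
    percent changes of the realized amino-acid composition relative to
    ``base_composition``, applied at the designated surface positions
    only when ``surface_only`` (mirroring the observation that
    adaptation signatures concentrate at the protein surface).
    """

    clades: Mapping[str, int] = field(
        default_factory=lambda: {c: p.n_isolates for c, p in DEFAULT_CLADES.items()}
    )
    n_families: int = 40
    protein_length: int = 300
    length_jitter: float = 0.2  # +-20% uniform jitter per family
    target_identity: float = 0.80
    identity_sd: float = 0.08
    surface_fraction: float = 0.5
    surface_only: bool = True
    shifts: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {c: dict(s) for c, s in DEFAULT_SHIFTS.items()}
    )
    base_composition: Mapping[str, float] = field(
        default_factory=lambda: dict(BASE_COMPOSITION)
    )

    def min_substitution_rate(self) -> float:
        """Smallest rate compatible with the planted negative shifts
        (a shift of -x % needs s >= x/100 to keep t non-negative)."""
        worst = 0.0
        for shift in self.shifts.values():
            for pct in shift.values():
                worst = max(worst, -pct / 100.0)
        return worst

    def validate(self) -> None:
        b = np.array([self.base_composition[a] for a in AMINO_ACIDS])
        if abs(b.sum() - 1.0) > 1e-6:
            raise ValueError("base composition must sum to 1")
        s = _substitution_rate(self.target_identity, b)
        if s < self.min_substitution_rate():
            raise ValueError(
                "planted shift drives a substitution frequency negative at "
                f"the target identity (rate {s:.3f} < required "
                f"{self.min_substitution_rate():.3f})"
            )
        for clade, shift in self.shifts.items():
            t = _tilted_distribution(b, shift, max(s, self.min_substitution_rate()))
            if (t < 0).any():
                raise ValueError(
                    f"clade {clade}: planted shift drives a substitution "
                    "frequency negative"
                )


@dataclass
class SyntheticProteomeSet:
    #: (protein_id, isolate_id, clade, sequence)
    proteins: list[tuple[str, str, str, str]]
    #: family_id -> boolean surface mask over positions
    surface_masks: dict[str, np.ndarray]
    #: protein_id -> family_id
    protein_family: dict[str, str]
    truth: dict


def _substitution_rate(target_identity: float, base: np.ndarray) -> float:
    """Per-member substitution probability so that the expected pairwise
    identity between two members of a family equals the target.

    Each member independently redraws a position from the tilted
    distribution with probability s (the draw may coincide with the
    ancestor residue).  With t ~ base, the match probability is
    ``(1-s)^2 + 2 s (1-s) T2 + s^2 T2`` where ``T2 = sum(base^2)``;
    solving the quadratic gives s.
    """
    if not 0 < target_identity <= 1:
        raise ValueError("target identity must be in (0, 1]")
    t2 = float((base**2).sum())
    inner = 1.0 - (1.0 - target_identity) / (1.0 - t2)
    if inner < 0:
        raise ValueError(f"target identity {target_identity} unattainable")
    return 1.0 - math.sqrt(inner)


def _tilted_distribution(
    base: np.ndarray, shift: Mapping[str, float], s: float
) -> np.ndarray:
    """Substitution target distribution planting exact realized shifts.

    The realized composition of a member is ``(1-s) b + s t``; to plant
    a delta of ``shift[a] %`` on the realized frequency of amino acid a,
    the substitution distribution needs ``t(a) = b(a) (1 + delta/s)``.
    Unshifted amino acids absorb the compensation proportionally so t
    sums to 1.
    """
    t = base.copy()
    shifted_idx = []
    for aa, pct in shift.items():
        i = AMINO_ACIDS.index(aa)
        t[i] = base[i] * (1.0 + (pct / 100.0) / s)
        shifted_idx.append(i)
    excess = t.sum() - 1.0
    unshifted = np.setdiff1d(np.arange(20), shifted_idx)
    denom = base[unshifted].sum()
    t[unshifted] = base[unshifted] * (1.0 - excess / denom)
    return t


def make_protein_families(
    config: ProteomeSimConfig | None = None, seed: int = 0
) -> SyntheticProteomeSet:
    """Generate per-isolate proteomes organized in homologous families.

    Each family draws an ancestor from the base composition; every
    member (one per isolate) redraws positions at the solved
    substitution rate from its clade's tilted distribution — at surface
    positions — or from the base distribution (non-surface positions, or
    clades without planted shifts).  Truth records every planted
    quantity: family ancestors, per-family identity targets, surface
    masks, clade shift vectors and the solved substitution rate.
    """
    config = config or ProteomeSimConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    base = np.array([config.base_composition[a] for a in AMINO_ACIDS])

    proteins: list[tuple[str, str, str, str]] = []
    surface_masks: dict[str, np.ndarray] = {}
    protein_family: dict[str, str] = {}
    fam_truth: dict[str, dict] = {}

    isolates = [
        (f"{clade}_{k:03d}", clade)
        for clade, n in config.clades.items()
        for k in range(n)
    ]

    for fi in range(config.n_families):
        fam_id = f"F{fi:05d}"
        jitter = rng.uniform(1.0 - config.length_jitter, 1.0 + config.length_jitter)
        length = max(30, int(round(config.protein_length * jitter)))
        identity = float(
            np.clip(rng.normal(config.target_identity, config.identity_sd), 0.55, 0.98)
        )
        # families drawn at very high identity are clamped to the smallest
        # substitution rate compatible with the planted negative shifts
        s = max(_substitution_rate(identity, base), config.min_substitution_rate())
        ancestor = rng.choice(aa, size=length, p=base)
        n_surface = int(round(config.surface_fraction * length))
        mask = np.zeros(length, dtype=bool)
        mask[rng.choice(length, size=n_surface, replace=False)] = True
        surface_masks[fam_id] = mask

        tilted = {
            clade: _tilted_distribution(base, config.shifts.get(clade, {}), s)
            for clade in config.clades
        }
        for iso, clade in isolates:
            member = ancestor.copy()
            redraw = rng.random(length) < s
            if redraw.any():
                if config.surface_only:
                    surf_redraw = redraw & mask
                    other_redraw = redraw & ~mask
                    if surf_redraw.any():
                        member[surf_redraw] = rng.choice(
                            aa, size=surf_redraw.sum(), p=tilted[clade]
                        )
                    if other_redraw.any():
                        member[other_redraw] = rng.choice(
                            aa, size=other_redraw.sum(), p=base
                        )
                else:
                    member[redraw] = rng.choice(aa, size=redraw.sum(), p=tilted[clade])
            pid = f"{iso}|{fam_id}"
            proteins.append((pid, iso, clade, "".join(member)))
            protein_family[pid] = fam_id
        fam_truth[fam_id] = {
            "length": length,
            "target_identity": identity,
            "substitution_rate": s,
        }

    truth = {
        "seed": seed,
        "families": fam_truth,
        "shifts": {c: dict(v) for c, v in config.shifts.items()},
        "surface_only": config.surface_only,
        "mean_target_identity": config.target_identity,
    }
    return SyntheticProteomeSet(proteins, surface_masks, protein_family, truth)


def per_protein_frequencies(
    protset: SyntheticProteomeSet, region: str = "all"
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-protein amino-acid frequency table, optionally restricted to
    the planted surface (``region="surface"``) or core (``"core"``)
    positions of each protein's family.

    Returns (frequency DataFrame indexed by protein id with one column
    per amino acid, Series of clade labels).
    """
    if region not in {"all", "surface", "core"}:
        raise ValueError(f"unknown region {region!r}")
    rows = {}
    clades = {}
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    for pid, _iso, clade, seq in protset.proteins:
        mask = protset.surface_masks[protset.protein_family[pid]]
        arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
        if region == "surface":
            arr = arr[mask]
        elif region == "core":
            arr = arr[~mask]
        counts = np.zeros(20)
        for ch in arr:
            counts[aa_index[ch]] += 1
        rows[pid] = counts / counts.sum()
        clades[pid] = clade
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(AMINO_ACIDS))
    return df, pd.Series(clades)


# ---------------------------------------------------------------------------
# peptide builder
# ---------------------------------------------------------------------------

# ideal backbone geometry
_B_N_CA = 1.46
_B_CA_C = 1.52
_B_C_N = 1.33
_B_C_O = 1.23
_A_N_CA_C = 111.0
_A_CA_C_N = 117.0
_A_C_N_CA = 121.0
_A_CA_C_O = 121.0

_CONFORMATIONS = {
    "helix": (-57.0, -47.0),
    "strand": (-139.0, 135.0),
    "extended": (180.0, 180.0),
}

#: Idealized side-chain pseudo-atom templates in the local residue frame
#: (origin CA, x along CA->CB, y toward the backbone N projection,
#: z completing the right-handed frame).  Only the atoms the interaction
#: detector consults are placed; geometry is approximate except for the
#: CB attachment.
_SIDE_CHAINS: dict[str, list[tuple[str, float, float, float]]] = {
    "GLY": [],
    "ALA": [("CB", 1.53, 0.0, 0.0)],
    "VAL": [("CB", 1.53, 0.0, 0.0), ("CG1", 2.80, 0.84, 0.0), ("CG2", 2.20, -0.50, 1.20)],
    "LEU": [("CB", 1.53, 0.0, 0.0), ("CG", 2.80, 0.84, 0.0), ("CD1", 4.07, 0.0, 0.0),
            ("CD2", 3.30, 1.90, 0.80)],
    "ILE": [("CB", 1.53, 0.0, 0.0), ("CG1", 2.80, 0.84, 0.0), ("CG2", 2.20, -0.80, 1.10),
            ("CD1", 4.07, 0.0, 0.0)],
    "MET": [("CB", 1.53, 0.0, 0.0), ("CG", 2.80, 0.84, 0.0), ("SD", 4.30, 0.0, 0.0),
            ("CE", 5.60, 0.80, 0.0)],
    "PRO": [("CB", 1.53, 0.0, 0.0), ("CG", 2.60, 0.90, 0.0), ("CD", 2.40, 1.90, -0.50)],
    "SER": [("CB", 1.53, 0.0, 0.0), ("OG", 2.70, 0.80, 0.0)],
    "THR": [("CB", 1.53, 0.0, 0.0), ("OG1", 2.70, 0.80, 0.0), ("CG2", 2.20, -0.80, 1.10)],
    "CYS": [("CB", 1.53, 0.0, 0.0), ("SG", 3.00, 0.90, 0.0)],
    "ASN": [("CB", 1.53, 0.0, 0.0), ("CG", 2.80, 0.84, 0.0), ("OD1", 3.40, 2.00, 0.0),
            ("ND2", 4.00, 0.10, 0.0)],
    "GLN": [("CB", 1.53, 0.0, 0.0), ("CG", 2.80, 0.84, 0.0), ("CD", 4.07, 0.0, 0.0),
            ("OE1", 4.60, -1.20, 0.0), ("NE2", 5.20, 0.90, 0.0)],
    "ASP": [("CB", 1.53, 0.0, 0.0), ("CG", 2.80, 0.84, 0.0), ("OD1", 3.40, 2.00, 0.0),
            ("OD2", 4.00, 0.10, 0.0)],
    "GLU": [("CB", 1.53, 0.0, 0.0), ("CG", 2.80, 0.84, 0.0), ("CD", 4.07, 0.0, 0.0),
            ("OE1", 4.60, -1.20, 0.0), ("OE2", 5.20, 0.90, 0.0)],
    "LYS": [("CB", 1.53, 0.0, 0.0), ("CG", 2.80, 0.84, 0.0), ("CD", 4.07, 0.0, 0.0),
            ("CE", 5.34, 0.84, 0.0), ("NZ", 6.60, 0.0, 0.0)],
    "ARG": [("CB", 1.53, 0.0, 0.0), ("CG", 2.80, 0.84, 0.0), ("CD", 4.07, 0.0, 0.0),
            ("NE", 5.30, 0.80, 0.0), ("CZ", 6.50, 0.30, 0.0), ("NH1", 7.60, 1.00, 0.0),
            ("NH2", 6.60, -1.00, 0.0)],
    "HIS": [("CB", 1.53, 0.0, 0.0), ("CG", 2.80, 0.84, 0.0), ("ND1", 3.50, 2.00, 0.0),
            ("CD2", 3.70, -0.30, 0.0), ("CE1", 4.90, 1.90, 0.0), ("NE2", 5.00, 0.50, 0.0)],
    "PHE": [("CB", 1.53, 0.0, 0.0), ("CG", 2.80, 0.84, 0.0), ("CD1", 3.55, 2.00, 0.0),
            ("CD2", 3.45, -0.32, 0.0), ("CE1", 4.94, 2.00, 0.0), ("CE2", 4.84, -0.32, 0.0),
            ("CZ", 5.59, 0.84, 0.0)],
    "TYR": [("CB", 1.53, 0.0, 0.0), ("CG", 2.80, 0.84, 0.0), ("CD1", 3.55, 2.00, 0.0),
            ("CD2", 3.45, -0.32, 0.0), ("CE1", 4.94, 2.00, 0.0), ("CE2", 4.84, -0.32, 0.0),
            ("CZ", 5.59, 0.84, 0.0), ("OH", 6.97, 0.84, 0.0)],
    "TRP": [("CB", 1.53, 0.0, 0.0), ("CG", 2.80, 0.84, 0.0), ("CD1", 3.50, 2.00, 0.0),
            ("NE1", 4.80, 1.90, 0.0), ("CE2", 5.00, 0.60, 0.0), ("CD2", 3.90, -0.10, 0.0),
            ("CE3", 3.80, -1.50, 0.0), ("CZ3", 5.00, -2.20, 0.0), ("CH2", 6.20, -1.60, 0.0),
            ("CZ2", 6.20, -0.20, 0.0)],
}

_ONE_TO_THREE = {v: k for k, v in
                 {"ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
                  "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
                  "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
                  "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V"}.items()}


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _place(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, r: float, theta_deg: float, tau_deg: float
) -> np.ndarray:
    """Natural extension reference frame: place D from A-B-C with bond
    length r(C-D), angle theta(B-C-D) and torsion tau(A-B-C-D)."""
    theta = math.radians(theta_deg)
    tau = math.radians(tau_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array(
        [-r * math.cos(theta), r * math.sin(theta) * math.cos(tau),
         r * math.sin(theta) * math.sin(tau)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_peptide(sequence: str, conformation: str = "extended") -> StructureModel:
    """Build an idealized peptide with the requested backbone conformation.

    The backbone uses ideal bond lengths (N-CA 1.46, CA-C 1.52,
    C-N 1.33 A) and angles (111/117/121 deg) with omega = 180 and
    phi/psi set by the conformation (helix -57/-47, strand -139/+135,
    extended 180/180).  Side chains are reduced to the pseudo-atoms the
    interaction detector consults, at idealized geometry.  Deterministic:
    identical inputs give identical coordinates.
    """
    if conformation not in _CONFORMATIONS:
        raise ValueError(f"unknown conformation {conformation!r}")
    phi, psi = _CONFORMATIONS[conformation]
    seq3 = []
    for ch in sequence.upper():
        if ch not in _ONE_TO_THREE:
            raise ValueError(f"unknown residue {ch!r}")
        seq3.append(_ONE_TO_THREE[ch])

    n_res = len(seq3)
    if n_res == 0:
        raise ValueError("empty sequence")

    # backbone trace
    bb: list[dict[str, np.ndarray]] = []
    n0 = np.zeros(3)
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(180.0 - _A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
    bb.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = bb[-1]
        n_i = _place(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi)
        ca_i = _place(prev["CA"], prev["C"], n_i, _B_N_CA, _A_C_N_CA, 180.0)
        c_i = _place(prev["C"], n_i, ca_i, _B_CA_C, _A_N_CA_C, phi)
        bb.append({"N": n_i, "CA": ca_i, "C": c_i})

    residues: list[Residue] = []
    for i, res3 in enumerate(seq3):
        n_at, ca_at, c_at = bb[i]["N"], bb[i]["CA"], bb[i]["C"]
        atoms = [
            Atom("N", "N", n_at),
            Atom("CA", "C", ca_at),
            Atom("C", "C", c_at),
            Atom("O", "O", _place(n_at, ca_at, c_at, _B_C_O, _A_CA_C_O, psi + 180.0)),
        ]
        # local side-chain frame
        template = _SIDE_CHAINS[res3]
        if template:
            u1 = _unit(n_at - ca_at)
            u2 = _unit(c_at - ca_at)
            bis = _unit(u1 + u2)
            nrm = _unit(np.cross(u1, u2))
            cos_t = math.cos(math.radians(110.5))
            alpha = cos_t / float(np.dot(bis, u1))
            beta = math.sqrt(max(0.0, 1.0 - alpha * alpha))
            x_hat = _unit(alpha * bis + beta * nrm)
            y_hat = _unit(u1 - np.dot(u1, x_hat) * x_hat)
            z_hat = np.cross(x_hat, y_hat)
            for name, x, y, z in template:
                coord = ca_at + x * x_hat + y * y_hat + z * z_hat
                atoms.append(Atom(name, name[0], coord))
        residues.append(Residue(index=i + 1, name=res3, atoms=atoms))
    return StructureModel(protein_id=f"peptide_{sequence}", residues=residues)


# ---------------------------------------------------------------------------
# contact fixtures
# ---------------------------------------------------------------------------

_FIXTURE_RESIDUES: dict[str, tuple[str, str]] = {
    "disulfide": ("C", "C"),
    "ionic": ("K", "D"),
    "aromatic_aromatic": ("F", "F"),
    "aromatic_sulfur": ("M", "F"),
    "cation_pi": ("K", "F"),
    "hydrophobic": ("A", "A"),
}


def _anchor(res: Residue, role: str, itype: str) -> np.ndarray:
    """The point whose pair distance defines the interaction criterion."""
    def centroid(names: Sequence[str]) -> np.ndarray:
        return np.mean([res.atom(n).coord for n in names if res.atom(n)], axis=0)

    if itype == "disulfide":
        return res.atom("SG").coord
    if itype == "ionic":
        table = CATION_ATOMS if role == "a" else ANION_ATOMS
        return centroid(table[res.name])
    if itype == "aromatic_aromatic":
        return centroid(RING_ATOMS[res.name])
    if itype == "aromatic_sulfur":
        return res.atom(SULFUR_ATOMS[res.name]).coord if role == "a" else centroid(RING_ATOMS[res.name])
    if itype == "cation_pi":
        return res.atom(CATION_PI_ATOMS[res.name]).coord if role == "a" else centroid(RING_ATOMS[res.name])
    if itype == "hydrophobic":
        return res.atom("CB").coord
    raise ValueError(f"unknown interaction type {itype!r}")


def _criterion_truth(itype: str, distance: float, crit: InteractionCriteria) -> bool:
    if itype == "aromatic_aromatic":
        return crit.aromatic_min <= distance <= crit.aromatic_max
    cutoff = {
        "disulfide": crit.disulfide_max,
        "ionic": crit.ionic_max,
        "aromatic_sulfur": crit.aromatic_sulfur_max,
        "cation_pi": crit.cation_pi_max,
        "hydrophobic": crit.hydrophobic_max,
    }[itype]
    return distance <= cutoff


def make_contact_fixture(
    interaction_type: str,
    distance: float,
    criteria: InteractionCriteria | None = None,
) -> tuple[StructureModel, bool]:
    """Two-residue fixture whose defining distance equals ``distance``.

    A spacer glycine (placed 60 A away) separates the two residues so
    the sequence-separation rule is met.  Returns (structure, expected
    detection flag), with the flag computed from the distance criterion,
    never by running the detector.
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    if interaction_type not in _FIXTURE_RESIDUES:
        raise ValueError(f"unknown interaction type {interaction_type!r}")
    crit = criteria or InteractionCriteria()
    aa1, aa2 = _FIXTURE_RESIDUES[interaction_type]

    pep1 = build_peptide(aa1, "extended")
    pep2 = build_peptide(aa2, "extended")
    spacer = build_peptide("G", "extended")

    res1 = pep1.residues[0]
    res2 = pep2.residues[0]

    # point residue 2's side chain back toward residue 1
    rot = np.diag([-1.0, -1.0, 1.0])  # 180 deg about z
    for atom in res2.atoms:
        atom.coord = rot @ atom.coord

    a1 = _anchor(res1, "a", interaction_type)
    a2 = _anchor(res2, "b", interaction_type)
    target = a1 + np.array([distance, 0.0, 0.0])
    shift = target - a2
    for atom in res2.atoms:
        atom.coord = atom.coord + shift

    for atom in spacer.residues[0].atoms:
        atom.coord = atom.coord + np.array([0.0, 60.0, 0.0])

    residues = [
        Residue(index=1, name=res1.name, atoms=res1.atoms),
        Residue(index=2, name="GLY", atoms=spacer.residues[0].atoms),
        Residue(index=3, name=res2.name, atoms=res2.atoms),
    ]
    model = StructureModel(
        protein_id=f"fixture_{interaction_type}_{distance:g}", residues=residues
    )
    return model, _criterion_truth(interaction_type, distance, crit)


def make_core_surface_fixture(
    n_core: int, n_surface: int, shell_radius: float = 4.9
) -> tuple[StructureModel, dict[int, str]]:
    """Sphere fixture with known core/surface truth.

    ``n_core`` alanines are packed at the center and enclosed by
    ``n_surface`` alanines on a shell with side chains pointing outward,
    so the central residues' relative accessibility is far below the
    20 % core threshold and the shell residues' far above it.  Dense
    coverage needs roughly 16+ shell residues.  Returns (structure,
    truth mapping residue index -> "core"/"surface").
    """
    if n_core < 1 or n_surface < 1:
        raise ValueError("need at least one core and one surface residue")
    residues: list[Residue] = []
    truth: dict[int, str] = {}
    idx = 1

    core_dirs = fibonacci_sphere(max(n_core, 2))[:n_core]
    for k in range(n_core):
        p = 0.9 * core_dirs[k]
        atoms = [
            Atom("N", "N", p + np.array([-0.7, 0.0, 0.0])),
            Atom("CA", "C", p),
            Atom("C", "C", p + np.array([0.7, 0.0, 0.0])),
            Atom("CB", "C", p + np.array([0.0, 0.7, 0.0])),
        ]
        residues.append(Residue(index=idx, name="ALA", atoms=atoms))
        truth[idx] = "core"
        idx += 1

    dirs = fibonacci_sphere(n_surface)
    for k in range(n_surface):
        u = dirs[k]
        # tangent frame
        ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        t1 = _unit(np.cross(u, ref))
        t2 = np.cross(u, t1)
        ca = shell_radius * u
        atoms = [
            Atom("N", "N", ca + 0.8 * t1),
            Atom("CA", "C", ca),
            Atom("C", "C", ca + 0.8 * t2),
            Atom("CB", "C", ca + 1.45 * u),
        ]
        residues.append(Residue(index=idx, name="ALA", atoms=atoms))
        truth[idx] = "surface"
        idx += 1

    model = StructureModel(protein_id=f"core_surface_{n_core}_{n_surface}", residues=residues)
    return model, truth


# ---------------------------------------------------------------------------
# auxiliary fixtures: tree, QC metrics, AAI matrix
# ---------------------------------------------------------------------------


def make_clade_tree(
    clade_isolates: Mapping[str, Sequence[str]], seed: int = 0, depth: float = 0.30
) -> str:
    """Newick string for a clade-structured tree with leaf depths around
    ``depth`` substitutions per site (below the 0.5 comparability check)."""
    rng = np.random.default_rng(seed)
    stem = 0.10
    leaf_base = max(0.01, depth - 2 * stem)

    def clade_newick(members: Sequence[str]) -> str:
        # polytomy: every leaf hangs directly off the clade node
        leaves = ",".join(
            f"{m}:{leaf_base * rng.uniform(0.8, 1.2):.4f}" for m in members
        )
        return f"({leaves}):{stem:.4f}"

    clades = list(clade_isolates)
    half = len(clades) // 2 or 1
    groups = []
    for group in (clades[:half], clades[half:]):
        if not group:
            continue
        sub = ",".join(clade_newick(clade_isolates[c]) for c in group)
        groups.append(f"({sub}):{stem:.4f}")
    return f"({','.join(groups)});"


def make_qc_metrics_fixture(
    n_total: int = 108, n_retained: int = 78, seed: int = 0
) -> tuple[list[GenomeQCMetrics], set[str]]:
    """Assembly-metrics table with planted QC violations.

    ``n_total - n_retained`` genomes receive at least one planted
    violation (too many contigs, low N50, low completeness or high
    contamination); the rest safely pass.  Returns (metrics in shuffled
    order, truth set of passing isolate ids).
    """
    if not 0 <= n_retained <= n_total:
        raise ValueError("need 0 <= n_retained <= n_total")
    rng = np.random.default_rng(seed)
    metrics: list[GenomeQCMetrics] = []
    passing: set[str] = set()
    for i in range(n_total):
        iid = f"G{i:04d}"
        good = i < n_retained
        contigs = int(rng.integers(5, 250))
        n50v = float(rng.uniform(30_000, 500_000))
        comp = float(rng.uniform(95.5, 100.0))
        cont = float(rng.uniform(0.0, 4.0))
        if not good:
            # plant 1-2 violations of random type
            kinds = rng.choice(4, size=int(rng.integers(1, 3)), replace=False)
            if 0 in kinds:
                contigs = int(rng.integers(301, 800))
            if 1 in kinds:
                n50v = float(rng.uniform(1_000, 19_000))
            if 2 in kinds:
                comp = float(rng.uniform(60.0, 94.5))
            if 3 in kinds:
                cont = float(rng.uniform(5.5, 20.0))
        else:
            passing.add(iid)
        metrics.append(GenomeQCMetrics(iid, contigs, n50v, comp, cont))
    order = rng.permutation(n_total)
    return [metrics[i] for i in order], passing


def make_aai_fixture(
    ids: Sequence[str],
    n_components: int = 5,
    component_size: int = 2,
    threshold: float = 99.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[set[str]]]:
    """Symmetric AAI matrix with planted duplicate components.

    ``n_components`` disjoint groups of ``component_size`` isolates get
    pairwise AAI at or above the threshold (duplicates); every other
    pair sits well below.  Returns (matrix, list of planted component
    member sets).
    """
    rng = np.random.default_rng(seed)
    n = len(ids)
    if n_components * component_size > n:
        raise ValueError("not enough isolates for the requested components")
    m = rng.uniform(85.0, 97.0, size=(n, n))
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 100.0)
    chosen = rng.choice(n, size=n_components * component_size, replace=False)
    components: list[set[str]] = []
    for c in range(n_components):
        grp = chosen[c * component_size : (c + 1) * component_size]
        for a in grp:
            for b in grp:
                if a != b:
                    v = rng.uniform(threshold, 99.99)
                    m[a, b] = v
                    m[b, a] = v
        components.append({ids[g] for g in grp})
    return pd.DataFrame(m, index=list(ids), columns=list(ids)), components
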