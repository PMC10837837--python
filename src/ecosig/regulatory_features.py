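"""Regulatory-element feature statistics per isolate.

The extremophile clades differ not only in gene content but in the
composition and copy number of regulatory elements: GC content of the
rRNA and tmRNA genes, AT content of predicted promoters, and the counts
of insertion sequences, small RNAs, CRISPR loci and operons (the latter
normalised per CDS).  All element intervals are consumed as annotations
produced upstream by dedicated predictors; no prediction happens here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .genome_features import at_content, gc_content
from .io_core import AnnotationSet, GenomeRecord, extract_feature_sequence

__all__ = [
    "RegulatoryFeatureVector",
    "feature_gc",
    "promoter_at",
    "element_counts",
    "operons_per_cds",
    "regulatory_feature_table",
]

logger = logging.getLogger(__name__)


@dataclass
class RegulatoryFeatureVector:
    isolate_id: str
    gc_rrna: float  # NaN when the genome has no annotated rRNA
    gc_tmrna: float
    at_promoter: float
    n_insertion_sequences: int
    n_srna: int
    n_crispr: int
    n_operons: int
    operons_per_cds: float


def feature_gc(
    genome: GenomeRecord, annotations: AnnotationSet, feature_type: str
) -> float:
    """GC fraction pooled over all features of the requested type.

    Multi-copy features (e.g. the rRNA genes) are pooled by
    concatenation, which weights long copies more; extraction is
    strand-resolved (GC is strand-invariant, but this keeps the
    convention uniform with codon-position statistics).  Returns NaN
    with a warning when the genome has no feature of the type.
    """
    feats = annotations.of_type(feature_type)
    if not feats:
        logger.warning("no %s features; GC undefined", feature_type)
        return float("nan")
    pooled = "".join(extract_feature_sequence(genome, f) for f in feats)
    return gc_content(pooled)


def promoter_at(genome: GenomeRecord, annotations: AnnotationSet) -> float:
    """AT fraction pooled over all promoter intervals ((A+T)/(A+C+G+T));
    ambiguity codes are excluded from both counts.  NaN when the genome
    has no promoter annotation."""
    feats = annotations.of_type("promoter")
    if not feats:
        logger.warning("no promoter features; AT content undefined")
        return float("nan")
    pooled = "".join(extract_feature_sequence(genome, f) for f in feats)
    return at_content(pooled)


def element_counts(annotations: AnnotationSet) -> dict[str, int]:
    """Raw counts of insertion_sequence, sRNA, CRISPR and operon records."""
    counts = annotations.counts()
    return {
        "insertion_sequence": counts["insertion_sequence"],
        "sRNA": counts["sRNA"],
        "CRISPR": counts["CRISPR"],
        "operon": counts["operon"],
    }


def operons_per_cds(annotations: AnnotationSet) -> float:
    """Number of operons divided by the number of CDS (errors on 0 CDS)."""
    n_cds = len(annotations.of_type("CDS"))
    if n_cds == 0:
        raise ValueError("zero CDS: operons per CDS undefined")
    return len(annotations.of_type("operon")) / n_cds


def regulatory_feature_vector(
    isolate_id: str, genome: GenomeRecord, annotations: AnnotationSet
) -> RegulatoryFeatureVector:
    """The complete per-isolate regulatory feature vector.

    Every field is always present; undefined values are NaN, never
    silently dropped.
    """
    counts = element_counts(annotations)
    n_cds = len(annotations.of_type("CDS"))
    return RegulatoryFeatureVector(
        isolate_id=isolate_id,
        gc_rrna=feature_gc(genome, annotations, "rRNA"),
        gc_tmrna=feature_gc(genome, annotations, "tmRNA"),
        at_promoter=promoter_at(genome, annotations),
        n_insertion_sequences=counts["insertion_sequence"],
        n_srna=counts["sRNA"],
        n_crispr=counts["CRISPR"],
        n_operons=counts["operon"],
        operons_per_cds=(counts["operon"] / n_cds) if n_cds else float("nan"),
    )


def regulatory_feature_table(
    genomes: dict[str, GenomeRecord], annotations: dict[str, AnnotationSet]
) -> pd.DataFrame:
    """Per-isolate table of all regulatory features (rows = isolate ids)."""
    rows = []
    for iid, genome in genomes.items():
        v = regulatory_feature_vector(iid, genome, annotations[iid])
        rows.append(
            {
                "isolate_id": iid,
                "gc_rRNA": v.gc_rrna,
                "gc_tmRNA": v.gc_tmrna,
                "at_promoter": v.at_promoter,
                "n_insertion_sequences": v.n_insertion_sequences,
                "n_sRNA": v.n_srna,
                "n_CRISPR": v.n_crispr,
                "n_operons": v.n_operons,
                "operons_per_CDS": v.operons_per_cds,
            }
        )
    return pd.DataFrame(rows).set_index("isolate_id")
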