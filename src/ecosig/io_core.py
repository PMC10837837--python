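"""Shared data model and readers/writers for the formats the pipeline touches.

Everything downstream (genome features, regulatory features, proteome
composition, structure analysis, clade contrasts) consumes the containers
defined here: :class:`GenomeRecord`, :class:`IsolateMetadata`,
:class:`AnnotationSet`, :class:`StructureModel` and :class:`PhyloTree`.

Coordinate convention
---------------------
All in-memory intervals are 0-based half-open.  GFF3 files are 1-based
inclusive; the conversion happens exactly once, inside :func:`read_gff3`
and :func:`write_gff3`, so converting twice is the identity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "GenomeRecord",
    "IsolateMetadata",
    "GenomeFeature",
    "AnnotationSet",
    "Atom",
    "Residue",
    "StructureModel",
    "PhyloTree",
    "FEATURE_TYPES",
    "DEFAULT_FEATURE_ALIASES",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_pdb",
    "write_pdb",
    "read_newick",
    "read_metadata",
    "write_metadata",
    "read_table",
    "write_table",
    "reverse_complement",
    "extract_feature_sequence",
]

logger = logging.getLogger(__name__)

TOOL_VERSION = "0.1.0"

# IUPAC nucleotide alphabet, upper-case canonical
_IUPAC_NT = set("ACGTNRYSWKMBDHV")

_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHVacgtnryswkmbdhv",
    "TGCANYRSWMKVHDBtgcanyrswmkvhdb",
)

#: Closed vocabulary of genomic feature types the pipeline understands.
FEATURE_TYPES = frozenset(
    {
        "CDS",
        "rRNA",
        "tmRNA",
        "sRNA",
        "insertion_sequence",
        "CRISPR",
        "operon",
        "promoter",
    }
)

#: Default alias table mapping common annotator vocabularies onto the
#: closed feature-type set.  Users extend this to match their annotator
#: (e.g. which attribute their CRISPR caller emits).
DEFAULT_FEATURE_ALIASES: dict[str, str] = {
    "cds": "CDS",
    "rrna": "rRNA",
    "tmrna": "tmRNA",
    "tRNA-like tmRNA": "tmRNA",
    "srna": "sRNA",
    "ncRNA": "sRNA",
    "small_regulatory_ncRNA": "sRNA",
    "insertion sequence": "insertion_sequence",
    "IS": "insertion_sequence",
    "mobile_genetic_element": "insertion_sequence",
    "repeat_region": "CRISPR",
    "direct_repeat": "CRISPR",
    "CRISPR_array": "CRISPR",
    "transcriptional_unit": "operon",
    "TSS": "promoter",
}


def reverse_complement(sequence: str) -> str:
    """Reverse-complement a nucleotide sequence (IUPAC-aware, case kept)."""
    return sequence.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenomeRecord:
    """Contig sequences of one isolate.

    Parameters
    ----------
    isolate_id : str
        Unique isolate identifier.
    contigs : list of (contig_id, sequence)
        Ordered contigs; sequences over the IUPAC nucleotide alphabet
        (validated case-insensitively).
    source : str
        Free-text provenance.
    """

    isolate_id: str
    contigs: list[tuple[str, str]]
    source: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cid, seq in self.contigs:
            if cid in seen:
                raise ValueError(f"duplicate contig id {cid!r} in {self.isolate_id!r}")
            seen.add(cid)
            if not seq:
                raise ValueError(f"empty sequence for contig {cid!r}")
            bad = set(seq.upper()) - _IUPAC_NT
            if bad:
                raise ValueError(
                    f"invalid nucleotide characters {sorted(bad)} in contig {cid!r}"
                )

    @property
    def contig_map(self) -> dict[str, str]:
        return dict(self.contigs)

    def contig_length(self, contig_id: str) -> int:
        return len(self.contig_map[contig_id])

    @property
    def genome_length(self) -> int:
        return sum(len(s) for _, s in self.contigs)


@dataclass
class IsolateMetadata:
    """Per-isolate metadata row (clade label, habitat, QC metrics)."""

    isolate_id: str
    clade_label: str
    habitat: str | None = None
    mat: float | None = None  # mean annual temperature of isolation site, degC
    salinity: float | None = None  # % NaCl m/v
    completeness: float | None = None  # %
    contamination: float | None = None  # %
    n_contigs: int | None = None
    is_type_strain: bool = False

    def __post_init__(self) -> None:
        for name in ("completeness", "contamination"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        if self.salinity is not None and self.salinity < 0:
            raise ValueError(f"salinity must be >= 0, got {self.salinity}")


@dataclass
class GenomeFeature:
    """One typed, stranded genomic feature in 0-based half-open coordinates."""

    feature_type: str
    contig_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str = "+"
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.feature_type!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.feature_type}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotationSet:
    """Validated collection of :class:`GenomeFeature` records for one genome."""

    features: list[GenomeFeature] = field(default_factory=list)

    def of_type(self, feature_type: str) -> list[GenomeFeature]:
        if feature_type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {feature_type!r}")
        return [f for f in self.features if f.feature_type == feature_type]

    def counts(self) -> dict[str, int]:
        out = {t: 0 for t in sorted(FEATURE_TYPES)}
        for f in self.features:
            out[f.feature_type] += 1
        return out

    def validate_against(self, genome: GenomeRecord) -> None:
        cmap = genome.contig_map
        for f in self.features:
            if f.contig_id not in cmap:
                raise ValueError(f"feature on unknown contig {f.contig_id!r}")
            if f.end > len(cmap[f.contig_id]):
                raise ValueError(
                    f"feature [{f.start}, {f.end}) exceeds contig "
                    f"{f.contig_id!r} length {len(cmap[f.contig_id])}"
                )

    def __len__(self) -> int:
        return len(self.features)


def extract_feature_sequence(genome: GenomeRecord, feature: GenomeFeature) -> str:
    """Feature sequence, reverse-complemented for minus-strand features."""
    seq = genome.contig_map[feature.contig_id][feature.start : feature.end]
    if feature.strand == "-":
        seq = reverse_complement(seq)
    return seq


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # shape (3,), Angstrom

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,):
            raise ValueError("atom coordinate must be a 3-vector")
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinates for atom {self.name!r}")


@dataclass
class Residue:
    index: int
    name: str  # 3-letter amino-acid code
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_backbone(self) -> bool:
        return all(self.atom(n) is not None for n in ("N", "CA", "C"))


@dataclass
class StructureModel:
    """Single-chain protein structure: residues with explicit atoms."""

    protein_id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue indices must be strictly increasing")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def missing_backbone(self) -> list[int]:
        """Indices of residues lacking any of N/CA/C."""
        return [r.index for r in self.residues if not r.has_backbone()]


class PhyloTree:
    """Rooted tree with isolate-labelled leaves and branch lengths.

    Thin wrapper around a :class:`dendropy.Tree`; exposes the two queries
    the pipeline needs (leaf labels and root-to-leaf path lengths).
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValueError("leaf labels are not unique")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("negative branch length")

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def leaf_depths(self) -> dict[str, float]:
        """Sum of branch lengths from the root to each leaf."""
        depths: dict[str, float] = {}
        for leaf in self.tree.leaf_node_iter():
            d = 0.0
            node = leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            depths[leaf.taxon.label] = d
        return depths


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]`` in file order.

    Ids are taken up to the first whitespace; sequence whitespace is
    stripped.  Raises on an empty file and on duplicate ids.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    rid: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if rid is not None:
                    records.append((rid, "".join(chunks)))
                rid = line[1:].split()[0] if line[1:].split() else ""
                if rid in seen:
                    raise ValueError(f"duplicate FASTA id {rid!r} in {path}")
                seen.add(rid)
                chunks = []
            elif line.strip():
                if rid is None:
                    raise ValueError(f"sequence before first header in {path}")
                chunks.append("".join(line.split()))
    if rid is not None:
        records.append((rid, "".join(chunks)))
    if not records:
        raise ValueError(f"no records in FASTA file {path}")
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    """Write ``(id, sequence)`` pairs as FASTA (no comment lines: the FASTA
    dialect has no portable comment syntax, so the version tag is omitted)."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def read_gff3(
    path: str | Path,
    genome: GenomeRecord,
    aliases: Mapping[str, str] | None = None,
) -> AnnotationSet:
    """Read a GFF3 file against its genome.

    Coordinates are converted from GFF3 1-based inclusive to the internal
    0-based half-open convention.  Feature types outside the closed
    vocabulary are resolved through the alias table; still-unknown types
    are skipped with a logged warning.  A coordinate outside its contig
    raises with the offending line number.
    """
    from gffutils.feature import feature_from_line

    alias_table = dict(DEFAULT_FEATURE_ALIASES)
    if aliases:
        alias_table.update(aliases)
    cmap = genome.contig_map

    features: list[GenomeFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            feat = feature_from_line(line)
            ftype = feat.featuretype
            if ftype not in FEATURE_TYPES:
                ftype = alias_table.get(ftype, alias_table.get(ftype.lower(), ""))
            if ftype not in FEATURE_TYPES:
                logger.warning(
                    "line %d: feature type %r not in vocabulary or alias table; skipped",
                    lineno,
                    feat.featuretype,
                )
                continue
            if feat.seqid not in cmap:
                raise ValueError(f"line {lineno}: unknown contig {feat.seqid!r}")
            if not (1 <= feat.start <= feat.end <= len(cmap[feat.seqid])):
                raise ValueError(
                    f"line {lineno}: coordinates {feat.start}..{feat.end} outside "
                    f"contig {feat.seqid!r} (length {len(cmap[feat.seqid])})"
                )
            features.append(
                GenomeFeature(
                    feature_type=ftype,
                    contig_id=feat.seqid,
                    start=feat.start - 1,  # GFF3 1-based inclusive -> half-open
                    end=feat.end,
                    strand=feat.strand if feat.strand in "+-" else "+",
                    attributes={k: ",".join(v) for k, v in feat.attributes.items()},
                )
            )
    ann = AnnotationSet(features)
    ann.validate_against(genome)
    return ann


def write_gff3(path: str | Path, annotations: AnnotationSet, source: str = "ecosig") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"#!ecosig {TOOL_VERSION}\n")
        for f in annotations.features:
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items()) or "."
            fh.write(
                "\t".join(
                    [
                        f.contig_id,
                        source,
                        f.feature_type,
                        str(f.start + 1),  # half-open -> GFF3 1-based inclusive
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

_WATER_NAMES = {"HOH", "WAT", "DOD"}


def read_pdb(path: str | Path) -> StructureModel:
    """Read a PDB coordinate file into a :class:`StructureModel`.

    HETATM records and waters are excluded; alternate locations are
    resolved by highest occupancy then first-seen; only the first model
    and first chain are used (with a warning when more are present).
    Residues missing any of N/CA/C are kept but flagged via
    :meth:`StructureModel.missing_backbone`.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    pdb = PDBFile.read(str(path))
    if pdb.get_model_count() > 1:
        warnings.warn(f"{path.name}: multiple models, using the first")
    atoms = pdb.get_structure(model=1, altloc="occupancy")
    atoms = atoms[~atoms.hetero]
    atoms = atoms[~np.isin(atoms.res_name, list(_WATER_NAMES))]
    if atoms.array_length() == 0:
        raise ValueError(f"{path.name}: zero residues after removing waters/HETATM")
    chains = np.unique(atoms.chain_id)
    if len(chains) > 1:
        warnings.warn(f"{path.name}: multiple chains {list(chains)}, using the first")
        atoms = atoms[atoms.chain_id == atoms.chain_id[0]]

    residues: list[Residue] = []
    for res_id in np.unique(atoms.res_id):
        sel = atoms[atoms.res_id == res_id]
        residues.append(
            Residue(
                index=int(res_id),
                name=str(sel.res_name[0]),
                atoms=[
                    Atom(name=str(n), element=str(e).upper(), coord=c)
                    for n, e, c in zip(sel.atom_name, sel.element, sel.coord)
                ],
            )
        )
    model = StructureModel(protein_id=path.stem, residues=residues)
    if not model.residues:
        raise ValueError(f"{path.name}: zero residues")
    return model


def write_pdb(path: str | Path, model: StructureModel) -> None:
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = sum(len(r.atoms) for r in model.residues)
    arr = struc.AtomArray(n)
    i = 0
    for res in model.residues:
        for atom in res.atoms:
            arr.chain_id[i] = "A"
            arr.res_id[i] = res.index
            arr.res_name[i] = res.name
            arr.atom_name[i] = atom.name
            arr.element[i] = atom.element
            arr.coord[i] = atom.coord
            arr.hetero[i] = False
            i += 1
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def read_newick(path: str | Path) -> PhyloTree:
    """Read a Newick tree; missing branch lengths become 0 with a warning."""
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"Newick parse error in {path}: {exc}") from exc
    n_missing = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = 0.0
            n_missing += 1
    if n_missing:
        warnings.warn(f"{n_missing} branch length(s) missing; set to 0")
    return PhyloTree(tree)


# ---------------------------------------------------------------------------
# metadata / feature tables (TSV)
# ---------------------------------------------------------------------------

_METADATA_COLUMNS = {
    "habitat": "habitat",
    "MAT": "mat",
    "salinity": "salinity",
    "completeness": "completeness",
    "contamination": "contamination",
    "n_contigs": "n_contigs",
    "is_type_strain": "is_type_strain",
}


def read_metadata(path: str | Path) -> list[IsolateMetadata]:
    """Read the isolate metadata TSV (required: isolate_id, clade_label)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"isolate_id": str})
    for col in ("isolate_id", "clade_label"):
        if col not in df.columns:
            raise ValueError(f"metadata table is missing required column {col!r}")
    out: list[IsolateMetadata] = []
    for _, row in df.iterrows():
        kwargs: dict = {
            "isolate_id": str(row["isolate_id"]),
            "clade_label": str(row["clade_label"]),
        }
        for col, attr in _METADATA_COLUMNS.items():
            if col in df.columns and not pd.isna(row[col]):
                v = row[col]
                if attr == "n_contigs":
                    v = int(v)
                elif attr == "is_type_strain":
                    v = bool(v) if isinstance(v, (bool, np.bool_)) else str(v).lower() in {"true", "1", "yes"}
                elif attr != "habitat":
                    v = float(v)
                kwargs[attr] = v
        out.append(IsolateMetadata(**kwargs))
    return out


def write_metadata(path: str | Path, records: Sequence[IsolateMetadata]) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "isolate_id": r.isolate_id,
                "clade_label": r.clade_label,
                "habitat": r.habitat,
                "MAT": r.mat,
                "salinity": r.salinity,
                "completeness": r.completeness,
                "contamination": r.contamination,
                "n_contigs": r.n_contigs,
                "is_type_strain": r.is_type_strain,
            }
        )
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(f"# ecosig {TOOL_VERSION}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path, index_col: str = "isolate_id") -> pd.DataFrame:
    """Read a feature table written by :func:`write_table`."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df[index_col].duplicated().any():
        dup = df[index_col][df[index_col].duplicated()].iloc[0]
        raise ValueError(f"duplicated row key {dup!r}")
    return df.set_index(index_col)


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    """Write a feature table as TSV with a version comment header.

    Missing values are written as empty cells and round-trip as NaN,
    never as zero.
    """
    with open(path, "w") as fh:
        fh.write(f"# ecosig {TOOL_VERSION}\n")
        table.to_csv(fh, sep="\t")
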