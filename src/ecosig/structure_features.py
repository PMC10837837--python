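"""Structure-derived features: solvent accessibility, secondary structure,
residue-residue interactions, stratified composition, stability scores.

Solvent-accessible surface area (SASA) is computed with a Shrake-Rupley
point-sampling engine; relative solvent accessibility (RSA) divides the
residue SASA by its value in an extended Gly-X-Gly tripeptide built with
the very same engine, and residues with RSA <= 0.20 are classified as
core, the rest as surface.  Secondary structure is assigned from
backbone phi/psi torsion windows.  Six interaction classes
(aromatic-aromatic, aromatic-sulfur, cation-pi, ionic, disulfide,
hydrophobic) are detected with explicit, configurable distance criteria.
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
from scipy.spatial import cKDTree

from .io_core import Residue, StructureModel

__all__ = [
    "ResidueAnnotation",
    "InteractionContact",
    "InteractionCriteria",
    "vdw_radius",
    "fibonacci_sphere",
    "compute_sasa",
    "max_asa",
    "relative_accessibility",
    "backbone_torsions",
    "assign_secondary_structure",
    "detect_interactions",
    "interaction_density",
    "stratified_composition",
    "aggregate_stability",
    "percent_change",
    "AA_3TO1",
]

logger = logging.getLogger(__name__)

AA_3TO1: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# residue sets used by the interaction detector (His is treated both as
# aromatic and as a cationic-group donor)
HYDROPHOBIC_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "TYR"}
RING_ATOMS: dict[str, tuple[str, ...]] = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}
CATION_ATOMS: dict[str, tuple[str, ...]] = {
    "ARG": ("NH1", "NH2", "NE"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}
ANION_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}
CATION_PI_ATOMS: dict[str, str] = {"LYS": "NZ", "ARG": "CZ"}
SULFUR_ATOMS: dict[str, str] = {"CYS": "SG", "MET": "SD"}

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


@lru_cache(maxsize=None)
def _vdw_table() -> Mapping[str, float]:
    text = (importlib.resources.files("ecosig.data") / "vdw_radii.tsv").read_text()
    out = {}
    for line in text.splitlines():
        if line.startswith("#") or not line.strip():
            continue
        el, r = line.split("\t")
        out[el] = float(r)
    return out


def vdw_radius(element: str) -> float:
    """Van der Waals radius (A) of a heavy element; raises when unknown."""
    table = _vdw_table()
    el = element.upper()
    if el not in table:
        raise ValueError(f"unknown element {element!r} (no van der Waals radius)")
    return table[el]


@dataclass
class ResidueAnnotation:
    residue_index: int
    sasa: float  # A^2
    rsa: float  # fraction of the Gly-X-Gly reference (may exceed 1 at termini)
    region: str  # "core" (RSA <= 0.20) or "surface"
    ss_class: str  # H / E / C


@dataclass(frozen=True)
class InteractionContact:
    type: str
    res_i: int
    res_j: int  # res_i < res_j
    distance: float


@dataclass(frozen=True)
class InteractionCriteria:
    """Distance criteria (A) for the six interaction classes.

    The defaults instantiate the common defaults of residue-interaction
    scanners; every threshold is a config key so other tools' defaults
    can be matched.  All "within" criteria are boundary-inclusive; the
    aromatic-aromatic window is inclusive at both ends.
    """

    hydrophobic_max: float = 5.0
    ionic_max: float = 6.0
    aromatic_min: float = 4.5
    aromatic_max: float = 7.0
    aromatic_sulfur_max: float = 5.3
    cation_pi_max: float = 6.0
    disulfide_max: float = 2.2
    min_seq_sep: int = 2  # |i - j| >= 2 for all classes except disulfide
    tol: float = 1e-9  # float guard so inclusive boundaries are robust

    def within(self, d: float, cutoff: float) -> bool:
        return d <= cutoff + self.tol

    def in_window(self, d: float, lo: float, hi: float) -> bool:
        return lo - self.tol <= d <= hi + self.tol


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA
# ---------------------------------------------------------------------------


@lru_cache(maxsize=8)
def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n_points) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n_points)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def compute_sasa(
    model: StructureModel, probe_radius: float = 1.4, n_points: int = 960
) -> tuple[dict[int, float], np.ndarray, list[tuple[int, str]]]:
    """Shrake-Rupley solvent-accessible surface area.

    Each heavy atom is surrounded by ``n_points`` quasi-uniform sphere
    points at radius ``r_vdw + probe``; a point is buried when it lies
    strictly inside any other atom's expanded sphere (a point exactly on
    the boundary counts as exposed).  Hydrogens are ignored; an unknown
    element raises.

    Returns
    -------
    per_residue : dict residue_index -> SASA (A^2)
    per_atom : array of atom SASA values
    atom_keys : list of (residue_index, atom_name) aligned with per_atom
    """
    coords: list[np.ndarray] = []
    expanded: list[float] = []
    atom_keys: list[tuple[int, str]] = []
    for res in model.residues:
        for atom in res.atoms:
            if atom.element.upper() == "H":
                continue
            coords.append(atom.coord)
            expanded.append(vdw_radius(atom.element) + probe_radius)
            atom_keys.append((res.index, atom.name))
    if not coords:
        raise ValueError("structure has no heavy atoms")
    xyz = np.asarray(coords)
    rad = np.asarray(expanded)
    n = len(rad)
    sphere = fibonacci_sphere(n_points)

    tree = cKDTree(xyz)
    rmax = rad.max()
    per_atom = np.empty(n)
    for i in range(n):
        neigh = tree.query_ball_point(xyz[i], r=rad[i] + rmax)
        neigh = [j for j in neigh if j != i]
        pts = xyz[i] + rad[i] * sphere  # (n_points, 3)
        if neigh:
            nxyz = xyz[neigh]  # (m, 3)
            nrad = rad[neigh]
            d2 = ((pts[:, None, :] - nxyz[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nrad**2)[None, :]).any(axis=1)
            exposed_frac = 1.0 - buried.mean()
        else:
            exposed_frac = 1.0
        per_atom[i] = 4.0 * math.pi * rad[i] ** 2 * exposed_frac

    per_residue: dict[int, float] = {r.index: 0.0 for r in model.residues}
    for (res_idx, _), a in zip(atom_keys, per_atom):
        per_residue[res_idx] += a
    return per_residue, per_atom, atom_keys


@lru_cache(maxsize=None)
def max_asa(residue_type: str, probe_radius: float = 1.4, n_points: int = 960) -> float:
    """Reference SASA of residue X in an extended Gly-X-Gly tripeptide.

    Built on demand with :func:`ecosig.synthetic_data.build_peptide`
    (phi = psi = 180 deg) and measured with the same Shrake-Rupley
    settings, so RSA = 1 for the reference conformation by construction.
    """
    from .synthetic_data import build_peptide

    res3 = residue_type.upper()
    if res3 not in AA_3TO1:
        raise ValueError(f"residue type {residue_type!r} not in the reference table")
    one = AA_3TO1[res3]
    tri = build_peptide(f"G{one}G", conformation="extended")
    per_residue, _, _ = compute_sasa(tri, probe_radius=probe_radius, n_points=n_points)
    return per_residue[tri.residues[1].index]


def relative_accessibility(
    residue_sasa: float,
    residue_type: str,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> tuple[float, str]:
    """RSA and core/surface region of one residue.

    RSA = SASA / maxASA(residue type); region is ``core`` iff
    RSA <= 0.20 (boundary inclusive), else ``surface``.
    """
    ref = max_asa(residue_type, probe_radius, n_points)
    rsa = residue_sasa / ref
    return rsa, ("core" if rsa <= 0.20 else "surface")


# ---------------------------------------------------------------------------
# secondary structure from torsion windows
# ---------------------------------------------------------------------------


def _dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Dihedral angle in degrees, IUPAC sign convention."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


def backbone_torsions(
    model: StructureModel, chain_break_distance: float = 4.5
) -> list[tuple[float | None, float | None]]:
    """Per-residue (phi, psi) in degrees; None where undefined.

    phi(i) needs C(i-1), N(i), CA(i), C(i); psi(i) needs N(i), CA(i),
    C(i), N(i+1).  A CA-CA gap above ``chain_break_distance`` between
    consecutive residues is treated as a chain break and invalidates the
    torsions across it.
    """
    res = model.residues
    n = len(res)

    def ca(i: int) -> np.ndarray | None:
        a = res[i].atom("CA")
        return a.coord if a else None

    linked = []
    for i in range(n - 1):
        c1, c2 = ca(i), ca(i + 1)
        linked.append(
            c1 is not None
            and c2 is not None
            and np.linalg.norm(c2 - c1) <= chain_break_distance
            and res[i + 1].index == res[i].index + 1
        )

    torsions: list[tuple[float | None, float | None]] = []
    for i in range(n):
        phi = psi = None
        atoms_i = {nm: res[i].atom(nm) for nm in ("N", "CA", "C")}
        if all(atoms_i.values()):
            if i > 0 and linked[i - 1]:
                c_prev = res[i - 1].atom("C")
                if c_prev:
                    phi = _dihedral(
                        c_prev.coord,
                        atoms_i["N"].coord,
                        atoms_i["CA"].coord,
                        atoms_i["C"].coord,
                    )
            if i < n - 1 and linked[i]:
                n_next = res[i + 1].atom("N")
                if n_next:
                    psi = _dihedral(
                        atoms_i["N"].coord,
                        atoms_i["CA"].coord,
                        atoms_i["C"].coord,
                        n_next.coord,
                    )
        torsions.append((phi, psi))
    return torsions


def _helix_candidate(phi: float, psi: float) -> bool:
    return -100.0 <= phi <= -30.0 and -80.0 <= psi <= -5.0


def _strand_candidate(phi: float, psi: float) -> bool:
    return -180.0 <= phi <= -90.0 and (90.0 <= psi <= 180.0 or -180.0 <= psi <= -170.0)


def assign_secondary_structure(
    model: StructureModel,
    chain_break_distance: float = 4.5,
    min_helix_run: int = 4,
    min_strand_run: int = 3,
) -> dict[int, str]:
    """Three-class secondary structure (H helix, E sheet, C loop).

    Residues whose phi/psi fall in the helix window form H runs when at
    least ``min_helix_run`` long; the strand window forms E runs of at
    least ``min_strand_run``; everything else — including termini that
    lack a complete torsion pair and residues at chain breaks — is loop.
    """
    torsions = backbone_torsions(model, chain_break_distance)
    flags = []
    for phi, psi in torsions:
        if phi is None or psi is None:
            flags.append("C")
        elif _helix_candidate(phi, psi):
            flags.append("h")
        elif _strand_candidate(phi, psi):
            flags.append("e")
        else:
            flags.append("C")

    out = {r.index: "C" for r in model.residues}
    i = 0
    n = len(flags)
    while i < n:
        if flags[i] in ("h", "e"):
            j = i
            while j < n and flags[j] == flags[i]:
                j += 1
            run = j - i
            if flags[i] == "h" and run >= min_helix_run:
                for k in range(i, j):
                    out[model.residues[k].index] = "H"
            elif flags[i] == "e" and run >= min_strand_run:
                for k in range(i, j):
                    out[model.residues[k].index] = "E"
            i = j
        else:
            i += 1
    return out


def annotate_structure(
    model: StructureModel, probe_radius: float = 1.4, n_points: int = 960
) -> dict[int, ResidueAnnotation]:
    """Full per-residue annotation: SASA, RSA, region, secondary structure."""
    per_residue, _, _ = compute_sasa(model, probe_radius, n_points)
    ss = assign_secondary_structure(model)
    out: dict[int, ResidueAnnotation] = {}
    for res in model.residues:
        rsa, region = relative_accessibility(
            per_residue[res.index], res.name, probe_radius, n_points
        )
        out[res.index] = ResidueAnnotation(
            residue_index=res.index,
            sasa=per_residue[res.index],
            rsa=rsa,
            region=region,
            ss_class=ss[res.index],
        )
    return out


# ---------------------------------------------------------------------------
# interaction detection
# ---------------------------------------------------------------------------


def _atoms(res: Residue, names: Iterable[str]) -> np.ndarray | None:
    coords = [res.atom(n).coord for n in names if res.atom(n) is not None]
    if not coords:
        return None
    return np.asarray(coords)


def _centroid(res: Residue, names: Iterable[str], require: int = 1) -> np.ndarray | None:
    coords = _atoms(res, names)
    if coords is None or len(coords) < require:
        return None
    return coords.mean(axis=0)


def _sidechain_carbons(res: Residue) -> np.ndarray | None:
    coords = [
        a.coord
        for a in res.atoms
        if a.element.upper() == "C" and a.name not in ("C", "CA")
    ]
    if not coords:
        return None
    return np.asarray(coords)


def detect_interactions(
    model: StructureModel, criteria: InteractionCriteria | None = None
) -> list[InteractionContact]:
    """Detect the six interaction classes between residue pairs.

    All classes require sequence separation |i - j| >= 2 except
    disulfides.  At most one contact per residue pair per type is
    recorded, at the closest qualifying distance.  Residues that lack
    the side-chain atoms a class needs are skipped for that class (the
    total skip count is logged).
    """
    crit = criteria or InteractionCriteria()
    res = model.residues
    skipped = 0

    rings: dict[int, np.ndarray] = {}
    cations: dict[int, np.ndarray] = {}
    anions: dict[int, np.ndarray] = {}
    catpi: dict[int, np.ndarray] = {}
    sulfur: dict[int, np.ndarray] = {}
    sg: dict[int, np.ndarray] = {}
    hydro: dict[int, np.ndarray] = {}

    for k, r in enumerate(res):
        if r.name in RING_ATOMS:
            c = _centroid(r, RING_ATOMS[r.name], require=3)
            if c is None:
                skipped += 1
            else:
                rings[k] = c
        if r.name in CATION_ATOMS:
            c = _centroid(r, CATION_ATOMS[r.name])
            if c is None:
                skipped += 1
            else:
                cations[k] = c
        if r.name in ANION_ATOMS:
            c = _centroid(r, ANION_ATOMS[r.name])
            if c is None:
                skipped += 1
            else:
                anions[k] = c
        if r.name in CATION_PI_ATOMS:
            a = r.atom(CATION_PI_ATOMS[r.name])
            if a is not None:
                catpi[k] = a.coord
        if r.name in SULFUR_ATOMS:
            a = r.atom(SULFUR_ATOMS[r.name])
            if a is not None:
                sulfur[k] = a.coord
        if r.name == "CYS":
            a = r.atom("SG")
            if a is not None:
                sg[k] = a.coord
        if r.name in HYDROPHOBIC_RESIDUES:
            c = _sidechain_carbons(r)
            if c is None:
                skipped += 1
            else:
                hydro[k] = c

    if skipped:
        logger.info("%d residues lacked side-chain atoms for some class", skipped)

    def sep_ok(a: int, b: int, min_sep: int) -> bool:
        return abs(res[a].index - res[b].index) >= min_sep

    contacts: list[InteractionContact] = []

    def add(ctype: str, a: int, b: int, dist: float) -> None:
        i, j = sorted((res[a].index, res[b].index))
        contacts.append(InteractionContact(type=ctype, res_i=i, res_j=j, distance=float(dist)))

    keys = sorted(rings)
    for x, a in enumerate(keys):
        for b in keys[x + 1 :]:
            if not sep_ok(a, b, crit.min_seq_sep):
                continue
            d = float(np.linalg.norm(rings[a] - rings[b]))
            if crit.in_window(d, crit.aromatic_min, crit.aromatic_max):
                add("aromatic_aromatic", a, b, d)

    for a in sorted(sulfur):
        for b in sorted(rings):
            if a == b or not sep_ok(a, b, crit.min_seq_sep):
                continue
            d = float(np.linalg.norm(sulfur[a] - rings[b]))
            if crit.within(d, crit.aromatic_sulfur_max):
                add("aromatic_sulfur", a, b, d)

    for a in sorted(catpi):
        for b in sorted(rings):
            if a == b or not sep_ok(a, b, crit.min_seq_sep):
                continue
            d = float(np.linalg.norm(catpi[a] - rings[b]))
            if crit.within(d, crit.cation_pi_max):
                add("cation_pi", a, b, d)

    for a in sorted(cations):
        for b in sorted(anions):
            if a == b or not sep_ok(a, b, crit.min_seq_sep):
                continue
            d = float(np.linalg.norm(cations[a] - anions[b]))
            if crit.within(d, crit.ionic_max):
                add("ionic", a, b, d)

    keys = sorted(sg)
    for x, a in enumerate(keys):
        for b in keys[x + 1 :]:
            if not sep_ok(a, b, 1):
                continue
            d = float(np.linalg.norm(sg[a] - sg[b]))
            if crit.within(d, crit.disulfide_max):
                add("disulfide", a, b, d)

    keys = sorted(hydro)
    for x, a in enumerate(keys):
        for b in keys[x + 1 :]:
            if not sep_ok(a, b, crit.min_seq_sep):
                continue
            d2 = ((hydro[a][:, None, :] - hydro[b][None, :, :]) ** 2).sum(axis=2)
            d = float(math.sqrt(d2.min()))
            if crit.within(d, crit.hydrophobic_max):
                add("hydrophobic", a, b, d)

    # deduplicate (one contact per pair per type, closest distance)
    best: dict[tuple[str, int, int], InteractionContact] = {}
    for c in contacts:
        key = (c.type, c.res_i, c.res_j)
        if key not in best or c.distance < best[key].distance:
            best[key] = c
    return sorted(best.values(), key=lambda c: (c.type, c.res_i, c.res_j))


INTERACTION_TYPES = (
    "aromatic_aromatic",
    "aromatic_sulfur",
    "cation_pi",
    "ionic",
    "disulfide",
    "hydrophobic",
)


def interaction_density(
    contacts: Sequence[InteractionContact], n_residues: int
) -> dict[str, float]:
    """Contacts per residue, by interaction type."""
    if n_residues <= 0:
        raise ValueError("n_residues must be positive")
    out = {t: 0.0 for t in INTERACTION_TYPES}
    for c in contacts:
        out[c.type] += 1.0
    return {t: v / n_residues for t, v in out.items()}


# ---------------------------------------------------------------------------
# stratified composition and stability aggregation
# ---------------------------------------------------------------------------

STRATA = [
    ("core", "H"), ("core", "E"), ("core", "C"),
    ("surface", "H"), ("surface", "E"), ("surface", "C"),
]


def stratified_composition(
    structures: Sequence[tuple[StructureModel, Mapping[int, ResidueAnnotation]]],
    low_support: int = 100,
) -> tuple[pd.DataFrame, dict[str, float], set[tuple[str, str]]]:
    """Amino-acid frequencies per (region x secondary structure) stratum.

    Returns the 6 x 20 frequency table (rows sum to 1 where populated),
    the overall H/E/C fractions, and the set of strata with fewer than
    ``low_support`` residues (flagged, not dropped).
    """
    from .protein_sequence import AMINO_ACIDS

    counts = {s: np.zeros(20) for s in STRATA}
    ss_counts = {"H": 0, "E": 0, "C": 0}
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    for model, ann in structures:
        for r in model.residues:
            a = ann[r.index]
            one = AA_3TO1.get(r.name)
            if one is None:
                continue
            counts[(a.region, a.ss_class)][aa_index[one]] += 1
            ss_counts[a.ss_class] += 1

    rows = {}
    low: set[tuple[str, str]] = set()
    for s in STRATA:
        total = counts[s].sum()
        if total < low_support:
            low.add(s)
        rows["_".join(s)] = counts[s] / total if total > 0 else np.full(20, np.nan)
    freq = pd.DataFrame.from_dict(rows, orient="index", columns=list(AMINO_ACIDS))
    total_ss = sum(ss_counts.values())
    fractions = {k: (v / total_ss if total_ss else float("nan")) for k, v in ss_counts.items()}
    return freq, fractions, low


def percent_change(target: float, reference: float) -> float:
    """Change of target relative to reference in %, scaled by |reference|
    so the sign reads as the direction of the shift (e.g. a stability
    score moving from -0.090 to -0.085 is +5.6 %: toward zero, less
    stable)."""
    if reference == 0:
        return float("nan")
    return 100.0 * (target - reference) / abs(reference)


def aggregate_stability(
    scores: pd.DataFrame,
    protein_clades: Mapping[str, str] | None = None,
    known_residues: Mapping[str, set[int]] | None = None,
) -> tuple[pd.Series, pd.Series | None]:
    """Mean per-residue stability score <S> per protein and per clade.

    ``scores`` must have columns protein_id, residue_index, S (kcal/mol;
    negative = stabilizing).  When ``known_residues`` maps protein ids to
    their structure's residue indices, score rows for unknown residues
    are dropped with a warning that reports the count.  Clade means are
    unweighted over proteins; returns (per_protein, per_clade-or-None).
    An empty table yields empty results.
    """
    required = {"protein_id", "residue_index", "S"}
    if not required.issubset(scores.columns):
        raise ValueError(f"score table needs columns {sorted(required)}")
    df = scores.copy()
    if known_residues is not None:
        mask = [
            row.residue_index in known_residues.get(row.protein_id, set())
            for row in df.itertuples()
        ]
        n_bad = len(df) - sum(mask)
        if n_bad:
            logger.warning("%d score rows reference unknown residues; dropped", n_bad)
        df = df[mask]
    per_protein = df.groupby("protein_id")["S"].mean()
    per_clade = None
    if protein_clades is not None and len(per_protein):
        clades = per_protein.index.map(lambda p: protein_clades.get(p))
        per_clade = per_protein.groupby(clades).mean()
    return per_protein, per_clade
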