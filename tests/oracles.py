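"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results with the simplest possible code
(naive loops, no spatial indexing, no shared helpers with the package)
so they can serve as cross-checks for the optimized implementations.
"""

from __future__ import annotations

import math

import numpy as np

# criteria restated independently (same published thresholds)
HYDROPHOBIC = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "TYR"}
RINGS = {
    "PHE": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TYR": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TRP": ["CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "HIS": ["CG", "ND1", "CD2", "CE1", "NE2"],
}
CATIONS = {"ARG": ["NH1", "NH2", "NE"], "LYS": ["NZ"], "HIS": ["ND1", "NE2"]}
ANIONS = {"ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"]}
TOL = 1e-9


def _get(res, name):
    for a in res.atoms:
        if a.name == name:
            return np.asarray(a.coord)
    return None


def _mean(res, names, require=1):
    pts = [(_get(res, n)) for n in names]
    pts = [p for p in pts if p is not None]
    if len(pts) < require:
        return None
    return np.mean(pts, axis=0)


def brute_force_contacts(model):
    """All-pairs scan over residues with the six published criteria.

    Returns a set of (type, res_i, res_j) with res_i < res_j.
    """
    out = set()
    res = model.residues
    for x in range(len(res)):
        for y in range(x + 1, len(res)):
            r1, r2 = res[x], res[y]
            sep = abs(r1.index - r2.index)
            i, j = sorted((r1.index, r2.index))

            if sep >= 1 and r1.name == "CYS" and r2.name == "CYS":
                a, b = _get(r1, "SG"), _get(r2, "SG")
                if a is not None and b is not None and np.linalg.norm(a - b) <= 2.2 + TOL:
                    out.add(("disulfide", i, j))
            if sep < 2:
                continue
            # hydrophobic: any pair of side-chain carbons within 5.0
            if r1.name in HYDROPHOBIC and r2.name in HYDROPHOBIC:
                found = False
                for a in r1.atoms:
                    if a.element.upper() != "C" or a.name in ("C", "CA"):
                        continue
                    for b in r2.atoms:
                        if b.element.upper() != "C" or b.name in ("C", "CA"):
                            continue
                        if np.linalg.norm(np.asarray(a.coord) - np.asarray(b.coord)) <= 5.0 + TOL:
                            found = True
                if found:
                    out.add(("hydrophobic", i, j))
            # aromatic-aromatic
            if r1.name in RINGS and r2.name in RINGS:
                c1, c2 = _mean(r1, RINGS[r1.name], 3), _mean(r2, RINGS[r2.name], 3)
                if c1 is not None and c2 is not None:
                    d = np.linalg.norm(c1 - c2)
                    if 4.5 - TOL <= d <= 7.0 + TOL:
                        out.add(("aromatic_aromatic", i, j))
            # aromatic-sulfur (either direction)
            for ra, rb in ((r1, r2), (r2, r1)):
                if ra.name in ("CYS", "MET") and rb.name in RINGS:
                    s = _get(ra, "SG" if ra.name == "CYS" else "SD")
                    c = _mean(rb, RINGS[rb.name], 3)
                    if s is not None and c is not None and np.linalg.norm(s - c) <= 5.3 + TOL:
                        out.add(("aromatic_sulfur", i, j))
                # cation-pi
                if ra.name in ("LYS", "ARG") and rb.name in RINGS:
                    p = _get(ra, "NZ" if ra.name == "LYS" else "CZ")
                    c = _mean(rb, RINGS[rb.name], 3)
                    if p is not None and c is not None and np.linalg.norm(p - c) <= 6.0 + TOL:
                        out.add(("cation_pi", i, j))
                # ionic
                if ra.name in CATIONS and rb.name in ANIONS:
                    cp = _mean(ra, CATIONS[ra.name])
                    cn = _mean(rb, ANIONS[rb.name])
                    if cp is not None and cn is not None and np.linalg.norm(cp - cn) <= 6.0 + TOL:
                        out.add(("ionic", i, j))
    return out


def monte_carlo_sasa(coords, radii, probe=1.4, n_samples=100_000, seed=0):
    """Random surface sampling SASA oracle (independent of the
    quasi-uniform point engine).  Returns per-atom areas."""
    rng = np.random.default_rng(seed)
    coords = np.asarray(coords, dtype=float)
    expanded = np.asarray(radii, dtype=float) + probe
    n = len(coords)
    out = np.empty(n)
    for i in range(n):
        v = rng.normal(size=(n_samples, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = coords[i] + expanded[i] * v
        buried = np.zeros(n_samples, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            buried |= ((pts - coords[j]) ** 2).sum(axis=1) < expanded[j] ** 2
        out[i] = 4.0 * math.pi * expanded[i] ** 2 * (1.0 - buried.mean())
    return out


def henderson_hasselbalch_pi(sequence, tol=1e-6):
    """Independent isoelectric-point oracle: scipy root of the net
    charge with the same EMBOSS pKa constants written out explicitly."""
    from scipy.optimize import brentq

    pka_pos = {"Nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
    pka_neg = {"Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}

    def q(ph):
        total = 0.0
        for g, pka in pka_pos.items():
            n = 1 if g == "Nterm" else sequence.count(g)
            total += n / (1 + 10 ** (ph - pka))
        for g, pka in pka_neg.items():
            n = 1 if g == "Cterm" else sequence.count(g)
            total -= n / (1 + 10 ** (pka - ph))
        return total

    return brentq(q, 0.0, 14.0, xtol=tol)
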