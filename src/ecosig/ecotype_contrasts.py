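"""The clade-contrast engine.

Given per-unit feature tables (units are isolates for genomic and
regulatory features, proteins for composition and interaction features)
and a clade scheme, this module computes, for every ordered contrast
(target clade vs reference clade), the percentage difference of the
clade means, a two-sample test p-value, the arrow class that
discretizes the effect size, and the significance stars.  It also
provides the tree leaf-depth check, per-clade habitat summaries, and a
non-metric multidimensional scaling (NMDS) ordination.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .genome_features import rank_contrast, star_class
from .io_core import IsolateMetadata, PhyloTree
from .protein_sequence import ks_contrast

__all__ = [
    "CladeScheme",
    "ContrastResult",
    "SignatureReport",
    "DEFAULT_CONTRASTS",
    "arrow_class",
    "run_contrasts",
    "clade_leaf_depth",
    "habitat_summary",
    "ordination",
]

logger = logging.getLogger(__name__)

#: Default ordered contrasts: (target clade, reference clade, adaptation).
DEFAULT_CONTRASTS: list[tuple[str, str, str]] = [
    ("Ib", "Ia", "psychrophilic"),
    ("IIa", "Ia", "halophilic"),
    ("IIb", "IIa", "thermophilic"),
]


@dataclass
class CladeScheme:
    """Isolate-to-clade mapping plus the ordered contrast list."""

    clades: dict[str, str]  # isolate_id -> clade label
    contrasts: list[tuple[str, str, str]] = field(
        default_factory=lambda: list(DEFAULT_CONTRASTS)
    )

    def __post_init__(self) -> None:
        known = set(self.clades.values())
        for target, reference, _label in self.contrasts:
            for clade in (target, reference):
                if clade not in known:
                    raise ValueError(f"contrast clade {clade!r} not in the clade mapping")

    def members(self, clade: str) -> list[str]:
        return [i for i, c in self.clades.items() if c == clade]


@dataclass
class ContrastResult:
    contrast: str  # adaptation label
    feature: str
    target_mean: float
    reference_mean: float
    d: float  # percentage difference
    p: float
    arrow: str
    star: str


@dataclass
class SignatureReport:
    """Complete contrasts-by-features result table with provenance."""

    table: pd.DataFrame
    provenance: dict


def arrow_class(d: float, p: float) -> str:
    """Discretize a percentage difference into the five arrow classes.

    No arrow ("-") when the change is not significant (p > .05) or the
    magnitude is below 1 %.  A single arrow covers 1 % <= |d| < 5 %, a
    double arrow |d| >= 5 % (both boundaries closed on the outer
    interval), in the direction of the sign of d.  Missing d gives a
    missing arrow.
    """
    if d is None or (isinstance(d, float) and math.isnan(d)):
        return ""
    if (p is None or math.isnan(p)) or p > 0.05 or abs(d) < 1.0:
        return "-"
    if abs(d) >= 5.0:
        return "↑↑" if d > 0 else "↓↓"
    return "↑" if d > 0 else "↓"


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvals, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    m = len(pv)
    if m == 0:
        return out
    order = np.argsort(pv)
    ranked = pv[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[mask] = adj
    return out


def run_contrasts(
    features: pd.DataFrame,
    units_clades: Mapping[str, str] | pd.Series,
    scheme: CladeScheme,
    test: str = "KS",
) -> SignatureReport:
    """Contrast every feature between each (target, reference) clade pair.

    Parameters
    ----------
    features : DataFrame
        Rows = unit ids (isolates or proteins), columns = numeric
        features.
    units_clades : mapping
        Unit id -> clade label.  For per-isolate tables this is the
        scheme's own mapping; for per-protein tables it maps each
        protein to the clade of its isolate.
    scheme : CladeScheme
        Supplies the ordered contrasts.
    test : {"KS", "rank"}
        Two-sample test used for the p-values; KS needs >= 5 units per
        clade, the rank-sum test >= 2.

    Percentage differences use the clade means:
    d = 100 (mean_target - mean_ref) / mean_ref, missing when the
    reference mean is 0.  Raw p-values drive the arrows; a
    Benjamini-Hochberg column (adjusted across features within each
    contrast) is reported alongside.
    """
    if test not in {"KS", "rank"}:
        raise ValueError(f"unknown test {test!r}")
    if features.columns.duplicated().any():
        dup = features.columns[features.columns.duplicated()][0]
        raise ValueError(f"duplicated feature column {dup!r}")
    clades = pd.Series(dict(units_clades) if not isinstance(units_clades, pd.Series) else units_clades)
    rows = []
    for target, reference, label in scheme.contrasts:
        t_units = clades.index[clades == target]
        r_units = clades.index[clades == reference]
        for missing, name in ((t_units, target), (r_units, reference)):
            if len(missing) == 0:
                raise ValueError(f"contrast clade {name!r} has no units in the table")
        for feature_name in features.columns:
            tv = features.loc[features.index.intersection(t_units), feature_name].dropna()
            rv = features.loc[features.index.intersection(r_units), feature_name].dropna()
            t_mean = tv.mean() if len(tv) else float("nan")
            r_mean = rv.mean() if len(rv) else float("nan")
            if r_mean == 0 or math.isnan(r_mean) or math.isnan(t_mean):
                d = float("nan")
            else:
                d = 100.0 * (t_mean - r_mean) / r_mean
            if len(tv) and len(rv) and np.ptp(np.concatenate([tv, rv])) == 0:
                p = 1.0  # constant feature: no distributional difference
            else:
                try:
                    if test == "KS":
                        _, p = ks_contrast(tv.to_numpy(), rv.to_numpy())
                    else:
                        _, p, _ = rank_contrast(tv.to_numpy(), rv.to_numpy())
                except ValueError:
                    p = float("nan")
            rows.append(
                {
                    "contrast": label,
                    "target_clade": target,
                    "reference_clade": reference,
                    "feature": feature_name,
                    "target_mean": t_mean,
                    "reference_mean": r_mean,
                    "n_target": len(tv),
                    "n_reference": len(rv),
                    "d_percent": d,
                    "p": p,
                    "arrow": arrow_class(d, p),
                    "star": star_class(p) if not math.isnan(p) else "",
                }
            )
    table = pd.DataFrame(rows)
    table["p_bh"] = np.nan
    for label in table["contrast"].unique():
        mask = table["contrast"] == label
        table.loc[mask, "p_bh"] = _bh_adjust(table.loc[mask, "p"].to_numpy())

    config = {
        "test": test,
        "contrasts": scheme.contrasts,
        "n_features": len(features.columns),
    }
    provenance = {
        "config": config,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "n_units": int(len(features)),
    }
    return SignatureReport(table=table, provenance=provenance)


def clade_leaf_depth(
    tree: PhyloTree, scheme: CladeScheme, flag_threshold: float = 0.5
) -> tuple[pd.Series, bool]:
    """Mean root-to-leaf branch length per clade, plus a flag.

    The flag is raised when any clade mean is at or above
    ``flag_threshold`` (clades should sit at comparable, shallow depth).
    Errors when a clade member is not a tree leaf.
    """
    depths = tree.leaf_depths()
    clade_means = {}
    for clade in sorted(set(scheme.clades.values())):
        members = scheme.members(clade)
        missing = [m for m in members if m not in depths]
        if missing:
            raise ValueError(f"isolate(s) {missing} not found in the tree")
        clade_means[clade] = float(np.mean([depths[m] for m in members]))
    series = pd.Series(clade_means, name="mean_leaf_depth")
    return series, bool((series >= flag_threshold).any())


def habitat_summary(
    metadata: Sequence[IsolateMetadata],
    scheme: CladeScheme,
    main_clade_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-clade (and per main-clade) mean MAT and salinity with n.

    Missing values are excluded; per-cell n reports the contributing
    isolates.  Main clades are derived from subclade labels by stripping
    a trailing lower-case letter (Ia, Ib -> I) unless an explicit
    mapping is given.  An all-missing cell is NaN with a warning.
    """
    if main_clade_of is None:
        main_clade_of = {
            c: (c[:-1] if c[-1].islower() and len(c) > 1 else c)
            for c in set(scheme.clades.values())
        }
    rows = []
    groups: dict[str, list[IsolateMetadata]] = {}
    for m in metadata:
        clade = scheme.clades.get(m.isolate_id)
        if clade is None:
            continue
        groups.setdefault(clade, []).append(m)
        main = main_clade_of[clade]
        if main != clade:
            groups.setdefault(main, []).append(m)
    for clade in sorted(groups):
        members = groups[clade]
        if not members:
            logger.warning("clade %r empty; habitat summary missing", clade)
        for var, attr in (("MAT", "mat"), ("salinity", "salinity")):
            vals = [getattr(m, attr) for m in members if getattr(m, attr) is not None]
            if not vals:
                logger.warning("clade %r has no %s values", clade, var)
            rows.append(
                {
                    "clade": clade,
                    "variable": var,
                    "mean": float(np.mean(vals)) if vals else float("nan"),
                    "n": len(vals),
                }
            )
    return pd.DataFrame(rows).set_index(["clade", "variable"])


def _kruskal_stress(dist_flat: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against target dissimilarities,
    using monotone (isotonic) regression of the configuration distances."""
    from sklearn.isotonic import IsotonicRegression

    d_conf = pdist(coords)
    iso = IsotonicRegression()
    d_hat = iso.fit_transform(dist_flat, d_conf)
    denom = (d_conf**2).sum()
    if denom == 0:
        return float("inf")
    return math.sqrt(((d_conf - d_hat) ** 2).sum() / denom)


def ordination(
    features: pd.DataFrame,
    distance: str = "bray_curtis",
    k: int = 2,
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[pd.DataFrame, float]:
    """Non-metric MDS of a feature matrix.

    Dissimilarities are Bray-Curtis (requires non-negative entries) or
    Euclidean.  The embedding minimizes Kruskal stress-1 by iterative
    majorization (SMACOF) with monotone regression; the best of
    ``n_restarts`` seeded restarts is returned with centered
    coordinates.  All-identical rows raise ("zero variance").
    """
    from sklearn.manifold import MDS

    x = features.to_numpy(dtype=float)
    if len(x) < k + 1:
        raise ValueError(f"need at least {k + 1} rows for a {k}-dimensional ordination")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance: all rows identical")
    if distance == "bray_curtis":
        if (x < 0).any():
            raise ValueError("bray_curtis requires non-negative entries")
        dmat = squareform(pdist(x, metric="braycurtis"))
    elif distance == "euclidean":
        dmat = squareform(pdist(x))
    else:
        raise ValueError(f"unknown distance {distance!r}")

    mds = MDS(
        n_components=k,
        metric_mds=False,
        metric="precomputed",
        init="random",
        n_init=n_restarts,
        random_state=seed,
        normalized_stress=True,
        max_iter=500,
        eps=1e-9,
    )
    coords = mds.fit_transform(dmat)
    coords = coords - coords.mean(axis=0)
    stress = _kruskal_stress(dmat[np.triu_indices(len(x), 1)], coords)
    out = pd.DataFrame(
        coords, index=features.index, columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return out, float(stress)
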