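"""Proteome composition indices, family conservation, and signatures.

Computes per-isolate amino-acid frequencies, isoelectric point and
GRAVY, measures within-family sequence conservation on a sample of
families with the global-alignment identity used by the clusterer, and
derives the three adaptation signatures (psychrophilic Ib vs Ia,
halophilic IIa vs Ia, thermophilic IIb vs IIa) as per-amino-acid
percentage differences with Kolmogorov-Smirnov support and arrows.

Run from the repository root:  python analysis/04_proteome_composition.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ecosig.ecotype_contrasts import CladeScheme, run_contrasts
from ecosig.io_core import write_table
from ecosig.protein_sequence import (
    AMINO_ACIDS,
    aa_frequencies,
    aa_ratio,
    gravy,
    isoelectric_point,
    mean_pairwise_identity,
)
from ecosig.synthetic_data import make_protein_families, per_protein_frequencies

SEED = 7
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    ps = make_protein_families(seed=SEED)

    by_iso: dict[str, list[str]] = {}
    iso_clade: dict[str, str] = {}
    for _pid, iso, clade, seq in ps.proteins:
        by_iso.setdefault(iso, []).append(seq)
        iso_clade[iso] = clade
    rows = []
    for iso, seqs in by_iso.items():
        freqs, _ = aa_frequencies(seqs)
        rows.append(
            {"isolate_id": iso, "clade": iso_clade[iso],
             "pI": float(np.mean([isoelectric_point(s) for s in seqs])),
             "GRAVY": float(np.mean([gravy(s) for s in seqs])),
             "Lys_Arg": aa_ratio(freqs, "K", "R"),
             "Glu_Asp": aa_ratio(freqs, "E", "D")}
        )
    comp = pd.DataFrame(rows).set_index("isolate_id")
    write_table(RESULTS / "proteome_composition.tsv", comp)
    print("per-clade proteome indices:")
    print(comp.groupby("clade")[["pI", "GRAVY", "Lys_Arg", "Glu_Asp"]]
          .mean().round(3).to_string())

    # family conservation on a sample of families (10-member subsample each)
    fams: dict[str, list[str]] = {}
    for pid, _iso, _clade, seq in ps.proteins:
        fams.setdefault(ps.protein_family[pid], []).append(seq)
    rng = np.random.default_rng(SEED)
    sample = sorted(fams)[:12]
    idents = []
    for fam_id in sample:
        seqs = fams[fam_id]
        pick = [seqs[i] for i in rng.choice(len(seqs), size=10, replace=False)]
        mean_id, _ = mean_pairwise_identity(pick)
        idents.append({"family_id": fam_id, "n_sampled": 10,
                       "mean_identity_pct": mean_id})
    ident = pd.DataFrame(idents).set_index("family_id")
    write_table(RESULTS / "family_identity.tsv", ident)
    print(f"within-family identity over {len(sample)} families: "
          f"{ident['mean_identity_pct'].mean():.1f} % "
          f"(SD {ident['mean_identity_pct'].std(ddof=1):.1f} %)")

    # surface-restricted composition signatures
    freq, prot_clades = per_protein_frequencies(ps, region="surface")
    scheme = CladeScheme(dict(prot_clades))
    report = run_contrasts(freq, prot_clades, scheme, test="KS")
    write_table(RESULTS / "composition_signatures.tsv",
                report.table.set_index(["contrast", "feature"]))
    for label, aas in (("halophilic", ["D", "E", "K", "W"]),
                       ("psychrophilic", ["K", "R", "N", "T"]),
                       ("thermophilic", ["E", "D", "K", "R"])):
        sub = report.table[report.table["contrast"] == label]
        parts = [f"{aa} {sub[sub['feature'] == aa]['d_percent'].iloc[0]:+.1f}%"
                 f"{sub[sub['feature'] == aa]['arrow'].iloc[0]}" for aa in aas]
        print(f"{label:>13} surface signature: " + ", ".join(parts))


if __name__ == "__main__":
    main()
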