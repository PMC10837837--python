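"""Assemble the final ecotype signature report and habitat summaries.

Joins the per-isolate genomic, regulatory and proteome tables produced
by the earlier steps (regenerating them from the same seed so the script
is self-contained), runs all three clade contrasts over every feature,
summarizes habitat variables (mean annual temperature, salinity) per
subclade and main clade, and checks that all clades sit at comparable
root-to-leaf depth in the phylogenomic tree.

Run from the repository root:  python analysis/06_ecotype_contrasts.py
"""

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from ecosig.ecotype_contrasts import (
    CladeScheme,
    clade_leaf_depth,
    habitat_summary,
    run_contrasts,
)
from ecosig.genome_features import gc_content
from ecosig.io_core import read_newick, write_table
from ecosig.protein_sequence import aa_frequencies, aa_ratio, gravy, isoelectric_point
from ecosig.regulatory_features import regulatory_feature_table
from ecosig.synthetic_data import make_clade_genomes, make_clade_tree, make_protein_families

SEED = 7
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    gs = make_clade_genomes(seed=SEED)
    ps = make_protein_families(seed=SEED)
    clades = {m.isolate_id: m.clade_label for m in gs.metadata}
    scheme = CladeScheme(clades)

    reg = regulatory_feature_table(gs.genomes, gs.annotations)
    gc = pd.Series(
        {iso: gc_content("".join(s for _, s in g.contigs)) for iso, g in gs.genomes.items()},
        name="GC",
    )
    by_iso: dict[str, list[str]] = {}
    for _pid, iso, _clade, seq in ps.proteins:
        by_iso.setdefault(iso, []).append(seq)
    prot_rows = []
    for iso, seqs in by_iso.items():
        freqs, _ = aa_frequencies(seqs)
        prot_rows.append({"isolate_id": iso,
                          "pI": float(np.mean([isoelectric_point(s) for s in seqs])),
                          "GRAVY": float(np.mean([gravy(s) for s in seqs])),
                          "Lys_Arg": aa_ratio(freqs, "K", "R"),
                          "Glu_Asp": aa_ratio(freqs, "E", "D")})
    prot = pd.DataFrame(prot_rows).set_index("isolate_id")
    features = reg.join(gc).join(prot)

    report = run_contrasts(features, clades, scheme, test="rank")
    write_table(RESULTS / "signature_report.tsv",
                report.table.set_index(["contrast", "feature"]))
    doubles = report.table[report.table["arrow"].isin(["↑↑", "↓↓"])]
    print(f"signature report: {len(report.table)} contrast rows, "
          f"{len(doubles)} strong (double-arrow) signatures "
          f"(config {report.provenance['config_hash']})")
    for _, r in doubles.iterrows():
        print(f"  {r['contrast']:>13} {r['feature']:<12} d = {r['d_percent']:+7.1f} % "
              f"{r['arrow']} {r['star']}")

    habitats = habitat_summary(gs.metadata, scheme)
    write_table(RESULTS / "habitat_summary.tsv", habitats)
    print("habitat summary (means):")
    print(habitats.round(2).to_string())

    clade_isolates: dict[str, list[str]] = {}
    for m in gs.metadata:
        clade_isolates.setdefault(m.clade_label, []).append(m.isolate_id)
    with tempfile.NamedTemporaryFile("w", suffix=".nwk", delete=False) as fh:
        fh.write(make_clade_tree(clade_isolates, seed=SEED) + "\n")
        tree_path = fh.name
    depths, flag = clade_leaf_depth(read_newick(tree_path), scheme)
    print("clade mean leaf depths:",
          {k: round(v, 3) for k, v in depths.items()},
          "(flagged)" if flag else "(all < 0.5)")


if __name__ == "__main__":
    main()
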