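# ecosig

Reverse-ecology analysis of a poly-extremophile bacterial group:
delineating ecotypes (clades tied to habitat) by contrasting genomic,
regulatory, proteome-composition and protein-structure features between
clades — e.g. a nonsaline mesophilic clade Ia, a psychrophilic clade Ib,
a saline mesophilic clade IIa and a saline thermophilic clade IIb.

The package is written for comparative microbial genomicists who have,
per isolate, a genome assembly (FASTA), annotations (GFF3 with CDS,
rRNA, tmRNA, sRNA, insertion-sequence, CRISPR, operon and promoter
features), protein sequences, predicted 3D structures (PDB), a
phylogenomic tree (Newick) and a metadata table — and who want to ask:
*which measurable molecular features separate the clades, and in which
direction?*

## What it computes

**Genome scale** — GC content, codon-position GC1/GC2/GC3, codon usage
(frequencies and RSCU) with non-metric multidimensional scaling, N50,
coding density, CRISPR counts; a quality gate (remove genomes with
>300 contigs, N50 < 20 kb, completeness < 95 % or contamination > 5 %)
and AAI-based deduplication at ≥ 99.5 %.

**Regulatory elements** — GC of the rRNA and tmRNA genes, AT content of
predicted promoters, counts of insertion sequences, sRNAs and CRISPR
loci, operons per CDS.

**Proteome composition** — amino-acid frequency vectors, grand average
of hydropathicity (GRAVY, Kyte–Doolittle), isoelectric point
(Henderson–Hasselbalch bisection, EMBOSS pKa set), Lys/Arg and Glu/Asp
ratios; greedy centroid clustering into homologous families (identity
≥ 0.50, coverage ≥ 0.80) and within-family mean pairwise identity.

**Protein structure** — Shrake–Rupley solvent-accessible surface area;
relative accessibility against an extended Gly-X-Gly reference built by
the same engine (core = RSA ≤ 20 %); torsion-window secondary structure
(H/E/C); six residue-interaction classes (aromatic–aromatic,
aromatic–sulfur, cation–π, ionic, disulfide, hydrophobic) with
configurable distance criteria; interaction densities per protein
length; composition stratified by region × secondary structure;
aggregation of external per-residue stability scores ⟨S⟩.

**Contrast engine** — for every (target, reference) clade pair and
feature: percentage difference of clade means
d = 100·(x̄_t − x̄_r)/x̄_r, a Kolmogorov–Smirnov or Wilcoxon rank-sum
p-value, significance stars (*, **, ***), and the arrow discretization
(↑↑ for d ≥ 5 %, ↑ for 1–5 %, − for non-significant or |d| < 1 %, ↓/↓↓
mirrored).

A seeded synthetic-data generator plants the known adaptation
signatures (tmRNA GC lowered in extremophiles, promoter AT raised in
the psychrophilic clade, surface Asp/Glu enrichment in halophiles,
Lys/Arg ratio up in psychrophiles, Glu/Asp ratio up in thermophiles) so
the whole pipeline is testable without downloading any external data.

## Worked example

```bash
ecosig simulate --seed 1 --out-dir demo/
ecosig reg-features   --fasta-dir demo/fasta --gff-dir demo/gff --out demo/reg.tsv
ecosig prot-features  --proteome-dir demo/proteomes --out demo/prot.tsv
ecosig contrast --features demo/reg.tsv --features demo/prot.tsv \
                --metadata demo/metadata.tsv --test rank --out demo/report.tsv
ecosig tree-depth --newick demo/tree.nwk --metadata demo/metadata.tsv
```

The report lists one row per contrast × feature.  On the seed-1
synthetic dataset the strong signatures include (excerpt of the actual
output):

```
  psychrophilic gc_tmRNA     d =   -10.7 % ↓↓ ***
     halophilic at_promoter  d =   -11.5 % ↓↓ ***
     halophilic GC           d =   +10.8 % ↑↑ ***
     halophilic pI           d =    -6.8 % ↓↓ ***
   thermophilic gc_tmRNA     d =    -6.5 % ↓↓ **
   thermophilic Glu_Asp      d =    +5.4 % ↑↑ ***
```

reading as: the psychrophilic clade's tmRNA gene is ~11 % lower in GC
than the mesophilic reference (rank-sum p ≤ .001); the halophilic clade
has AT-poorer promoters, a higher genome GC, a lower proteome
isoelectric point, and a raised Glu/Asp ratio appears in the
thermophilic contrast — the directions these features take in the
organisms the generator emulates.  `tree-depth` prints per-clade mean
root-to-leaf distances (here 0.29–0.30, all below the 0.5
comparability bound).

The same analyses, as scripted narratives writing tables under
`results/`, are in `analysis/01_simulate_dataset.py` …
`analysis/06_ecotype_contrasts.py`.

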