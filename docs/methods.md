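# Methods

This note documents the models, conventions and numerical choices
behind `ecosig`, and what the synthetic-data experiments do and do not
demonstrate about real data.

## Data model and conventions

All intervals are held 0-based half-open in memory; GFF3's 1-based
inclusive coordinates are converted exactly once at the reader/writer
boundary, so a round trip is the identity.  Minus-strand feature
sequences are reverse-complemented on extraction — irrelevant for GC/AT
content (strand-invariant) but required for codon-position statistics.
Ambiguity codes are retained in storage; each statistic documents its
own treatment (GC/AT exclude them from numerator and denominator,
codon counting skips codons containing them).  Missing values are NaN
throughout and are never silently converted to zero.

## Genome-scale statistics

* **GC1/GC2/GC3** are pooled over all CDS of an isolate, stop codons
  included, trailing partial codons dropped with a warning.
* **RSCU** divides each codon count by the mean count of its synonym
  family under the bacterial genetic code (NCBI translation table 11);
  single-codon families (ATG, TGG) have RSCU 1 when present.
* **N50** is the length of the contig at which the descending
  cumulative sum first reaches half the assembly length; it is always
  the length of an actual contig and is order-invariant.
* **Quality gate**: a genome is removed when *any* criterion is
  violated (defaults: > 300 contigs, N50 < 20 kb, completeness < 95 %,
  contamination > 5 %). The OR combination errs on the side of quality.
* **AAI deduplication** builds a graph over isolates with edges at
  AAI ≥ 99.5 % and keeps one representative per connected component
  (highest completeness, then lowest contamination, then smallest id).
  Component-wise handling makes the result independent of input order,
  and re-running on the retained set is the identity.
* **Rank contrast** is the unpaired two-sided Mann–Whitney test —
  clades have unequal sizes, so a paired test is impossible — exact for
  both sides ≤ 8 without ties, otherwise the tie-corrected normal
  approximation.  Stars: p ≤ .05 *, ≤ .01 **, ≤ .001 ***.

## Proteome composition

GRAVY uses the Kyte–Doolittle table and the isoelectric point a
bisection on the Henderson–Hasselbalch net charge with the EMBOSS pKa
set; both tables ship as versioned data files
(`src/ecosig/data/*.tsv`), never as constants in logic.  The bisection
narrows the pH interval below 1e-7 *and* requires |Q| < 1e-4: between
well-separated pKa values the charge curve is nearly flat, so a stop on
the charge alone would leave the root located only to ~0.3 pH units.

Family clustering is greedy centroid clustering: proteins sorted by
decreasing length (ties by id, making the clustering deterministic
under input permutation), each joining the first representative with
global-alignment identity ≥ 0.50 and coverage ≥ 0.80, else founding a
new family.  Alignment scoring is match +1 / mismatch 0 / gap open −10
/ gap extend −0.5; identity = identical columns over the alignment span
excluding terminal gaps; coverage = that span over the shorter
sequence.  These denominators follow common clustering practice; the
thresholds are the conventional cut-offs for pangenome families.
Families present in at least half of the genomes (⌈n/2⌉) are
considered pangenome-wide.

The Kolmogorov–Smirnov contrast defaults to per-protein observations
within a clade (large n; per-isolate aggregation is available and is
what the rank-sum test is used with).  Exact p-values below 50
observations per side, asymptotic above.

## Structure analysis

**SASA** is Shrake–Rupley point sampling: 960 quasi-uniform points
(deterministic golden-spiral construction) per heavy atom at radius
r_vdW + 1.4 Å (C 1.70, N 1.55, O 1.52, S 1.80 Å; hydrogens ignored); a
point is buried iff strictly inside another atom's expanded sphere, so
a point exactly on a boundary counts as exposed (deterministic
tie-break).  A single isolated carbon reproduces the closed form
4π(1.70+1.4)² to machine precision by construction of the exposed
fraction.  Orientation dependence of the point grid is ~0.3 % on
whole-structure SASA and up to ~1–2 % per residue at 960 points; the
n=240 grid agrees with n=960 within 3 % per residue.

**RSA** divides residue SASA by the same engine's value for the central
residue of an extended (φ=ψ=180°) Gly-X-Gly tripeptide, built on demand
and cached — self-consistency with the engine is preferred over
literature maxASA tables.  Core iff RSA ≤ 0.20 (boundary inclusive),
else surface.

**Secondary structure** uses torsion windows rather than hydrogen-bond
energies (no hydrogen placement needed): helix candidates at
φ∈[−100°,−30°], ψ∈[−80°,−5°] forming runs of ≥ 4; strand candidates at
φ∈[−180°,−90°], ψ∈[90°,180°]∪[−180°,−170°] forming runs of ≥ 3;
everything else — including termini lacking a full (φ,ψ) pair and
residues across chain breaks (CA–CA > 4.5 Å) — is loop.  Window edges
and run lengths are parameters.

**Interactions** (one contact per residue pair per type, closest
qualifying distance; |i−j| ≥ 2 except disulfides): hydrophobic =
side-chain carbons of {Ala,Val,Leu,Ile,Met,Phe,Trp,Pro,Tyr} within
5.0 Å; ionic = cationic-group centroid (Arg NH1/NH2/NE, Lys NZ, His
ND1/NE2) to anionic centroid (Asp OD1/OD2, Glu OE1/OE2) within 6.0 Å;
aromatic–aromatic = ring centroids 4.5–7.0 Å; aromatic–sulfur = Cys
SG/Met SD to ring centroid within 5.3 Å; cation–π = Lys NZ/Arg CZ to
ring centroid within 6.0 Å; disulfide = SG–SG within 2.2 Å.  His is
both aromatic and a cation donor.  All bounds are inclusive with a
1e-9 Å float guard and are config keys, so other tools' defaults can be
matched.  Trp uses a single centroid over all nine ring atoms.

**Stability scores** ⟨S⟩ (kcal/mol, negative = stabilizing) are
consumed from an external per-residue table, averaged per protein and
then unweighted per clade; percentage changes are reported relative to
the magnitude of the reference value so the sign reads as the direction
of the shift (−0.090 → −0.085 is +5.6 %, toward zero, less stable).

## Contrast engine

Percentage difference d = 100·(mean_target − mean_ref)/mean_ref,
missing when the reference mean is 0.  Arrows follow the rule: "−" when
p > .05 or |d| < 1 %; single arrow for 1 % ≤ |d| < 5 %; double arrow
for |d| ≥ 5 % (outer intervals closed — the verbal rule leaves the
boundaries open, and closed intervals are chosen for determinism).  Raw
p-values drive the arrows; Benjamini–Hochberg adjusted p-values
(within contrast, across features) are reported as an extra column
only.  Default contrasts: Ib vs Ia (psychrophilic), IIa vs Ia
(halophilic), IIb vs IIa (thermophilic).

NMDS is SMACOF with monotone (isotonic) regression —
`sklearn.manifold.MDS(metric_mds=False)` — over Bray–Curtis or
Euclidean dissimilarities, 10 seeded random restarts, coordinates
centered; Kruskal stress-1 of the returned configuration is recomputed
explicitly.  All-identical rows raise ("zero variance").

## Synthetic data: what is planted and what it shows

Genomes are i.i.d. nucleotide draws at each clade's GC target with
features carved in non-overlapping intervals: CDS with valid start/stop
codons, tmRNA/rRNA/promoter intervals re-drawn at the planted
composition offsets, sRNA/IS/CRISPR counts Poisson at the clade means,
operons spanning 2–4 consecutive CDS.  Defaults mirror the study
system: clade sizes 23/15/29/10; GC 47.0/47.3/52.1/48.1 %; CRISPR
means 0.26/0.47/0.97/0.80; MAT 8.9/−1.6/12.1/45.5 °C; salinity
0.5/0.5/6/8 % NaCl; tmRNA GC −0.05 in all three extremophilic clades;
promoter AT highest in clade I.  Genomes default to 100 kb over 3
contigs with 60 CDS — a desk-scale size chosen so the full pipeline
runs in seconds while composition statistics stay well-resolved.

Proteomes are families with a shared ancestor per family (drawn from a
bacterial base composition) and one member per isolate; each member
redraws positions with probability s from its clade's substitution
distribution.  s is solved from the quadratic for the expected pairwise
identity (match probability (1−s)² + 2s(1−s)T₂ + s²T₂ with
T₂ = Σ base²), so the planted 80 % target is the *pairwise* identity
two members realize — the quantity the conservation analysis measures.
Clade shifts are planted exactly in the realized composition by tilting
the substitution distribution to t(a) = b(a)(1 + δ(a)/s) with
proportional compensation on unshifted amino acids; negative
frequencies are rejected at config validation, and families drawn at
very high identity are clamped to the smallest s the planted negative
shifts admit.  Shifts default to the adaptation signatures (surface
Asp +10 %/Glu +6 %/Trp +7 %/Lys −6 % for the halophilic clade, Lys/Arg
ratio ≈ +8 % for the psychrophilic clade, Glu/Asp ratio ≈ +10 % for
the thermophilic contrast) and apply to designated surface positions
only, mirroring the observation that adaptation concentrates at the
protein surface.

Structures are built by natural-extension-of-reference-frame placement
with ideal bond geometry (N–CA 1.46, CA–C 1.52, C–N 1.33 Å; angles
111°/117°/121°; ω = 180°) and conformation-set φ/ψ (helix −57°/−47°,
strand −139°/+135°, extended 180°/180°); side chains are reduced to
the pseudo-atoms the interaction detector consults.  Contact fixtures
place two residues so the type's defining distance equals the request
exactly; the expected flag comes from the distance rule, never from the
detector.  The core/surface fixture packs core alanines at the center
of a 4.9 Å shell of outward-pointing alanines; the construction gives
core RSA ≈ 0 and surface RSA ≥ 0.4, and needs roughly 16+ shell
residues for complete burial coverage.

These generators demonstrate *recovery of planted composition-level
effects under i.i.d. noise*.  They do not emulate phylogenetic
autocorrelation, within-genome compositional heterogeneity, operon or
gene-order structure, realistic protein packing, or annotation error —
so passing tests show the statistics and geometry engines are correct
and calibrated, not that the biological effect sizes would be
recoverable from any particular real dataset.

## Experiment sizes and calibration designs

* Signature recovery uses 200 proteins per clade with a +10 % surface
  Asp shift; protein length 3000 with half the positions surface was
  chosen by an a priori power analysis (standard error of the d
  estimate ≈ 0.8 percentage points; KS p ≪ .001), so the ±2-point
  recovery band is a ≈3σ interval.
* Test calibration simulates each test at the scale the pipeline
  applies it: the rank-sum test on per-isolate values (15 per clade)
  and the KS test on per-protein values (100 per clade, asymptotic
  regime).  The exact two-sample KS statistic is structurally
  conservative at small equal sample sizes (the attainable size at
  n = 15 per side is ≈ 0.02 because D is discrete in steps of 1/15),
  which is why the KS calibration is run at the per-protein scale where
  the test is actually used.
* The genome QC demonstration uses a 108-genome table with 30 planted
  violations (retaining 78) and six planted duplicate pairs at
  AAI ≥ 99.5 %.

## Known limitations

* The torsion-window secondary-structure assigner differs from
  hydrogen-bond-based assigners (DSSP-like) at borderline residues;
  only the three-class summary is supported.
* The greedy centroid clusterer is quadratic in the number of families
  and intended for desk-scale collections (thousands of proteins), not
  for hundreds of thousands; its scoring constants are exposed so
  results can be matched to external clusterers.
* The interaction detector requires the side-chain atoms named above;
  residues with missing atoms are skipped per class (counted and
  logged), not imputed.
* Ionic contacts consider side-chain groups only; chain termini are not
  treated as charged groups.
* The pI model treats all residues as independent titratable groups
  (no electrostatic coupling), as is standard for proteome-scale
  averages.
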