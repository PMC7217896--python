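# Methods

`hspscan` re-implements, as a self-contained and testable pipeline, the
computational protocol of a genome-wide heat-shock-protein (HSP) family
survey in a large plant genome: dual-evidence gene-family discovery,
sub-family classification and nomenclature, tandem-duplication and
expression-based pseudogene analysis, promoter cis-element scanning,
physico-chemical characterization, and progenitor orthology/synteny.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic validation does and does not demonstrate.

## Family discovery

Two evidence streams are combined, mirroring the standard two-pronged
protocol:

1. **Profile scanning.** Each signature domain is represented by a
   position-specific scoring matrix (PSSM) in half-bit log-odds units,
   built from a seed alignment with background-proportional pseudocounts
   (`score[p][a] = round(2·log2(f_pa / b_a))`, all-gap columns dropped,
   zero frequencies floored at −32 half-bits). Proteins are scanned with
   a gapped profile–sequence Gotoh dynamic program — the same affine-gap
   kernel used for sequence–sequence alignment, with the profile rows
   playing the role of per-position substitution scores. Gap cost for a
   length-k gap is `open + k·extend`; profile defaults are 20 + 2k
   half-bits (≈10/1 in bits). Hits are reported greedily by score,
   non-overlapping on protein coordinates (best hit first, then its
   unconsumed flanks).
2. **Homology search.** Exact Smith–Waterman (Gotoh affine-gap) against
   a reference set of known family proteins with BLOSUM62 and gap cost
   11 + k, filtered at E ≤ 1e-4 **and** bit score strictly > 100.

Candidates are the union of both streams; a candidate is confirmed only
if it carries a required sub-family domain at the domain E-value cutoff
(homology resemblance without a signature domain is not membership).
The domain-stream E-value cutoff has no published value in the source
protocol; the default (1e-4, matching the homology cutoff) is a package
choice.

### Score statistics

Raw local-alignment scores are converted with Karlin–Altschul theory:
`E = K·m·n·exp(−λS)`, `bits = (λS − ln K)/ln 2`. For ungapped scoring
systems λ is solved exactly (Brent root-finding on
`Σ p_i p_j exp(λ s_ij) = 1`) and K by the classical lattice-case series,
truncated when a term falls below 1e-10. This reproduces the textbook
BLOSUM62 constants (λ = 0.3176, K = 0.134) and the published nucleotide
match/mismatch tables to ≈2 digits. For gapped alignment, where no
analytic theory exists, the package follows standard practice and uses
configured constants (BLOSUM62 11/1: λ = 0.267, K = 0.041; nucleotide
+2/−3, 5+2k gaps: λ = 0.625, K = 0.41). Search space is `m·n` with no
length adjustment — a documented simplification. Profile λ is calibrated
per profile by solving the position-averaged normalisation; for
well-formed half-bit log-odds it sits near ln 2 / 2.

The DP kernels are numba-compiled; the test suite checks them against a
pure-Python full DP that scans every gap length (no affine recurrence),
and against Biopython's `PairwiseAligner`, exactly.

### Classification and naming

Sub-families are assigned by signature-domain content: SHSP =
α-crystallin domain (pfam00011); HSP60 = Cpn60_TCP1 (pfam00118); HSP70 =
pfam00012; HSP90 = pfam00183 with HATPase_c (pfam02518) expected but its
absence only recorded; HSP100 = at least two distinct domains of
{Clp_N (pfam02861), ClpB_D2-small (pfam10431), AAA variants (pfam07724,
pfam07728)} — the "min distinct" relaxation (default 2) approximates the
multi-domain requirement without demanding every domain on degraded
genes. The HSP40 signature is the DnaJ J-domain (pfam00226), the
field-standard choice. A protein matching required domains of two
sub-families is assigned by best domain bit score and the conflict is
logged; no published tie rule exists.

Names are positional: per sub-family, genes are ordered by chromosome
(natural order 1A, 1B, 1D, …, 7D) then ascending start coordinate, and
numbered from 1 — ascending coordinate stands in for "short arm to long
arm" because centromere positions are not inputs. Small HSPs are named
`TaSHSP<n>`; all others `Ta<subfamily>.<n>`. A gene with several
annotated mRNAs keeps one number and gains `.k` isoform suffixes in
annotation order — the interpretation of `.n.m` names is a documented
convention of this package, flagged as such. Unplaced genes (chromosome
`Un`) keep their family membership, are numbered last, and are excluded
from positional analyses. Gene structure uses the exon union of the
longest annotated transcript.

## Tandem duplication

A pair of family genes is a tandem event iff: same chromosome, same
strand, protein identity strictly > 40%, and strictly fewer than five
annotated genes (of any kind — the rule says "genes" without
qualification) between them in the start-sorted gene order. Identity is
local-alignment percent identity with gap columns in the denominator
(BLAST-style reporting); both the identity convention and the
denominator are configurable because the source protocol does not pin
them. Qualifying pairs are chained transitively; arrays are the
connected components of the pair graph. Identical duplicates
(byte-identical proteins within a sub-family) are detected independently
of position. Tandem "events" are reported both as pairs and as arrays,
since the correspondence between event counts and array sizes is
ambiguous in the source.

## Pseudogenes, expression, promoters, physico-chemistry

* **Pseudogene rule:** TPM sum over all samples strictly < 1
  (threshold and strictness configurable).
* **Heatmap scaling:** row-wise centre and divide by the sample standard
  deviation (n−1, the ClustVis convention; population sd available).
  Constant rows become zeros and are flagged.
* **PCA:** column-centred SVD of the samples × genes matrix (gene rows
  unit-variance scaled first); variance explained sums to 100% of total
  variance; component signs are fixed by making each component's
  largest-magnitude loading positive, so results are reproducible up to
  that convention under sample reordering.
* **CARE scanning:** promoters are the 1500 bp upstream of the
  transcription start on the coding strand (minus-strand genes: reverse
  complement of the downstream flank), clipped at chromosome ends.
  Every IUPAC-degenerate motif occurrence is counted, overlaps included,
  on both strands; self-reverse-complementary patterns are scanned
  forward only so each position counts once. Both-strand and overlap
  behaviour are flags, since the original scanning convention is
  unstated. The bundled catalogue holds 20 classical plant promoter
  elements (HSE, ABRE, W-box, DRE/CRT, G-box, MYB/MYC cores, TATA,
  polyadenylation signal, …) in seven functional categories.
* **Molecular weight** is the sum of average-isotopic residue masses
  plus one water; X contributes the unweighted mean residue mass
  (configurable).
* **Isoelectric point** is the unique root of the strictly decreasing
  Henderson–Hasselbalch net-charge curve, found by bisection on pH 0–14
  to an interval below 1e-6 (the curve can be nearly flat around neutral
  peptides, so converging on |charge| alone would not localise the pH);
  the returned root satisfies |charge| < 1e-4. The pKa set is explicit
  configuration — an IPC-style protein table by default, EMBOSS values
  as the alternative — because web pI calculators are not
  bit-reproducible.

## Orthology and synteny

Family CDS are aligned (nucleotide Smith–Waterman, +2/−3, gaps 5+2k)
against a progenitor CDS set; per query the best-bit-score subject
passing E ≤ 1e-10 and bit ≥ 150 is the ortholog (ties: lower E-value,
then lexical subject id). An ortholog is syntenic when it lies on the
progenitor chromosome corresponding to the wheat gene's chromosome
(e.g. 7A ↔ 7 of the A-genome donor); per-chromosome synteny fraction is
syntenic orthologs over family genes on that chromosome. Chromosomes
missing from the correspondence map count as non-syntenic and are
logged. The query/subject orientation (family CDS as queries) is the
transpose of the original BLASTN direction but yields the same
per-family-gene top-hit relation and matches the per-chromosome synteny
summary. Cross-sub-genome homoeolog detection reuses the ortholog
machinery with sub-genome-partitioned inputs and is labelled
exploratory.

## The synthetic genome generator

The generator emulates the statistical structure the pipeline assumes,
with machine-readable truth. Defaults define the validation study
conditions: 6 chromosomes × 1 Mb, 60 family genes (mix 30% SHSP, 25%
HSP40, 10% HSP60, 15% HSP70, 5% HSP90, 15% HSP100), 140 decoys, domain
divergence 0.2, tandem arrays of 2, 5 and 7 genes, pseudogene fraction
0.2, progenitor divergence 0.05, 15 expression samples in seven groups
(grain/leaf/root/spike stages, abiotic and biotic stress, control).

Key constructions:

* **Domains.** Sub-family consensus sequences are bundled fixtures built
  from short artificial six-row seed alignments (~8% row divergence),
  not real Pfam downloads — the repository stays download-free. The
  stored consensus is the column-wise argmax of the PSSM built with
  default parameters, so a zero-divergence plant attains the profile's
  maximum attainable score (an exactness anchor for the scan tests).
  Planted domains are consensus copies with independent per-site
  substitution at the configured divergence; decoys are
  background-composition proteins with no domain.
* **Layout.** Genes sit in "units" (tandem arrays or lone family genes)
  distributed round-robin over chromosomes, with ≥ 2 decoys between
  units, alternating unit strands, and 0–2 decoys between array members.
  This guarantees no spurious pair can satisfy the tandem rule:
  consecutive units differ in strand; units two apart have ≥ 5
  intervening genes. Array members are near-identical copies (3%
  protein drift per step); the first two members of each array are
  byte-identical (planted identical duplicates). Intergenic spacing
  (≥ 3.3 kb) keeps 1500 bp promoters clear of neighbouring gene bodies.
* **Pseudogenes** draw per-sample TPM from U(0, 0.9/n_samples), so sums
  stay strictly below 0.9; expressed genes use a per-gene log-normal
  baseline with group-specific induction multipliers (SHSP ×10 in grain,
  ×3 abiotic; HSP70 ×4 spike and abiotic; HSP40/HSP60 biotic; …,
  recorded in the truth table) and a floor that keeps sums ≥ 1. The
  induction design makes the grain/other grouping of samples linearly
  recoverable, mirroring the seed-development expression signal the
  family is known for.
* **Promoter motifs** are planted as concrete IUPAC instances at
  non-overlapping random positions. The truth table stores the
  *post-planting* count from an independent naive position-by-position
  scan, because planting into a random background can create or absorb
  incidental occurrences; recovery can therefore be exact by
  construction, and the scanner is checked against a third, test-local
  counting routine.
* **Progenitor CDS** are per-site mutated copies at the configured
  divergence, placed on the corresponding progenitor chromosome. Tandem
  arrays get a single progenitor ortholog (their first member),
  modelling arrays as lineage-specific expansions; this keeps planted
  top-hit orthology unambiguous among near-identical copies.
* Everything flows from one seeded generator; identical configurations
  are byte-identical on disk.

**What the synthetic validation does not show.** The generator uses
uniform residue/nucleotide backgrounds, fixed-codon reverse translation,
independent per-site substitution and idealised domain placements. Real
proteomes have compositional bias, splice-variant ambiguity, partial
domains and repeat-induced spurious homology, so the measured
precision/recall are properties of the method under the stated
conditions, not performance guarantees on a real 17-gigabase hexaploid
annotation. The source survey's headline counts (753 family members, 65
tandem events, 119/169 small-HSP pseudogenes, 212 unique promoter
elements) depend on specific external database versions and are not
reproducible at this scale; validation is therefore property-based.

## Problem sizes and runtime choices

The validation suite runs the full default conditions once
(6 × 1 Mb, 200 genes; ≈30 s on one core including JIT compilation) and
smaller bundles (2–3 chromosomes, 12–24 family genes) for unit-level
cross-checks; the determinism check uses a 3-chromosome × 300 kb bundle,
since byte-level reproducibility does not depend on problem size.
Alignment-oracle comparisons use 100 random pairs of length ≤ 60 (the
gap-scanning oracle is cubic); the pI oracle uses 200 random peptides
against a 0.001-pH grid.

## Known limitations

* No heuristic seeding: all alignments are exact DP, fine at desk scale,
  not at proteome-against-proteome scale.
* Gapped λ/K are configured constants, not estimated from the data.
* GFF3 support covers gene/mRNA/exon/CDS with ID/Parent attributes only.
* The promoter scanner assumes promoters fit in memory as strings and
  motifs are short IUPAC patterns (no PWM scoring).
* Expression analysis takes TPM as given; no normalisation or
  differential-expression testing is performed.
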