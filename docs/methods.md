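# Methods

## Scope and data model

The package reimplements the computational layer of a multi-trait
hybrid-breeding evaluation: phenotype scoring, genome-wide distance,
resistance-gene variability, and in-silico marker assays. The raw inputs
of the original field study (replicate trait tables, the ddRAD/array
genotype matrices, the GenBank allele sequences) are not deposited
anywhere, so the package is organised around two input channels:

1. **Fixture tables** transcribing what was printed: the 57-gene/71-SNP
   resistance-gene catalog with per-genotype SNP multiplicities, the
   parental and F₁ marker-call tables for the six assayed loci
   (Mi-1.2, Ph-3, Sw-5, Tm-2, Ty-3, Ve-1), and the 13-hybrid × 6-trait
   mid-parent heterosis table.
2. **Seeded generators** for everything else: replicate trait tables
   with planted heterosis, biallelic genotype matrices with controlled
   identity-by-state, and allele template sequences that reproduce the
   published assay geometries.

A third, smaller fixture (`synthetic_crosses.tsv`) reconstructs the
13-cross design. Only two crosses are documented in prose
(17H39 = E103×PDLUC, 17H57 = E103×E111); the remaining parent pairs were
chosen so that every printed F₁ marker call is Mendelian-consistent with
the parental calls, and the file is labelled synthetic. One genuine
inconsistency in the source data is preserved as-is: 17H39's Ph-3 call is
susceptible although one documented parent is homozygous resistant — the
marker tables hold *observed* calls, not pedigree predictions.

The catalog fixture carries no genomic coordinates (the printed table has
none), so each gene gets a deterministic synthetic interval derived from
its Solyc identifier; interval-based scanning (`popgen.prg_scan`) is meant
for real BED/GFF catalogs, while the fixture path (`prg_scan_fixture`)
works from the printed multiplicities directly. The only reading of the
multiplicity notation under which the printed totals are mutually
consistent is: a bracketed count is that genotype's SNP count in the gene,
a bare name is 1, and a gene's distinct-SNP count is the **maximum**
multiplicity across genotypes. That reading gives 71 SNPs over 57 genes
and 38 SNPs for the most polymorphic line.

## Scores

- `si_trait_score` bins a non-negative value with half-open intervals
  (10k, 10(k+1)], with [0,10] → 0, so non-integers are totalised while the
  printed integer mapping (11–20 → 1, 21–30 → 2, …) is preserved. The
  selection index sums the FS, TNF and 10×YP scores per environment and
  never pools environments. The alternative reading of "the scale was
  applied by multiplying the kg/plant value by 10" — adding 10×YP without
  binning — is exposed as `yp_mode="raw"`.
- Heterosis is computed on genotype trait means across replicates and
  reported in percent; a zero mid-parent mean raises an explicit
  undefined-result error rather than returning 0.
- QS divides titratable acidity, soluble solids and their ratio by the
  literature optima 0.3 g/100 g, 5.5 °Brix and 12.5.
- RGS default ("locus") counts assayed genes carrying ≥1 resistant allele
  over all assayed genes, bounding it in [0, 1]. The "dosage" alternative
  counts resistant alleles (RR = 2, RS = 1) over assayed loci and ranges
  [0, 2]. Neither mode reproduces the two printed 0.7 values for the two
  best hybrids (locus gives 0.5/0.67, dosage 0.67/0.83), so no mode is
  labelled canonical. A consequence worth knowing: with the printed
  calls, only one hybrid exceeds the across-hybrid RGS mean under locus
  counting, so the strict all-three elite rule can select at most that
  one hybrid regardless of the trait data.
- Elite classification uses strict inequality against the arithmetic
  means over fully-scored hybrids ("above the mean"); hybrids with a
  missing score are excluded from the means and never flagged.
- Titratable acidity: TA = 0.070 × [NaOH]·V/m × 100 (g citric acid per
  100 g), with the 0.070 conversion factor fixed by the assay.

## Genotype matrices

Calls are alternate-allele dosages 0/1/2 with −1 for missing; any VCF
genotype containing an uncalled allele (including half-calls) is missing.
Multi-allelic sites are dropped by default (the analyses are biallelic),
with an optional split policy. Filtering follows the vcftools flag
semantics the study used: `max-missing 0.5` *keeps* sites with ≥50%
called data; `min-mean-DP 5` drops shallow sites, and matrices without
depth annotations (array data) pass that filter with a warning;
monomorphic sites are removed. IBS is the dosage-sharing mean
(2 − |gᵢ−gⱼ|)/2 over jointly non-missing loci — the common
distance-matrix convention; the upstream tool's exact formula is not
printed, so this choice is a documented assumption, cross-checked against
a brute-force double loop in the tests.

Impact classes (HIGH/MODERATE/LOW/MODIFIER) are consumed as annotations;
no variant-effect predictor is implemented because that step was external
software and the reproducible content is the tally. Percentages print
with two decimals below 1% and one decimal otherwise, half-up — the
convention that reproduces all four printed percentages from the printed
counts.

## Marker assays

The primer-binding model is exact string match (with a configurable
mismatch budget); no melting-temperature or secondary-structure model is
included because assays are validated by fragment pattern, not kinetics.
An engineered dCAPS mismatch is always tolerated as a designed
template mismatch. Digestion expands IUPAC recognition strings, scans
both strands, and deduplicates: a window matching both orientations (a
palindromic pattern) is one double-strand site and contributes one cut,
taken at the top-strand offset. Fragment lengths always sum to the
amplicon length. Heterozygote gel patterns are the union of the two
allele band sets with co-migrating duplicates collapsed.

The mirror property "digesting the reverse complement reverses the
fragment multiset" holds exactly only for blunt-end palindromic cutters;
sticky-end enzymes (DdeI C^TNAG, Hpy188I TCN^GA) shift each cut by the
overhang, which the tests account for.

The dCAPS designer lays the forward primer with its 3′ end immediately
before the SNP, enumerates every enzyme × recognition-window placement
overlapping the SNP, and accepts a placement when (i) all mismatching
window positions left of the SNP can be rewritten by ≤1 primer
substitution that is neither at the SNP column nor within the 3 terminal
3′ bases, (ii) window positions right of the SNP match the template
naturally, and (iii) the site then completes for exactly one allele.
Every accepted design is re-simulated (PCR + digestion on both allele
templates) and returned only if the patterns differ.

### Template fixtures

The allele templates for the three designed assays are synthetic: random
backgrounds with recognition sites planted at the published cut
positions, scrubbed of accidental sites for the assay enzyme (both
strands, iterated to a fixed point), with the two alleles differing only
at the planted diagnostic bases. They reproduce the published fragment
multisets exactly — Sw-5: 358 bp, susceptible 133+225, resistant
43+133+182 (diagnostic C→T in the second Hpy188I site; the 133 fragment
was fixed on the left, as the printed text does not orient it); Ve-1:
1016 bp outer then 261 bp inner, resistant 156+105, susceptible
130+105+26; Tm-2: two 206-bp allele-specific products — but they are not
the GenBank regions, and only the assay geometry is faithful.

One geometric choice deserves a note: the published description of the
Ve-1 dCAPS (engineered A→C at forward-primer position 22) cannot be
reconciled exactly with the published 26-bp susceptible fragment under
DdeI's cut offset, because an engineered base at primer position 22
cannot participate in a site whose cut falls 26 bases into the amplicon
unless the primer covered the SNP itself. The fixture keeps the fragment
sizes exact and lets the geometry follow: a 29-base forward primer with
the engineered A→C at position 26, the recognition window at amplicon
positions 26–30, and the diagnostic C(resistant)/G(susceptible) at
position 30 — the designer independently recovers exactly this assay
from the template. The paralog in the nested fixture runs ≈91% identity
with strongly divergent blocks under the outer primers, which is what
makes the outer round locus-specific.

## Synthetic-data generators

All generators are pure functions of their spec, which includes the
seed (NumPy `default_rng`).

- **Traits.** Parent replicate values are trait mean + Gaussian noise
  truncated at zero (fruit set additionally capped at 100%); the F₁
  expectation is mid-parent × (1 + e/100) with e the planted heterosis.
  The demo spec uses the 15-line panel, the 13-cross design and the
  printed heterosis table as its planted effects; parent means sit at
  field-realistic scales (≈55% fruit set, 40 fruits, 80 g, 2.5 kg/plant,
  6 °Brix, 0.35 g/100 g) with ±20% per-line variation, three replicates
  per genotype as in the trial design, and zero noise by default so
  recovery is exact. What this does *not* emulate: genotype × environment
  interaction, trait correlations, or non-Gaussian replicate error — so a
  passing recovery test validates the formula chain, not field behaviour.
- **Genotypes.** A base sample of homozygous dosages (0/2, optional
  heterozygote rate for the near-homozygous inbred context) is copied
  and flipped 0↔2 per locus with probability 1 − target, making the
  expected dosage-sharing against the base equal the target; the binomial
  sd over L loci (≈0.007 at 5 000 loci) is the resolution limit. A full
  target matrix is accepted only when its off-base entries are consistent
  with this single-base construction (within 0.05), otherwise generation
  fails naming the pair. No linkage disequilibrium or pedigree structure
  is simulated.
- **Markers.** As above; the closure test (PCR → digestion reproduces the
  planted multiset) runs inside the generator, so a returned fixture is
  already verified.

## Numerical and testing choices

Problem sizes are chosen so the whole suite runs in seconds: IBS recovery
uses 5 000 loci (binomial sd ≈ 0.007 against the ±0.02 assertion), digest
fuzzing uses 1 200 random sequence/enzyme pairs, and the demo pipeline
uses 2 000 loci. Hypothesis runs derandomised with 50 examples per
property. The acceptance script (`scripts/acceptance.py`) recomputes all
reported numbers from scratch at run time; fixture-derived values are
seed-independent, synthetic-recovery values vary within their stated
tolerances.

Known limitations: the field-scale results that depend on the
undeposited raw data (the per-environment selection-index extremes, the
exact hybrid-index values and the seven-elite outcome) cannot be
recomputed, only their formula chains exercised on planted truth; primer
binding ignores thermodynamics; the IBS formula is an assumption about an
external tool; and the synthetic cross design is one satisfying
assignment, not the true pedigree.
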