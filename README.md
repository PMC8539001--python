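# heatcross

Tools for a marker-assisted tomato breeding workflow under heat stress:
scoring parental lines and F₁ hybrids from phenotype tables, measuring
genome-wide genetic distance from genotype matrices, scanning a
resistance-gene catalog, and designing and simulating CAPS/dCAPS/SCAR
assays for resistance loci — everything a breeding group needs between
"we have trait tables and a VCF" and "these are the hybrids worth
advancing".

It is aimed at plant-breeding and molecular-marker groups who work with
small panels of inbred lines and their hybrids, and it runs entirely on
delimited text, VCF and FASTA.

## The quantities it computes

**Selection index (SI).** Each of fruit set (FS, %), fruit number per
plant (TNF) and yield per plant (YP, kg, pre-scaled by 10) is binned on an
arbitrary 10-wide integer scale ([0,10]→0, (10,20]→1, …) and the three
scores are summed per environment.

**Mid-parent heterosis.** Het% = 100·(F₁ₜ − PMₜ)/PMₜ with PMₜ the parental
mean for trait *t*, computed on genotype means across replicates.

**Hybrid index.** Three scores per hybrid —

- HTS = TNF/10 + 10·YP (heat tolerance),
- QS = TA/0.3 + TSSC/5.5 + TSSC/(TA·12.5) (fruit quality, each term a
  ratio to the literature optimum),
- RGS = resistant loci / assayed marker loci (resistance, with an
  allele-dosage counting mode as an alternative)

— with a mean threshold per score over the hybrid set; hybrids above all
three means are flagged elite (two-of-three and HTS+QS rules are
selectable).

**Identity-by-state.** For a sample pair, IBS is the mean over jointly
non-missing loci of (2 − |gᵢ − gⱼ|)/2 with alternate-allele dosage coding,
after filtering sites on ≥50% data, mean depth ≥ 5 and polymorphism.

**Marker design.** Diagnostic-SNP discovery from allele alignments,
virtual PCR (including nested PCR against close paralogs), IUPAC
restriction digestion on both strands, dCAPS primer engineering (a single
deliberate primer mismatch completes a restriction site for exactly one
allele), allele-specific SCAR pairs, and genotype calling from observed
fragment patterns.

## Worked example

The package ships fixture tables (the resistance-gene SNP catalog, the
parental and F₁ marker calls, the hybrid heterosis table, and a synthetic
reconstruction of the 13-cross design) plus seeded generators for
everything else. The numbered scripts under `analysis/` walk the whole
workflow; for example:

```
$ python analysis/03_marker_screen.py
Sw-5: 358 bp amplicon; R (43, 133, 182), S (133, 225); het -> RS
Ve-1: nested 1016 -> 261 bp; engineered mismatch (26, 'A', 'C'); R (105, 156), S (26, 105, 130)
Tm-2: both allele-specific products 206 bp; cross-reaction amplifies: False
parental screen: 8 lines homozygous resistant for Ph-3; all lines carry Mi-1.2; none carry Sw-5
```

The Sw-5 line says: the CAPS assay amplifies a 358-bp fragment that
Hpy188I cuts into 43+133+182 bp on the resistant allele but only 133+225
on the susceptible one, and a heterozygote shows the union of bands and is
called RS. The Ve-1 dCAPS assay needs two PCR rounds (1016 bp then 261 bp)
to avoid a 91%-identical paralog, and one engineered A→C in the forward
primer makes DdeI cut the susceptible allele next to the primer (the
26-bp band).

```
$ python analysis/04_genomic_distance.py
filter: 4090 of 5000 sites survive (>=50% data, mean DP >= 5, polymorphic)
most distant pair: IBS = 0.553 (target 0.54)
catalog: 57 genes, 71 SNPs; most polymorphic line E11 with 38 SNPs (53.5%)
impact classes: HIGH 0.53%, MODERATE 9.3%, LOW 12.0%, MODIFIER 78.2%
```

The same operations are available as a CLI (`heatcross si`, `heterosis`,
`hybrid-index`, `titration`, `pcr`, `digest`, `design-dcaps`,
`design-scar`, `specific-windows`, `call-markers`, `filter`, `ibs`,
`prg-scan`, `impact-tally`, `simulate`, `run`).

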