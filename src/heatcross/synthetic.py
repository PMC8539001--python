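"""Seeded generators for every input the pipeline consumes.

The study's raw data (replicate trait tables, genotype matrices, allele
template sequences) are not deposited, so every stage is exercised on
synthetic inputs with planted truth: trait tables invert the mid-parent
heterosis formula, genotype matrices are built by dosage flips against a
base sample to hit a target identity-by-state, and marker templates are
random backgrounds with restriction sites planted (and accidental sites
scrubbed) so that virtual PCR plus digestion reproduces a specified
fragment pattern exactly.

All generators are pure functions of their spec (which includes the seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CrossDesign, TraitRecord, load_fixture
from .marker_design import (
    DDEI,
    HPY188I,
    Amplicon,
    DcapsDesign,
    DesignFailure,
    DiagnosticSnp,
    Enzyme,
    MarkerAssay,
    PrimerPair,
    cut_positions,
    design_dcaps,
    digest,
    in_silico_pcr,
    reverse_complement,
)
from .popgen import MISSING, GenotypeMatrix, Locus

BASES = np.array(list("ACGT"))

TRAITS = ("FS", "TNF", "FW", "YP", "TSSC", "TA")

# Nominal parental trait scales for a heat-stressed tomato trial:
# fruit set ~55%, ~40 fruits/plant, ~80 g fruits, ~2.5 kg/plant,
# ~6 Brix, ~0.35 g citric acid/100 g, with replicate noise well below
# the genotype differences.
DEFAULT_PARENT_MEANS = {"FS": 55.0, "TNF": 40.0, "FW": 80.0, "YP": 2.5, "TSSC": 6.0, "TA": 0.35}
DEFAULT_NOISE_SD = {"FS": 5.0, "TNF": 5.0, "FW": 8.0, "YP": 0.3, "TSSC": 0.4, "TA": 0.04}


class GenerationError(RuntimeError):
    """A spec that cannot be realised (e.g. inconsistent similarity targets)."""


# ---------------------------------------------------------------------------
# trait tables with planted heterosis


@dataclass(frozen=True)
class TraitSimSpec:
    """Parent trait means, per-cross planted heterosis and replicate noise.

    ``heterosis[hybrid][trait]`` is the planted mid-parent heterosis in
    percent; the generated F1 expectation is mid-parent * (1 + e/100).
    ``noise_sd`` maps trait -> additive Gaussian replicate sd (truncated
    at zero since traits are non-negative); a scalar applies to all traits.
    """

    parent_means: Mapping[str, Mapping[str, float]]
    crosses: Sequence[CrossDesign]
    heterosis: Mapping[str, Mapping[str, float]]
    noise_sd: float | Mapping[str, float] = 0.0
    n_reps: int = 3
    environment: str = "synthetic"
    year: int = 2019
    seed: int = 0

    def sd(self, trait: str) -> float:
        if isinstance(self.noise_sd, Mapping):
            return float(self.noise_sd.get(trait, 0.0))
        return float(self.noise_sd)


def gen_trait_table(spec: TraitSimSpec) -> tuple[list[TraitRecord], pd.DataFrame]:
    """Replicate trait rows for parents and F1s, plus the planted truth.

    With zero noise the F1 genotype means equal mid-parent * (1 + e/100)
    exactly, so the heterosis computation recovers every planted e.
    """
    if spec.n_reps < 1:
        raise ValueError("need at least one replicate")
    for geno, means in spec.parent_means.items():
        for trait, value in means.items():
            if value < 0:
                raise ValueError(f"negative mean {trait}={value} for {geno}")
    rng = np.random.default_rng(spec.seed)
    records: list[TraitRecord] = []

    def emit(genotype: str, means: Mapping[str, float]) -> None:
        for rep in range(1, spec.n_reps + 1):
            values = {}
            for trait in TRAITS:
                if trait not in means:
                    continue
                value = means[trait] + rng.normal(0.0, spec.sd(trait)) if spec.sd(trait) else means[trait]
                value = max(0.0, value)
                if trait == "FS":
                    value = min(100.0, value)
                values[trait] = value
            records.append(
                TraitRecord(
                    genotype_id=genotype,
                    environment=spec.environment,
                    year=spec.year,
                    replicate=rep,
                    **values,
                )
            )

    for geno, means in spec.parent_means.items():
        emit(geno, means)

    truth_rows = []
    for cross in spec.crosses:
        p1 = spec.parent_means[cross.parent1_id]
        p2 = spec.parent_means[cross.parent2_id]
        planted = spec.heterosis.get(cross.hybrid_id, {})
        f1_means = {}
        for trait in TRAITS:
            if trait not in p1 or trait not in p2:
                continue
            pm = (p1[trait] + p2[trait]) / 2.0
            e = planted.get(trait, 0.0)
            f1_means[trait] = pm * (1.0 + e / 100.0)
            truth_rows.append({"hybrid": cross.hybrid_id, "trait": trait, "planted_het_pct": e})
        emit(cross.hybrid_id, f1_means)
    truth = pd.DataFrame(truth_rows)
    return records, truth


def demo_trait_spec(seed: int = 0, noise_sd: float | Mapping[str, float] = 0.0) -> TraitSimSpec:
    """The packaged demo: 15 parents, the 13-cross design, and the printed
    hybrid heterosis table as the planted per-trait effects."""
    crosses = load_fixture("crosses")
    het = load_fixture("table3")
    rng = np.random.default_rng(seed)
    parents = sorted({p for c in crosses for p in (c.parent1_id, c.parent2_id)})
    parent_means = {}
    for geno in parents:
        jitter = rng.uniform(0.8, 1.2, size=len(TRAITS))
        means = {t: DEFAULT_PARENT_MEANS[t] * j for t, j in zip(TRAITS, jitter)}
        means["FS"] = min(100.0, means["FS"])
        parent_means[geno] = means
    heterosis = {
        hybrid: {t: float(row[t]) for t in ("TNF", "FW", "YP", "TSSC", "TA")}
        for hybrid, row in het.iterrows()
    }
    return TraitSimSpec(
        parent_means=parent_means,
        crosses=crosses,
        heterosis=heterosis,
        noise_sd=noise_sd,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# genotype matrices with controlled IBS


@dataclass(frozen=True)
class GenoSimSpec:
    """Controlled-similarity biallelic matrix.

    ``target_similarity`` is either a sequence of length n_samples-1 of
    IBS targets of each non-base sample against the base (sample 0), or a
    full symmetric matrix; the generator builds each sample by independent
    0<->2 dosage flips against the base, so a full matrix is only feasible
    when its entries are consistent with that construction — otherwise a
    :class:`GenerationError` names the offending pair.
    """

    n_samples: int
    n_loci: int
    target_similarity: Sequence[float] | np.ndarray
    missing_rate: float = 0.0
    depth_mean: float | None = 20.0
    depth_sd: float = 4.0
    het_rate: float = 0.0  # breeding lines are near-fully homozygous
    seed: int = 0
    chromosome: str = "SL4.0ch01"
    pairwise_tolerance: float = 0.05


def _flip_probs(spec: GenoSimSpec) -> np.ndarray:
    target = np.asarray(spec.target_similarity, dtype=float)
    if target.ndim == 1:
        if target.shape != (spec.n_samples - 1,):
            raise ValueError("need one base-relative target per non-base sample")
        base_rel = target
    elif target.ndim == 2:
        if target.shape != (spec.n_samples, spec.n_samples):
            raise ValueError("similarity matrix shape mismatch")
        base_rel = target[0, 1:]
        f = 1.0 - base_rel
        for i in range(1, spec.n_samples):
            for j in range(i + 1, spec.n_samples):
                implied = 1.0 - (f[i - 1] + f[j - 1] - 2.0 * f[i - 1] * f[j - 1])
                if abs(implied - target[i, j]) > spec.pairwise_tolerance:
                    raise GenerationError(
                        f"similarity target for pair ({i}, {j}) = {target[i, j]:.3f} "
                        f"is infeasible under base-relative flips (implied {implied:.3f})"
                    )
    else:
        raise ValueError("target_similarity must be a vector or a square matrix")
    if ((base_rel < 0) | (base_rel > 1)).any():
        raise ValueError("similarity targets must lie in [0, 1]")
    return 1.0 - base_rel


def gen_genotype_matrix(spec: GenoSimSpec) -> GenotypeMatrix:
    """Build the matrix; deterministic under the spec's seed.

    Sample 0 is the base haplotype; sample i flips dosage 0<->2 at an
    independent per-locus Bernoulli(1 - target_i) set of loci, which makes
    the expected pairwise dosage-sharing against the base equal the
    target. Missingness and per-site mean depth are planted afterwards.
    """
    if spec.n_samples < 2 or spec.n_loci < 1:
        raise ValueError("need >=2 samples and >=1 locus")
    if not 0.0 <= spec.missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    flip = _flip_probs(spec)
    rng = np.random.default_rng(spec.seed)

    base = rng.choice([0, 2], size=spec.n_loci)
    if spec.het_rate:
        base[rng.random(spec.n_loci) < spec.het_rate] = 1
    calls = np.empty((spec.n_samples, spec.n_loci), dtype=np.int8)
    calls[0] = base
    for i in range(1, spec.n_samples):
        flips = (rng.random(spec.n_loci) < flip[i - 1]) & (base != 1)
        row = base.copy()
        row[flips] = 2 - row[flips]
        calls[i] = row
    if spec.missing_rate:
        calls[rng.random(calls.shape) < spec.missing_rate] = MISSING

    positions = np.cumsum(rng.integers(1, 1000, size=spec.n_loci))
    loci = []
    for pos in positions:
        ref, alt = rng.choice(BASES, size=2, replace=False)
        loci.append(Locus(spec.chromosome, int(pos), str(ref), str(alt)))

    depth = None
    if spec.depth_mean is not None:
        depth = np.clip(rng.normal(spec.depth_mean, spec.depth_sd, size=spec.n_loci), 0.0, None)
    sample_ids = [f"S{i:02d}" for i in range(spec.n_samples)]
    return GenotypeMatrix(sample_ids, loci, calls, depth)


# ---------------------------------------------------------------------------
# marker fixture templates


@dataclass(frozen=True)
class SitePlan:
    """One planted restriction site inside the amplicon.

    ``cut_after`` is the 1-based amplicon position left of the cut.
    ``presence`` is "both", "R" or "S". For allele-specific sites the
    other allele carries the same window broken at ``snp_offset`` (0-based
    within the recognition) by ``absent_base`` — that broken base is the
    diagnostic SNP.
    """

    cut_after: int
    presence: str = "both"
    snp_offset: int | None = None
    absent_base: str | None = None

    def __post_init__(self) -> None:
        if self.presence not in ("both", "R", "S"):
            raise ValueError(f"presence {self.presence!r}")


@dataclass(frozen=True)
class MarkerFixtureSpec:
    name: str
    amplicon_length: int
    enzyme: Enzyme
    sites: tuple[SitePlan, ...]
    primer_len: int = 20
    flank: int = 30
    seed: int = 0


@dataclass(frozen=True)
class MarkerTemplates:
    """Synthetic allele templates plus the ready-made assay definition."""

    name: str
    r_template: str
    s_template: str
    primers: PrimerPair
    enzyme: Enzyme
    assay: MarkerAssay
    amplicon_length: int

    def amplicons(self) -> tuple[Amplicon, Amplicon]:
        r = in_silico_pcr(self.r_template, self.primers)
        s = in_silico_pcr(self.s_template, self.primers)
        if r is None or s is None:
            raise RuntimeError("fixture primers failed to amplify their own template")
        return r, s


def _concrete_instance(enzyme: Enzyme, rng: np.random.Generator) -> str:
    from Bio.Data.IUPACData import ambiguous_dna_values

    return "".join(
        c if c in "ACGT" else rng.choice(list(ambiguous_dna_values[c]))
        for c in enzyme.recognition
    )


def _expected_fragments(length: int, cuts: Sequence[int]) -> tuple[int, ...]:
    bounds = [0, *sorted(cuts), length]
    return tuple(sorted(b - a for a, b in zip(bounds, bounds[1:])))


def gen_marker_templates(spec: MarkerFixtureSpec) -> MarkerTemplates:
    """Random-background allele templates reproducing a digest pattern.

    Sites are planted at the requested offsets, the background is scrubbed
    of accidental recognition sites for the assay enzyme (both strands,
    re-scanned to a fixed point), primers are the amplicon's terminal
    ``primer_len`` bases, and the closure PCR -> digestion check is run
    before returning.
    """
    enz = spec.enzyme
    L = len(enz)
    for plan in spec.sites:
        s0 = plan.cut_after - enz.cut_offset  # 0-based window start in amplicon
        if s0 < spec.primer_len or s0 + L > spec.amplicon_length - spec.primer_len:
            raise ValueError(
                f"{spec.name}: site cut_after={plan.cut_after} overlaps a primer region"
            )
    rng = np.random.default_rng(spec.seed)
    total = spec.flank + spec.amplicon_length + spec.flank
    background = rng.choice(BASES, size=total)

    r_seq = background.copy()
    s_seq = background.copy()
    protected: set[int] = set()
    r_cuts, s_cuts = [], []
    for plan in spec.sites:
        s0 = spec.flank + plan.cut_after - enz.cut_offset
        instance = _concrete_instance(enz, rng)
        window = np.array(list(instance))
        broken = window.copy()
        if plan.presence != "both":
            offset = plan.snp_offset
            if offset is None:
                offset = max(
                    k for k, c in enumerate(enz.recognition) if c in "ACGT"
                )
            alt = plan.absent_base or ("A" if instance[offset] != "A" else "G")
            if alt == instance[offset]:
                raise ValueError(f"{spec.name}: absent_base equals the site base")
            broken[offset] = alt
        if plan.presence in ("both", "R"):
            r_seq[s0 : s0 + L] = window
            r_cuts.append(plan.cut_after)
        else:
            r_seq[s0 : s0 + L] = broken
        if plan.presence in ("both", "S"):
            s_seq[s0 : s0 + L] = window
            s_cuts.append(plan.cut_after)
        else:
            s_seq[s0 : s0 + L] = broken
        protected.update(range(s0, s0 + L))

    _scrub(r_seq, s_seq, enz, protected, spec, rng)

    amp = slice(spec.flank, spec.flank + spec.amplicon_length)
    r_amp = "".join(r_seq[amp])
    s_amp = "".join(s_seq[amp])
    forward = r_amp[: spec.primer_len]
    reverse = reverse_complement(r_amp[-spec.primer_len :])
    primers = PrimerPair(forward, reverse, target_gene=spec.name)

    r_template = "".join(r_seq)
    s_template = "".join(s_seq)
    r_pat = digest(r_amp, enz, "R")
    s_pat = digest(s_amp, enz, "S")
    expect_r = _expected_fragments(spec.amplicon_length, r_cuts)
    expect_s = _expected_fragments(spec.amplicon_length, s_cuts)
    if r_pat.fragment_lengths != expect_r or s_pat.fragment_lengths != expect_s:
        raise GenerationError(
            f"{spec.name}: scrubbed template does not reproduce the planted pattern "
            f"(R {r_pat.fragment_lengths} vs {expect_r}, S {s_pat.fragment_lengths} vs {expect_s})"
        )
    assay = MarkerAssay(
        name=spec.name,
        assay_type="CAPS",
        enzyme=enz,
        primers=primers,
        r_pattern=r_pat,
        s_pattern=s_pat,
    )
    return MarkerTemplates(
        name=spec.name,
        r_template=r_template,
        s_template=s_template,
        primers=primers,
        enzyme=enz,
        assay=assay,
        amplicon_length=spec.amplicon_length,
    )


def _scrub(
    r_seq: np.ndarray,
    s_seq: np.ndarray,
    enz: Enzyme,
    protected: set[int],
    spec: MarkerFixtureSpec,
    rng: np.random.Generator,
    max_rounds: int = 200,
) -> None:
    """Mutate accidental recognition windows until only planted sites cut.

    The same background position is mutated in both alleles so the pair
    stays identical outside the planted diagnostic differences.
    """
    allowed = {spec.flank + plan.cut_after for plan in spec.sites}
    for _round in range(max_rounds):
        dirty = False
        for seq in (r_seq, s_seq):
            text = "".join(seq)
            extra = [c for c in cut_positions(text, enz) if c not in allowed]
            if not extra:
                continue
            cut = extra[0]
            # mutate a free base near the offending cut (same base in both
            # alleles, keeping them identical outside the planted SNPs)
            candidates = [
                p
                for p in range(max(0, cut - len(enz)), min(len(seq), cut + len(enz)))
                if p not in protected
            ]
            if not candidates:
                raise GenerationError(f"{spec.name}: cannot scrub site at cut {cut}")
            pos = int(rng.choice(candidates))
            new = rng.choice([b for b in "ACGT" if b != r_seq[pos]])
            r_seq[pos] = new
            s_seq[pos] = new
            dirty = True
            break
        if not dirty:
            return
    raise GenerationError(f"{spec.name}: scrubbing did not converge")


# canned fixtures reproducing the published assay geometries -----------------


def sw5_fixture(seed: int = 0) -> MarkerTemplates:
    """Tomato spotted wilt CAPS assay: 358-bp amplicon, Hpy188I.

    The susceptible allele cuts once (133 + 225); the resistant allele
    carries a second site from its diagnostic C (T in the susceptible
    allele), giving 43 + 133 + 182. Synthetic template, not the GenBank
    region; only the assay geometry is faithful.
    """
    spec = MarkerFixtureSpec(
        name="Sw-5",
        amplicon_length=358,
        enzyme=HPY188I,
        sites=(
            SitePlan(cut_after=133, presence="both"),
            SitePlan(cut_after=176, presence="R", snp_offset=1, absent_base="T"),
        ),
        primer_len=20,
        flank=40,
        seed=seed,
    )
    return gen_marker_templates(spec)


def ve1_caps_fixture(seed: int = 0) -> MarkerTemplates:
    """Verticillium-wilt assay at the second-round scale: 261 bp, DdeI.

    Resistant allele: one cut (156 + 105); susceptible: an extra site near
    the forward primer (26 + 130 + 105). The susceptible-only window is
    broken in the resistant allele at its final G (the printed C/G SNP).
    """
    spec = MarkerFixtureSpec(
        name="Ve-1",
        amplicon_length=261,
        enzyme=DDEI,
        sites=(
            SitePlan(cut_after=156, presence="both"),
            SitePlan(cut_after=26, presence="S", snp_offset=4, absent_base="C"),
        ),
        primer_len=20,
        flank=40,
        seed=seed,
    )
    return gen_marker_templates(spec)


@dataclass(frozen=True)
class NestedFixture:
    """A gene/paralog pair with outer primers and a dCAPS inner assay."""

    r_genomic: str
    s_genomic: str
    paralog: str
    outer_primers: PrimerPair
    dcaps: DcapsDesign
    snp: DiagnosticSnp
    outer_length: int
    inner_length: int


def ve1_nested_fixture(seed: int = 0) -> NestedFixture:
    """Full nested-PCR geometry for a Ve-1-like locus with a close paralog.

    A 1016-bp first-round amplicon contains the 261-bp dCAPS region; the
    inner forward primer carries an engineered A->C so that the DdeI site
    completes only on the susceptible G variant (the resistant C breaks
    it), while a natural shared site 156 bases in splits both alleles.
    The paralog runs ~91% identity overall with strongly divergent blocks
    under the outer primers, which is what makes the nested outer round
    locus-specific.
    """
    rng = np.random.default_rng(seed)
    outer_len, inner_len = 1016, 261
    inner_offset = 300  # inner region start within the outer amplicon (0-based)
    left_flank, right_flank = 120, 80
    total = left_flank + outer_len + right_flank
    genomic = rng.choice(BASES, size=total)

    inner0 = left_flank + inner_offset  # 0-based genomic start of the inner region
    # dCAPS window: genomic A T . A at inner positions 25-28, SNP at 29
    fixed = {25: "A", 26: "T", 28: "A"}
    for off, base in fixed.items():
        genomic[inner0 + off] = base
    snp_pos = inner0 + 29
    # natural shared DdeI site cutting 156 bases into the inner amplicon
    nat0 = inner0 + 156 - DDEI.cut_offset
    genomic[nat0 : nat0 + 5] = list("CTTAG")

    r_genomic = genomic.copy()
    s_genomic = genomic.copy()
    r_genomic[snp_pos] = "C"
    s_genomic[snp_pos] = "G"

    protected = set(range(inner0 + 20, inner0 + 35)) | set(range(nat0, nat0 + 5)) | {snp_pos}
    _scrub_nested(r_genomic, s_genomic, DDEI, protected, {inner0 + 156}, inner0, inner0 + inner_len, rng)

    outer_fwd = "".join(r_genomic[left_flank : left_flank + 22])
    outer_rev = reverse_complement("".join(r_genomic[left_flank + outer_len - 22 : left_flank + outer_len]))
    outer = PrimerPair(outer_fwd, outer_rev, target_gene="Ve-1")

    inner_context_r = "".join(r_genomic[inner0 : inner0 + inner_len + 60])
    snp = DiagnosticSnp(column=29, resistant_base="C", susceptible_base="G")
    design = design_dcaps(
        inner_context_r,
        snp,
        enzymes=[DDEI],
        primer_len=29,
        product_len=inner_len,
    )
    if isinstance(design, DesignFailure):
        raise GenerationError(f"Ve-1 nested dCAPS design failed: {design.near_misses}")

    paralog = _make_paralog(r_genomic, rng, outer, left_flank, outer_len)
    return NestedFixture(
        r_genomic="".join(r_genomic),
        s_genomic="".join(s_genomic),
        paralog=paralog,
        outer_primers=outer,
        dcaps=design,
        snp=snp,
        outer_length=outer_len,
        inner_length=inner_len,
    )


def _scrub_nested(
    r_seq: np.ndarray,
    s_seq: np.ndarray,
    enz: Enzyme,
    protected: set[int],
    allowed_cuts: set[int],
    region_start: int,
    region_end: int,
    rng: np.random.Generator,
    max_rounds: int = 400,
) -> None:
    """Remove accidental enzyme sites from the digested region of both alleles."""
    for _round in range(max_rounds):
        dirty = False
        for seq in (r_seq, s_seq):
            text = "".join(seq[region_start:region_end])
            for cut in cut_positions(text, enz):
                if region_start + cut in allowed_cuts:
                    continue
                lo = max(region_start, region_start + cut - len(enz))
                hi = min(region_end, region_start + cut + len(enz))
                free = [p for p in range(lo, hi) if p not in protected]
                if not free:
                    raise GenerationError("cannot scrub nested fixture")
                pos = int(rng.choice(free))
                new = rng.choice([b for b in "ACGT" if b != r_seq[pos]])
                r_seq[pos] = new
                s_seq[pos] = new
                dirty = True
                break
            if dirty:
                break
        if not dirty:
            return
    raise GenerationError("nested scrubbing did not converge")


def _make_paralog(
    genomic: np.ndarray,
    rng: np.random.Generator,
    outer: PrimerPair,
    left_flank: int,
    outer_len: int,
) -> str:
    """~91% identical copy, heavily diverged under the outer primer sites."""
    paralog = genomic.copy()
    n = len(paralog)
    fwd_region = range(left_flank, left_flank + len(outer.forward))
    rev_region = range(left_flank + outer_len - len(outer.reverse), left_flank + outer_len)
    primer_pos = set(fwd_region) | set(rev_region)
    for p in range(n):
        rate = 0.40 if p in primer_pos else 0.09
        if rng.random() < rate:
            paralog[p] = rng.choice([b for b in "ACGT" if b != paralog[p]])
    # guarantee the outer primers cannot bind the paralog exactly
    for region in (fwd_region, rev_region):
        pos = list(region)[len(outer.forward) // 2]
        if paralog[pos] == genomic[pos]:
            paralog[pos] = rng.choice([b for b in "ACGT" if b != genomic[pos]])
    return "".join(paralog)


def tm2_fixture(seed: int = 0) -> tuple[str, str]:
    """Aligned resistant/susceptible alleles for a 206-bp SCAR pair.

    One discriminating base sits 40 bases in (G resistant, A susceptible);
    the flanks are identical so both allele-specific products are 206 bp.
    """
    rng = np.random.default_rng(seed)
    n = 320
    seq = rng.choice(BASES, size=n)
    r = seq.copy()
    s = seq.copy()
    r[39] = "G"
    s[39] = "A"
    return "".join(r), "".join(s)
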