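"""In-silico CAPS, dCAPS and SCAR assay design and simulation.

A CAPS assay scores a SNP that creates or destroys a restriction site in a
PCR product; a dCAPS assay engineers the site with a deliberate mismatch in
one primer when the SNP does not touch a natural site; a SCAR assay scores
allele-specific amplification with a discriminating base at a primer's 3'
terminus. This module finds diagnostic SNPs in allele alignments, runs
virtual (and nested) PCR, simulates IUPAC restriction digestion on both
strands, engineers dCAPS primers, ranks paralog-divergent primer-placement
windows, and calls genotypes from observed fragment patterns.

The primer binding model is exact sequence match (a configurable mismatch
budget aside); assays are validated by fragment pattern, not kinetics, so
no melting-temperature model is included.
"""

from __future__ import annotations

import csv
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

DNA = frozenset("ACGT")

GAP_CHARS = frozenset("-.")


class DesignError(ValueError):
    """The requested assay cannot be designed on the given context."""


class SpecificityError(ValueError):
    """A nested inner pair binds the template outside the outer amplicon."""


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _check_dna(seq: str, what: str = "sequence") -> str:
    seq = seq.upper()
    bad = set(seq) - DNA
    if bad:
        raise ValueError(f"{what} contains non-ACGT characters: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: IUPAC recognition string and cut offset.

    ``cut_offset`` counts bases after the recognition start on the scanned
    strand; C^TNAG is offset 1, TCN^GA offset 3.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        rec = self.recognition.upper()
        if not rec or any(b not in "ACGTRYSWKMBDHVN" for b in rec):
            raise ValueError(f"{self.name}: recognition {rec!r} is not IUPAC DNA")
        if not 0 <= self.cut_offset <= len(rec):
            raise ValueError(f"{self.name}: cut offset {self.cut_offset} outside recognition")
        object.__setattr__(self, "recognition", rec)

    def __len__(self) -> int:
        return len(self.recognition)


HPY188I = Enzyme("Hpy188I", "TCNGA", 3)
DDEI = Enzyme("DdeI", "CTNAG", 1)

DEFAULT_ENZYMES = (HPY188I, DDEI)


def load_enzyme_catalog(path: str | Path) -> list[Enzyme]:
    """Read a delimited enzyme catalog (name, IUPAC site, cut offset)."""
    with Path(path).open(encoding="utf-8") as fh:
        return [
            Enzyme(row["name"], row["recognition"], int(row["cut_offset"]))
            for row in csv.DictReader(fh, delimiter="\t")
        ]


@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse primers, both written 5'->3'.

    ``engineered_mismatch`` records a dCAPS substitution as (1-based
    position from the primer 5' end, template base, introduced base) on
    the forward primer.
    """

    forward: str
    reverse: str
    engineered_mismatch: tuple[int, str, str] | None = None
    target_gene: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "forward", _check_dna(self.forward, "forward primer"))
        object.__setattr__(self, "reverse", _check_dna(self.reverse, "reverse primer"))
        for name, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if len(seq) < 15:
                raise ValueError(f"{name} primer shorter than 15 bases")
        if self.engineered_mismatch is not None:
            pos = self.engineered_mismatch[0]
            if not 1 <= pos <= len(self.forward):
                raise ValueError(f"engineered mismatch position {pos} outside primer")


@dataclass(frozen=True)
class Amplicon:
    """A PCR product with 1-based inclusive template coordinates."""

    sequence: str
    template_start: int
    template_end: int

    def __post_init__(self) -> None:
        if self.template_end - self.template_start + 1 != len(self.sequence):
            raise ValueError("amplicon coordinates do not match sequence length")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DigestPattern:
    """A multiset of restriction fragment lengths for one allele class."""

    allele_label: str  # R, S or H
    fragment_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fragment_lengths):
            raise ValueError("fragment lengths must be positive")
        object.__setattr__(
            self, "fragment_lengths", tuple(sorted(self.fragment_lengths))
        )

    @property
    def total(self) -> int:
        return sum(self.fragment_lengths)

    def as_multiset(self) -> Counter:
        return Counter(self.fragment_lengths)

    def band_set(self) -> frozenset[int]:
        """Distinct lengths: co-migrating duplicates collapse on a gel."""
        return frozenset(self.fragment_lengths)


def heterozygote_pattern(r: DigestPattern, s: DigestPattern) -> DigestPattern:
    """Expected heterozygote gel pattern: union of bands, shared ones once."""
    return DigestPattern("H", tuple(sorted(r.band_set() | s.band_set())))


@dataclass(frozen=True)
class DiagnosticSnp:
    """An alignment column separating resistant from susceptible alleles."""

    column: int  # 0-based alignment column
    resistant_base: str
    susceptible_base: str
    genome_position: int | None = None
    assembly: str = ""

    def __post_init__(self) -> None:
        if self.resistant_base == self.susceptible_base:
            raise ValueError("diagnostic SNP bases must differ")
        for b in (self.resistant_base, self.susceptible_base):
            if b not in DNA:
                raise ValueError(f"diagnostic base {b!r} is not a concrete nucleotide")


@dataclass(frozen=True)
class MarkerAssay:
    """A CAPS/dCAPS/SCAR definition with expected per-allele outcomes.

    For digestion assays ``r_pattern``/``s_pattern`` hold the expected
    fragment multisets; for SCAR assays the two allele-specific primer
    pairs define presence/absence outcomes instead.
    """

    name: str
    assay_type: str  # CAPS, dCAPS or SCAR
    enzyme: Enzyme | None = None
    primers: PrimerPair | None = None
    r_pattern: DigestPattern | None = None
    s_pattern: DigestPattern | None = None
    r_primers: PrimerPair | None = None
    s_primers: PrimerPair | None = None

    def __post_init__(self) -> None:
        if self.assay_type not in ("CAPS", "dCAPS", "SCAR"):
            raise ValueError(f"unknown assay type {self.assay_type!r}")
        if self.assay_type in ("CAPS", "dCAPS") and (
            self.r_pattern is None or self.s_pattern is None
        ):
            raise ValueError(f"{self.name}: digestion assay needs R and S patterns")


# ---------------------------------------------------------------------------
# diagnostic SNP discovery


def find_diagnostic_snps(
    resistant_seqs: Sequence[str], susceptible_seqs: Sequence[str]
) -> list[DiagnosticSnp]:
    """Columns where each allele class is monomorphic and the classes differ.

    Inputs are rows of one multiple alignment (equal lengths; gaps allowed
    but gap-containing columns are never diagnostic).
    """
    if not resistant_seqs or not susceptible_seqs:
        raise ValueError("need at least one sequence per class")
    seqs = [s.upper() for s in (*resistant_seqs, *susceptible_seqs)]
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("aligned sequences must share one length")
    n_res = len(resistant_seqs)
    out = []
    for col in range(length):
        bases = [s[col] for s in seqs]
        if any(b in GAP_CHARS or b not in DNA for b in bases):
            continue
        res = set(bases[:n_res])
        sus = set(bases[n_res:])
        if len(res) == 1 and len(sus) == 1 and res != sus:
            out.append(DiagnosticSnp(col, res.pop(), sus.pop()))
    return out


# ---------------------------------------------------------------------------
# virtual PCR


def _find_matches(template: str, probe: str, max_mismatches: int) -> list[int]:
    """0-based start positions where probe aligns with <= max mismatches."""
    hits = []
    n, m = len(template), len(probe)
    if max_mismatches == 0:
        start = template.find(probe)
        while start != -1:
            hits.append(start)
            start = template.find(probe, start + 1)
        return hits
    for start in range(n - m + 1):
        mism = 0
        window = template[start : start + m]
        for a, b in zip(window, probe):
            if a != b:
                mism += 1
                if mism > max_mismatches:
                    break
        else:
            hits.append(start)
    return hits


def in_silico_pcr(
    template: str,
    primers: PrimerPair,
    max_binding_mismatches: int = 0,
) -> Amplicon | None:
    """Predict the PCR product of a primer pair on a linear template.

    The forward primer is matched on the plus strand and the reverse on
    the minus strand; the product runs from the forward 5' end through the
    reverse binding site and carries the primer sequences (so engineered
    primer mismatches propagate into the product, which is what makes
    dCAPS work). With several products all are returned via
    :func:`in_silico_pcr_all`; this wrapper warns and returns the first.
    Returns None when either primer fails to bind.
    """
    products = in_silico_pcr_all(template, primers, max_binding_mismatches)
    if not products:
        return None
    if len(products) > 1:
        warnings.warn(
            f"{len(products)} products predicted; returning the first", stacklevel=2
        )
    return products[0]


def in_silico_pcr_all(
    template: str,
    primers: PrimerPair,
    max_binding_mismatches: int = 0,
) -> list[Amplicon]:
    template = _check_dna(template, "template")
    if not template:
        raise ValueError("empty template")
    budget_f = max_binding_mismatches
    if primers.engineered_mismatch is not None:
        # the engineered base is a designed template mismatch, always tolerated
        budget_f += 1
    fwd_sites = _find_matches(template, primers.forward, budget_f)
    rev_probe = reverse_complement(primers.reverse)
    rev_sites = _find_matches(template, rev_probe, max_binding_mismatches)
    products = []
    for f in fwd_sites:
        for r in rev_sites:
            rev_end = r + len(rev_probe)  # exclusive
            if rev_end <= f + len(primers.forward):
                continue  # overlapping or inverted orientation
            if r < f + len(primers.forward):
                raise ValueError("primer binding sites overlap")
            interior = template[f + len(primers.forward) : r]
            seq = primers.forward + interior + reverse_complement(primers.reverse)
            products.append(Amplicon(seq, f + 1, rev_end))
    return products


@dataclass(frozen=True)
class NestedResult:
    outer: Amplicon
    inner: Amplicon  # coordinates relative to the outer amplicon
    inner_on_template: Amplicon  # same product in original template coordinates


def nested_pcr(template: str, outer: PrimerPair, inner: PrimerPair) -> NestedResult:
    """Two-round PCR: the inner pair amplifies within the outer product.

    Raises :class:`SpecificityError` when the inner pair only binds the
    template outside the outer amplicon.
    """
    first = in_silico_pcr(template, outer)
    if first is None:
        raise DesignError("outer pair does not amplify the template")
    second = in_silico_pcr(first.sequence, inner)
    if second is None:
        if in_silico_pcr_all(template, inner):
            raise SpecificityError("inner pair binds the template outside the outer amplicon")
        raise DesignError("inner pair does not amplify the outer product")
    offset = first.template_start - 1
    on_template = Amplicon(
        second.sequence,
        second.template_start + offset,
        second.template_end + offset,
    )
    return NestedResult(first, second, on_template)


# ---------------------------------------------------------------------------
# restriction digestion


def _iupac_match(site_char: str, base: str) -> bool:
    return base in ambiguous_dna_values[site_char]


def _scan_strand(seq: str, recognition: str) -> list[int]:
    """0-based start positions of IUPAC-expanded recognition matches."""
    hits = []
    L = len(recognition)
    for start in range(len(seq) - L + 1):
        if all(_iupac_match(recognition[k], seq[start + k]) for k in range(L)):
            hits.append(start)
    return hits


def cut_positions(seq: str, enzyme: Enzyme) -> list[int]:
    """Deduplicated top-strand cut positions (bases to the left of the cut).

    Both strands are scanned: a minus-strand recognition at plus position s
    (i.e. the reverse complement of the site appears at s) cuts the top
    strand ``len - cut_offset`` bases into that window.
    """
    seq = seq.upper()
    L = len(enzyme)
    plus = set(_scan_strand(seq, enzyme.recognition))
    minus = set(_scan_strand(seq, reverse_complement(enzyme.recognition)))
    cuts = {s + enzyme.cut_offset for s in plus}
    # a window matching both orientations (palindromic pattern) is one
    # double-strand site and must not contribute a second cut
    cuts |= {s + (L - enzyme.cut_offset) for s in minus - plus}
    return sorted(c for c in cuts if 0 < c < len(seq))


def digest(amplicon: str | Amplicon, enzyme: Enzyme, allele_label: str = "R") -> DigestPattern:
    """Fragment lengths from a complete virtual digestion.

    Fragments are the maximal intervals between deduplicated cut positions;
    their lengths always sum to the amplicon length.
    """
    seq = amplicon.sequence if isinstance(amplicon, Amplicon) else amplicon
    seq = _check_dna(seq, "amplicon")
    if not seq:
        raise ValueError("empty amplicon")
    cuts = cut_positions(seq, enzyme)
    bounds = [0, *cuts, len(seq)]
    fragments = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    return DigestPattern(allele_label, fragments)


# ---------------------------------------------------------------------------
# dCAPS design


@dataclass(frozen=True)
class DcapsDesign:
    primers: PrimerPair
    enzyme: Enzyme
    cutting_allele: str  # which allele gains the engineered site, R or S
    r_pattern: DigestPattern
    s_pattern: DigestPattern

    def assay(self, name: str = "") -> MarkerAssay:
        kind = "dCAPS" if self.primers.engineered_mismatch else "CAPS"
        return MarkerAssay(
            name=name or f"{kind}-{self.enzyme.name}",
            assay_type=kind,
            enzyme=self.enzyme,
            primers=self.primers,
            r_pattern=self.r_pattern,
            s_pattern=self.s_pattern,
        )


@dataclass(frozen=True)
class DesignFailure:
    """No enzyme/window satisfied the constraints; near misses retained."""

    near_misses: tuple[str, ...]


def _apply_snp(context: str, snp: DiagnosticSnp, base: str) -> str:
    return context[: snp.column] + base + context[snp.column + 1 :]


def design_dcaps(
    context: str,
    snp: DiagnosticSnp,
    enzymes: Iterable[Enzyme] = DEFAULT_ENZYMES,
    max_engineered_mismatches: int = 1,
    primer_len: int = 25,
    product_len: int = 200,
    three_prime_clearance: int = 3,
) -> DcapsDesign | DesignFailure:
    """Engineer a CAPS/dCAPS assay around a diagnostic SNP.

    ``context`` is the template with either allele base at the SNP column
    (both allele templates are derived from it). For every enzyme and
    every recognition window overlapping the SNP, the designer checks
    whether primer substitutions (never at the SNP column, never in the 3
    terminal 3' bases, at most ``max_engineered_mismatches`` of them) can
    complete the site for exactly one allele. The forward primer is laid
    with its 3' end immediately before the SNP so that every window
    position left of the SNP is primer-writable. Zero required
    substitutions is the natural-CAPS degenerate case. The winning design
    is re-simulated on both allele templates (PCR then digestion) and is
    only returned when the patterns differ.
    """
    context = _check_dna(context, "context")
    if not 0 <= snp.column < len(context):
        raise ValueError("SNP column outside context")
    if snp.column < primer_len or len(context) - snp.column - 1 < primer_len:
        raise DesignError("SNP needs at least a primer length of context on both sides")

    r_template = _apply_snp(context, snp, snp.resistant_base)
    s_template = _apply_snp(context, snp, snp.susceptible_base)

    p_start = snp.column - primer_len  # primer covers [p_start, snp.column)
    near_misses: list[str] = []

    for enzyme in enzymes:
        L = len(enzyme)
        for s0 in range(snp.column - L + 1, snp.column + 1):
            if s0 < 0 or s0 + L > len(context):
                continue
            window = range(s0, s0 + L)
            # template bases right of the SNP must match naturally
            subs: list[int] = []
            feasible = True
            for p in window:
                if p == snp.column:
                    continue
                if _iupac_match(enzyme.recognition[p - s0], context[p]):
                    continue
                if p > snp.column:
                    feasible = False  # cannot engineer template-side bases
                    break
                subs.append(p)
            if not feasible:
                near_misses.append(
                    f"{enzyme.name}@{s0}: site extends past SNP over non-matching template"
                )
                continue
            if len(subs) > max_engineered_mismatches:
                near_misses.append(
                    f"{enzyme.name}@{s0}: needs {len(subs)} substitutions"
                )
                continue
            if any(p < p_start for p in subs):
                near_misses.append(f"{enzyme.name}@{s0}: substitution left of primer")
                continue
            if any(snp.column - p <= three_prime_clearance for p in subs):
                near_misses.append(
                    f"{enzyme.name}@{s0}: substitution within 3' terminal bases"
                )
                continue
            # does the site form for exactly one allele?
            rec_char = enzyme.recognition[snp.column - s0]
            r_cuts = _iupac_match(rec_char, snp.resistant_base)
            s_cuts = _iupac_match(rec_char, snp.susceptible_base)
            if r_cuts == s_cuts:
                near_misses.append(f"{enzyme.name}@{s0}: site does not discriminate")
                continue

            forward = list(context[p_start : snp.column])
            mismatch = None
            for p in subs:
                want = enzyme.recognition[p - s0]
                new_base = sorted(ambiguous_dna_values[want])[0]
                mismatch = (p - p_start + 1, forward[p - p_start], new_base)
                forward[p - p_start] = new_base
            fwd = "".join(forward)

            rev_start = min(p_start + product_len - primer_len, len(context) - primer_len)
            if rev_start <= snp.column:
                raise DesignError("not enough 3' context for the reverse primer")
            reverse = reverse_complement(context[rev_start : rev_start + primer_len])
            primers = PrimerPair(fwd, reverse, engineered_mismatch=mismatch)

            r_amp = in_silico_pcr(r_template, primers)
            s_amp = in_silico_pcr(s_template, primers)
            if r_amp is None or s_amp is None:
                near_misses.append(f"{enzyme.name}@{s0}: engineered primer failed to amplify")
                continue
            r_pat = digest(r_amp, enzyme, "R")
            s_pat = digest(s_amp, enzyme, "S")
            if r_pat.fragment_lengths == s_pat.fragment_lengths:
                near_misses.append(f"{enzyme.name}@{s0}: digests do not differ")
                continue
            return DcapsDesign(
                primers=primers,
                enzyme=enzyme,
                cutting_allele="R" if r_cuts else "S",
                r_pattern=r_pat,
                s_pattern=s_pat,
            )
    return DesignFailure(tuple(near_misses))


# ---------------------------------------------------------------------------
# SCAR design


@dataclass(frozen=True)
class ScarDesign:
    r_primers: PrimerPair
    s_primers: PrimerPair
    amplicon_length: int

    def assay(self, name: str = "SCAR") -> MarkerAssay:
        return MarkerAssay(
            name=name,
            assay_type="SCAR",
            r_primers=self.r_primers,
            s_primers=self.s_primers,
        )


def design_allele_specific_scar(
    resistant_seq: str,
    susceptible_seq: str,
    amplicon_target_length: int = 206,
    primer_len: int = 20,
) -> ScarDesign | DesignFailure:
    """Design R- and S-specific primer pairs of equal product length.

    Each allele-specific forward primer places a discriminating base at
    its 3' terminus; the shared reverse primer sits so both products have
    the target length (when the context allows it).
    """
    r = _check_dna(resistant_seq, "resistant allele")
    s = _check_dna(susceptible_seq, "susceptible allele")
    if len(r) != len(s):
        raise ValueError("allele sequences must be aligned to equal length")
    diffs = [i for i, (a, b) in enumerate(zip(r, s)) if a != b]
    if not diffs:
        return DesignFailure(("alleles are identical",))
    near = []
    for d in diffs:
        if d + 1 < primer_len:
            near.append(f"column {d}: too close to 5' end for a {primer_len}-mer")
            continue
        end = d + 1  # exclusive; 3' terminus on the discriminating base
        amp_end = end - primer_len + amplicon_target_length  # exclusive
        if amp_end > len(r):
            near.append(f"column {d}: not enough 3' context for {amplicon_target_length} bp")
            continue
        if r[amp_end - primer_len : amp_end] != s[amp_end - primer_len : amp_end]:
            near.append(f"column {d}: reverse primer region is polymorphic")
            continue
        r_fwd = r[end - primer_len : end]
        s_fwd = s[end - primer_len : end]
        reverse = reverse_complement(r[amp_end - primer_len : amp_end])
        return ScarDesign(
            r_primers=PrimerPair(r_fwd, reverse, target_gene="R-specific"),
            s_primers=PrimerPair(s_fwd, reverse, target_gene="S-specific"),
            amplicon_length=amplicon_target_length,
        )
    return DesignFailure(tuple(near))


# ---------------------------------------------------------------------------
# paralog-divergent windows


def find_specific_windows(
    gene_seq: str,
    paralog_seq: str,
    window_len: int = 20,
    identity_threshold: float = 90.0,
) -> list[tuple[int, float]]:
    """Sliding-window percent identity between a gene and its paralog.

    Inputs are positionally aligned (gap-free window comparison). Returns
    (0-based window start, percent identity) for windows strictly below
    the threshold, ranked ascending by identity — the low-identity zones
    are where locus-specific (e.g. nested outer) primers belong.
    """
    if not gene_seq or not paralog_seq:
        raise ValueError("sequences must be non-empty")
    if window_len > min(len(gene_seq), len(paralog_seq)):
        raise ValueError("window longer than a sequence")
    g, p = gene_seq.upper(), paralog_seq.upper()
    n = min(len(g), len(p))
    out = []
    for start in range(n - window_len + 1):
        same = sum(1 for k in range(window_len) if g[start + k] == p[start + k])
        identity = 100.0 * same / window_len
        if identity < identity_threshold:
            out.append((start, identity))
    out.sort(key=lambda t: (t[1], t[0]))
    return out


# ---------------------------------------------------------------------------
# genotype calling


def call_genotype(
    observed: DigestPattern | tuple[bool, bool],
    assay: MarkerAssay,
) -> str:
    """Call RR/RS/SS/NULL from an observed pattern.

    Digestion assays compare gel band sets: the R pattern calls RR, the S
    pattern SS, and the collapsed union of both calls RS. SCAR assays take
    (amplified in R-reaction, amplified in S-reaction).
    """
    if assay.assay_type == "SCAR":
        if not isinstance(observed, tuple):
            raise TypeError("SCAR assays take an (R-reaction, S-reaction) pair")
        r_amp, s_amp = observed
        if r_amp and s_amp:
            return "RS"
        if r_amp:
            return "RR"
        if s_amp:
            return "SS"
        return "NULL"
    if not isinstance(observed, DigestPattern):
        raise TypeError("digestion assays take a DigestPattern")
    bands = observed.band_set()
    r_bands = assay.r_pattern.band_set()
    s_bands = assay.s_pattern.band_set()
    if bands == r_bands:
        return "RR"
    if bands == s_bands:
        return "SS"
    if bands == (r_bands | s_bands):
        return "RS"
    warnings.warn(
        f"{assay.name}: observed bands {sorted(bands)} match no expected pattern",
        stacklevel=2,
    )
    return "NULL"
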