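"""Virtual PCR, restriction digestion, dCAPS/SCAR design and calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heatcross import marker_design as md
from heatcross.marker_design import (
    DDEI,
    HPY188I,
    DesignFailure,
    DiagnosticSnp,
    Enzyme,
    PrimerPair,
    call_genotype,
    cut_positions,
    design_allele_specific_scar,
    design_dcaps,
    digest,
    find_diagnostic_snps,
    find_specific_windows,
    heterozygote_pattern,
    in_silico_pcr,
    in_silico_pcr_all,
    nested_pcr,
    reverse_complement,
)
from heatcross.synthetic import tm2_fixture

dna = st.text(alphabet="ACGT", min_size=1)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestEnzyme:
    def test_bad_recognition_rejected(self):
        with pytest.raises(ValueError):
            Enzyme("X", "CTXAG", 1)

    def test_offset_outside_recognition(self):
        with pytest.raises(ValueError):
            Enzyme("X", "CTNAG", 6)

    def test_catalog_loads_packaged_enzymes(self):
        from heatcross.io_formats import _fixture_path

        enzymes = md.load_enzyme_catalog(_fixture_path("enzymes.tsv"))
        names = {e.name for e in enzymes}
        assert {"Hpy188I", "DdeI"} <= names


class TestDiagnosticSnps:
    def test_single_column_difference(self):
        snps = find_diagnostic_snps(["ACGT"], ["ACAT"])
        assert len(snps) == 1
        assert (snps[0].column, snps[0].resistant_base, snps[0].susceptible_base) == (2, "G", "A")

    def test_identical_classes_yield_nothing(self):
        assert find_diagnostic_snps(["ACGT", "ACGT"], ["ACGT"]) == []

    def test_within_class_polymorphism_excludes_column(self):
        # column 2 differs between classes but is polymorphic within resistant
        snps = find_diagnostic_snps(["ACGT", "ACCT"], ["ACAT"])
        assert snps == []

    def test_gap_columns_never_diagnostic(self):
        assert find_diagnostic_snps(["AC-T"], ["ACAT"]) == []

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            find_diagnostic_snps(["ACGT"], ["ACGTA"])

    def test_matches_brute_force_on_random_alignments(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n, length = 3, 60
            res = [random_seq(rng, length)]
            res.append(res[0] if rng.random() < 0.5 else random_seq(rng, length))
            sus = [random_seq(rng, length) for _ in range(2)]
            got = {(s.column, s.resistant_base, s.susceptible_base)
                   for s in find_diagnostic_snps(res, sus)}
            expect = set()
            for col in range(length):
                r = {x[col] for x in res}
                s = {x[col] for x in sus}
                if len(r) == 1 and len(s) == 1 and r != s:
                    expect.add((col, r.pop(), s.pop()))
            assert got == expect


class TestInSilicoPcr:
    def test_hand_constructed_sixty_mer(self):
        rng = np.random.default_rng(0)
        template = random_seq(rng, 60)
        primers = PrimerPair(template[:20], reverse_complement(template[40:60]))
        amp = in_silico_pcr(template, primers)
        assert amp is not None and len(amp) == 60
        assert (amp.template_start, amp.template_end) == (1, 60)
        assert amp.sequence == template

    def test_absent_primer_gives_none(self):
        rng = np.random.default_rng(1)
        template = random_seq(rng, 80)
        primers = PrimerPair("A" * 20, reverse_complement(template[-20:]))
        if "A" * 20 not in template:
            assert in_silico_pcr(template, primers) is None

    def test_multiple_products_warn(self):
        rng = np.random.default_rng(3)
        core = random_seq(rng, 30)
        fwd, rev_site = core[:16], core[14:30]
        template = fwd + "ACGTACGT" + rev_site + "GGGGCCCC" + rev_site
        primers = PrimerPair(fwd, reverse_complement(rev_site))
        with pytest.warns(UserWarning, match="products"):
            amp = in_silico_pcr(template, primers)
        assert amp is not None

    def test_agrees_with_brute_force_scan_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(15):
            template = random_seq(rng, 200)
            i = int(rng.integers(0, 80))
            j = int(rng.integers(i + 60, 180))
            primers = PrimerPair(template[i : i + 18], reverse_complement(template[j : j + 18]))
            products = in_silico_pcr_all(template, primers)
            # oracle: O(n*m) scan for all exact binding combinations
            fwd_hits = [k for k in range(len(template) - 17)
                        if template[k : k + 18] == primers.forward]
            rc = reverse_complement(primers.reverse)
            rev_hits = [k for k in range(len(template) - 17) if template[k : k + 18] == rc]
            expect = {
                (f + 1, r + 18)
                for f in fwd_hits
                for r in rev_hits
                if r + 18 > f + 18 and r >= f + 18
            }
            assert {(a.template_start, a.template_end) for a in products} == expect
            for a in products:
                assert len(a) == a.template_end - a.template_start + 1


class TestNestedPcr:
    def test_toy_two_rounds(self):
        rng = np.random.default_rng(11)
        template = random_seq(rng, 200)
        outer = PrimerPair(template[20:40], reverse_complement(template[150:170]))
        inner = PrimerPair(template[60:80], reverse_complement(template[100:120]))
        result = nested_pcr(template, outer, inner)
        assert len(result.outer) == 150
        assert len(result.inner) == 60
        assert result.inner_on_template.template_start == 61
        assert result.inner_on_template.template_end == 120

    def test_inner_equal_outer_is_idempotent(self):
        rng = np.random.default_rng(12)
        template = random_seq(rng, 120)
        outer = PrimerPair(template[:20], reverse_complement(template[-20:]))
        result = nested_pcr(template, outer, outer)
        assert result.inner.sequence == result.outer.sequence

    def test_inner_outside_outer_is_a_specificity_error(self):
        rng = np.random.default_rng(13)
        template = random_seq(rng, 300)
        outer = PrimerPair(template[100:120], reverse_complement(template[180:200]))
        inner = PrimerPair(template[10:30], reverse_complement(template[60:80]))
        with pytest.raises(md.SpecificityError):
            nested_pcr(template, outer, inner)

    def test_published_nested_geometry(self, ve1_nested):
        result = nested_pcr(ve1_nested.r_genomic, ve1_nested.outer_primers, ve1_nested.dcaps.primers)
        assert len(result.outer) == 1016
        assert len(result.inner) == 261

    def test_outer_primers_reject_the_paralog(self, ve1_nested):
        assert in_silico_pcr(ve1_nested.paralog, ve1_nested.outer_primers) is None


class TestDigest:
    def test_no_site_single_fragment(self):
        assert digest("A" * 50, HPY188I).fragment_lengths == (50,)

    def test_sw5_fixture_patterns(self, sw5):
        r, s = sw5.amplicons()
        assert digest(s, sw5.enzyme).fragment_lengths == (133, 225)
        assert digest(r, sw5.enzyme).fragment_lengths == (43, 133, 182)

    def test_ve1_fixture_patterns(self, ve1):
        r, s = ve1.amplicons()
        assert digest(r, ve1.enzyme).fragment_lengths == (105, 156)
        assert digest(s, ve1.enzyme).fragment_lengths == (26, 105, 130)

    def test_empty_amplicon_rejected(self):
        with pytest.raises(ValueError):
            digest("", DDEI)

    def test_length_conservation_fuzz(self):
        rng = np.random.default_rng(99)
        enzymes = [HPY188I, DDEI, Enzyme("TaqI", "TCGA", 1), Enzyme("AluI", "AGCT", 2)]
        for _ in range(300):
            seq = random_seq(rng, int(rng.integers(10, 400)))
            enz = enzymes[int(rng.integers(len(enzymes)))]
            assert digest(seq, enz).total == len(seq)

    def test_reverse_complement_mirrors_fragments_for_blunt_cutters(self):
        # exact mirror symmetry holds for palindromic blunt-end enzymes;
        # sticky-end cuts shift fragments by the overhang length
        blunt = [Enzyme("AluI", "AGCT", 2), Enzyme("RsaI", "GTAC", 2)]
        rng = np.random.default_rng(5)
        for _ in range(20):
            seq = random_seq(rng, 200)
            for enz in blunt:
                fwd = digest(seq, enz).as_multiset()
                rev = digest(reverse_complement(seq), enz).as_multiset()
                assert fwd == rev
            for enz in (HPY188I, DDEI):  # sticky: counts and totals still agree
                fwd = digest(seq, enz)
                rev = digest(reverse_complement(seq), enz)
                assert len(fwd.fragment_lengths) == len(rev.fragment_lengths)
                assert fwd.total == rev.total

    def test_palindromic_site_counts_one_cut(self):
        # one DdeI site must give exactly two fragments
        seq = "A" * 20 + "CTTAG" + "A" * 20
        assert len(digest(seq, DDEI).fragment_lengths) == 2
        assert cut_positions(seq, DDEI) == [21]


class TestDcapsDesign:
    def test_fixture_design_recovers_printed_assay(self, ve1_nested):
        design = ve1_nested.dcaps
        assert design.enzyme.name == "DdeI"
        assert design.primers.engineered_mismatch == (26, "A", "C")
        assert design.r_pattern.fragment_lengths == (105, 156)
        assert design.s_pattern.fragment_lengths == (26, 105, 130)
        assert design.cutting_allele == "S"

    def test_natural_caps_degenerate_case_needs_no_mismatch(self):
        rng = np.random.default_rng(21)
        while True:
            context = random_seq(rng, 120)
            # plant a TaqI site completed by the R base only at column 60
            context = context[:58] + "TC" + "G" + "A" + context[62:]
            taqi = Enzyme("TaqI", "TCGA", 1)
            if len(cut_positions(context, taqi)) == 1:
                break
        snp = DiagnosticSnp(60, "G", "C")
        design = design_dcaps(context, snp, [taqi], primer_len=25, product_len=100)
        assert not isinstance(design, DesignFailure)
        assert design.primers.engineered_mismatch is None
        assert design.cutting_allele == "R"

    def test_failure_lists_near_misses(self):
        rng = np.random.default_rng(22)
        context = "".join(c if c != "C" else "A" for c in random_seq(rng, 120))
        # no C anywhere: DdeI site can never be completed around a G/T SNP
        snp = DiagnosticSnp(60, "G", "T")
        result = design_dcaps(context, snp, [DDEI], primer_len=25, product_len=100)
        assert isinstance(result, DesignFailure)

    def test_insufficient_context_rejected(self):
        with pytest.raises(md.DesignError):
            design_dcaps("ACGTACGTACGT", DiagnosticSnp(5, "A", "G"), [DDEI])

    def test_closure_every_successful_design_discriminates(self):
        # brute-force enumeration over random planted SNPs: whenever the
        # designer returns an assay, re-simulating PCR + digestion on both
        # allele templates must give different patterns
        rng = np.random.default_rng(23)
        enzymes = [HPY188I, DDEI, Enzyme("TaqI", "TCGA", 1), Enzyme("RsaI", "GTAC", 2)]
        successes = 0
        for _ in range(40):
            context = random_seq(rng, 140)
            col = 70
            r_base, s_base = rng.choice(list("ACGT"), size=2, replace=False)
            snp = DiagnosticSnp(col, str(r_base), str(s_base))
            design = design_dcaps(context, snp, enzymes, primer_len=25, product_len=110)
            if isinstance(design, DesignFailure):
                continue
            successes += 1
            r_template = context[:col] + snp.resistant_base + context[col + 1 :]
            s_template = context[:col] + snp.susceptible_base + context[col + 1 :]
            r_amp = in_silico_pcr(r_template, design.primers)
            s_amp = in_silico_pcr(s_template, design.primers)
            assert r_amp is not None and s_amp is not None
            assert (
                digest(r_amp, design.enzyme).fragment_lengths
                != digest(s_amp, design.enzyme).fragment_lengths
            )
        assert successes > 0

    def test_engineered_mismatch_respects_3prime_clearance(self):
        rng = np.random.default_rng(24)
        for _ in range(30):
            context = random_seq(rng, 140)
            snp = DiagnosticSnp(70, "A", "G")
            design = design_dcaps(context, snp, [DDEI, HPY188I], primer_len=25, product_len=110)
            if isinstance(design, DesignFailure) or design.primers.engineered_mismatch is None:
                continue
            pos = design.primers.engineered_mismatch[0]
            assert len(design.primers.forward) - pos >= 3


class TestScarDesign:
    def test_toy_single_difference(self):
        rng = np.random.default_rng(31)
        base = random_seq(rng, 300)
        r = base[:49] + "G" + base[50:]
        s = base[:49] + "T" + base[50:]
        design = design_allele_specific_scar(r, s, amplicon_target_length=150)
        assert not isinstance(design, DesignFailure)
        assert design.r_primers.forward[-1] == "G"
        assert design.s_primers.forward[-1] == "T"
        r_amp = in_silico_pcr(r, design.r_primers)
        assert r_amp is not None and len(r_amp) == 150
        assert in_silico_pcr(s, design.r_primers) is None

    def test_identical_alleles_fail(self):
        seq = "ACGT" * 60
        assert isinstance(design_allele_specific_scar(seq, seq), DesignFailure)

    def test_tm2_fixture_both_products_206(self):
        r, s = tm2_fixture(seed=3)
        design = design_allele_specific_scar(r, s, 206)
        assert not isinstance(design, DesignFailure)
        assert design.amplicon_length == 206
        assert len(in_silico_pcr(r, design.r_primers)) == 206
        assert len(in_silico_pcr(s, design.s_primers)) == 206
        # cross reactions fail: that is the whole point of a SCAR pair
        assert in_silico_pcr(s, design.r_primers) is None
        assert in_silico_pcr(r, design.s_primers) is None


class TestSpecificWindows:
    def test_identical_sequences_have_no_divergent_window(self):
        seq = "ACGT" * 30
        assert find_specific_windows(seq, seq, 20, 99.9) == []

    def test_planted_divergent_block_ranks_first(self):
        rng = np.random.default_rng(41)
        gene = random_seq(rng, 300)
        paralog = list(gene)
        for k in range(100, 120):  # 20-base divergent block
            paralog[k] = {"A": "C", "C": "A", "G": "T", "T": "G"}[paralog[k]]
        windows = find_specific_windows(gene, "".join(paralog), 20, 100.0)
        best_start, best_identity = windows[0]
        assert best_identity == 0.0
        assert best_start == 100

    def test_vacuous_threshold_returns_all_windows(self):
        rng = np.random.default_rng(42)
        gene = random_seq(rng, 100)
        paralog = random_seq(rng, 100)
        assert len(find_specific_windows(gene, paralog, 20, 101.0)) == 81

    def test_window_longer_than_sequence(self):
        with pytest.raises(ValueError):
            find_specific_windows("ACGT", "ACGT", 10, 90.0)


class TestCallGenotype:
    def test_digestion_calls(self, sw5):
        r_pat = sw5.assay.r_pattern
        s_pat = sw5.assay.s_pattern
        assert call_genotype(r_pat, sw5.assay) == "RR"
        assert call_genotype(s_pat, sw5.assay) == "SS"
        assert call_genotype(heterozygote_pattern(r_pat, s_pat), sw5.assay) == "RS"

    def test_heterozygote_shares_comigrating_band(self, sw5):
        het = heterozygote_pattern(sw5.assay.r_pattern, sw5.assay.s_pattern)
        assert het.fragment_lengths == (43, 133, 182, 225)  # 133 reported once

    def test_unmatched_pattern_is_null_with_report(self, sw5):
        odd = md.DigestPattern("R", (100, 258))
        with pytest.warns(UserWarning, match="match no expected pattern"):
            assert call_genotype(odd, sw5.assay) == "NULL"

    @pytest.mark.parametrize(
        "pair,call", [((True, False), "RR"), ((False, True), "SS"), ((True, True), "RS"), ((False, False), "NULL")]
    )
    def test_scar_calls(self, pair, call):
        r, s = tm2_fixture(seed=3)
        design = design_allele_specific_scar(r, s, 206)
        assert call_genotype(pair, design.assay()) == call
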