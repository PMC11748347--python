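import itertools

import pytest

from panelprio.panels import ExceptionFlag, Mode
from panelprio.prioritize import (
    COMPHET_CANDIDATE,
    MONOALLELIC,
    NEEDS_CONFIRMATION,
    NO_FREQUENCY_DATA,
    PHASE_UNKNOWN,
    Candidate,
    CaseOutcome,
    FilterConfig,
    FunnelReport,
    OutcomeLabel,
    Phase,
    Segregation,
    check_segregation,
    check_zygosity_consistency,
    classify_outcome,
    detect_compound_het,
    filter_classification,
    filter_frequency,
    prioritize_case,
    rank_candidates,
)
from panelprio.synthetic import SimConfig, VariantSpike, simulate_variant_table
from panelprio.types import (
    CaseMode,
    ClinClass,
    PedMember,
    Pedigree,
    SampleCase,
    Sex,
    Zygosity,
)
from tests.conftest import mkvar

CFG = FilterConfig()


class TestFrequencyFilter:
    def test_common_variant_in_recessive_gene_removed(self, toy_panel):
        assert filter_frequency([mkvar(gene="GAR", maf=0.05)], toy_panel, CFG) == []

    def test_missing_maf_retained_and_flagged(self, toy_panel):
        (v,) = filter_frequency([mkvar(gene="GAR", maf=None)], toy_panel, CFG)
        assert NO_FREQUENCY_DATA in v.flags

    def test_exception_gene_bypasses_threshold(self, toy_panel):
        (v,) = filter_frequency([mkvar(gene="GEXC", maf=0.05)], toy_panel, CFG)
        assert v.gene == "GEXC"

    def test_most_permissive_mode_ceiling_wins(self, toy_panel):
        # GBOTH is AD+AR: the AR ceiling (0.01) applies, not the AD one
        (v,) = filter_frequency(
            [mkvar(gene="GBOTH", maf=0.005)], toy_panel, CFG
        )
        assert v.gene == "GBOTH"
        assert filter_frequency([mkvar(gene="GAD", maf=0.005)], toy_panel, CFG) == []


class TestClassificationFilter:
    def test_rule_table(self):
        vs = [
            mkvar(pos=1, clin=ClinClass.P),
            mkvar(pos=2, clin=ClinClass.LB),
            mkvar(pos=3, clin=ClinClass.VUS),
            mkvar(pos=4, clin=ClinClass.CIP, cip_has_plp=False),
        ]
        kept = filter_classification(vs, CFG)
        assert [v.clin_class for v in kept] == [ClinClass.P, ClinClass.VUS]

    def test_cip_with_plp_submission_retained(self):
        (v,) = filter_classification(
            [mkvar(clin=ClinClass.CIP, cip_has_plp=True)], CFG
        )
        assert v.clin_class is ClinClass.CIP

    def test_empty_input(self):
        assert filter_classification([], CFG) == []


class TestZygosity:
    def test_lone_het_vus_in_recessive_gene_removed(self, toy_panel):
        assert (
            check_zygosity_consistency([mkvar(gene="GAR", zyg=Zygosity.HET)], toy_panel)
            == []
        )

    def test_two_hets_same_recessive_gene_kept_as_comphet(self, toy_panel):
        vs = [
            mkvar(gene="GAR", pos=1, zyg=Zygosity.HET),
            mkvar(gene="GAR", pos=2, zyg=Zygosity.HET),
        ]
        kept = check_zygosity_consistency(vs, toy_panel)
        assert len(kept) == 2
        assert all(COMPHET_CANDIDATE in v.flags for v in kept)

    def test_lone_lp_het_in_recessive_gene_kept_monoallelic(self, toy_panel):
        (v,) = check_zygosity_consistency(
            [mkvar(gene="GAR", zyg=Zygosity.HET, clin=ClinClass.LP)], toy_panel
        )
        assert MONOALLELIC in v.flags

    @pytest.mark.parametrize(
        "gene,zyg,sex,kept",
        [
            ("GAD", Zygosity.HET, Sex.UNKNOWN, True),
            ("GAD", Zygosity.HOM, Sex.UNKNOWN, True),
            ("GAR", Zygosity.HOM, Sex.UNKNOWN, True),
            ("GXR", Zygosity.HEM, Sex.MALE, True),
            ("GXR", Zygosity.HOM, Sex.FEMALE, True),
            ("GXR", Zygosity.HET, Sex.FEMALE, False),  # lone VUS het
            ("GXD", Zygosity.HET, Sex.FEMALE, True),
        ],
    )
    def test_mode_rule_table(self, toy_panel, gene, zyg, sex, kept):
        out = check_zygosity_consistency([mkvar(gene=gene, zyg=zyg)], toy_panel, sex)
        assert (len(out) == 1) is kept

    def test_exception_gene_bypasses_removal(self, toy_panel):
        (v,) = check_zygosity_consistency(
            [mkvar(gene="GEXC", zyg=Zygosity.HET)], toy_panel
        )
        assert v.gene == "GEXC"

    def test_filters_commute_as_pure_predicates(self, toy_panel):
        # frequency and classification predicates are order-independent
        vs = lambda: [
            mkvar(pos=1, gene="GAR", maf=0.05, clin=ClinClass.P),
            mkvar(pos=2, gene="GAD", maf=1e-5, clin=ClinClass.LB),
            mkvar(pos=3, gene="GAR", maf=1e-5, clin=ClinClass.VUS),
            mkvar(pos=4, gene="GEXC", maf=0.5, clin=ClinClass.VUS),
        ]
        a = filter_classification(filter_frequency(vs(), toy_panel, CFG), CFG)
        b = filter_frequency(filter_classification(vs(), CFG), toy_panel, CFG)
        assert [v.pos for v in a] == [v.pos for v in b]


def trio_pedigree(child_gts, father_gts, mother_gts, father_affected=False):
    members = [
        PedMember("C", "F", "M", Sex.MALE, True),
        PedMember("F", None, None, Sex.MALE, father_affected),
        PedMember("M", None, None, Sex.FEMALE, False),
    ]
    return Pedigree(
        members=members,
        genotypes={"C": child_gts, "F": father_gts, "M": mother_gts},
    )


class TestCompoundHet:
    def v(self, pos):
        return mkvar(gene="GAR", pos=pos, zyg=Zygosity.HET)

    def test_trans_pair_confirmed(self):
        v1, v2 = self.v(1), self.v(2)
        ped = trio_pedigree(
            {v1.key: Zygosity.HET, v2.key: Zygosity.HET},
            {v1.key: Zygosity.HET},
            {v2.key: Zygosity.HET},
        )
        (pair,) = detect_compound_het([v1, v2], ped, "C")
        assert pair.phase is Phase.TRANS

    def test_cis_pair_flagged(self):
        v1, v2 = self.v(1), self.v(2)
        ped = trio_pedigree(
            {v1.key: Zygosity.HET, v2.key: Zygosity.HET},
            {v1.key: Zygosity.HET, v2.key: Zygosity.HET},
            {},
        )
        (pair,) = detect_compound_het([v1, v2], ped, "C")
        assert pair.phase is Phase.CIS

    def test_no_parents_gives_unknown_phase_and_brute_force_pairs(self):
        hets = [self.v(p) for p in range(1, 4)]
        pairs = detect_compound_het(hets, None)
        assert len(pairs) == 3
        assert all(p.phase is Phase.UNKNOWN for p in pairs)
        expected = {
            frozenset((a.key, b.key)) for a, b in itertools.combinations(hets, 2)
        }
        assert {p.keys for p in pairs} == expected

    @pytest.mark.parametrize("n_hets", [2, 3, 4, 5, 6])
    def test_matches_brute_force_enumeration(self, n_hets):
        hets = [self.v(p) for p in range(1, n_hets + 1)]
        pairs = detect_compound_het(hets)
        assert len(pairs) == n_hets * (n_hets - 1) // 2

    def test_pairs_never_cross_genes(self):
        vs = [
            mkvar(gene="GAR", pos=1, zyg=Zygosity.HET),
            mkvar(gene="GAD", pos=2, zyg=Zygosity.HET),
        ]
        assert detect_compound_het(vs) == []


def cand(v, modes, gene_flags=frozenset()):
    return Candidate(variant=v, panel_modes=set(modes), gene_flags=set(gene_flags))


class TestSegregation:
    def test_unaffected_carrier_parent_breaks_dominant_candidate(self):
        v = mkvar(gene="GAD", clin=ClinClass.P)
        ped = trio_pedigree({v.key: Zygosity.HET}, {v.key: Zygosity.HET}, {})
        c = cand(v, {Mode.AD})
        assert check_segregation(c, ped, "C") is Segregation.INCONSISTENT

    def test_incomplete_penetrance_flag_rescues(self):
        v = mkvar(gene="GPEN", clin=ClinClass.P)
        ped = trio_pedigree({v.key: Zygosity.HET}, {v.key: Zygosity.HET}, {})
        c = cand(v, {Mode.AD}, {ExceptionFlag.INCOMPLETE_PENETRANCE})
        assert check_segregation(c, ped, "C") is Segregation.CONSISTENT

    def test_no_relative_genotypes_uninformative(self):
        v = mkvar(gene="GAD", clin=ClinClass.P)
        ped = Pedigree(
            members=[PedMember("C", None, None, Sex.MALE, True)],
            genotypes={"C": {v.key: Zygosity.HET}},
        )
        assert check_segregation(cand(v, {Mode.AD}), ped, "C") is (
            Segregation.UNINFORMATIVE
        )

    def test_carrier_parent_fine_for_recessive(self):
        v = mkvar(gene="GAR", clin=ClinClass.P, zyg=Zygosity.HOM)
        ped = trio_pedigree(
            {v.key: Zygosity.HOM}, {v.key: Zygosity.HET}, {v.key: Zygosity.HET}
        )
        assert check_segregation(cand(v, {Mode.AR}), ped, "C") is (
            Segregation.CONSISTENT
        )

    def test_unaffected_homozygous_relative_breaks_recessive(self):
        v = mkvar(gene="GAR", clin=ClinClass.P, zyg=Zygosity.HOM)
        ped = trio_pedigree(
            {v.key: Zygosity.HOM}, {v.key: Zygosity.HOM}, {v.key: Zygosity.HET}
        )
        assert check_segregation(cand(v, {Mode.AR}), ped, "C") is (
            Segregation.INCONSISTENT
        )


class TestRanking:
    def test_class_dominates_frequency(self):
        vus = cand(mkvar(pos=1, clin=ClinClass.VUS, maf=1e-5), {Mode.AD})
        p = cand(mkvar(pos=2, clin=ClinClass.P, maf=1e-3), {Mode.AD})
        ranked = rank_candidates([vus, p])
        assert ranked[0].variant.clin_class is ClinClass.P
        assert [c.rank for c in ranked] == [1, 2]

    def test_smaller_maf_breaks_class_tie(self):
        a = cand(mkvar(pos=1, clin=ClinClass.VUS, maf=1e-3), {Mode.AD})
        b = cand(mkvar(pos=2, clin=ClinClass.VUS, maf=1e-6), {Mode.AD})
        assert rank_candidates([a, b])[0].variant.pos == 2

    def test_full_tie_broken_by_position_and_stable_on_rerun(self):
        mk = lambda pos: cand(mkvar(pos=pos, clin=ClinClass.VUS, maf=1e-4), {Mode.AD})
        first = [c.variant.pos for c in rank_candidates([mk(5), mk(3), mk(9)])]
        second = [c.variant.pos for c in rank_candidates([mk(9), mk(5), mk(3)])]
        assert first == second == [3, 5, 9]


class TestPrioritizeCase:
    def case(self, **kw):
        return SampleCase(sample_id="PC001", sex=Sex.MALE, panels=["SP1"], **kw)

    def test_spiked_recessive_homozygote_ranks_first(self, genome, library):
        gene = next(
            e.gene for e in library["SP1"].entries if e.modes == {Mode.AR}
        )
        cfg = SimConfig(
            seed=42,
            spikes=[VariantSpike(gene=gene, mode=Mode.AR, pattern="HOM",
                                 clin_class=ClinClass.P)],
        )
        variants, manifest = simulate_variant_table(cfg, genome)
        cands, funnel = prioritize_case(self.case(), variants, library)
        assert cands, "spike lost in cascade"
        top = cands[0].variant
        assert (top.chrom, top.pos) == (
            manifest.iloc[0]["chrom"],
            manifest.iloc[0]["pos"],
        )

    def test_funnel_counts_non_increasing(self, genome, library):
        cfg = SimConfig(seed=7)
        variants, _ = simulate_variant_table(cfg, genome)
        _, funnel = prioritize_case(self.case(), variants, library)
        counts = [c for _, c in funnel.stages]
        assert counts == sorted(counts, reverse=True)
        assert funnel.count("raw") == len(variants)

    def test_low_depth_survivor_flagged_for_confirmation(self, genome, library):
        gene = next(
            e.gene for e in library["SP1"].entries if e.modes == {Mode.AR}
        )
        cfg = SimConfig(
            seed=9,
            n_background_variants=0,
            spikes=[VariantSpike(gene=gene, mode=Mode.AR, pattern="HOM",
                                 clin_class=ClinClass.LP, depth=12)],
        )
        variants, _ = simulate_variant_table(cfg, genome)
        cands, _ = prioritize_case(self.case(), variants, library)
        assert NEEDS_CONFIRMATION in cands[0].flags

    def test_cis_pair_removed_when_vus(self, toy_library):
        from panelprio.synthetic import simulate_pedigree

        v1 = mkvar(gene="GAR", pos=10, zyg=Zygosity.HET, clin=ClinClass.VUS)
        v2 = mkvar(gene="GAR", pos=20, zyg=Zygosity.HET, clin=ClinClass.VUS)
        ped = trio_pedigree(
            {v1.key: Zygosity.HET, v2.key: Zygosity.HET},
            {v1.key: Zygosity.HET, v2.key: Zygosity.HET},
            {},
        )
        case = SampleCase(sample_id="C", sex=Sex.MALE, panels=["TOY"])
        cands, _ = prioritize_case(case, [v1, v2], toy_library, ped)
        assert cands == []

    def test_unphased_pair_kept_with_flag(self, toy_library):
        v1 = mkvar(gene="GAR", pos=10, zyg=Zygosity.HET, clin=ClinClass.P)
        v2 = mkvar(gene="GAR", pos=20, zyg=Zygosity.HET, clin=ClinClass.LP)
        case = SampleCase(sample_id="C", sex=Sex.MALE, panels=["TOY"])
        cands, _ = prioritize_case(case, [v1, v2], toy_library, None)
        assert len(cands) == 2
        assert all(PHASE_UNKNOWN in c.flags for c in cands)
        # pairing is symmetric
        assert cands[0].pairing == cands[1].variant.key
        assert cands[1].pairing == cands[0].variant.key

    def test_unknown_panel_id_raises(self, toy_library):
        case = SampleCase(sample_id="C", panels=["MISSING"])
        with pytest.raises(KeyError, match="MISSING"):
            prioritize_case(case, [], toy_library)


class TestOutcome:
    def case(self, mode=CaseMode.DIAGNOSTIC):
        return SampleCase(sample_id="C", sex=Sex.MALE, panels=["TOY"], mode=mode)

    def test_recessive_homozygote_lp_positive(self):
        c = cand(mkvar(gene="GAR", zyg=Zygosity.HOM, clin=ClinClass.LP), {Mode.AR})
        out = classify_outcome([c], self.case())
        assert out.label is OutcomeLabel.POSITIVE
        assert out.supporting == [c]

    def test_comphet_p_plus_vus_uncertain(self):
        a = cand(mkvar(gene="GAR", pos=1, zyg=Zygosity.HET, clin=ClinClass.P), {Mode.AR})
        b = cand(mkvar(gene="GAR", pos=2, zyg=Zygosity.HET, clin=ClinClass.VUS), {Mode.AR})
        a.pairing, b.pairing = b.variant.key, a.variant.key
        assert classify_outcome([a, b], self.case()).label is OutcomeLabel.UNCERTAIN

    def test_comphet_both_plp_positive(self):
        a = cand(mkvar(gene="GAR", pos=1, zyg=Zygosity.HET, clin=ClinClass.P), {Mode.AR})
        b = cand(mkvar(gene="GAR", pos=2, zyg=Zygosity.HET, clin=ClinClass.LP), {Mode.AR})
        a.pairing, b.pairing = b.variant.key, a.variant.key
        assert classify_outcome([a, b], self.case()).label is OutcomeLabel.POSITIVE

    def test_lone_p_het_in_recessive_gene_partial(self):
        c = cand(mkvar(gene="GAR", zyg=Zygosity.HET, clin=ClinClass.P), {Mode.AR})
        assert classify_outcome([c], self.case()).label is OutcomeLabel.PARTIAL

    def test_no_candidates_unsolved(self):
        assert classify_outcome([], self.case()).label is OutcomeLabel.UNSOLVED

    def test_never_positive_on_vus_only(self):
        c = cand(mkvar(gene="GAD", zyg=Zygosity.HET, clin=ClinClass.VUS), {Mode.AD})
        out = classify_outcome([c], self.case())
        assert out.label is not OutcomeLabel.POSITIVE

    def test_carrier_mode_reports_het_plp_in_recessive_gene(self):
        c = cand(mkvar(gene="GAR", zyg=Zygosity.HET, clin=ClinClass.LP), {Mode.AR})
        out = classify_outcome([c], self.case(mode=CaseMode.CARRIER))
        assert out.label is OutcomeLabel.CARRIER_FINDINGS

    def test_hemizygous_p_in_xlr_male_positive(self):
        c = cand(mkvar(gene="GXR", chrom="X", zyg=Zygosity.HEM, clin=ClinClass.P), {Mode.XLR})
        assert classify_outcome([c], self.case()).label is OutcomeLabel.POSITIVE


class TestFunnelReport:
    def test_rejects_increasing_counts(self):
        with pytest.raises(ValueError):
            FunnelReport(stages=[("raw", 5), ("panel", 9)])
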