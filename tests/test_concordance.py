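import numpy as np
import pytest

from concord.concordance import (
    ConcordanceStatus,
    GeneConcordanceRow,
    cohort_gene_table,
    conditional_mutation_frequency,
    match_locus,
    profile_patient,
)
from concord.panels import AlterationKind, Assay

from .conftest import make_alt


def t(gene, locus="", kind=AlterationKind.POINT_MUTATION, pid="P1"):
    return make_alt(gene, locus, kind, Assay.TISSUE, patient_id=pid)


def c(gene, locus="", kind=AlterationKind.POINT_MUTATION, pid="P1"):
    return make_alt(gene, locus, kind, Assay.CTDNA, patient_id=pid)


class TestMatchLocus:
    def test_identical_point_mutation(self):
        assert match_locus(t("TP53", "R175H"), c("TP53", "R175H"))

    def test_different_locus(self):
        assert not match_locus(t("TP53", "R175H"), c("TP53", "R273H"))

    def test_amplification_both(self):
        assert match_locus(
            t("MYC", kind=AlterationKind.AMPLIFICATION),
            c("MYC", kind=AlterationKind.AMPLIFICATION),
        )

    def test_amp_vs_point_mutation_no_match(self):
        assert not match_locus(
            t("EGFR", kind=AlterationKind.AMPLIFICATION), c("EGFR", "L858R")
        )

    def test_different_genes(self):
        assert not match_locus(t("TP53", "R175H"), c("KRAS", "R175H"))

    def test_fusion_never_matches(self):
        assert not match_locus(
            t("ALK", "F1", kind=AlterationKind.FUSION),
            c("ALK", "F1", kind=AlterationKind.FUSION),
        )

    def test_protein_prefix_normalized(self):
        assert match_locus(t("TP53", "p.R175H"), c("TP53", "r175h"))

    def test_indel_matches_point_mutation_rules(self):
        assert match_locus(
            t("EGFR", "E746_A750del", kind=AlterationKind.INDEL),
            c("EGFR", "E746_A750DEL", kind=AlterationKind.INDEL),
        )

    def test_empty_locus_never_matches(self):
        assert not match_locus(t("TP53", ""), c("TP53", ""))


class TestProfilePatient:
    def test_empty_tissue_is_n_n(self):
        prof = profile_patient([], [c("TP53", "R175H")])
        assert prof.status is ConcordanceStatus.N_N
        assert (prof.mutual_gene_count, prof.mutual_mutation_count) == (0, 0)

    def test_gene_level_only_is_y_n(self):
        prof = profile_patient(
            [t("TP53", "R175H"), t("KRAS", "G12D")],
            [c("TP53", "R273H"), c("EGFR", "L858R")],
        )
        assert prof.mutual_genes == {"TP53"}
        assert prof.mutual_mutation_genes == set()
        assert prof.status is ConcordanceStatus.Y_N

    def test_gene_deduplication(self):
        prof = profile_patient(
            [t("TP53", "R175H")], [c("TP53", "R175H"), c("TP53", "R273H")]
        )
        assert (prof.mutual_gene_count, prof.mutual_mutation_count) == (1, 1)
        assert prof.status is ConcordanceStatus.Y_Y

    def test_amp_one_side_pm_other_is_gene_level_only(self):
        prof = profile_patient(
            [t("EGFR", kind=AlterationKind.AMPLIFICATION)], [c("EGFR", "L858R")]
        )
        assert prof.status is ConcordanceStatus.Y_N

    def test_patient_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            profile_patient([t("TP53", "R175H", pid="P1")], [c("TP53", "R175H", pid="P2")])

    def test_mixed_patient_list_raises(self):
        with pytest.raises(ValueError, match="mixes patients"):
            profile_patient([t("TP53", "R1H", pid="P1"), t("KRAS", "G12D", pid="P2")], [])


class TestCohortGeneTable:
    def test_single_patient_tissue_only(self):
        rows = cohort_gene_table({"P1": ([t("TP53", "R175H")], [])})
        assert rows == [GeneConcordanceRow("TP53", 1, 0, 0, 0)]

    def test_hand_counted_three_patients(self):
        cohort = {
            "P1": (
                [t("TP53", "R175H", pid="P1"), t("KRAS", "G12D", pid="P1")],
                [c("TP53", "R175H", pid="P1")],
            ),
            "P2": (
                [t("TP53", "R273H", pid="P2")],
                [c("TP53", "R175H", pid="P2"), c("KRAS", "G12D", pid="P2")],
            ),
            "P3": ([], [c("TP53", "R175H", pid="P3")]),
        }
        rows = {r.gene: r for r in cohort_gene_table(cohort)}
        # hand count: TP53 tissue in P1,P2; ctdna in P1,P2,P3; mutual P1,P2;
        # locus-identical only P1. KRAS tissue P1, ctdna P2, no overlap.
        assert rows["TP53"] == GeneConcordanceRow("TP53", 2, 3, 2, 1)
        assert rows["KRAS"] == GeneConcordanceRow("KRAS", 1, 1, 0, 0)

    def test_row_invariant_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            GeneConcordanceRow("KIT", 6, 6, 1, 2)

    def test_column_sums_match_patient_sums(self):
        rng = np.random.default_rng(7)
        cohort = {}
        genes = ["TP53", "KRAS", "EGFR", "MYC"]
        for i in range(40):
            pid = f"P{i}"
            t_alts = [
                t(g, f"L{rng.integers(3)}", pid=pid)
                for g in genes
                if rng.random() < 0.4
            ]
            c_alts = [
                c(g, f"L{rng.integers(3)}", pid=pid)
                for g in genes
                if rng.random() < 0.4
            ]
            cohort[pid] = (t_alts, c_alts)
        rows = cohort_gene_table(cohort)
        per_gene = sum(r.mutual_gene_n for r in rows)
        per_patient = sum(
            profile_patient(*pair).mutual_gene_count for pair in cohort.values()
        )
        assert per_gene == per_patient
        per_gene_mut = sum(r.mutual_mutation_n for r in rows)
        per_patient_mut = sum(
            profile_patient(*pair).mutual_mutation_count for pair in cohort.values()
        )
        assert per_gene_mut == per_patient_mut


class TestConditionalMutationFrequency:
    def test_known_rows(self):
        table = [
            GeneConcordanceRow("APC", 40, 20, 16, 14),
            GeneConcordanceRow("KRAS", 81, 56, 36, 11),
            GeneConcordanceRow("RARE", 3, 3, 2, 1),  # below retention threshold
        ]
        freqs, median = conditional_mutation_frequency(table, min_mutual=5)
        assert freqs["APC"] == pytest.approx(14 / 16)  # 0.875
        assert freqs["KRAS"] == pytest.approx(11 / 36, abs=5e-4)  # ~0.306
        assert "RARE" not in freqs
        assert median == pytest.approx((14 / 16 + 11 / 36) / 2)

    def test_saturated_gene_is_one(self):
        table = [GeneConcordanceRow("TP53", 10, 10, 7, 7)]
        freqs, median = conditional_mutation_frequency(table)
        assert freqs["TP53"] == 1.0 and median == 1.0

    def test_empty_retained_set(self):
        freqs, median = conditional_mutation_frequency(
            [GeneConcordanceRow("TP53", 3, 3, 2, 1)], min_mutual=5
        )
        assert freqs == {} and median is None

    def test_min_mutual_validation(self):
        with pytest.raises(ValueError):
            conditional_mutation_frequency([], min_mutual=0)

    def test_reference_table_median(self):
        from concord.io import load_reference_gene_table

        rows = load_reference_gene_table()
        freqs, median = conditional_mutation_frequency(rows, min_mutual=5)
        assert len(freqs) == 11
        assert median == pytest.approx(69 / 110, abs=1e-12)
        assert min(freqs.values()) == pytest.approx(11 / 36, abs=5e-4)


def brute_force_profile(tissue, ctdna):
    """Independent O(n^2) all-pairs re-implementation of the concordance rules."""
    mutual, mutation = set(), set()
    for a in tissue:
        for b in ctdna:
            if a.gene == b.gene:
                mutual.add(a.gene)
                amp = AlterationKind.AMPLIFICATION
                locusful = (AlterationKind.POINT_MUTATION, AlterationKind.INDEL)
                same = (a.kind is amp and b.kind is amp) or (
                    a.kind in locusful
                    and b.kind in locusful
                    and a.locus.upper().removeprefix("P.")
                    == b.locus.upper().removeprefix("P.")
                    and a.locus != ""
                )
                if same:
                    mutation.add(a.gene)
    return mutual, mutation


class TestOracleEquivalence:
    def _random_lists(self, rng):
        genes = ["TP53", "KRAS", "EGFR", "MYC", "APC"]
        loci = ["R175H", "G12D", "L858R", "V600E"]
        kinds = [
            AlterationKind.POINT_MUTATION,
            AlterationKind.INDEL,
            AlterationKind.AMPLIFICATION,
            AlterationKind.FUSION,
        ]

        def mk(assay):
            out = []
            for _ in range(rng.integers(0, 6)):
                kind = kinds[rng.integers(len(kinds))]
                out.append(
                    make_alt(
                        genes[rng.integers(len(genes))],
                        locus=""
                        if kind is AlterationKind.AMPLIFICATION
                        else loci[rng.integers(len(loci))],
                        kind=kind,
                        assay=assay,
                    )
                )
            return out

        return mk(Assay.TISSUE), mk(Assay.CTDNA)

    def test_1000_random_cases(self, rng):
        for _ in range(1000):
            tissue, ctdna = self._random_lists(rng)
            prof = profile_patient(tissue, ctdna)
            mutual, mutation = brute_force_profile(tissue, ctdna)
            assert prof.mutual_genes == mutual
            assert prof.mutual_mutation_genes == mutation

    def test_symmetry(self, rng):
        for _ in range(200):
            tissue, ctdna = self._random_lists(rng)
            a = profile_patient(tissue, ctdna)
            # swap assay roles: concordance definitions are symmetric
            b_mutual, b_mutation = brute_force_profile(ctdna, tissue)
            assert a.mutual_genes == b_mutual
            assert a.mutual_mutation_genes == b_mutation
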