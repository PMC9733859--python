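"""Fisher exact association, perfect separation and control frequencies."""
from itertools import product
from math import comb, isnan

import numpy as np
import pytest

import cordmod as cm
from cordmod.association import ContingencyTable, fisher_exact, fisher_exact_rxc

from conftest import make_genotype_matrix, make_pedigree


def table(counts, scheme="carrier_2x2"):
    cols = ("a", "b") if len(counts[0]) == 2 else ("a", "b", "c")
    return ContingencyTable(np.array(counts), ("affected", "healthy"), cols, scheme)


def oracle_fisher_2x2(counts):
    """Independent enumeration oracle: hypergeometric over all tables with
    the observed margins, two-sided by probability ordering."""
    (a, b), (c, d) = counts
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):  # first cell = x
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    lo, hi = max(0, c1 - r2), min(c1, r1)
    p_obs = prob(a)
    return sum(p for x in range(lo, hi + 1)
               if (p := prob(x)) <= p_obs * (1 + 1e-12))


def oracle_fisher_2xc(counts):
    """Second, independent Freeman-Halton enumerator (itertools-based)."""
    counts = np.asarray(counts)
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)

    def prob(t):
        from math import factorial
        num = 1
        for r in rows:
            num *= factorial(int(r))
        for c in cols:
            num *= factorial(int(c))
        den = factorial(int(counts.sum()))
        for x in t.ravel():
            den *= factorial(int(x))
        return num / den

    p_obs = prob(counts)
    total = 0.0
    ranges = [range(min(rows[0], c) + 1) for c in cols]
    for first in product(*ranges):
        if sum(first) != rows[0]:
            continue
        second = [c - f for c, f in zip(cols, first)]
        if any(x < 0 for x in second):
            continue
        t = np.array([list(first), second])
        p = prob(t)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return total


class TestContingency:
    def test_cacng8_carrier_table_excluding_uncertain(self, table2, pedigree):
        t = cm.contingency_table(table2, pedigree, "CACNG8:c.*6819A>T")
        assert t.counts.tolist() == [[4, 0], [0, 3]]

    def test_cacng8_with_uncertain_as_healthy(self, table2, pedigree):
        t = cm.contingency_table(table2, pedigree, "CACNG8:c.*6819A>T",
                                 include_uncertain_as_healthy=True)
        assert t.counts.tolist() == [[4, 0], [0, 4]]

    def test_constant_variant_has_empty_column(self, table2, pedigree):
        t = cm.contingency_table(table2, pedigree, "PDE4DIP:c.7015C>A")
        assert t.counts.tolist() == [[4, 0], [3, 0]]

    def test_genotype_2x3_scheme(self, table2, pedigree):
        t = cm.contingency_table(table2, pedigree, "PAX2:c.-375C>A",
                                 scheme="genotype_2x3")
        # affected: het, wild, hom, het; healthy: hom, hom, hom
        assert t.counts.tolist() == [[1, 2, 1], [0, 0, 3]]

    def test_missing_status_group_rejected(self):
        g = make_genotype_matrix({"G:c.1A>T": "het wild"}, ["a", "b"])
        ped = make_pedigree(affected=["a", "b"], healthy=[])
        with pytest.raises(ValueError, match="healthy"):
            cm.contingency_table(g, ped, "G:c.1A>T")

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            table([[1, -1], [0, 2]])


class TestFisher2x2:
    def test_balanced_table(self):
        assert fisher_exact(table([[1, 1], [1, 1]])) == pytest.approx(1.0)

    def test_fixture_table_is_one_thirty_fifth(self):
        assert fisher_exact(table([[4, 0], [0, 3]])) == pytest.approx(1 / 35,
                                                                      rel=1e-12)

    def test_eight_member_table(self):
        assert fisher_exact(table([[4, 0], [0, 4]])) == pytest.approx(2 / 70,
                                                                      rel=1e-12)

    def test_exhaustive_agreement_with_enumeration_oracle(self):
        """Every 2x2 table with total <= 12 against the independent
        hypergeometric enumeration, to 1e-12 relative tolerance."""
        checked = 0
        for a, b, c, d in product(range(13), repeat=4):
            if a + b + c + d > 12 or a + b == 0 or c + d == 0:
                continue
            if a + c == 0 or b + d == 0:
                continue
            counts = [[a, b], [c, d]]
            assert fisher_exact(table(counts)) == pytest.approx(
                oracle_fisher_2x2(counts), rel=1e-12, abs=1e-15)
            checked += 1
        assert checked > 300

    def test_invariance_under_row_and_column_swap(self):
        for counts in ([[4, 0], [0, 3]], [[3, 1], [2, 5]], [[2, 2], [1, 4]]):
            swapped = [[counts[1][1], counts[1][0]], [counts[0][1], counts[0][0]]]
            assert fisher_exact(table(counts)) == pytest.approx(
                fisher_exact(table(swapped)), rel=1e-12)

    def test_2x3_rejected(self):
        with pytest.raises(ValueError, match="2x2"):
            fisher_exact(table([[1, 1, 1], [1, 1, 1]], scheme="genotype_2x3"))


class TestFisherRxC:
    def test_collapses_to_2x2_case(self):
        assert fisher_exact_rxc(table([[4, 0, 0], [0, 0, 3]],
                                      scheme="genotype_2x3")) == pytest.approx(
            1 / 35, rel=1e-12)

    @pytest.mark.parametrize("counts", [
        [[2, 1, 1], [1, 1, 1]],
        [[3, 0, 2], [1, 2, 0]],
        [[1, 2, 1], [0, 0, 3]],
        [[5, 1, 0], [0, 4, 2]],
    ])
    def test_agrees_with_independent_enumerator(self, counts):
        mine = fisher_exact_rxc(table(counts, scheme="genotype_2x3"))
        assert mine == pytest.approx(oracle_fisher_2xc(counts), rel=1e-12)

    def test_matches_2x2_routine_on_2x2_tables(self):
        for counts in ([[4, 0], [0, 3]], [[3, 2], [1, 4]], [[1, 1], [1, 1]]):
            assert fisher_exact_rxc(table(counts)) == pytest.approx(
                fisher_exact(table(counts)), rel=1e-12)

    def test_empty_row_margin_untestable(self):
        with pytest.raises(ValueError, match="untestable"):
            fisher_exact_rxc(table([[0, 0, 0], [1, 1, 1]], scheme="genotype_2x3"))

    def test_total_above_limit_directs_to_2x2(self):
        big = [[10, 10, 10], [10, 10, 10]]
        with pytest.raises(ValueError, match="2x2"):
            fisher_exact_rxc(table(big, scheme="genotype_2x3"))


class TestPerfectSeparation:
    def test_fixture_separated_variants(self, table2, candidates, pedigree):
        # The causative/associated variants separate by construction; among
        # the candidates, both the CACNG8 top variant and the ABCA4 variant
        # (whose genotype tracks disease status exactly) are disjoint
        # between the affected and healthy groups.
        assert cm.perfect_separation(table2, pedigree) == [
            "GUCY2D:c.2513G>C", "GUCY2D:c.3044-7G>T",
            "ABCA4:c.6730-3T>C", "CACNG8:c.*6819A>T"]
        assert cm.perfect_separation(candidates, pedigree) == [
            "ABCA4:c.6730-3T>C", "CACNG8:c.*6819A>T"]

    def test_shared_value_not_flagged(self):
        g = make_genotype_matrix({"G:c.1A>T": "het het het het"},
                                 ["a", "b", "c", "d"])
        ped = make_pedigree(affected=["a", "b"], healthy=["c", "d"])
        assert cm.perfect_separation(g, ped) == []

    def test_two_subject_toy_flagged(self):
        g = make_genotype_matrix({"G:c.1A>T": "wild hom"}, ["a", "b"])
        ped = make_pedigree(affected=["b"], healthy=["a"])
        assert cm.perfect_separation(g, ped) == ["G:c.1A>T"]

    def test_separation_implies_minimal_fisher_p(self, table2, pedigree):
        """A perfectly separated carrier table has the smallest exact p among
        all tables sharing its margins."""
        t = cm.contingency_table(table2, pedigree, "CACNG8:c.*6819A>T")
        p_obs = fisher_exact(t)
        (a, b), (c, d) = t.counts
        r1, c1, n = a + b, a + c, a + b + c + d
        for x in range(0, min(r1, c1) + 1):
            other = [[x, r1 - x], [c1 - x, n - r1 - c1 + x]]
            if min(min(r) for r in other) < 0:
                continue
            assert p_obs <= fisher_exact(table(other)) + 1e-12


class TestControlFrequencies:
    def test_all_wild_cohort_is_zero(self):
        g = make_genotype_matrix({"G:c.1A>T": " ".join(["wild"] * 100)},
                                 [f"C{i}" for i in range(100)])
        report = cm.control_frequencies(g)
        assert report.frequency("G:c.1A>T") == 0.0

    def test_het_plus_hom_pair(self):
        g = make_genotype_matrix({"G:c.1A>T": "het hom"}, ["c1", "c2"])
        assert cm.control_frequencies(g).frequency("G:c.1A>T") == 0.75

    def test_missing_calls_excluded_from_denominator(self):
        g = make_genotype_matrix({"G:c.1A>T": "het missing"}, ["c1", "c2"])
        # one called subject -> 1 alt allele over 2 chromosomes
        assert cm.control_frequencies(g).frequency("G:c.1A>T") == 0.5

    def test_untyped_variant_reported_not_zero(self):
        g = make_genotype_matrix({"G:c.1A>T": "wild wild"}, ["c1", "c2"])
        report = cm.control_frequencies(g, ["G:c.1A>T", "X:c.9A>T"])
        assert isnan(report.frequency("X:c.9A>T"))
        assert not report.table.at["X:c.9A>T", "typed"]

    def test_planted_frequency_recovered_within_3_binomial_sd(self):
        cfg = cm.SimulationConfig(seed=21, control_cohort_size=500,
                                  neutral_allele_freq=0.1,
                                  modifier_allele_freq=0.1)
        cohort = cm.simulate_cohort(cfg)
        report = cm.control_frequencies(cohort.controls)
        freqs = report.table.loc[
            [k for k in cohort.genotypes.variant_keys
             if k != cohort.truth.causative], "allele_freq"]
        sd = np.sqrt(0.1 * 0.9 / (2 * 500))
        assert ((freqs - 0.1).abs() <= 3 * sd).mean() > 0.95
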