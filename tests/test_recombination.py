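"""Site statistics, the permutation machinery and family classification."""

import numpy as np
import pytest

from conftest import brute_force_incompatibility
from gbgcscan.errors import InputError, NotComputableError
from gbgcscan.genome_io import GeneFamilyAlignment
from gbgcscan.recombination import (
    MaxChiTest,
    NssTest,
    PhiTest,
    classify_family,
    incompatibility_matrix,
    informative_sites,
    maxchi_statistic,
    nss_statistic,
    pair_incompatibility,
    permutation_test,
    phi_statistic,
    run_family_tests,
)


def _aln_from_columns(columns, spacing=1, total=None):
    """Build an alignment whose j-th column sits at position j*spacing."""
    n_taxa = len(columns[0])
    length = total or (len(columns) - 1) * spacing + 1
    seqs = [["A"] * length for _ in range(n_taxa)]
    for j, col in enumerate(columns):
        for t, base in enumerate(col):
            seqs[t][j * spacing] = base
    return GeneFamilyAlignment(
        "f", tuple(f"g{t:02d}" for t in range(n_taxa)), tuple("".join(s) for s in seqs)
    )


class TestInformativeSites:
    def test_definition(self):
        a = _aln_from_columns(["AACC", "AAAC", "A-A-", "GGTT"])
        m = informative_sites(a)
        # AACC and GGTT are parsimony informative; the singleton and the
        # gap-reduced column are not
        assert list(m.positions) == [0, 3]

    def test_empty_matrix_allowed(self):
        a = _aln_from_columns(["AAAA"])
        assert informative_sites(a).n_sites == 0


class TestPairIncompatibility:
    @pytest.mark.parametrize(
        "ci,cj,expected",
        [
            ("AACC", "GGTT", 0),   # compatible: 3 of 4 gametes
            ("AACC", "GTGT", 1),   # all four gametes
            ("AACC", "AACC", 0),
            ("AAC-", "GGTT", 0),   # missing taxon dropped
        ],
    )
    def test_known_pairs(self, ci, cj, expected):
        assert pair_incompatibility(list(ci), list(cj)) == expected

    def test_taxon_mismatch_rejected(self):
        with pytest.raises(InputError):
            pair_incompatibility(["A", "C"], ["A"])

    def test_matches_brute_force_on_random_multistate_pairs(self, rng):
        letters = np.array(list("ACGT-"))
        for _ in range(150):
            n = int(rng.integers(4, 7))
            ci = letters[rng.integers(0, 5, size=n)]
            cj = letters[rng.integers(0, 5, size=n)]
            assert pair_incompatibility(ci, cj) == brute_force_incompatibility(ci, cj), (
                ci, cj,
            )

    def test_matrix_fast_path_agrees_with_general(self, rng):
        # binary columns exercise the vectorised four-gamete path
        cols = ["".join(rng.choice(["A", "C"], size=6)) for _ in range(12)]
        a = _aln_from_columns(cols)
        m = informative_sites(a)
        inc = incompatibility_matrix(m)
        for i in range(m.n_sites):
            for j in range(m.n_sites):
                expected = pair_incompatibility(m.states[:, i], m.states[:, j]) if i != j else 0
                assert inc[i, j] == expected


class TestPhiStatistic:
    def test_all_pairs_compatible_gives_zero(self):
        a = _aln_from_columns(["AACC", "AACC", "GGTT"], spacing=10)
        assert phi_statistic(informative_sites(a)) == 0.0

    def test_single_incompatible_pair(self):
        a = _aln_from_columns(["AACC", "GTGT"], spacing=10)
        assert phi_statistic(informative_sites(a)) == 1.0

    def test_distant_pair_outside_window_not_computable(self):
        a = _aln_from_columns(["AACC", "GTGT"], spacing=500)
        with pytest.raises(NotComputableError):
            phi_statistic(informative_sites(a), window=100)

    def test_invariant_under_taxon_reordering(self, rng):
        cols = ["".join(rng.choice(["A", "C", "G"], size=8)) for _ in range(15)]
        a = _aln_from_columns(cols, spacing=5)
        perm = rng.permutation(8)
        b = GeneFamilyAlignment(
            "f", tuple(a.taxa[i] for i in perm), tuple(a.seqs[i] for i in perm)
        )
        sa, sb = informative_sites(a), informative_sites(b)
        if sa.n_sites >= 2:
            assert phi_statistic(sa) == pytest.approx(phi_statistic(sb))


class TestNssStatistic:
    def test_all_adjacent_compatible(self):
        a = _aln_from_columns(["AACC", "AACC", "CCAA"], spacing=10)
        m = informative_sites(a)
        assert nss_statistic(m, formulation="adjacent") == 1.0
        assert nss_statistic(m, formulation="matrix") == 1.0

    def test_alternating_pattern_adjacent_fraction(self):
        # five sites, four adjacencies of which two are compatible
        cols = ["AACC", "AACC", "GTGT", "GTGT", "AACC"]
        m = informative_sites(_aln_from_columns(cols, spacing=10))
        inc = incompatibility_matrix(m)
        adj = [inc[i, i + 1] for i in range(4)]
        assert sorted(adj) == [0, 0, 1, 1]
        assert nss_statistic(m, formulation="adjacent") == 0.5

    def test_single_site_not_computable(self):
        m = informative_sites(_aln_from_columns(["AACC"]))
        with pytest.raises(NotComputableError):
            nss_statistic(m)


class TestMaxChiStatistic:
    def test_identical_pair_only_not_computable(self):
        a = GeneFamilyAlignment("f", ("g01", "g02"), ("ACGT" * 5, "ACGT" * 5))
        with pytest.raises(NotComputableError):
            maxchi_statistic(a)

    def test_perfect_split_equals_table_total(self):
        # for the pair (g01, g02): 5 variable matching sites then 5
        # mismatching sites (the third sequence keeps the left half variable)
        s1 = "A" * 10 + "G" * 3
        s2 = "A" * 5 + "C" * 5 + "G" * 3
        s3 = "C" * 5 + "A" * 5 + "G" * 3
        a = GeneFamilyAlignment("f", ("g01", "g02", "g03"), (s1, s2, s3))
        assert maxchi_statistic(a, half_window="full") == pytest.approx(10.0)

    def test_windowed_variant_bounded_by_window_total(self):
        s1 = "A" * 40
        s2 = "A" * 20 + "C" * 20
        s3 = "C" * 20 + "A" * 20
        a = GeneFamilyAlignment("f", ("g01", "g02", "g03"), (s1, s2, s3))
        assert maxchi_statistic(a, half_window=5) == pytest.approx(10.0)


class TestPermutationMachinery:
    def test_invariant_statistic_gives_p_one(self):
        # two compatible informative sites: every permutation ties
        a = _aln_from_columns(["AACC", "AACC"], spacing=10)
        res = permutation_test(PhiTest(), a, n_perm=50, seed=1)
        assert res.p_value == 1.0

    def test_zero_permutations_rejected(self):
        a = _aln_from_columns(["AACC", "AACC"], spacing=10)
        with pytest.raises(InputError):
            permutation_test(PhiTest(), a, n_perm=0, seed=1)

    def test_not_computable_alignment_flagged(self):
        a = _aln_from_columns(["AAAA", "AAAC"])
        res = permutation_test(PhiTest(), a, n_perm=10, seed=1)
        assert not res.computable
        assert res.statistic is None and res.p_value is None

    def test_seeded_reproducibility(self, rng):
        cols = ["".join(rng.choice(["A", "C"], size=8)) for _ in range(30)]
        a = _aln_from_columns(cols, spacing=7)
        r1 = run_family_tests(a, n_perm=100, seed=7)
        r2 = run_family_tests(a, n_perm=100, seed=7)
        for k in r1:
            assert r1[k] == r2[k]

    @pytest.mark.parametrize("stat", [PhiTest(), NssTest(), MaxChiTest()])
    def test_p_values_in_unit_interval(self, stat, rng):
        cols = ["".join(rng.choice(["A", "C"], size=8)) for _ in range(25)]
        a = _aln_from_columns(cols, spacing=9)
        res = permutation_test(stat, a, n_perm=99, seed=3)
        if res.computable:
            assert 0.0 < res.p_value <= 1.0


class TestClassifyFamily:
    @staticmethod
    def _res(method, p):
        from gbgcscan.recombination import RecombTestResult

        if p is None:
            return RecombTestResult.not_computable(method)
        return RecombTestResult(method, 1.0, p, 1000, True)

    def test_consensus_all_significant_is_recombinant(self):
        results = {m: self._res(m, p) for m, p in
                   [("PHI", 0.01), ("NSS", 0.02), ("MaxChi2", 0.03)]}
        v = classify_family(results, methods=("PHI", "NSS", "MaxChi2"))
        assert v.status == "recombinant"

    def test_consensus_disagreement_is_discarded(self):
        results = {m: self._res(m, p) for m, p in
                   [("PHI", 0.01), ("NSS", 0.20), ("MaxChi2", 0.01)]}
        v = classify_family(results, methods=("PHI", "NSS", "MaxChi2"))
        assert v.status == "discarded"

    def test_consensus_all_nonsignificant_is_non_recombinant(self):
        results = {m: self._res(m, 0.5) for m in ("PHI", "NSS", "MaxChi2")}
        v = classify_family(results, methods=("PHI", "NSS", "MaxChi2"))
        assert v.status == "non_recombinant"

    def test_not_computable_means_unclassified(self):
        v = classify_family({"PHI": self._res("PHI", None)}, methods=("PHI",))
        assert v.status == "unclassified"

    def test_missing_method_rejected(self):
        with pytest.raises(InputError):
            classify_family({"PHI": self._res("PHI", 0.01)}, methods=("PHI", "NSS"))

    def test_single_method_threshold(self):
        assert classify_family({"PHI": self._res("PHI", 0.049)}).status == "recombinant"
        assert classify_family({"PHI": self._res("PHI", 0.05)}).status == "non_recombinant"
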