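"""Recombinant/non-recombinant contrasts, sign test, GC3 binning, OLS."""

import math

import numpy as np
import pytest

from gbgcscan.association import (
    bin_by_gc3,
    bin_regression,
    compare_groups,
    ingest_external_rates,
    sign_test_across_datasets,
)
from gbgcscan.errors import InputError


class TestCompareGroups:
    def test_identical_groups(self):
        r = compare_groups([0.3, 0.3], [0.3, 0.3])
        assert (r.mean_difference, r.t_statistic, r.p_value) == (0.0, 0.0, 1.0)

    def test_separated_constant_groups(self):
        r = compare_groups([0.3, 0.3], [0.2, 0.2])
        assert r.mean_difference == pytest.approx(0.1)
        assert r.p_value == pytest.approx(0.0)

    def test_difference_sign_is_recombinant_minus_nonrecombinant(self):
        r = compare_groups([0.5, 0.6], [0.1, 0.2])
        assert r.mean_difference > 0
        assert r.t_statistic > 0

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            compare_groups([], [0.1, 0.2])

    def test_matches_closed_form_pooled_t(self):
        a, b = [0.1, 0.2, 0.3], [0.15, 0.25, 0.45]
        r = compare_groups(a, b)
        na, nb = 3, 3
        sp2 = (np.var(a, ddof=1) * (na - 1) + np.var(b, ddof=1) * (nb - 1)) / (na + nb - 2)
        t = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / na + 1 / nb))
        assert r.t_statistic == pytest.approx(t)


class TestSignTest:
    def test_eleven_of_fourteen(self):
        chi2, p = sign_test_across_datasets([1.0] * 11 + [-1.0] * 3)
        assert chi2 == pytest.approx(32 / 7)
        assert p == pytest.approx(0.0325, abs=0.0005)

    def test_balanced_split_is_null(self):
        chi2, p = sign_test_across_datasets([1.0] * 7 + [-1.0] * 7)
        assert (chi2, p) == (0.0, 1.0)

    def test_unanimous_split(self):
        chi2, _ = sign_test_across_datasets([1.0] * 14)
        assert chi2 == pytest.approx(14.0)

    def test_symmetry_under_sign_swap(self):
        a = sign_test_across_datasets([1.0] * 11 + [-1.0] * 3)
        b = sign_test_across_datasets([-1.0] * 11 + [1.0] * 3)
        assert a == pytest.approx(b)

    def test_zeros_dropped_with_warning(self):
        with pytest.warns(UserWarning):
            chi2, _ = sign_test_across_datasets([1.0, -1.0, 0.0])
        assert chi2 == 0.0

    def test_all_zero_rejected(self):
        with pytest.raises(InputError), pytest.warns(UserWarning):
            sign_test_across_datasets([0.0, 0.0])


def _genes(gc3s, statuses, rates=None):
    rates = rates or [math.nan] * len(gc3s)
    return [
        (f"f{i:03d}", g, s, r) for i, (g, s, r) in enumerate(zip(gc3s, statuses, rates))
    ]


class TestBinByGc3:
    def test_exact_division(self, rng):
        genes = _genes(rng.random(40), ["recombinant"] * 40)
        bins = bin_by_gc3(genes)
        assert [b.n_genes for b in bins] == [2] * 20
        assert all(b.p_rec == 1.0 for b in bins)

    def test_remainder_rule_478(self, rng):
        statuses = ["recombinant" if rng.random() < 0.3 else "non_recombinant"
                    for _ in range(478)]
        bins = bin_by_gc3(_genes(rng.random(478), statuses))
        sizes = [b.n_genes for b in bins]
        assert sizes == [24] * 18 + [23] * 2
        assert sum(sizes) == 478

    def test_bins_sorted_and_partition_preserved(self, rng):
        gc3s = rng.random(95)
        bins = bin_by_gc3(_genes(gc3s, ["non_recombinant"] * 95))
        means = [b.mean_gc3 for b in bins]
        assert means == sorted(means)
        assert sum(b.n_genes for b in bins) == 95
        assert max(b.n_genes for b in bins) - min(b.n_genes for b in bins) <= 1

    def test_too_few_genes_rejected(self):
        with pytest.raises(InputError):
            bin_by_gc3(_genes([0.1] * 10, ["recombinant"] * 10))

    def test_unexpected_status_rejected(self):
        with pytest.raises(InputError):
            bin_by_gc3(_genes([0.1] * 25, ["unclassified"] * 25))

    def test_external_rates_averaged_per_bin(self):
        genes = _genes([0.1] * 10 + [0.9] * 10,
                       ["non_recombinant"] * 20,
                       rates=[1.0] * 10 + [3.0] * 10)
        bins = bin_by_gc3(genes, n_bins=2)
        assert bins[0].mean_external_rate == pytest.approx(1.0)
        assert bins[1].mean_external_rate == pytest.approx(3.0)


class TestBinRegression:
    def test_perfect_linear_relation(self, rng):
        gc3s = np.linspace(0.2, 0.6, 60)
        statuses = ["recombinant" if g > 0.4 else "non_recombinant" for g in gc3s]
        bins = bin_by_gc3(_genes(gc3s, statuses), n_bins=3)
        res = bin_regression(bins)
        assert 0.0 <= res.r_squared <= 1.0

    def test_collinear_points_have_r2_one(self):
        from gbgcscan.association import BinSummary

        bins = [BinSummary(i + 1, 0.1 * i, 0.05 * i, 10) for i in range(5)]
        res = bin_regression(bins)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(0.5)

    def test_constant_response_is_undefined(self):
        from gbgcscan.association import BinSummary

        bins = [BinSummary(i + 1, 0.1 * i, 0.5, 10) for i in range(5)]
        res = bin_regression(bins)
        assert math.isnan(res.r_squared)

    def test_two_bins_rejected(self):
        from gbgcscan.association import BinSummary

        bins = [BinSummary(1, 0.1, 0.2, 10), BinSummary(2, 0.2, 0.4, 10)]
        with pytest.raises(InputError):
            bin_regression(bins)

    def test_independent_response_has_small_r2(self, rng):
        from gbgcscan.association import BinSummary

        bins = [BinSummary(i + 1, i / 200, float(rng.random()), 10) for i in range(200)]
        res = bin_regression(bins)
        assert res.r_squared < 0.05


class TestIngestExternalRates:
    def test_round_trip(self, tmp_path):
        p = tmp_path / "rates.tsv"
        lines = ["family_id\trho"] + [f"f{i:03d}\t{i * 0.1:.3f}" for i in range(478)]
        p.write_text("\n".join(lines) + "\n")
        rates = ingest_external_rates(p)
        assert len(rates) == 478
        assert rates["f010"] == pytest.approx(1.0)

    def test_exclusion_list_applied(self, tmp_path):
        p = tmp_path / "rates.tsv"
        p.write_text("family_id\trho\nf1\t0.5\nf2\t0.7\n")
        assert set(ingest_external_rates(p, exclude=["f2"])) == {"f1"}

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "rates.tsv"
        p.write_text("family_id\trho\nf1\t0.5\nf1\t0.7\n")
        with pytest.raises(InputError):
            ingest_external_rates(p)

    def test_non_numeric_rate_rejected(self, tmp_path):
        p = tmp_path / "rates.tsv"
        p.write_text("family_id\trho\nf1\tabc\n")
        with pytest.raises(InputError):
            ingest_external_rates(p)
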