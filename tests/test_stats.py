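import math
from fractions import Fraction

import numpy as np
import pytest

from conftest import brute_force_pi_sum
from walnutkit.io_windows import GenotypeMatrix, Window
from walnutkit.stats import (
    fst_from_components,
    rod,
    tajima_d,
    wc_fst_components,
    wc_fst_site,
    window_fst,
    window_pi,
    windowed_stats,
)


def oracle_tajima_d(n: int, S: int, pi_sum: float) -> float:
    """Independent transcription of the 1989 constants in exact fractions."""
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi_sum - S / float(a1)) / math.sqrt(
        float(e1) * S + float(e2) * S * (S - 1)
    )


def _mat(calls, positions=None, chrom_length=1000):
    calls = np.asarray(calls, dtype=np.int8)
    n = len(calls)
    return GenotypeMatrix(
        chroms=np.asarray(["c"] * n, dtype=object),
        positions=np.asarray(positions if positions is not None else range(1, n + 1)),
        calls=calls,
        samples=[f"s{i}" for i in range(calls.shape[1])],
        chrom_lengths={"c": chrom_length},
    )


class TestPi:
    def test_single_site_four_chromosomes(self):
        # c=2 of k=4: 4 mismatching haplotype pairs of 6 -> 2/3 per site
        mat = _mat([[1, 1]])
        w = Window("c", 0, 100)
        assert window_pi(mat, w) == pytest.approx(2 / 3 / 100)

    def test_no_variants_is_zero(self):
        mat = _mat(np.empty((0, 2)))
        assert window_pi(mat, Window("c", 0, 100)) == 0.0

    def test_monomorphic_contributes_zero(self):
        assert window_pi(_mat([[0, 0]]), Window("c", 0, 100)) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        calls = rng.integers(-1, 3, size=(rng.integers(1, 21), rng.integers(2, 7)))
        mat = _mat(calls, positions=range(1, len(calls) + 1))
        w = Window("c", 0, 500)
        assert window_pi(mat, w) * 500 == pytest.approx(
            brute_force_pi_sum(calls), abs=1e-12
        )


class TestTajimaD:
    def test_zero_when_pi_equals_watterson(self):
        # n=4: a1 = 11/6, S=11 -> S/a1 = 6 exactly
        assert tajima_d(4, 11, 6.0) == 0.0

    def test_undefined_when_no_segregating_sites(self):
        assert math.isnan(tajima_d(10, 0, 0.0))

    def test_small_n_errors(self):
        with pytest.raises(ValueError):
            tajima_d(3, 5, 1.0)

    def test_frozen_fixture_equals_independent_oracle(self):
        # 16 segregating sites in 5 diploids drawn once with seed 42
        rng = np.random.default_rng(42)
        calls = rng.integers(0, 3, size=(16, 5))
        c = calls.sum(axis=1).astype(float)
        assert ((c > 0) & (c < 10)).all()
        pi_sum = float((2 * c * (10 - c) / 90.0).sum())
        assert pi_sum == pytest.approx(7.822222222222223)
        assert tajima_d(10, 16, pi_sum) == pytest.approx(1.773212477544863, abs=1e-12)

    @pytest.mark.parametrize("n,S", [(4, 1), (10, 16), (23, 40), (46, 7)])
    def test_matches_oracle_across_sample_sizes(self, n, S):
        pi_sum = 0.7 * S  # arbitrary diversity level
        assert tajima_d(n, S, pi_sum) == pytest.approx(
            oracle_tajima_d(n, S, pi_sum), abs=1e-12
        )

    def test_sign_rare_allele_excess_negative(self):
        # all singletons: pi_sum far below S/a1
        calls = np.zeros((20, 5), dtype=np.int8)
        calls[np.arange(20), np.arange(20) % 5] = 1
        c = calls.sum(axis=1).astype(float)
        pi_sum = float((2 * c * (10 - c) / 90.0).sum())
        assert tajima_d(10, 20, pi_sum) < 0

    def test_sign_intermediate_frequency_positive(self):
        calls = np.full((20, 5), 1, dtype=np.int8)  # every site at 0.5
        c = calls.sum(axis=1).astype(float)
        pi_sum = float((2 * c * (10 - c) / 90.0).sum())
        assert tajima_d(10, 20, pi_sum) > 0


IDX1 = np.asarray([0, 1])
IDX2 = np.asarray([2, 3])


def oracle_wc_components(n1, p1, h1, n2, p2, h2):
    """Two-population Weir–Cockerham components, transcribed independently."""
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 / 2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 / 2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


class TestWcFst:
    def test_fixed_difference_is_one(self):
        a, b, c = wc_fst_site(np.asarray([[0, 0, 2, 2]]), IDX1, IDX2)
        assert a / (a + b + c) == pytest.approx(1.0)

    def test_identical_populations_nonpositive(self):
        a, b, c = wc_fst_site(np.asarray([[0, 1, 0, 1]]), IDX1, IDX2)
        assert a <= 0

    def test_hand_checked_table(self):
        # pop1 {0/0, 0/1}, pop2 {1/1, 0/1}: frozen hand calculation
        a, b, c = wc_fst_site(np.asarray([[0, 1, 2, 1]]), IDX1, IDX2)
        assert (a, b, c) == pytest.approx((0.0625, 0.0, 0.25))
        assert a / (a + b + c) == pytest.approx(0.2)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_independent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 9, size=2)
        g1 = rng.integers(0, 3, size=n1)
        g2 = rng.integers(0, 3, size=n2)
        calls = np.concatenate([g1, g2])[None, :]
        i1, i2 = np.arange(n1), np.arange(n1, n1 + n2)
        a, b, c = wc_fst_site(calls, i1, i2)
        exp = oracle_wc_components(
            n1, g1.sum() / (2 * n1), (g1 == 1).mean(),
            n2, g2.sum() / (2 * n2), (g2 == 1).mean(),
        )
        assert (a, b, c) == pytest.approx(exp, abs=1e-12)

    def test_window_ratio_of_sums_not_mean_of_ratios(self):
        calls = np.asarray([[0, 1, 2, 1], [0, 0, 2, 2]], dtype=np.int8)
        mat = _mat(calls)
        w = Window("c", 0, 10)
        a1_, b1_, c1_ = wc_fst_site(calls[:1], IDX1, IDX2)
        a2_, b2_, c2_ = wc_fst_site(calls[1:], IDX1, IDX2)
        expected = (a1_ + a2_) / (a1_ + b1_ + c1_ + a2_ + b2_ + c2_)
        got = window_fst(mat, w, IDX1, IDX2)
        assert got == pytest.approx(expected)
        mean_of_ratios = np.mean(
            [a1_ / (a1_ + b1_ + c1_), a2_ / (a2_ + b2_ + c2_)]
        )
        assert got != pytest.approx(mean_of_ratios)

    def test_single_site_window_reduces_to_site_estimate(self):
        calls = np.asarray([[0, 1, 2, 1]], dtype=np.int8)
        a, b, c = wc_fst_site(calls, IDX1, IDX2)
        assert window_fst(_mat(calls), Window("c", 0, 10), IDX1, IDX2) == (
            pytest.approx(a / (a + b + c))
        )

    def test_all_fixed_windows_give_one(self):
        calls = np.asarray([[0, 0, 2, 2]] * 3, dtype=np.int8)
        assert window_fst(_mat(calls), Window("c", 0, 10), IDX1, IDX2) == (
            pytest.approx(1.0)
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_invariances(self, seed):
        rng = np.random.default_rng(seed)
        calls = rng.integers(0, 3, size=(30, 8)).astype(np.int8)
        i1, i2 = np.arange(4), np.arange(4, 8)

        def wfst(c, a_idx, b_idx):
            a, b, cc, _ = wc_fst_components(c, a_idx, b_idx)
            return fst_from_components(a, b, cc)

        base = wfst(calls, i1, i2)
        assert wfst(calls, i2, i1) == pytest.approx(base)  # label swap
        assert wfst(2 - calls, i1, i2) == pytest.approx(base)  # ref<->alt
        perm = rng.permutation(30)
        assert wfst(calls[perm], i1, i2) == pytest.approx(base)  # site order

    def test_all_missing_group_site_undefined(self):
        a, b, c = wc_fst_site(np.asarray([[-1, -1, 1, 1]]), IDX1, IDX2)
        assert math.isnan(a)


class TestRod:
    def test_printed_pi_values(self):
        assert rod(2.5e-4, 5.0e-4) == pytest.approx(0.5)

    def test_equal_diversity_zero(self):
        assert rod(3e-4, 3e-4) == 0.0

    def test_total_loss_is_one(self):
        assert rod(0.0, 5e-4) == 1.0

    def test_zero_denominator_undefined(self):
        assert math.isnan(rod(1e-4, 0.0))

    @pytest.mark.parametrize("x,y", [(1.0, 2.0), (0.3, 0.1), (5e-4, 2e-4)])
    def test_complement_identity(self, x, y):
        assert rod(x, y) + x / y == pytest.approx(1.0)


class TestWindowedStats:
    def test_two_group_columns_and_consistency(self, tiny_matrix):
        from walnutkit.io_windows import tile_windows

        ws = tile_windows({"Chr1": 300_000}, 100_000)
        df = windowed_stats(tiny_matrix, ws, "popA", "popB")
        for col in ("pi", "S", "tajima_d", "g1_pi", "g2_pi", "fst", "rod"):
            assert col in df.columns
        assert df["n_snps"].sum() == tiny_matrix.n_sites
        # ROD column is exactly 1 - pi1/pi2 where defined
        ok = df["g2_pi"] > 0
        np.testing.assert_allclose(
            df.loc[ok, "rod"], 1 - df.loc[ok, "g1_pi"] / df.loc[ok, "g2_pi"]
        )
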