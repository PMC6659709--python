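import numpy as np
import pytest

from mtpopgen.core import MISSING
from mtpopgen.differentiation import (
    classical_mds,
    pca_mds,
    tajima_constants,
    tajima_d_from_counts,
    tajimas_d,
    weighted_fst,
)
from .conftest import make_gm, make_table


def wc_haploid_oracle(calls, idx_a, idx_b):
    """Independent transcription of the WC84 two-population haploid
    variance components, looped site by site and allele by allele."""
    num = den = 0.0
    for row in calls:
        a_calls = [row[j] for j in idx_a if row[j] != MISSING]
        b_calls = [row[j] for j in idx_b if row[j] != MISSING]
        n1, n2 = len(a_calls), len(b_calls)
        if n1 < 2 or n2 < 2:
            continue
        alleles = sorted(set(a_calls) | set(b_calls))
        if len(alleles) < 2:
            continue
        for al in alleles:
            p1 = a_calls.count(al) / n1
            p2 = b_calls.count(al) / n2
            r = 2
            nbar = (n1 + n2) / 2
            nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
            pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
            s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r)
            num += a
            den += a + b
    return num / den if den else float("nan")


def two_group_table(n_a, n_b):
    labels = {}
    for j in range(n_a):
        labels[f"s{j}"] = "indica"
    for j in range(n_a, n_a + n_b):
        labels[f"s{j}"] = "wild_rufipogon"
    return make_table(labels)


class TestWeightedFst:
    def test_fixed_difference_gives_one(self):
        calls = np.array([[0, 0, 0, 1, 1, 1]] * 5, dtype=np.int16)
        gm = make_gm(calls, positions=list(range(10, 60, 10)))
        st = two_group_table(3, 3)
        assert weighted_fst(gm, st, "indica", "wild").fst == pytest.approx(1.0)

    def test_matches_oracle_on_random_matrices(self, rng):
        for _ in range(30):
            calls = rng.choice(
                [0, 1, 2, MISSING], p=[0.5, 0.3, 0.08, 0.12], size=(25, 12)
            ).astype(np.int16)
            gm = make_gm(
                calls, positions=list(range(10, 260, 10)), alts=[("G", "T")] * 25
            )
            st = two_group_table(6, 6)
            mine = weighted_fst(gm, st, "indica", "wild").fst
            oracle = wc_haploid_oracle(calls, list(range(6)), list(range(6, 12)))
            if np.isnan(oracle):
                assert np.isnan(mine)
            else:
                assert mine == pytest.approx(oracle, abs=1e-10)

    def test_panmictic_pool_near_zero(self, rng):
        # both groups drawn from one allele-frequency pool
        vals = []
        for _ in range(20):
            p = rng.uniform(0.1, 0.9, size=200)
            calls = (rng.random((200, 100)) < p[:, None]).astype(np.int16)
            gm = make_gm(calls, positions=list(range(10, 2010, 10)))
            st = two_group_table(50, 50)
            vals.append(weighted_fst(gm, st, "indica", "wild").fst)
        assert abs(np.mean(vals)) < 0.02

    def test_empty_group_rejected(self, toy_gm):
        st = make_table({"s0": "indica"})
        with pytest.raises(ValueError):
            weighted_fst(toy_gm, st, "indica", "wild")


class TestTajima:
    def test_constants_a1_is_harmonic_sum(self):
        for n in (4, 10, 25):
            c = tajima_constants(n)
            assert c["a1"] == pytest.approx(sum(1 / i for i in range(1, n)))

    def test_zero_when_pi_equals_watterson(self):
        # n=4, a1=11/6; 3 sites with counts {2,2} and 8 with {1,3}:
        # pi_hat = 3*(2/3) + 8*(1/2) = 6 = S/a1 = 11/(11/6)
        calls = np.array(
            [[0, 0, 1, 1]] * 3 + [[1, 0, 0, 0]] * 8, dtype=np.int16
        )
        gm = make_gm(calls, positions=list(range(10, 120, 10)),
                     reference_length=200)
        st = make_table({s: "wild_rufipogon" for s in gm.samples})
        (w,) = tajimas_d(gm, st, "wild", 200, 200)
        assert w.S == 11
        assert w.tajima_d == pytest.approx(0.0, abs=1e-12)

    def test_na_when_no_segregating_sites(self):
        assert tajima_d_from_counts(0.0, 0, 10) is None
        assert tajima_d_from_counts(1.0, 2, 3) is None  # n < 4

    def test_formula_matches_direct_transcription(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 15))
            S = int(rng.integers(1, 40))
            pi_hat = float(rng.uniform(0, S))
            d = tajima_d_from_counts(pi_hat, S, n)
            i = np.arange(1, n)
            a1 = (1 / i).sum()
            a2 = (1 / i**2).sum()
            b1 = (n + 1) / (3 * (n - 1))
            b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
            c1 = b1 - 1 / a1
            c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
            e1, e2 = c1 / a1, c2 / (a1**2 + a2)
            expected = (pi_hat - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))
            assert d == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_allele_relabel(self):
        calls = np.array([[0, 1, 1, 0, 1]] * 4, dtype=np.int16)
        gm = make_gm(calls, positions=list(range(10, 50, 10)), reference_length=100)
        st = make_table({s: "indica" for s in gm.samples})
        d1 = tajimas_d(gm, st, "indica", 100, 100)[0].tajima_d
        gm2 = make_gm((1 - calls).astype(np.int16),
                      positions=list(range(10, 50, 10)), reference_length=100)
        d2 = tajimas_d(gm2, st, "indica", 100, 100)[0].tajima_d
        assert d1 == pytest.approx(d2)

    def test_sites_with_missing_calls_dropped(self):
        calls = np.array([[0, 1, 1, 1], [0, MISSING, 1, 1]], dtype=np.int16)
        gm = make_gm(calls, positions=[10, 20], reference_length=100)
        st = make_table({s: "indica" for s in gm.samples})
        (w,) = tajimas_d(gm, st, "indica", 100, 100)
        assert w.S == 1


class TestPcaMds:
    def test_identical_samples_zero_variance(self):
        calls = np.tile(np.array([[1], [0], [1]], dtype=np.int16), (1, 5))
        gm = make_gm(calls, positions=[10, 20, 30])
        st = make_table({s: "indica" for s in gm.samples})
        res = pca_mds(gm, st)
        assert np.allclose(res["pcs"], 0)
        assert np.allclose(res["mds"], 0)

    def test_diverged_groups_separate_on_pc1(self, rng):
        block_a = np.zeros((30, 8), dtype=np.int16)
        block_b = np.ones((30, 8), dtype=np.int16)
        noise = rng.choice([0, 1], size=(30, 16), p=[0.9, 0.1]).astype(np.int16)
        calls = np.hstack([block_a, block_b]) ^ noise
        gm = make_gm(calls, positions=list(range(10, 310, 10)))
        st = make_table(
            {f"s{j}": ("indica" if j < 8 else "temperate_japonica") for j in range(16)}
        )
        res = pca_mds(gm, st)
        pc1 = res["pcs"][:, 0]
        assert (pc1[:8].max() < pc1[8:].min()) or (pc1[:8].min() > pc1[8:].max())

    def test_too_few_samples_rejected(self):
        gm = make_gm([[0, 1]], positions=[10])
        st = make_table({"s0": "indica", "s1": "indica"})
        with pytest.raises(ValueError):
            pca_mds(gm, st)

    def test_mds_recovers_euclidean_configuration(self, rng):
        X = rng.normal(size=(10, 3))
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        Y = classical_mds(D, 3)
        D2 = np.sqrt(((Y[:, None, :] - Y[None, :, :]) ** 2).sum(-1))
        assert np.allclose(D, D2, atol=1e-8)
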