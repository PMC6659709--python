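from itertools import permutations

import numpy as np
import pytest
from Bio.Data import CodonTable

from mtpopgen.dnds import gene_screen, nei_gojobori

BASES = "ACGT"


def oracle_ng86(seq_a, seq_b, table_id=1):
    """Independent brute-force NG86 transcription (fresh code path)."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    aa = dict(table.forward_table)
    for s in table.stop_codons:
        aa[s] = "*"

    def sites(codon):
        syn = 0.0
        for pos in range(3):
            for b in BASES:
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1:]
                if aa[mut] == aa[codon] and aa[codon] != "*":
                    syn += 1 / 3
        return syn

    S = N = sd = nd = 0.0
    for i in range(len(seq_a) // 3):
        ca, cb = seq_a[3 * i:3 * i + 3], seq_b[3 * i:3 * i + 3]
        S += (sites(ca) + sites(cb)) / 2
        N += 3 - (sites(ca) + sites(cb)) / 2
        diffs = [p for p in range(3) if ca[p] != cb[p]]
        if not diffs:
            continue
        path_counts = []
        for order in permutations(diffs):
            cur, s_steps, n_steps, blocked = ca, 0, 0, False
            for p in order:
                nxt = cur[:p] + cb[p] + cur[p + 1:]
                if aa[nxt] == "*" and nxt != cb:
                    blocked = True
                s_steps += aa[nxt] == aa[cur]
                n_steps += aa[nxt] != aa[cur]
                cur = nxt
            path_counts.append((s_steps, n_steps, blocked))
        ok = [p for p in path_counts if not p[2]] or path_counts
        sd += sum(p[0] for p in ok) / len(ok)
        nd += sum(p[1] for p in ok) / len(ok)
    ps, pn = sd / S, nd / N
    def jc(p):
        return None if p >= 0.75 else -0.75 * np.log(1 - 4 * p / 3)
    return jc(pn), jc(ps), S, N, sd, nd


def random_codon(rng, code):
    while True:
        c = "".join(rng.choice(list(BASES), 3))
        if code.get(c, "*") != "*":
            return c


@pytest.fixture
def standard_code():
    table = CodonTable.unambiguous_dna_by_id[1]
    code = dict(table.forward_table)
    for s in table.stop_codons:
        code[s] = "*"
    return code


class TestNeiGojobori:
    def test_identical_sequences(self):
        res = nei_gojobori("ATGAAA", "ATGAAA")
        assert res.dn == 0 and res.ds == 0
        assert res.omega is None and res.note == "identical"

    def test_single_synonymous_third_position_change(self):
        a = "GGT" * 10
        b = "GGC" + "GGT" * 9  # GGT->GGC: glycine either way
        res = nei_gojobori(a, b)
        dn_o, ds_o, S, N, sd, nd = oracle_ng86(a, b)
        assert res.dn == 0
        assert res.ds == pytest.approx(ds_o, abs=1e-12)
        assert res.ds > 0
        assert res.sd == pytest.approx(1.0)

    def test_nonsynonymous_only_flagged(self):
        a = "ATG" + "GGT" * 9
        b = "ATG" + "GGT" * 8 + "TGT"  # GGT->TGT: Gly->Cys, nonsyn only? (G->T at pos1)
        res = nei_gojobori(a, b)
        assert res.ds == 0 and res.omega is None
        assert res.note == "nonsyn-only"

    def test_site_counts_partition_exactly(self, rng, standard_code):
        for _ in range(20):
            n_codon = int(rng.integers(2, 12))
            a = "".join(random_codon(rng, standard_code) for _ in range(n_codon))
            b = "".join(random_codon(rng, standard_code) for _ in range(n_codon))
            res = nei_gojobori(a, b)
            assert res.S + res.N == pytest.approx(3 * n_codon, abs=1e-10)

    def test_symmetric_in_arguments(self, rng, standard_code):
        for _ in range(20):
            a = "".join(random_codon(rng, standard_code) for _ in range(8))
            b = "".join(random_codon(rng, standard_code) for _ in range(8))
            r1, r2 = nei_gojobori(a, b), nei_gojobori(b, a)
            assert r1.sd == pytest.approx(r2.sd, abs=1e-12)
            assert r1.nd == pytest.approx(r2.nd, abs=1e-12)

    def test_matches_independent_oracle(self, rng, standard_code):
        for _ in range(60):
            n_codon = int(rng.integers(4, 15))
            a = "".join(random_codon(rng, standard_code) for _ in range(n_codon))
            b = "".join(random_codon(rng, standard_code) for _ in range(n_codon))
            res = nei_gojobori(a, b)
            dn_o, ds_o, S, N, sd, nd = oracle_ng86(a, b)
            assert res.S == pytest.approx(S, abs=1e-10)
            assert res.sd == pytest.approx(sd, abs=1e-10)
            assert res.nd == pytest.approx(nd, abs=1e-10)
            if ds_o is not None and dn_o is not None:
                assert res.ds == pytest.approx(ds_o, abs=1e-10)
                assert res.dn == pytest.approx(dn_o, abs=1e-10)

    def test_internal_stop_rejected_terminal_trimmed(self):
        with pytest.raises(ValueError, match="stop"):
            nei_gojobori("TAAATG", "TAAATG")
        res = nei_gojobori("ATGTAA", "ATGTAA")  # shared terminal stop dropped
        assert res.S + res.N == pytest.approx(3.0)

    def test_gap_codons_dropped_pairwise(self):
        res = nei_gojobori("ATG---AAA", "ATGGGTAAA")
        assert res.S + res.N == pytest.approx(6.0)

    def test_length_validation(self):
        with pytest.raises(ValueError):
            nei_gojobori("ATGA", "ATGA")
        with pytest.raises(ValueError):
            nei_gojobori("ATG", "ATGATG")


class TestGeneScreen:
    def test_conserved_gene_not_flagged(self):
        aln = {"g1": [("fg", "ATGGGT" * 5), ("bg", "ATGGGC" * 5)]}
        df = gene_screen(aln, foreground={"fg"})
        assert not df["positive"].iloc[0]

    def test_omega_outlier_removed(self):
        # nonsynonymous-heavy pair with one synonymous change so omega is
        # defined and large -> filtered when above cutoff
        a = "ATG" + "GGT" * 6
        b = "ATG" + "CAT" * 5 + "GGC"
        res = nei_gojobori(a, b)
        assert res.omega is not None
        aln = {"g1": [("fg", a), ("bg", b)]}
        kept = gene_screen(aln, foreground={"fg"}, omega_outlier=res.omega - 0.01)
        assert kept.empty

    def test_nonsynonymous_excess_flagged_positive(self):
        # one synonymous and several nonsynonymous differences
        a = "ATG" + "GGT" * 4 + "AAA" * 4
        b = "ATG" + "GGC" + "GGT" * 3 + "GAC" * 4
        aln = {"g1": [("fg", a), ("x", a), ("bg", b)]}
        df = gene_screen(aln, foreground={"fg", "x"}, omega_outlier=50)
        assert df["positive"].iloc[0]

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            gene_screen({"g": [("a", "ATG")]}, foreground={"a"})
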