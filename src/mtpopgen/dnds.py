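"""Counting-method (Nei-Gojobori 1986) dN/dS for codon-aligned sequences.

Synonymous/nonsynonymous site fractions are computed per codon over all
single-nucleotide changes (changes creating stop codons count as
nonsynonymous, keeping S + N = 3 x codons exactly); observed differences
are classified by averaging over all minimal mutational pathways between
the two codons, excluding pathways through stop codons unless every
pathway is blocked.  Proportions are Jukes-Cantor corrected:
``d = -(3/4) ln(1 - 4p/3)``, and ``omega = dN/dS``.

Plant mitochondria use the standard genetic code, which is the default;
any NCBI translation table id can be supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

BASES = "ACGT"


def _code(table_id: int) -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


@dataclass
class PairwiseDnDs:
    dn: float | None
    ds: float | None
    omega: float | None
    S: float
    N: float
    sd: float
    nd: float
    note: str = ""


def _codon_sites(codon: str, code: dict[str, str]) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site fractions of one codon."""
    aa = code[codon]
    syn = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if code[alt] == aa and aa != "*":
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _pathway_counts(c1: str, c2: str, code: dict[str, str]):
    """Mean (syn, nonsyn) difference counts over minimal mutational pathways."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in permutations(diffs):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if code[nxt] == "*" and nxt != c2:
                blocked = True
            if code[nxt] == code[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, blocked))
    open_paths = [p for p in paths if not p[2]]
    use = open_paths if open_paths else paths
    sd = float(np.mean([p[0] for p in use]))
    nd = float(np.mean([p[1] for p in use]))
    return sd, nd


def _jc(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * float(np.log(1.0 - 4.0 * p / 3.0))


def nei_gojobori(seq_a: str, seq_b: str, table_id: int = 1) -> PairwiseDnDs:
    """NG86 dN, dS and omega for one codon-aligned sequence pair.

    Sequences must have equal length divisible by three.  Codon pairs with
    gaps or ambiguous bases are dropped pairwise; a terminal stop codon
    shared by both sequences is trimmed, any other stop raises.  ``omega``
    is ``None`` when ``dS = 0`` (flagged in ``note``).
    """
    a, b = seq_a.upper(), seq_b.upper()
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    if len(a) % 3:
        raise ValueError("length not divisible by 3")
    code = _code(table_id)
    codons = []
    n_codons = len(a) // 3
    for i in range(n_codons):
        ca, cb = a[3 * i : 3 * i + 3], b[3 * i : 3 * i + 3]
        if any(ch not in BASES for ch in ca + cb):
            continue  # gap or ambiguity: drop column pairwise
        if code[ca] == "*" or code[cb] == "*":
            if i == n_codons - 1:
                continue  # shared terminal stop
            raise ValueError(f"internal stop codon at codon {i + 1}")
        codons.append((ca, cb))
    S = N = sd = nd = 0.0
    for ca, cb in codons:
        sa, na = _codon_sites(ca, code)
        sb, nb = _codon_sites(cb, code)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        d_s, d_n = _pathway_counts(ca, cb, code)
        sd += d_s
        nd += d_n
    note = ""
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    ds = _jc(ps)
    dn = _jc(pn)
    if ds is None or dn is None:
        return PairwiseDnDs(dn, ds, None, S, N, sd, nd, "p >= 3/4: JC undefined")
    if ds == 0.0:
        note = "nonsyn-only" if dn > 0 else "identical"
        return PairwiseDnDs(dn, ds, None, S, N, sd, nd, note)
    return PairwiseDnDs(dn, ds, dn / ds, S, N, sd, nd, note)


def gene_screen(
    alignments: dict,
    foreground: set[str] | list[str],
    omega_outlier: float = 5.0,
    table_id: int = 1,
) -> pd.DataFrame:
    """Mean foreground-vs-background pairwise omega per gene.

    ``alignments`` maps gene id to a list of ``(label, codon_sequence)``;
    labels in ``foreground`` are the focal sequences, the rest background.
    Genes whose mean omega exceeds ``omega_outlier`` are removed as
    outliers; genes with mean omega > 1 are flagged ``positive``.
    """
    foreground = set(foreground)
    rows = []
    for gene, seqs in alignments.items():
        fg = [(l, s) for l, s in seqs if l in foreground]
        bg = [(l, s) for l, s in seqs if l not in foreground]
        if len(seqs) < 2:
            raise ValueError(f"gene {gene}: need at least two sequences")
        pairs = (
            [(fa, ba) for fa in fg for ba in bg]
            if fg and bg
            else [(x, y) for i, x in enumerate(seqs) for y in seqs[i + 1 :]]
        )
        omegas = []
        for (_, sa), (_, sb) in pairs:
            res = nei_gojobori(sa, sb, table_id)
            if res.omega is not None:
                omegas.append(res.omega)
        mean_omega = float(np.mean(omegas)) if omegas else float("nan")
        rows.append(
            {
                "gene": gene,
                "n_pairs": len(pairs),
                "n_informative": len(omegas),
                "omega": mean_omega,
                "positive": bool(mean_omega > 1.0) if omegas else False,
            }
        )
    df = pd.DataFrame(rows)
    return df[~(df["omega"] > omega_outlier)].reset_index(drop=True)
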