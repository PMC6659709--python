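"""Introgression check via group-diagnostic alleles and accession painting.

If two groups exchanged migrants since their split, accessions should carry
runs of the other group's diagnostic (near-fixed) alleles.  The procedure:
find alleles near fixation in a focal group and near absence in a background
group, call each accession's allele at every diagnostic locus, and measure
maximal runs of other-group calls as candidate introgressed fragments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MISSING, GenotypeMatrix, SampleTable


@dataclass
class SpecificAlleleSet:
    """Alleles diagnostic for ``focal`` against ``background``.

    ``loci`` holds ``(variant_index, allele_index, freq_focal, freq_background)``
    tuples, position-sorted.
    """

    focal: str
    background: str
    hi: float
    lo: float
    loci: list = field(default_factory=list)


@dataclass
class Fragment:
    start_bp: int
    end_bp: int
    n_loci: int

    @property
    def length(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class Painting:
    accession: str
    own_group: str
    calls: list            # (variant_index, group_or_None)
    fragments: list[Fragment]
    proportion: float      # sum fragment bp / reference_length; NaN if no loci


def find_specific_alleles(
    gm: GenotypeMatrix,
    st: SampleTable,
    focal: str,
    background: str,
    hi: float = 0.95,
    lo: float = 0.05,
    min_calls: int = 5,
) -> SpecificAlleleSet:
    """Alleles with frequency > ``hi`` in focal and < ``lo`` in background.

    Inequalities are strict; sites need at least ``min_calls`` non-missing
    calls in each group.  Swapping the roles yields a disjoint set in
    (variant, allele) whenever ``hi > lo``.
    """
    if focal == background:
        raise ValueError("focal and background groups must differ")
    fi = st.indices(gm, focal)
    bi = st.indices(gm, background)
    cf, nf = gm.allele_counts(fi)
    cb, nb = gm.allele_counts(bi)
    ok = (nf >= min_calls) & (nb >= min_calls)
    out = SpecificAlleleSet(focal, background, hi, lo)
    loci = []
    for i in np.flatnonzero(ok):
        for a in range(gm.variants[i].n_alleles):
            ff = cf[i, a] / nf[i]
            fb = cb[i, a] / nb[i]
            if ff > hi and fb < lo:
                loci.append((i, a, float(ff), float(fb)))
    loci.sort(key=lambda t: gm.variants[t[0]].pos)
    out.loci = loci
    return out


def paint_accessions(
    gm: GenotypeMatrix,
    st: SampleTable,
    set_a: SpecificAlleleSet,
    set_b: SpecificAlleleSet,
    min_run: int = 2,
    gap_policy: str = "skip",
) -> list[Painting]:
    """Per-accession painting over the union of two diagnostic-allele sets.

    ``set_a`` and ``set_b`` must be the two directions of one group pair
    (focal of one = background of the other).  At each informative locus an
    accession is called for the group whose diagnostic allele it carries
    (or neither / missing).  For members of the pair's groups, runs of at
    least ``min_run`` consecutive other-group calls become fragments whose
    bp extent runs midpoint-to-midpoint between flanking informative loci
    (edge loci extend by half the median inter-locus spacing).

    ``gap_policy="skip"`` (default): missing/neither calls do not break a
    run; ``"break"``: they do.
    """
    pair = {set_a.focal, set_a.background}
    if pair != {set_b.focal, set_b.background}:
        raise ValueError("sets are not the two directions of one group pair")
    diag: dict[tuple[int, int], str] = {}
    for i, a, *_ in set_a.loci:
        diag[(i, a)] = set_a.focal
    for i, a, *_ in set_b.loci:
        diag[(i, a)] = set_b.focal
    locus_ids = sorted({i for i, _ in diag}, key=lambda i: gm.variants[i].pos)
    group_members = {g: set(st.members(g)) for g in pair}
    paintings = []
    pos = np.array([gm.variants[i].pos for i in locus_ids], dtype=float)
    if len(pos) >= 2:
        half_med = float(np.median(np.diff(pos))) / 2.0
    else:
        half_med = 0.0
    mids = (pos[:-1] + pos[1:]) / 2.0 if len(pos) >= 2 else np.array([])
    left_edge = np.concatenate([[pos[0] - half_med], mids]) if len(pos) else pos
    right_edge = np.concatenate([mids, [pos[-1] + half_med]]) if len(pos) else pos
    for j, acc in enumerate(gm.samples):
        own = next((g for g in pair if acc in group_members[g]), None)
        if own is None:
            continue
        other = next(g for g in pair if g != own)
        calls = []
        for i in locus_ids:
            c = gm.calls[i, j]
            if c == MISSING:
                calls.append((i, None))
            else:
                calls.append((i, diag.get((i, int(c)))))
        fragments = _fragments(calls, other, min_run, gap_policy,
                               locus_ids, left_edge, right_edge)
        if not locus_ids:
            prop = float("nan")
        else:
            prop = sum(f.length for f in fragments) / gm.reference_length
        paintings.append(Painting(acc, own, calls, fragments, prop))
    return paintings


def _fragments(calls, other, min_run, gap_policy, locus_ids, left_edge, right_edge):
    index_of = {i: k for k, i in enumerate(locus_ids)}
    runs = []
    current: list[int] = []
    for i, g in calls:
        if g == other:
            current.append(i)
        elif g is None and gap_policy == "skip":
            continue
        else:
            if len(current) >= min_run:
                runs.append(current)
            current = []
    if len(current) >= min_run:
        runs.append(current)
    out = []
    for run in runs:
        k0, k1 = index_of[run[0]], index_of[run[-1]]
        out.append(
            Fragment(int(round(left_edge[k0])), int(round(right_edge[k1])), len(run))
        )
    return out
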