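"""Nucleotide diversity (pi) in sliding windows and genome-wide.

Site diversity for a haploid sample of size ``n`` with allele counts
``c_1..c_k`` is the mean pairwise difference

    pi_site = sum_{i<j} c_i c_j / C(n, 2) = 1 - sum_i c_i (c_i - 1) / (n (n - 1)),

computed pairwise-complete: ``n`` is the number of non-missing calls at
that site within the group.  Window pi divides the summed site values by
the full window length in bp (monomorphic positions count as invariant),
the convention of VCF-based window-diversity tools.  InDels contribute as
single segregating events at their anchor position.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .core import MISSING, GenotypeMatrix, SampleTable, WindowStat, windows_tiling


def site_pi(gm: GenotypeMatrix, sample_idx: np.ndarray) -> np.ndarray:
    """Per-site mean pairwise difference within a sample subset.

    Sites with fewer than two non-missing calls return 0 (no pair to
    compare; they carry no diversity signal either way).
    """
    counts, n = gm.allele_counts(sample_idx)
    num = (counts * (counts - 1)).sum(axis=1).astype(float)
    denom = (n * (n - 1)).astype(float)
    out = np.zeros(gm.n_variants, dtype=float)
    ok = n >= 2
    out[ok] = 1.0 - num[ok] / denom[ok]
    return out


def _segregating(gm: GenotypeMatrix, sample_idx: np.ndarray) -> np.ndarray:
    counts, _ = gm.allele_counts(sample_idx)
    return (counts > 0).sum(axis=1) >= 2


def _class_mask(gm: GenotypeMatrix, variant_classes: str) -> np.ndarray:
    if variant_classes == "SNP":
        return gm.is_snp
    if variant_classes == "SNP+InDel":
        return np.ones(gm.n_variants, dtype=bool)
    raise ValueError("variant_classes must be 'SNP' or 'SNP+InDel'")


def window_pi(
    gm: GenotypeMatrix,
    st: SampleTable,
    group: str,
    window: int = 1000,
    step: int = 500,
    variant_classes: str = "SNP+InDel",
) -> list[WindowStat]:
    """Sliding-window per-bp nucleotide diversity for one group.

    Windows tile ``[0, reference_length)`` half-open with the given step;
    the final partial window is normalized by its true length.  A group
    with fewer than two samples yields all-NaN windows.
    """
    idx = st.indices(gm, group)
    if len(idx) == 0:
        raise ValueError(f"group {group!r} is empty")
    keep = _class_mask(gm, variant_classes)
    sub = gm.take_variants(keep)
    pis = site_pi(sub, idx)
    seg = _segregating(sub, idx)
    pos0 = sub.positions - 1
    order = np.argsort(pos0, kind="stable")
    pos0 = pos0[order]
    pis = pis[order]
    seg = seg[order]
    cum_pi = np.concatenate([[0.0], np.cumsum(pis)])
    cum_s = np.concatenate([[0], np.cumsum(seg.astype(np.int64))])
    degenerate = len(idx) < 2
    out = []
    for start, end in windows_tiling(gm.reference_length, window, step):
        lo = np.searchsorted(pos0, start, side="left")
        hi = np.searchsorted(pos0, end, side="left")
        s = int(cum_s[hi] - cum_s[lo])
        pi = float(cum_pi[hi] - cum_pi[lo]) / (end - start)
        if degenerate:
            s, pi = 0, float("nan")
        out.append(WindowStat(start, end, group, len(idx), s, pi))
    return out


def group_pi(
    gm: GenotypeMatrix,
    st: SampleTable,
    group: str,
    variant_classes: str = "SNP+InDel",
) -> float:
    """Genome-wide per-site mean pi for a group (single full-length window)."""
    stats_ = window_pi(
        gm, st, group,
        window=gm.reference_length, step=gm.reference_length,
        variant_classes=variant_classes,
    )
    return stats_[0].pi


def compare_group_diversity(windows_a, windows_b):
    """Welch two-sample t-test on window pi values of two groups.

    Returns ``(t, df, p)``; identical vectors give t = 0, p = 1.  NaN
    windows are dropped; fewer than two usable windows per group is an
    error.
    """
    a = np.array([w.pi for w in windows_a], dtype=float)
    b = np.array([w.pi for w in windows_b], dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two non-NA windows per group")
    res = stats.ttest_ind(a, b, equal_var=False)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        return 0.0, float(len(a) + len(b) - 2), 1.0
    return float(res.statistic), float(res.df), float(res.pvalue)


def windows_to_frame(windows: list[WindowStat]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "start": w.start,
                "end": w.end,
                "group": w.group,
                "n_used": w.n_used,
                "S": w.S,
                "pi": w.pi,
                "tajima_d": w.tajima_d,
                **w.extras,
            }
            for w in windows
        ]
    )
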