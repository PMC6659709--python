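"""Population differentiation: Weir-Cockerham F_ST, Tajima's D, PCA/MDS.

The F_ST estimator is the Weir & Cockerham (1984) variance-component
estimator adapted to haploid calls: each call is a single allele draw, so
the within-individual heterozygosity component is identically zero and the
estimator reduces to the between-population component ``a`` over ``a + b``
(among-individuals-within-population).  The genome-wide value is the
ratio-of-sums ("weighted") combination across sites and alleles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MISSING, GenotypeMatrix, SampleTable, WindowStat, windows_tiling


@dataclass
class FstResult:
    group_a: str
    group_b: str
    fst: float
    site_a: np.ndarray      # per-site between-population variance component
    site_ab: np.ndarray     # per-site total (a + b)
    site_index: np.ndarray  # variant indices of contributing sites


def _wc_components(n1, n2, c1, c2):
    """Per-allele WC84 haploid variance components for two populations.

    Parameters are scalars or arrays: sample sizes ``n1, n2`` (non-missing
    haploid calls) and allele counts ``c1, c2`` for one allele.
    Returns ``(a, b)``.
    """
    r = 2.0
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    p1 = c1 / n1
    p2 = c2 / n2
    nbar = (n1 + n2) / r
    nsum = n1 + n2
    nc = (nsum - (n1**2 + n2**2) / nsum) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / nsum
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    # haploid: h_bar = 0, so the diploid formulas lose their h terms
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r) / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - s2 * (r - 1.0) / r)
    return a, b


def weighted_fst(
    gm: GenotypeMatrix,
    st: SampleTable,
    group_a: str,
    group_b: str,
) -> FstResult:
    """Weighted (ratio-of-sums) Weir-Cockerham F_ST between two groups.

    Sites contribute when both groups have at least two non-missing calls
    and the pooled sample is polymorphic; multiallelic sites contribute one
    component pair per allele.  Per-site values may be negative and are
    kept as computed; only the genome-wide ratio is clamped by nothing.
    """
    ia = st.indices(gm, group_a)
    ib = st.indices(gm, group_b)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("empty group")
    ca, na = gm.allele_counts(ia)
    cb, nb = gm.allele_counts(ib)
    pooled = ca + cb
    poly = (pooled > 0).sum(axis=1) >= 2
    usable = (na >= 2) & (nb >= 2) & poly
    idx = np.flatnonzero(usable)
    if len(idx) == 0:
        return FstResult(group_a, group_b, float("nan"),
                         np.array([]), np.array([]), idx)
    a_site = np.zeros(len(idx))
    ab_site = np.zeros(len(idx))
    for k, i in enumerate(idx):
        alleles = np.flatnonzero(pooled[i] > 0)
        a_sum = b_sum = 0.0
        for al in alleles:
            a_c, b_c = _wc_components(na[i], nb[i], ca[i, al], cb[i, al])
            a_sum += a_c
            b_sum += b_c
        a_site[k] = a_sum
        ab_site[k] = a_sum + b_sum
    denom = ab_site.sum()
    fst = a_site.sum() / denom if denom != 0 else float("nan")
    return FstResult(group_a, group_b, float(fst), a_site, ab_site, idx)


def windowed_fst(
    gm: GenotypeMatrix,
    st: SampleTable,
    group_a: str,
    group_b: str,
    window: int = 1000,
    step: int = 500,
) -> list[WindowStat]:
    """Per-window ratio-of-sums F_ST on the diversity module's windows."""
    res = weighted_fst(gm, st, group_a, group_b)
    pos0 = gm.positions[res.site_index] - 1
    order = np.argsort(pos0, kind="stable")
    pos0 = pos0[order]
    a = res.site_a[order]
    ab = res.site_ab[order]
    cum_a = np.concatenate([[0.0], np.cumsum(a)])
    cum_ab = np.concatenate([[0.0], np.cumsum(ab)])
    out = []
    for start, end in windows_tiling(gm.reference_length, window, step):
        lo = np.searchsorted(pos0, start, side="left")
        hi = np.searchsorted(pos0, end, side="left")
        denom = cum_ab[hi] - cum_ab[lo]
        fst = (cum_a[hi] - cum_a[lo]) / denom if denom != 0 else float("nan")
        w = WindowStat(start, end, f"{group_a}|{group_b}", 0, hi - lo, float("nan"))
        w.extras["fst"] = float(fst)
        out.append(w)
    return out


# -- Tajima's D --------------------------------------------------------------


def tajima_constants(n: int) -> dict:
    """The standard a1, a2, b1, b2, c1, c2, e1, e2 constants for sample size n."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajima_d_from_counts(pi_hat: float, S: int, n: int) -> float | None:
    """D = (pi_hat - S/a1) / sqrt(e1 S + e2 S (S-1)); NA when undefined.

    ``pi_hat`` is the mean pairwise-difference *count* (summed over sites,
    not per bp).
    """
    if S == 0 or n < 4:
        return None
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    if var <= 0:
        return None
    return float((pi_hat - S / c["a1"]) / np.sqrt(var))


def tajimas_d(
    gm: GenotypeMatrix,
    st: SampleTable,
    group: str,
    window: int = 1000,
    step: int = 500,
) -> list[WindowStat]:
    """Windowed Tajima's D for one group, SNP sites only.

    Sites with any missing call within the group are dropped (the constants
    assume a fixed sample size), so ``n`` is the full group size.
    """
    idx = st.indices(gm, group)
    if len(idx) == 0:
        raise ValueError(f"group {group!r} is empty")
    n = len(idx)
    snp = gm.take_variants(gm.is_snp)
    sub = snp.calls[:, idx]
    complete = (sub != MISSING).all(axis=1)
    snp = snp.take_variants(complete)
    from .diversity import site_pi, _segregating

    pis = site_pi(snp, np.arange(n)) if snp.n_variants else np.array([])
    seg = _segregating(snp, np.arange(n)) if snp.n_variants else np.array([], bool)
    pos0 = snp.positions - 1 if snp.n_variants else np.array([], dtype=np.int64)
    order = np.argsort(pos0, kind="stable")
    pos0, pis, seg = pos0[order], pis[order], seg[order]
    cum_pi = np.concatenate([[0.0], np.cumsum(pis)])
    cum_s = np.concatenate([[0], np.cumsum(seg.astype(np.int64))])
    out = []
    for start, end in windows_tiling(gm.reference_length, window, step):
        lo = np.searchsorted(pos0, start, side="left")
        hi = np.searchsorted(pos0, end, side="left")
        S = int(cum_s[hi] - cum_s[lo])
        pi_hat = float(cum_pi[hi] - cum_pi[lo])
        d = tajima_d_from_counts(pi_hat, S, n)
        out.append(WindowStat(start, end, group, n, S, pi_hat / (end - start), d))
    return out


# -- PCA / MDS ---------------------------------------------------------------


def _dosage_matrix(gm: GenotypeMatrix, sample_idx, max_missing: float):
    """Samples x biallelic-SNP alt-dosage matrix with NaN for missing."""
    snp = gm.take_variants(gm.is_biallelic_snp)
    sub = snp.calls[:, sample_idx].T.astype(float)  # samples x variants
    sub[sub == MISSING] = np.nan
    miss = np.isnan(sub).mean(axis=1)
    keep = miss <= max_missing
    return sub[keep], np.asarray(sample_idx)[keep]


def pca_mds(
    gm: GenotypeMatrix,
    st: SampleTable,
    scope: str = "all",
    n_components: int = 10,
    max_missing: float = 0.5,
):
    """PCA and classical MDS of samples on filtered biallelic SNPs.

    PCA operates on the mean-imputed, frequency-centered dosage matrix; MDS
    is classical (Torgerson) scaling of the pairwise identity-by-state
    mismatch distance matrix.  Returns a dict with sample ids, PC
    coordinates, explained-variance ratios, and MDS coordinates.
    """
    idx = (
        np.arange(gm.n_samples) if scope == "all" else st.indices(gm, scope)
    )
    X, kept = _dosage_matrix(gm, idx, max_missing)
    if X.shape[0] < 3:
        raise ValueError("need at least three samples")
    n_components = min(n_components, X.shape[0] - 1, max(X.shape[1], 1))
    mean = np.nanmean(X, axis=0)
    mean = np.nan_to_num(mean)  # sites missing everywhere impute to 0
    Ximp = np.where(np.isnan(X), mean[None, :], X)
    Xc = Ximp - mean[None, :]
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    pcs = U[:, :n_components] * s[:n_components]
    total_var = (s**2).sum()
    explained = (
        s[:n_components] ** 2 / total_var if total_var > 0 else np.zeros(n_components)
    )
    # identity-by-state mismatch distance over pairwise-complete sites
    nsamp = X.shape[0]
    D = np.zeros((nsamp, nsamp))
    valid = ~np.isnan(X)
    for i in range(nsamp):
        both = valid[i] & valid
        diff = (X[i] != X) & both
        with np.errstate(invalid="ignore"):
            D[i] = diff.sum(axis=1) / both.sum(axis=1)
    np.fill_diagonal(D, 0.0)
    D = np.nan_to_num(D)
    mds = classical_mds(D, n_components)
    return {
        "samples": [gm.samples[j] for j in kept],
        "pcs": pcs,
        "explained": explained,
        "mds": mds,
    }


def classical_mds(D: np.ndarray, n_components: int) -> np.ndarray:
    """Torgerson classical scaling of a distance matrix."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    k = min(n_components, n)
    w = np.clip(w[:k], 0, None)
    return V[:, :k] * np.sqrt(w)
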