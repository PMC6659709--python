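"""Heterozygosity-excess bottleneck test (Cornuet & Luikart style).

After a recent bottleneck, allele number drops faster than gene diversity,
so the observed (unbiased) gene diversity at a locus exceeds the
equilibrium expectation given the surviving allele count.  For each
polymorphic locus the equilibrium distribution of gene diversity ``Heq``
is simulated under the infinite-allele model conditional on the observed
allele count ``k`` and sample size ``n``; a one-tailed Wilcoxon signed-rank
test across loci assesses systematic excess ``He_obs > Heq``.  The
signed-rank is applied to mid-rank probability-integral-transformed
deviations rather than raw ``He_obs - mean(Heq)`` differences: for
low-allele-count loci the equilibrium He distribution is strongly skewed,
which violates the symmetry the signed-rank test assumes and badly
inflates its size; the quantile deviations are symmetric about zero under
the null by construction.

Only the IAM is implemented: the data here are sequence variants, for
which the stepwise (microsatellite) mutation models are inapplicable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .core import GenotypeMatrix, SampleTable


@dataclass
class LocusResult:
    variant_index: int
    k: int
    n: int
    he_obs: float
    heq_mean: float
    heq_sd: float
    dh: float  # standardized (he_obs - heq_mean) / heq_sd
    u_quantile: float = float("nan")  # mid-rank of he_obs in the Heq sample


@dataclass
class BottleneckResult:
    group: str
    loci: list[LocusResult]
    p_excess: float  # one-tailed Wilcoxon p for He_obs > Heq
    n_loci_used: int
    reps: int
    seed: int


def unbiased_gene_diversity(counts: np.ndarray) -> float:
    """He = n/(n-1) (1 - sum p_i^2) from allele counts."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n < 2:
        return float("nan")
    p = counts / n
    return float(n / (n - 1.0) * (1.0 - np.sum(p**2)))


def watterson_theta_for_k(k: int, n: int) -> float:
    """Solve E[k_alleles] = sum_{i=0}^{n-1} theta/(theta+i) = k for theta (Ewens)."""
    if k <= 1:
        return 0.0

    def expected_k(theta):
        i = np.arange(n, dtype=float)
        return float(np.sum(theta / (theta + i)))

    hi = 1.0
    while expected_k(hi) < k and hi < 1e8:
        hi *= 2.0
    return brentq(lambda t: expected_k(t) - k, 1e-12, hi, xtol=1e-10)


def _ewens_samples(theta: float, n: int, n_sims: int, rng) -> np.ndarray:
    """Vectorized Hoppe-urn (Chinese restaurant) sampling under the IAM.

    Returns an array (n_sims, n) of allele labels per simulated sample.
    """
    labels = np.zeros((n_sims, n), dtype=np.int32)
    next_label = np.ones(n_sims, dtype=np.int32)
    for i in range(1, n):
        new = rng.random(n_sims) < theta / (theta + i)
        copy_from = rng.integers(0, i, size=n_sims)
        labels[:, i] = np.where(
            new, next_label, labels[np.arange(n_sims), copy_from]
        )
        next_label += new.astype(np.int32)
    return labels


def equilibrium_he(
    k: int, n: int, reps: int, rng, batch: int | None = None, max_batches: int = 200
) -> np.ndarray:
    """Simulated equilibrium He values conditional on k alleles in n copies.

    Rejection-samples Ewens configurations at the theta matched to E[k]=k
    until ``reps`` acceptances (or the batch budget is exhausted).
    """
    theta = watterson_theta_for_k(k, n)
    batch = batch or max(4 * reps, 200)
    out: list[np.ndarray] = []
    got = 0
    for _ in range(max_batches):
        labels = _ewens_samples(theta, n, batch, rng)
        sort = np.sort(labels, axis=1)
        distinct = 1 + (np.diff(sort, axis=1) > 0).sum(axis=1)
        accept = distinct == k
        if accept.any():
            acc = labels[accept]
            m = acc.shape[0]
            counts = np.zeros((m, n + 1), dtype=np.int64)
            rows = np.repeat(np.arange(m), n)
            np.add.at(counts, (rows, acc.ravel()), 1)
            sumsq = (counts.astype(float) ** 2).sum(axis=1)
            he = n / (n - 1.0) * (1.0 - sumsq / n**2)
            out.append(he)
            got += m
        if got >= reps:
            break
    if got == 0:
        raise RuntimeError(f"could not condition on k={k}, n={n}")
    return np.concatenate(out)[:reps]


def heterozygosity_excess_test(
    gm: GenotypeMatrix,
    st: SampleTable,
    group: str,
    model: str = "IAM",
    reps: int = 1000,
    seed: int = 0,
    maf_min: float = 0.05,
) -> BottleneckResult:
    """Heterozygosity-excess test for one group.

    Loci are the group's polymorphic sites after removing minor allele
    frequencies below ``maf_min``; with a fixed ``seed`` the result is
    reproducible bit for bit.  Fewer than four usable loci is an error
    (the signed-rank test is undefined).
    """
    if model != "IAM":
        raise ValueError("only the infinite-allele model is implemented")
    idx = st.indices(gm, group)
    if len(idx) == 0:
        raise ValueError(f"group {group!r} is empty")
    counts, n = gm.allele_counts(idx)
    rng = np.random.default_rng(seed)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(n > 0, 1.0 - counts.max(axis=1) / np.maximum(n, 1), np.nan)
    k_obs = (counts > 0).sum(axis=1)
    usable = (k_obs >= 2) & (np.nan_to_num(maf, nan=-1) >= maf_min) & (n >= 4)
    loci_idx = np.flatnonzero(usable)
    if len(loci_idx) < 4:
        raise ValueError(
            f"only {len(loci_idx)} usable loci after the MAF filter; test undefined"
        )
    # Per (k, n) a large conditioned pool is simulated once; each locus then
    # receives its own independent resample of size `reps` from the pool.
    # Sharing one fixed sample across many loci lets the pool's estimation
    # error shift every locus's quantile coherently, which inflates the
    # signed-rank test's size; independent per-locus resamples from a
    # ~20x-larger pool keep those errors effectively uncorrelated.
    pool_cache: dict[tuple[int, int], np.ndarray] = {}
    loci = []
    for i in loci_idx:
        k = int(k_obs[i])
        ni = int(n[i])
        key = (k, ni)
        if key not in pool_cache:
            pool_cache[key] = equilibrium_he(k, ni, 20 * reps, rng)
        heq = pool_cache[key][rng.integers(0, len(pool_cache[key]), size=reps)]
        he_obs = unbiased_gene_diversity(counts[i][counts[i] > 0])
        mean, sd = float(heq.mean()), float(heq.std(ddof=1))
        dh = (he_obs - mean) / sd if sd > 0 else float("nan")
        # mid-rank probability-integral transform of He_obs within the
        # simulated equilibrium distribution: U is symmetric about 1/2
        # under the null even though He itself is strongly skewed for
        # low allele counts, which keeps the signed-rank test calibrated
        # tolerance-based comparison: He takes few discrete values per
        # (k, n), and ties must be recognized across float arithmetic paths
        tol = 1e-9
        below = (heq < he_obs - tol).sum()
        tied = (np.abs(heq - he_obs) <= tol).sum()
        u = float((below + 0.5 * tied + 0.5) / (len(heq) + 1))
        loci.append(LocusResult(int(i), k, ni, he_obs, mean, sd, dh, u))
    u_dev = np.array([l.u_quantile - 0.5 for l in loci])
    if np.allclose(u_dev, 0):
        p = 1.0
    else:
        p = float(
            stats.wilcoxon(u_dev, alternative="greater", zero_method="wilcox").pvalue
        )
    return BottleneckResult(group, loci, p, len(loci), reps, seed)
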