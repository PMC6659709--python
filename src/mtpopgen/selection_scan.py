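"""Selective-sweep scans for a non-recombining genome.

Two detectors:

* Reduction of diversity (ROD): the per-window ratio pi_wild / pi_cultivated,
  with windows at or above the top percentile cutoff called as sweep regions.
  A domestication sweep removes diversity from the cultivated group only, so
  high ratios mark candidate selected regions.

* A composite ``mu`` statistic multiplying three sweep signatures evaluated
  in windows of a fixed number of SNPs: the bp span of the window (sweeps
  leave SNP deserts, so spans stretch), folded-SFS singleton enrichment, and
  a linkage-disequilibrium contrast between the window halves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import MISSING, GenotypeMatrix, SampleTable, WindowStat


@dataclass
class SweepRegion:
    """A merged run of selected windows, 0-based half-open."""

    start: int
    end: int
    score: float  # max window score within the region (inf if capped)
    percentile: float
    group: str
    n_windows: int = 1

    @property
    def length(self) -> int:
        return self.end - self.start


def rod_scan(
    windows_wild: list[WindowStat],
    windows_cult: list[WindowStat],
    cutoff_percentile: float = 5.0,
    cap: float = math.inf,
    group: str | None = None,
):
    """Call top-percentile pi_wild/pi_cultivated windows as sweep regions.

    Window lists must be aligned on identical intervals.  Windows with
    ``pi_c = 0 < pi_w`` take ``cap`` (default +inf: ranked above every
    finite ratio, reported as capped); windows with ``pi_w = pi_c = 0``
    are excluded from scoring.  The selection threshold is the k-th largest
    score with ``k = ceil(cutoff% x n_scored)``; ties at the boundary are
    all included.  Adjacent or overlapping selected windows are merged.

    Returns ``(regions, scored_windows)`` where ``scored_windows`` carry
    the ratio in ``extras["rod"]``.
    """
    if len(windows_wild) != len(windows_cult) or any(
        (a.start, a.end) != (b.start, b.end)
        for a, b in zip(windows_wild, windows_cult)
    ):
        raise ValueError("window lists are not aligned on identical intervals")
    group = group or windows_cult[0].group
    scored: list[WindowStat] = []
    scores = []
    for ww, wc in zip(windows_wild, windows_cult):
        pw, pc = ww.pi, wc.pi
        if np.isnan(pw) or np.isnan(pc) or (pw == 0 and pc == 0):
            continue
        r = cap if pc == 0 else pw / pc
        w = WindowStat(ww.start, ww.end, group, wc.n_used, wc.S, wc.pi)
        w.extras["rod"] = r
        w.extras["pi_wild"] = pw
        scored.append(w)
        scores.append(r)
    if not scored:
        return [], []
    scores = np.array(scores)
    order = np.sort(scores)[::-1]
    k = math.ceil(cutoff_percentile / 100.0 * len(scores))
    k = max(k, 1)
    threshold = order[k - 1]
    ranks = scores.argsort()[::-1].argsort()  # 0 = highest
    for w, rk in zip(scored, ranks):
        w.extras["percentile"] = 100.0 * (1.0 - rk / len(scores))
    selected = [w for w, s in zip(scored, scores) if s >= threshold]
    regions = _merge_windows(selected, group, cutoff_percentile)
    return regions, scored


def _merge_windows(selected, group, cutoff):
    regions = []
    for w in sorted(selected, key=lambda w: (w.start, w.end)):
        if regions and w.start <= regions[-1].end:
            r = regions[-1]
            r.end = max(r.end, w.end)
            r.score = max(r.score, w.extras["rod"])
            r.n_windows += 1
        else:
            regions.append(
                SweepRegion(w.start, w.end, w.extras["rod"], 100 - cutoff, group)
            )
    return regions


def region_overlap(regions_a, regions_b):
    """Total intersection bp between two merged region sets.

    Returns ``(overlap_bp, fraction_of_A)`` where the fraction divides by
    the total bp of set A.  Symmetric in bp, bounded by min(|A|, |B|).
    """
    def spans(regions):
        return sorted((r.start, r.end) if hasattr(r, "start") else tuple(r) for r in regions)

    a, b = spans(regions_a), spans(regions_b)
    total_a = sum(e - s for s, e in a)
    overlap = 0
    for sa, ea in a:
        for sb, eb in b:
            overlap += max(0, min(ea, eb) - max(sa, sb))
    frac = overlap / total_a if total_a > 0 else 0.0
    return overlap, frac


# -- composite mu statistic --------------------------------------------------


def _r2_matrix(G: np.ndarray) -> np.ndarray:
    """Pairwise r^2 between SNP rows of a 0/1 matrix; missing mean-imputed."""
    X = G.astype(float)
    mask = X < 0
    if mask.any():
        with np.errstate(invalid="ignore"):
            means = np.where(
                (~mask).sum(1) > 0,
                np.where(mask, 0, X).sum(1) / np.maximum((~mask).sum(1), 1),
                0.0,
            )
        X = np.where(mask, means[:, None], X)
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = Xc.std(axis=1)
    cov = Xc @ Xc.T / X.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.outer(sd, sd)
    r2 = r**2
    r2[~np.isfinite(r2)] = 0.0
    return r2


def _mu_ld(r2: np.ndarray, half: int) -> float:
    iu = np.triu_indices(half, k=1)
    wl = float(r2[:half, :half][iu].mean()) if half >= 2 else 0.0
    wr = float(r2[half:, half:][iu].mean()) if half >= 2 else 0.0
    between = float(r2[:half, half:].mean())
    num = wl + wr
    if between == 0.0:
        return 1.0 if num == 0.0 else num  # degenerate; see methods note
    return num / between


def mu_scan(
    gm: GenotypeMatrix,
    st: SampleTable,
    group: str,
    snp_window: int = 20,
    grid_step: int = 50,
) -> list[WindowStat]:
    """Composite-mu sweep scan over a grid of evaluation points.

    At each grid point the ``snp_window`` (W) nearest biallelic SNPs that
    segregate within the group form the window, split into halves:

    * ``mu_var`` = window bp span / (genome length x W) — stretches over
      SNP-poor swept regions;
    * ``mu_sfs`` = folded-singleton fraction (sites whose minor allele
      count is 1) in the window;
    * ``mu_ld`` = (mean r^2 within left half + within right half) /
      mean r^2 between halves.

    ``mu = mu_var x mu_sfs x mu_ld``.  Grid points with fewer than W
    usable SNPs genome-wide yield no score (NaN).  The factors are stored
    in ``extras``.
    """
    W = snp_window
    if W < 4 or W % 2:
        raise ValueError("snp_window must be an even number >= 4")
    idx = st.indices(gm, group)
    if len(idx) == 0:
        raise ValueError(f"group {group!r} is empty")
    snp = gm.take_variants(gm.is_biallelic_snp)
    sub = snp.calls[:, idx]
    counts, n = snp.allele_counts(idx)
    seg = (counts > 0).sum(axis=1) >= 2
    snp = snp.take_variants(seg)
    sub = sub[seg]
    counts, n = counts[seg], n[seg]
    pos = snp.positions  # 1-based
    order = np.argsort(pos, kind="stable")
    pos, sub, counts, n = pos[order], sub[order], counts[order], n[order]
    L = gm.reference_length
    S = len(pos)
    minor = counts.min(axis=1)  # biallelic: min of the two counts
    singleton = minor == 1
    out = []
    cache: dict[int, tuple] = {}
    half = W // 2
    for g in range(0, L, grid_step):
        if S < W:
            out.append(_mu_na(g, grid_step, group, len(idx)))
            continue
        lo = _nearest_window_start(pos, g, W)
        if lo in cache:
            mu, factors, span = cache[lo]
        else:
            window_pos = pos[lo : lo + W]
            span = int(window_pos[-1] - window_pos[0])
            mu_var = span / (L * W)
            mu_sfs = float(singleton[lo : lo + W].sum()) / W
            r2 = _r2_matrix(sub[lo : lo + W])
            mu_ld = _mu_ld(r2, half)
            mu = mu_var * mu_sfs * mu_ld
            factors = (mu_var, mu_sfs, mu_ld)
            cache[lo] = (mu, factors, span)
        w = WindowStat(g, min(g + grid_step, L), group, len(idx), W, float("nan"))
        w.extras.update(
            mu=mu, mu_var=factors[0], mu_sfs=factors[1], mu_ld=factors[2], span=span
        )
        out.append(w)
    return out


def _mu_na(g, grid_step, group, n):
    w = WindowStat(g, g + grid_step, group, n, 0, float("nan"))
    w.extras.update(mu=float("nan"), mu_var=float("nan"),
                    mu_sfs=float("nan"), mu_ld=float("nan"), span=0)
    return w


def _nearest_window_start(pos: np.ndarray, g: int, W: int) -> int:
    """Start index of the W consecutive SNPs nearest to grid point g."""
    S = len(pos)
    j = int(np.searchsorted(pos, g))
    lo = max(0, min(j - W // 2, S - W))
    # slide to minimize the maximum distance of window endpoints to g
    best, best_cost = lo, None
    for s in range(max(0, j - W), min(j, S - W) + 1):
        cost = max(abs(int(pos[s]) - g), abs(int(pos[s + W - 1]) - g))
        if best_cost is None or cost < best_cost:
            best, best_cost = s, cost
    return best
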