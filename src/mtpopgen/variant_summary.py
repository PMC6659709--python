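"""Variant summaries: quality filters, per-group counts, Ts/Tv, shared-SNP sets.

Frequencies are computed on non-missing haploid calls.  The quality filter
retains variants whose minor allele frequency is at least ``maf_min`` and
whose missing fraction is at most ``missing_max``; it is idempotent when the
scope is held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, SampleTable


@dataclass
class FilterConfig:
    """Minor-allele-frequency and missingness filter settings.

    ``scope`` names the sample subset over which frequencies are computed
    (``"all"``, a coarse class, or a subgroup label); default all samples.
    """

    maf_min: float = 0.01
    missing_max: float = 0.20
    scope: str = "all"

    def __post_init__(self):
        if not 0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if not 0 <= self.missing_max <= 1:
            raise ValueError("missing_max must be in [0, 1]")


@dataclass
class GroupSummary:
    group: str
    n_accessions: int
    n_snps: int
    n_indels: int
    tstv_ratio: float | None
    spectrum: dict = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return self.n_snps + self.n_indels


def minor_allele_frequency(gm: GenotypeMatrix, sample_idx=None) -> np.ndarray:
    """Per-site MAF = 1 - max allele frequency, NaN where no calls."""
    counts, n = gm.allele_counts(sample_idx)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = 1.0 - counts.max(axis=1) / n
    maf[n == 0] = np.nan
    return maf


def apply_filters(
    gm: GenotypeMatrix,
    cfg: FilterConfig | None = None,
    st: SampleTable | None = None,
    return_report: bool = False,
):
    """Retain variants with MAF >= ``maf_min`` and missingness <= ``missing_max``.

    Both criteria are evaluated over ``cfg.scope`` (requires ``st`` for any
    scope other than ``"all"``).  Returns the filtered matrix, and with
    ``return_report=True`` also a dict of per-criterion removal counts.
    """
    cfg = cfg or FilterConfig()
    if cfg.scope == "all":
        idx = np.arange(gm.n_samples)
    else:
        if st is None:
            raise ValueError("scoped filtering requires a SampleTable")
        idx = st.indices(gm, cfg.scope)
    if len(idx) == 0:
        raise ValueError(f"filter scope {cfg.scope!r} contains no samples")
    sub = gm.calls[:, idx]
    n_nonmiss = (sub != MISSING).sum(axis=1)
    miss_frac = 1.0 - n_nonmiss / len(idx)
    maf = minor_allele_frequency(gm, idx)
    maf_ok = np.nan_to_num(maf, nan=-1.0) >= cfg.maf_min
    miss_ok = miss_frac <= cfg.missing_max
    keep = maf_ok & miss_ok
    out = gm.take_variants(keep)
    if return_report:
        report = {
            "n_input": gm.n_variants,
            "n_retained": int(keep.sum()),
            "removed_maf": int((~maf_ok).sum()),
            "removed_missing": int((~miss_ok).sum()),
        }
        return out, report
    return out


def presence_mask(
    gm: GenotypeMatrix,
    sample_idx: np.ndarray,
    rule: str = "nonref",
) -> np.ndarray:
    """Which variants count as present in a sample subset.

    ``"nonref"`` (default): at least one non-reference, non-missing call —
    appropriate when the reference is itself a member of one subgroup, so
    non-reference carriage is what varies.  ``"polymorphic"``: at least two
    distinct non-missing alleles within the subset.
    """
    sub = gm.calls[:, sample_idx]
    if rule == "nonref":
        return ((sub != MISSING) & (sub > 0)).any(axis=1)
    if rule == "polymorphic":
        masked = np.where(sub == MISSING, np.iinfo(np.int16).max, sub)
        lo = masked.min(axis=1)
        hi = np.where(sub == MISSING, np.iinfo(np.int16).min, sub).max(axis=1)
        return (lo < hi) & (lo != np.iinfo(np.int16).max)
    raise ValueError(f"unknown presence rule {rule!r}")


#: Unordered substitution-type labels for the biallelic SNP spectrum.
def _subst_label(ref: str, alt: str) -> str:
    return "/".join(sorted((ref.upper(), alt.upper())))


def summarize_groups(
    gm: GenotypeMatrix,
    st: SampleTable,
    presence_rule: str = "nonref",
    extra_groups: tuple[str, ...] = ("cultivated", "wild", "all"),
) -> list[GroupSummary]:
    """Per-subgroup (plus cultivated/wild/total) variant counts and Ts/Tv.

    A variant is counted for a group iff the group's presence rule holds;
    Ts/Tv is computed over biallelic SNPs only, with the substitution-type
    spectrum (G/A, C/T, ...) reported alongside.  Empty groups yield an
    all-NA row.
    """
    subgroups = [g for g in st.df["subgroup"].unique()]
    out = []
    for g in list(subgroups) + list(extra_groups):
        idx = st.indices(gm, g) if g != "all" else np.arange(gm.n_samples)
        if len(idx) == 0:
            out.append(GroupSummary(g, 0, 0, 0, None))
            continue
        present = presence_mask(gm, idx, presence_rule)
        n_snp = n_indel = ts = tv = 0
        spectrum: dict[str, int] = {}
        for i in np.flatnonzero(present):
            v = gm.variants[i]
            if v.vclass == "SNP":
                n_snp += 1
                if v.tstv == "transition":
                    ts += 1
                elif v.tstv == "transversion":
                    tv += 1
                if len(v.alts) == 1:
                    lab = _subst_label(v.ref, v.alts[0])
                    spectrum[lab] = spectrum.get(lab, 0) + 1
            else:
                n_indel += 1
        ratio = ts / tv if tv > 0 else None
        out.append(GroupSummary(g, len(idx), n_snp, n_indel, ratio, spectrum))
    return out


def summaries_to_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": s.group,
                "n_accessions": s.n_accessions,
                "SNPs": s.n_snps,
                "InDels": s.n_indels,
                "Total": s.n_total,
                "TsTv": s.tstv_ratio,
            }
            for s in summaries
        ]
    )


def shared_variants(
    gm: GenotypeMatrix,
    st: SampleTable,
    groups: list[str],
    presence_rule: str = "nonref",
) -> dict[frozenset, set]:
    """Full inclusion-exclusion (Venn) table of variant presence across groups.

    Returns a dict keyed by the frozenset of groups in which each variant is
    present (the exact Venn cell); the empty-set cell is omitted.  ``common``
    variants are the cell keyed by ``frozenset(groups)``.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    masks = {}
    for g in groups:
        idx = st.indices(gm, g)  # raises KeyError on unknown label
        masks[g] = presence_mask(gm, idx, presence_rule)
    cells: dict[frozenset, set] = {}
    for i in range(gm.n_variants):
        key = frozenset(g for g in groups if masks[g][i])
        if key:
            cells.setdefault(key, set()).add(i)
    return cells


def venn_to_frame(cells: dict[frozenset, set], groups: list[str]) -> pd.DataFrame:
    rows = []
    for r in range(len(groups), 0, -1):
        for combo in combinations(groups, r):
            key = frozenset(combo)
            rows.append(
                {"groups": "&".join(combo), "n_variants": len(cells.get(key, set()))}
            )
    return pd.DataFrame(rows)
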