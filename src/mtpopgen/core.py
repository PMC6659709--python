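"""Core data model: variants, haploid genotype matrices, and sample metadata.

The substrate of every statistic in this package is a haploid allele-index
matrix over a single non-recombining contig (an organellar genome).  Calls
are small integers: 0 for the reference allele, ``k >= 1`` for the k-th
alternate allele, and :data:`MISSING` (-1) for no-calls.  Heteroplasmic
(diploid-coded heterozygous) calls are resolved at I/O time, before this
layer sees them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing haploid call.
MISSING: int = -1

TRANSITIONS = ({"A", "G"}, {"C", "T"})

#: Controlled vocabulary of subgroup labels.
SUBGROUPS = (
    "temperate_japonica",
    "tropical_japonica",
    "indica",
    "aus",
    "aromatic",
    "wild_rufipogon",
    "wild_nivara",
    "admixture",
)

WILD_SUBGROUPS = frozenset({"wild_rufipogon", "wild_nivara"})

#: Case-insensitive synonyms accepted in metadata tables.
LABEL_SYNONYMS: Mapping[str, str] = {
    "te_japonica": "temperate_japonica",
    "te_j": "temperate_japonica",
    "tej": "temperate_japonica",
    "tr_japonica": "tropical_japonica",
    "tr_j": "tropical_japonica",
    "trj": "tropical_japonica",
    "ind": "indica",
    "rufipogon": "wild_rufipogon",
    "o_rufipogon": "wild_rufipogon",
    "nivara": "wild_nivara",
    "o_nivara": "wild_nivara",
    "wild": "wild_rufipogon",
    "admix": "admixture",
}

#: Composite group labels resolvable by :meth:`SampleTable.indices`.
COMPOSITE_GROUPS: Mapping[str, tuple[str, ...]] = {
    "japonica": ("temperate_japonica", "tropical_japonica"),
    "wild": tuple(sorted(WILD_SUBGROUPS)),
}


@dataclass
class VariantRecord:
    """One VCF row: position, alleles, and derived classifications.

    Attributes
    ----------
    chrom : str
        Reference sequence id.
    pos : int
        1-based reference coordinate.
    ref : str
        Reference allele.
    alts : tuple of str
        Alternate alleles, in VCF order.
    region : str
        Annotation region, one of ``CDS``, ``ORF``, ``intergenic``,
        ``unannotated`` (default).
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    region: str = "unannotated"

    @property
    def vclass(self) -> str:
        """``"SNP"`` iff ref and every alt are single bases, else ``"InDel"``."""
        if len(self.ref) == 1 and all(len(a) == 1 for a in self.alts):
            return "SNP"
        return "InDel"

    @property
    def tstv(self) -> str | None:
        """Transition/transversion class for biallelic SNPs, else ``None``."""
        if self.vclass != "SNP" or len(self.alts) != 1:
            return None
        pair = {self.ref.upper(), self.alts[0].upper()}
        if pair in (set(t) for t in TRANSITIONS):
            return "transition"
        return "transversion"

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alts)


class GenotypeMatrix:
    """Haploid variants x samples allele-index matrix with a missingness sentinel.

    Parameters
    ----------
    variants : sequence of VariantRecord
    samples : sequence of str
        Accession ids, one per column.
    calls : ndarray of shape (n_variants, n_samples), integer dtype
        Allele indices; ``MISSING`` marks no-calls.
    reference_length : int
        Length in bp of the (single) reference contig.
    """

    def __init__(
        self,
        variants: Sequence[VariantRecord],
        samples: Sequence[str],
        calls: np.ndarray,
        reference_length: int,
    ):
        calls = np.asarray(calls, dtype=np.int16)
        if calls.shape != (len(variants), len(samples)):
            raise ValueError(
                f"calls shape {calls.shape} != ({len(variants)}, {len(samples)})"
            )
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample ids")
        for i, v in enumerate(variants):
            if not 1 <= v.pos <= reference_length:
                raise ValueError(f"variant {i} at pos {v.pos} outside [1, {reference_length}]")
        max_allele = np.array([v.n_alleles - 1 for v in variants], dtype=np.int16)
        bad = (calls > max_allele[:, None]) | ((calls < 0) & (calls != MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(f"call {calls[i, j]} out of range at variant {i}, sample {j}")
        self.variants = list(variants)
        self.samples = list(samples)
        self.calls = calls
        self.reference_length = int(reference_length)

    # -- basic views ---------------------------------------------------------

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def positions(self) -> np.ndarray:
        """1-based positions as an int64 array."""
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    @property
    def is_snp(self) -> np.ndarray:
        return np.array([v.vclass == "SNP" for v in self.variants])

    @property
    def is_biallelic_snp(self) -> np.ndarray:
        return np.array(
            [v.vclass == "SNP" and len(v.alts) == 1 for v in self.variants]
        )

    def take_variants(self, index) -> "GenotypeMatrix":
        """Subset rows by boolean mask or integer index, order preserved."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            [self.variants[i] for i in index],
            self.samples,
            self.calls[index],
            self.reference_length,
        )

    def take_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.variants,
            [self.samples[i] for i in index],
            self.calls[:, index],
            self.reference_length,
        )

    # -- counting ------------------------------------------------------------

    def allele_counts(self, sample_idx: np.ndarray | None = None):
        """Per-site allele counts over a sample subset.

        Returns
        -------
        counts : ndarray (n_variants, max_n_alleles)
            ``counts[i, a]`` = number of non-missing calls of allele ``a``.
        n : ndarray (n_variants,)
            Non-missing call count per site.
        """
        sub = self.calls if sample_idx is None else self.calls[:, sample_idx]
        n_all = max((v.n_alleles for v in self.variants), default=1)
        counts = np.zeros((self.n_variants, n_all), dtype=np.int64)
        rows, cols = np.nonzero(sub != MISSING)
        np.add.at(counts, (rows, sub[rows, cols]), 1)
        return counts, counts.sum(axis=1)


class SampleTable:
    """Accession-to-subgroup assignment with a derived cultivated/wild label.

    Wraps a DataFrame with columns ``accession``, ``subgroup``, ``coarse``.
    ``cultivated`` is the union of the five cultivated subgroups plus, by
    default, the admixture class (configurable).
    """

    def __init__(self, df: pd.DataFrame, admixture_is_cultivated: bool = True):
        if df["accession"].duplicated().any():
            dups = df.loc[df["accession"].duplicated(), "accession"].tolist()
            raise ValueError(f"duplicate accession id(s): {dups}")
        unknown = set(df["subgroup"]) - set(SUBGROUPS)
        if unknown:
            rows = df.index[df["subgroup"].isin(unknown)].tolist()
            raise ValueError(f"unknown subgroup label(s) {sorted(unknown)} in rows {rows}")
        df = df.copy()
        wild = df["subgroup"].isin(WILD_SUBGROUPS)
        admix = df["subgroup"] == "admixture"
        coarse = np.where(wild, "wild", "cultivated")
        if not admixture_is_cultivated:
            coarse = np.where(admix, "admixture", coarse)
        df["coarse"] = coarse
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str]], **kwargs
    ) -> "SampleTable":
        """Build from ``(accession, subgroup)`` pairs; labels normalized."""
        rows = [(a, normalize_label(s)) for a, s in records]
        return cls(pd.DataFrame(rows, columns=["accession", "subgroup"]), **kwargs)

    def subgroup_of(self, accession: str) -> str:
        row = self.df[self.df["accession"] == accession]
        if row.empty:
            raise KeyError(accession)
        return row["subgroup"].iloc[0]

    def members(self, group: str) -> list[str]:
        """Accessions in a subgroup, composite group, or coarse class."""
        if group == "all":
            return self.df["accession"].tolist()
        if group in ("cultivated", "wild") and group in set(self.df["coarse"]):
            mask = self.df["coarse"] == group
        elif group in COMPOSITE_GROUPS:
            mask = self.df["subgroup"].isin(COMPOSITE_GROUPS[group])
        elif group in SUBGROUPS:
            mask = self.df["subgroup"] == group
        else:
            raise KeyError(f"unknown group label {group!r}")
        return self.df.loc[mask, "accession"].tolist()

    def indices(self, gm: GenotypeMatrix, group: str) -> np.ndarray:
        """Column indices in ``gm`` of the samples belonging to ``group``.

        Samples present in the table but absent from the matrix are ignored;
        matrix samples absent from the table never match any group.
        """
        members = set(self.members(group))
        return np.array(
            [j for j, s in enumerate(gm.samples) if s in members], dtype=np.int64
        )

    def unmatched(self, gm: GenotypeMatrix) -> list[str]:
        """Matrix samples with no metadata row."""
        known = set(self.df["accession"])
        return [s for s in gm.samples if s not in known]


def normalize_label(label: str) -> str:
    """Map a free-form subgroup label onto the controlled vocabulary."""
    key = label.strip().lower().replace(" ", "_").replace("-", "_")
    key = LABEL_SYNONYMS.get(key, key)
    if key not in SUBGROUPS:
        raise ValueError(f"unknown subgroup label {label!r}")
    return key


@dataclass
class WindowStat:
    """Per-window summary over a 0-based half-open interval ``[start, end)``."""

    start: int
    end: int
    group: str
    n_used: int
    S: int
    pi: float
    tajima_d: float | None = None
    extras: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start


def windows_tiling(reference_length: int, window: int, step: int):
    """Half-open windows tiling ``[0, reference_length)``.

    The last window may be partial; every start is a multiple of ``step``
    strictly below the reference length.
    """
    if not (window >= step > 0):
        raise ValueError("require window >= step > 0")
    out = []
    start = 0
    while start < reference_length:
        out.append((start, min(start + window, reference_length)))
        start += step
    return out
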