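"""Reading and writing variant data for a haploid organellar genome.

VCFs deposited for organellar resequencing studies are typically
diploid-coded by the variant caller even though the genome is effectively
haploid (uniparental inheritance).  :func:`read_vcf` collapses homozygous
diploid genotypes to single allele indices and resolves heterozygous
(heteroplasmic) calls according to a policy — by default they become
missing, since heteroplasmy is noise for a uniparental genome.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import (
    MISSING,
    GenotypeMatrix,
    SampleTable,
    VariantRecord,
    normalize_label,
)

PLOIDY_POLICIES = ("missing", "major")


def read_vcf(
    path,
    ploidy_policy: str = "missing",
    reference_length: int | None = None,
) -> GenotypeMatrix:
    """Read a multi-sample VCF into a haploid :class:`GenotypeMatrix`.

    Parameters
    ----------
    path : str or Path
        VCF 4.x file (plain or bgzip) with a GT field.
    ploidy_policy : {"missing", "major"}
        How to resolve heterozygous diploid-coded calls: ``"missing"``
        treats them as no-calls; ``"major"`` assigns the site's major
        allele (among resolved calls), falling back to missing on ties.
    reference_length : int, optional
        Contig length in bp; taken from the VCF header when present.

    Notes
    -----
    Half-missing diploid genotypes (``./1``) follow the same policy as
    heterozygous calls.  Multiple contigs trigger a warning; records are
    kept with their contig ids.
    """
    if ploidy_policy not in PLOIDY_POLICIES:
        raise ValueError(f"ploidy_policy must be one of {PLOIDY_POLICIES}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    header_len = None
    for line in vcf.raw_header.splitlines():
        if line.startswith("##contig") and "length=" in line:
            field = line.split("length=")[1]
            header_len = int(field.rstrip(">").split(",")[0].split(">")[0])
            break
    variants: list[VariantRecord] = []
    rows = []
    het_rows = []  # (row, col) cells needing the major-allele fallback
    chroms = set()
    for rec in vcf:
        chroms.add(rec.CHROM)
        alts = tuple(rec.ALT)
        variants.append(VariantRecord(rec.CHROM, rec.POS, rec.REF, alts))
        row = np.full(len(samples), MISSING, dtype=np.int16)
        try:
            gts = rec.genotypes
        except Exception as exc:  # pragma: no cover - malformed input
            raise ValueError(f"malformed GT at {rec.CHROM}:{rec.POS}") from exc
        for j, gt in enumerate(gts):
            alleles = [a for a in gt[:-1]]  # last element is the phased flag
            called = [a for a in alleles if a >= 0]
            if not called:
                continue
            if len(set(called)) == 1 and len(called) == len(alleles):
                row[j] = called[0]
            else:
                # heterozygous or half-missing diploid call
                if ploidy_policy == "major":
                    het_rows.append((len(variants) - 1, j))
                # else: stays MISSING
        rows.append(row)
    if len(chroms) > 1:
        warnings.warn(
            f"VCF contains {len(chroms)} contigs; statistics assume a single "
            "non-recombining reference",
            stacklevel=2,
        )
    calls = (
        np.vstack(rows) if rows else np.zeros((0, len(samples)), dtype=np.int16)
    )
    if ploidy_policy == "major" and het_rows:
        _fill_major(calls, het_rows, variants)
    if reference_length is None:
        reference_length = header_len
    if reference_length is None:
        reference_length = int(max((v.pos + len(v.ref) for v in variants), default=1))
    return GenotypeMatrix(variants, samples, calls, reference_length)


def _fill_major(calls, cells, variants):
    for i, j in cells:
        row = calls[i]
        counts = np.bincount(row[row != MISSING], minlength=variants[i].n_alleles)
        if counts.sum() == 0:
            continue
        best = np.flatnonzero(counts == counts.max())
        if len(best) == 1:
            calls[i, j] = best[0]


def read_metadata(path, accession_col=None, subgroup_col=None, **kwargs) -> SampleTable:
    """Read a delimited accession/subgroup table into a :class:`SampleTable`.

    Column names are auto-detected (first column = accession, a column named
    like ``subgroup``/``group``/``population`` = subgroup) unless given.
    Labels are matched case-insensitively against the controlled vocabulary
    and its synonyms; unknown labels raise with the offending rows listed.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else None
    df = pd.read_csv(path, sep=sep, engine="python")
    if accession_col is None:
        accession_col = df.columns[0]
    if subgroup_col is None:
        candidates = [
            c for c in df.columns if c.lower() in ("subgroup", "group", "population", "pop")
        ]
        subgroup_col = candidates[0] if candidates else df.columns[1]
    bad = []
    labels = []
    for idx, raw in df[subgroup_col].items():
        try:
            labels.append(normalize_label(str(raw)))
        except ValueError:
            bad.append((idx, raw))
    if bad:
        raise ValueError(f"unknown subgroup label(s) in rows: {bad}")
    out = pd.DataFrame(
        {"accession": df[accession_col].astype(str), "subgroup": labels}
    )
    return SampleTable(out, **kwargs)


def read_gff3(path) -> pd.DataFrame:
    """Read a GFF3 file into a frame of 1-based inclusive feature intervals."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=[
            "seqid", "source", "type", "start", "end",
            "score", "strand", "phase", "attributes",
        ],
    )
    return df[["seqid", "type", "start", "end"]]


def annotate_regions(gm: GenotypeMatrix, annotation) -> GenotypeMatrix:
    """Assign each variant a region label by interval containment.

    Parameters
    ----------
    gm : GenotypeMatrix
    annotation : DataFrame, path, or iterable of (start, end, type)
        1-based inclusive intervals (GFF convention) typed ``CDS``, ``ORF``
        or ``gene``; ``gene`` intervals count at ORF precedence.

    Returns
    -------
    GenotypeMatrix
        New matrix (calls shared) whose variants carry ``region`` labels
        with precedence CDS > ORF > intergenic.
    """
    if isinstance(annotation, (str, Path)):
        annotation = read_gff3(annotation)
    if isinstance(annotation, pd.DataFrame):
        intervals = list(
            annotation[["start", "end", "type"]].itertuples(index=False, name=None)
        )
    else:
        intervals = list(annotation)
    for start, end, ftype in intervals:
        if ftype not in ("CDS", "ORF", "gene"):
            raise ValueError(f"unsupported feature type {ftype!r}")
        if end > gm.reference_length or start < 1:
            raise ValueError(
                f"interval [{start}, {end}] outside reference of length "
                f"{gm.reference_length}"
            )
    cds = [(s, e) for s, e, t in intervals if t == "CDS"]
    orf = [(s, e) for s, e, t in intervals if t in ("ORF", "gene")]
    new_variants = []
    for v in gm.variants:
        if any(s <= v.pos <= e for s, e in cds):
            region = "CDS"
        elif any(s <= v.pos <= e for s, e in orf):
            region = "ORF"
        else:
            region = "intergenic"
        new_variants.append(dataclasses.replace(v, region=region))
    return GenotypeMatrix(new_variants, gm.samples, gm.calls, gm.reference_length)


# -- writers -----------------------------------------------------------------


def write_vcf(gm: GenotypeMatrix, path, contig: str | None = None) -> None:
    """Write the matrix as a haploid plain-text VCF 4.2 file."""
    contig = contig or (gm.variants[0].chrom if gm.variants else "chr1")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={gm.reference_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for i, v in enumerate(gm.variants):
            gts = [
                "." if c == MISSING else str(int(c)) for c in gm.calls[i]
            ]
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{','.join(v.alts)}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def write_fasta(gm: GenotypeMatrix, path) -> None:
    """Per-sample FASTA of concatenated variant-site alleles.

    Missing calls are emitted as ``N``.  Intended for external tree/network
    software; columns are variant sites, not the full reference.
    """
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = []
    for j, s in enumerate(gm.samples):
        parts = []
        for i, v in enumerate(gm.variants):
            c = gm.calls[i, j]
            if c == MISSING:
                parts.append("N")
            elif c == 0:
                parts.append(v.ref)
            else:
                parts.append(v.alts[c - 1])
        records.append(SeqRecord(Seq("".join(parts)), id=s, description=""))
    SeqIO.write(records, str(path), "fasta")


def write_bed(gm: GenotypeMatrix, st: SampleTable, path, groups) -> None:
    """BED track of variant positions carried (non-reference) per group."""
    with open(path, "w") as fh:
        for g in groups:
            idx = st.indices(gm, g)
            sub = gm.calls[:, idx]
            present = ((sub != MISSING) & (sub > 0)).any(axis=1)
            for i in np.flatnonzero(present):
                v = gm.variants[i]
                fh.write(f"{v.chrom}\t{v.pos - 1}\t{v.pos - 1 + len(v.ref)}\t{g}\n")
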