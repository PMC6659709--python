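"""Coalescent synthetic-data generator for a non-recombining haploid genome.

One genealogy is drawn per dataset from a structured coalescent: a wild
ancestral population (size 1 in coalescent units) and two domesticated
lineages that split from it, each evolving at a reduced relative size
``B`` in ``(0, 1]`` from the present back to its founding (the
domestication bottleneck; smaller ``B`` is a stronger bottleneck).
Mutations are Poisson on the tree at rate ``theta_wild / 2`` per site per
unit branch length, placed uniformly along the genome, so wild pairwise
diversity has expectation ``theta_wild`` per site.

Selective sweeps are modeled phenomenologically: inside a lineage's sweep
interval, that lineage's private polymorphism (variants whose derived
carriers all lie in the lineage) is thinned by a configured factor.  This
reproduces the reduction-of-diversity signature the sweep detectors look
for without forward simulation.  A configurable fraction of mutations is
emitted as short InDels, and missing and heteroplasmic (diploid-coded
heterozygous) calls are added so the quality filters are exercised.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .core import MISSING, GenotypeMatrix, SampleTable, VariantRecord

BASES = "ACGT"
TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass
class SimConfig:
    """Study-condition parameters of the generator.

    Defaults mirror a rice-like mitochondrial collection: a ~490 kb
    non-recombining genome, 66 samples in one domesticated lineage
    ("dom_a", indica-like), 278 in the other ("dom_b", japonica-like,
    stronger bottleneck), 54 wild samples; lineage-specific sweep windows
    at distinct positions; about 30% of variants emitted as InDels.
    """

    reference_length: int = 490_520
    chrom: str = "mt"
    n_wild: int = 54
    n_dom_a: int = 66
    n_dom_b: int = 278
    theta_wild: float = 0.005
    split_a: float = 0.5
    split_b: float = 0.5
    bottleneck_a: float = 0.5
    bottleneck_b: float = 0.1
    sweeps_a: tuple = ((250_000, 260_000),)
    sweeps_b: tuple = ((100_000, 110_000),)
    sweep_thinning: float = 0.95
    indel_fraction: float = 0.3
    missing_rate: float = 0.005
    high_missing_site_fraction: float = 0.01
    high_missing_rate: float = 0.30
    het_rate: float = 0.005
    migrants: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_wild + self.n_dom_a + self.n_dom_b < 2:
            raise ValueError("need at least two samples in total")
        for b in (self.bottleneck_a, self.bottleneck_b):
            if not 0 < b <= 1:
                raise ValueError("bottleneck intensity must be in (0, 1]")
        for iv in tuple(self.sweeps_a) + tuple(self.sweeps_b):
            if not (0 <= iv[0] < iv[1] <= self.reference_length):
                raise ValueError(f"sweep interval {iv} outside the genome")
        if not 0 <= self.sweep_thinning <= 1:
            raise ValueError("sweep_thinning must be in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset, JSON-serializable."""

    config: dict
    seed: int
    tmrca: float
    total_tree_length: float
    n_variants: int
    sweeps: dict = field(default_factory=dict)       # lineage -> [[start, end), ...]
    migration_events: list = field(default_factory=list)
    expected_pi_order: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


@dataclass
class SimDataset:
    gm: GenotypeMatrix
    samples: SampleTable
    truth: SimTruth
    het_cells: np.ndarray  # (row, col) pairs coded heterozygous in the VCF
    het_alleles: np.ndarray

    def write_vcf(self, path) -> None:
        _write_sim_vcf(self, path)

    def write_metadata(self, path) -> None:
        self.samples.df[["accession", "subgroup"]].to_csv(path, sep="\t", index=False)

    def write_truth(self, path) -> None:
        self.truth.to_json(path)


# -- genealogy ---------------------------------------------------------------


def _structured_coalescent(cfg: SimConfig, rng: np.random.Generator):
    """Single genealogy under the wild + two-bottlenecked-lineages model.

    Returns ``(parent, node_time, n_leaves)`` with leaves
    ``0..n-1`` ordered wild, dom_a, dom_b.
    """
    n = cfg.n_wild + cfg.n_dom_a + cfg.n_dom_b
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    node_time = np.zeros(2 * n - 1)
    pops = {
        "wild": list(range(cfg.n_wild)),
        "dom_a": list(range(cfg.n_wild, cfg.n_wild + cfg.n_dom_a)),
        "dom_b": list(range(cfg.n_wild + cfg.n_dom_a, n)),
    }
    sizes = {"wild": 1.0, "dom_a": cfg.bottleneck_a, "dom_b": cfg.bottleneck_b}
    merges = sorted(
        [(cfg.split_a, "dom_a"), (cfg.split_b, "dom_b")], key=lambda e: e[0]
    )
    t = 0.0
    next_node = n
    while True:
        rates = {
            p: len(l) * (len(l) - 1) / 2.0 / sizes[p] for p, l in pops.items() if len(l) >= 2
        }
        total = sum(rates.values())
        if total == 0.0:
            if merges:
                t = max(t, merges[0][0])
                _, pop = merges.pop(0)
                pops["wild"].extend(pops.pop(pop, []))
                continue
            break
        wait = rng.exponential(1.0 / total)
        if merges and t + wait >= merges[0][0]:
            t = merges[0][0]
            _, pop = merges.pop(0)
            pops["wild"].extend(pops.pop(pop, []))
            continue
        t += wait
        u = rng.random() * total
        acc = 0.0
        for p, r in rates.items():
            acc += r
            if u <= acc:
                pop = p
                break
        lineages = pops[pop]
        i, j = rng.choice(len(lineages), size=2, replace=False)
        a, b = lineages[i], lineages[j]
        node = next_node
        next_node += 1
        parent[a] = parent[b] = node
        node_time[node] = t
        pops[pop] = [x for x in lineages if x not in (a, b)] + [node]
        if sum(len(l) for l in pops.values()) == 1 and not merges:
            break
    return parent, node_time, n


def _leaf_sets(parent: np.ndarray, n_leaves: int) -> list[np.ndarray]:
    n_nodes = len(parent)
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    for v in range(n_nodes):
        if parent[v] >= 0:
            children[parent[v]].append(v)
    sets: list = [None] * n_nodes
    for v in range(n_leaves):
        sets[v] = np.array([v], dtype=np.int64)
    for v in range(n_leaves, n_nodes):
        parts = [sets[c] for c in children[v] if sets[c] is not None]
        sets[v] = np.concatenate(parts) if parts else np.array([], dtype=np.int64)
    return sets


# -- dataset assembly --------------------------------------------------------


def _sample_names(cfg: SimConfig):
    """Accession ids and subgroup labels mirroring the emulated collection."""
    names, labels = [], []
    n_ruf = int(round(cfg.n_wild * 2 / 3))
    for i in range(cfg.n_wild):
        lab = "wild_rufipogon" if i < n_ruf else "wild_nivara"
        names.append(f"W{i + 1:03d}")
        labels.append(lab)
    for i in range(cfg.n_dom_a):
        names.append(f"A{i + 1:03d}")
        labels.append("indica")
    n_te = int(round(cfg.n_dom_b * 0.9))
    for i in range(cfg.n_dom_b):
        lab = "temperate_japonica" if i < n_te else "tropical_japonica"
        names.append(f"B{i + 1:03d}")
        labels.append(lab)
    return names, labels


def _draw_alleles(cfg: SimConfig, positions: np.ndarray, rng):
    """Random ref/alt allele strings; SNPs with a 2:1 transition bias."""
    refs, alts = [], []
    for pos0 in positions:
        ref = BASES[rng.integers(4)]
        if rng.random() >= cfg.indel_fraction:  # SNP
            if rng.random() < 2 / 3:
                alt = TRANSITION_OF[ref]
            else:
                alt = rng.choice([b for b in BASES if b != ref and b != TRANSITION_OF[ref]])
        else:
            k = int(rng.integers(1, 6))
            k = min(k, cfg.reference_length - int(pos0) - 1) or 1
            extra = "".join(rng.choice(list(BASES), size=k))
            if rng.random() < 0.5:
                ref, alt = ref + extra, ref  # deletion
            else:
                ref, alt = ref, ref + extra  # insertion
        refs.append(ref)
        alts.append(alt)
    return refs, alts


def simulate_dataset(cfg: SimConfig) -> SimDataset:
    """Draw one dataset (genotypes, metadata, ground truth) under ``cfg``.

    Deterministic under ``cfg.seed``: the same configuration yields a
    byte-identical VCF.
    """
    rng = np.random.default_rng(cfg.seed)
    parent, node_time, n = _structured_coalescent(cfg, rng)
    lengths = np.zeros(len(parent))
    has_parent = parent >= 0
    lengths[has_parent] = node_time[parent[has_parent]] - node_time[np.flatnonzero(has_parent)]
    total_len = float(lengths.sum())
    n_mut = rng.poisson(cfg.theta_wild / 2.0 * cfg.reference_length * total_len)
    n_mut = min(n_mut, cfg.reference_length)
    branch_nodes = np.flatnonzero(has_parent)
    probs = lengths[branch_nodes] / total_len
    mut_nodes = rng.choice(branch_nodes, size=n_mut, p=probs)
    positions = rng.choice(cfg.reference_length, size=n_mut, replace=False)
    order = np.argsort(positions)
    positions, mut_nodes = positions[order], mut_nodes[order]
    leaf_sets = _leaf_sets(parent, n)

    names, labels = _sample_names(cfg)
    st = SampleTable.from_records(zip(names, labels))
    idx_a = np.arange(cfg.n_wild, cfg.n_wild + cfg.n_dom_a)
    idx_b = np.arange(cfg.n_wild + cfg.n_dom_a, n)
    group_idx = {"dom_a": idx_a, "dom_b": idx_b}

    # sweep thinning of private polymorphism
    keep = np.ones(n_mut, dtype=bool)
    sweeps = {"dom_a": [list(iv) for iv in cfg.sweeps_a],
              "dom_b": [list(iv) for iv in cfg.sweeps_b]}
    for lineage, intervals in (("dom_a", cfg.sweeps_a), ("dom_b", cfg.sweeps_b)):
        gset = set(group_idx[lineage].tolist())
        for m in range(n_mut):
            if not keep[m]:
                continue
            pos0 = positions[m]
            if any(s <= pos0 < e for s, e in intervals):
                carriers = leaf_sets[mut_nodes[m]]
                if len(carriers) and all(int(c) in gset for c in carriers):
                    if rng.random() < cfg.sweep_thinning:
                        keep[m] = False
    positions, mut_nodes = positions[keep], mut_nodes[keep]
    n_mut = len(positions)

    calls = np.zeros((n_mut, n), dtype=np.int16)
    for m in range(n_mut):
        calls[m, leaf_sets[mut_nodes[m]]] = 1

    migration_events = []
    for _ in range(cfg.migrants):
        src = int(rng.choice(idx_a))
        dst = int(rng.choice(idx_b))
        calls[:, dst] = calls[:, src]
        migration_events.append({"from": names[src], "to": names[dst]})

    refs, alts = _draw_alleles(cfg, positions, rng)
    variants = [
        VariantRecord(cfg.chrom, int(p) + 1, r, (a,))
        for p, r, a in zip(positions, refs, alts)
    ]

    # missingness: baseline rate plus a sprinkling of high-dropout sites
    site_rate = np.full(n_mut, cfg.missing_rate)
    high = rng.random(n_mut) < cfg.high_missing_site_fraction
    site_rate[high] = cfg.high_missing_rate
    miss = rng.random((n_mut, n)) < site_rate[:, None]
    # heteroplasmic coding: resolved to MISSING by the default read policy
    het = (rng.random((n_mut, n)) < cfg.het_rate) & ~miss
    het_cells = np.argwhere(het)
    het_alleles = calls[het_cells[:, 0], het_cells[:, 1]] if len(het_cells) else np.array([], dtype=np.int16)
    calls[miss | het] = MISSING

    gm = GenotypeMatrix(variants, names, calls, cfg.reference_length)
    root = int(np.argmax(node_time))
    truth = SimTruth(
        config=dataclasses.asdict(cfg),
        seed=cfg.seed,
        tmrca=float(node_time[root]),
        total_tree_length=total_len,
        n_variants=n_mut,
        sweeps=sweeps,
        migration_events=migration_events,
        expected_pi_order=["wild", "dom_a", "dom_b"]
        if cfg.bottleneck_b <= cfg.bottleneck_a
        else ["wild", "dom_b", "dom_a"],
    )
    return SimDataset(gm, st, truth, het_cells, het_alleles)


def _write_sim_vcf(ds: SimDataset, path) -> None:
    """Diploid-coded VCF: hom calls as a/a, het cells as 0/x, missing ./."""
    gm = ds.gm
    het_lookup = {
        (int(r), int(c)): int(a)
        for (r, c), a in zip(ds.het_cells, ds.het_alleles)
    }
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            f"##contig=<ID={gm.variants[0].chrom if gm.variants else 'mt'},"
            f"length={gm.reference_length}>\n"
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples) + "\n"
        )
        for i, v in enumerate(gm.variants):
            gts = []
            for j in range(gm.n_samples):
                c = gm.calls[i, j]
                if (i, j) in het_lookup:
                    a = max(het_lookup[(i, j)], 1)
                    gts.append(f"0/{a}")
                elif c == MISSING:
                    gts.append("./.")
                else:
                    gts.append(f"{c}/{c}")
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{','.join(v.alts)}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )


def simulate_unlinked_loci(
    n: int,
    reference_length: int,
    theta: float,
    seed: int,
    chrom: str = "mt",
) -> SimDataset:
    """Neutral constant-size simulation with every site on its own genealogy.

    Site allele configurations are drawn from the exact marginal neutral
    site-frequency spectrum (derived count ``i`` with probability
    proportional to ``1/i``), with the segregating-site count Poisson at
    the unlinked-locus expectation ``(theta/2) L 2 H_{n-1}``.  This is the
    independence regime assumed by per-locus equilibrium tests (notably
    the heterozygosity-excess bottleneck test); the single-genealogy
    generator violates it by construction, since a non-recombining genome
    shares one tree across all sites.
    """
    rng = np.random.default_rng(seed)
    harmonic = float(np.sum(1.0 / np.arange(1, n)))
    mean_s = theta / 2.0 * reference_length * 2.0 * harmonic
    n_sites = int(min(rng.poisson(mean_s), reference_length))
    positions = np.sort(rng.choice(reference_length, size=n_sites, replace=False))
    freqs = np.arange(1, n)
    probs = (1.0 / freqs) / harmonic
    derived = rng.choice(freqs, size=n_sites, p=probs)
    calls = np.zeros((n_sites, n), dtype=np.int16)
    for m in range(n_sites):
        carriers = rng.choice(n, size=derived[m], replace=False)
        calls[m, carriers] = 1
    refs, alts = [], []
    for _ in range(n_sites):
        ref = BASES[rng.integers(4)]
        alt = TRANSITION_OF[ref] if rng.random() < 2 / 3 else rng.choice(
            [b for b in BASES if b != ref and b != TRANSITION_OF[ref]]
        )
        refs.append(ref)
        alts.append(alt)
    variants = [
        VariantRecord(chrom, int(p) + 1, r, (a,))
        for p, r, a in zip(positions, refs, alts)
    ]
    names = [f"W{i + 1:03d}" for i in range(n)]
    st = SampleTable.from_records((nm, "wild_rufipogon") for nm in names)
    gm = GenotypeMatrix(variants, names, calls, reference_length)
    truth = SimTruth(
        config={"model": "unlinked", "n": n, "theta": theta,
                "reference_length": reference_length},
        seed=seed, tmrca=float("nan"), total_tree_length=float("nan"),
        n_variants=n_sites,
    )
    return SimDataset(gm, st, truth,
                      np.empty((0, 2), dtype=np.int64), np.array([], dtype=np.int16))


# -- recovery scoring --------------------------------------------------------


def evaluate_recovery(
    truth: SimTruth,
    regions: dict | None = None,
    pi: dict | None = None,
    fst: dict | None = None,
    shared_haplotypes: int | None = None,
    coverage_threshold: float = 0.5,
) -> dict:
    """Score pipeline outputs against the generator's ground truth.

    Parameters
    ----------
    regions : dict, optional
        Lineage key ("dom_a"/"dom_b") -> list of detected regions (objects
        with start/end, or (start, end) pairs).
    pi : dict, optional
        Lineage/"wild" -> genome-wide per-site diversity.
    fst : dict, optional
        Pair label -> weighted F_ST, e.g. ``{"a_b": .., "a_wild": ..}``.
    shared_haplotypes : int, optional
        Observed shared-haplotype count between the two lineages.
    coverage_threshold : float
        A true sweep counts as detected when the scan's regions cover at
        least this fraction of it (majority coverage by default: a real
        multi-kb sweep sweeps nearly all of its windows, while noise picks
        scattered single windows).

    Returns a dict with per-sweep hits, diversity/F_ST ordering checks, and
    the shared-haplotype comparison (expected 0 without migration).
    """
    from .selection_scan import region_overlap

    report: dict = {"sweep_hits": [], "n_true_sweeps": 0}
    if regions is not None:
        for lineage, intervals in truth.sweeps.items():
            for iv in intervals:
                report["n_true_sweeps"] += 1
                for scanned, regs in regions.items():
                    bp, frac = region_overlap([tuple(iv)], regs or [])
                    report["sweep_hits"].append(
                        {
                            "lineage": lineage,
                            "scanned_group": scanned,
                            "interval": list(iv),
                            "overlap_bp": bp,
                            "coverage": frac,
                            "detected": bool(
                                frac >= coverage_threshold and scanned == lineage
                            ),
                            "false_positive": bool(
                                frac >= coverage_threshold and scanned != lineage
                            ),
                        }
                    )
    if pi is not None:
        order = truth.expected_pi_order
        vals = [pi.get(g) for g in order if g in pi]
        report["pi_order_expected"] = order
        report["pi_order_ok"] = all(
            vals[i] > vals[i + 1] for i in range(len(vals) - 1)
        ) if len(vals) >= 2 else None
    if fst is not None:
        report["fst"] = dict(fst)
        if "a_b" in fst and "a_wild" in fst:
            report["fst_between_lineages_highest"] = bool(fst["a_b"] > fst["a_wild"])
    if shared_haplotypes is not None:
        expected = 0 if not truth.migration_events else None
        report["shared_haplotypes"] = shared_haplotypes
        report["shared_haplotypes_expected"] = expected
        report["shared_haplotypes_ok"] = (
            shared_haplotypes == 0 if expected == 0
            else shared_haplotypes >= 1
        )
    return report
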