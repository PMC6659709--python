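"""Haplotype collapsing and mutational-step network construction.

Samples are collapsed into haplotypes over the retained variant sites and
connected by a minimum spanning tree on pairwise Hamming (mutational-step)
distances — a deterministic simplification of the TCS statistical-parsimony
network sufficient for group-sharing and cluster structure.  An optional
connection limit (fixed, or derived from a 0.95 parsimony probability)
cuts long edges into separate components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

from .core import MISSING, GenotypeMatrix, SampleTable


@dataclass
class Haplotype:
    id: str
    vector: tuple
    members: list[str]
    group_counts: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.members)


def collapse_haplotypes(
    gm: GenotypeMatrix,
    st: SampleTable | None = None,
    missing_policy: str = "complete-sites",
) -> list[Haplotype]:
    """Group identical allele vectors into haplotypes.

    ``"complete-sites"`` (default) first drops sites with any missing call,
    mirroring common haplotype software; ``"complete-samples"`` instead
    drops samples containing missing calls.  Haplotype ids are assigned in
    order of first occurrence (H1, H2, ...).
    """
    calls = gm.calls
    samples = list(gm.samples)
    if missing_policy == "complete-sites":
        keep = (calls != MISSING).all(axis=1)
        calls = calls[keep]
    elif missing_policy == "complete-samples":
        keep_s = (calls != MISSING).all(axis=0)
        calls = calls[:, keep_s]
        samples = [s for s, k in zip(samples, keep_s) if k]
    else:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if calls.shape[0] == 0 and gm.n_variants > 0:
        raise ValueError(
            "no sites retained under complete-sites; try missing_policy="
            "'complete-samples'"
        )
    seen: dict[tuple, Haplotype] = {}
    order: list[Haplotype] = []
    for j, s in enumerate(samples):
        vec = tuple(int(c) for c in calls[:, j])
        hap = seen.get(vec)
        if hap is None:
            hap = Haplotype(f"H{len(order) + 1}", vec, [])
            seen[vec] = hap
            order.append(hap)
        hap.members.append(s)
    if st is not None:
        for hap in order:
            counts: dict[str, int] = {}
            for s in hap.members:
                try:
                    g = st.subgroup_of(s)
                except KeyError:
                    g = "unknown"
                counts[g] = counts.get(g, 0) + 1
            hap.group_counts = counts
    return order


def shared_haplotypes(
    haps: list[Haplotype], st: SampleTable, group_a: str, group_b: str
):
    """Haplotypes whose membership intersects both groups; ``(count, ids)``."""
    ma = set(st.members(group_a))
    mb = set(st.members(group_b))
    ids = [
        h.id
        for h in haps
        if any(s in ma for s in h.members) and any(s in mb for s in h.members)
    ]
    return len(ids), ids


def hamming(a: tuple, b: tuple) -> int:
    return sum(x != y for x, y in zip(a, b))


def parsimony_limit(
    aligned_length: int, confidence: float = 0.95, max_steps: int = 1000
) -> int:
    """Largest step count with multiple-hit-free probability >= ``confidence``.

    Changes are modeled as Poisson across the ``aligned_length`` sites: for
    ``j`` observed differences the per-site substitution number ``d`` is the
    Jukes-Cantor correction of ``p = j / m``, and the chance that every one
    of the ``j`` differing sites experienced exactly one change is
    ``(d e^-d / (1 - e^-d))^j``.  The limit is the largest ``j`` keeping
    that probability at or above the confidence level — the same 0.95
    criterion statistical parsimony applies.
    """
    m = aligned_length
    limit = 0
    for j in range(1, max_steps + 1):
        p = j / m
        if p >= 0.75:
            break
        d = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
        single = d * math.exp(-d) / (1.0 - math.exp(-d))
        if single**j >= confidence:
            limit = j
        else:
            break
    return limit


def build_network(
    haps: list[Haplotype],
    connection_limit: int | str | None = None,
    aligned_length: int | None = None,
) -> nx.Graph:
    """Minimum spanning tree over pairwise Hamming distances.

    Edges carry ``steps``; ties are broken deterministically by
    lexicographic haplotype id.  ``connection_limit`` may be ``None`` (no
    limit), an integer (fixed maximum steps), or ``"parsimony-95"``
    (requires ``aligned_length``); MST edges above the limit are removed,
    splitting the network into components.
    """
    if not haps:
        raise ValueError("need at least one haplotype")
    G = nx.Graph()
    for h in haps:
        G.add_node(h.id, n=h.n, group_counts=dict(h.group_counts))
    edges = []
    for ha, hb in combinations(haps, 2):
        edges.append((hamming(ha.vector, hb.vector), ha.id, hb.id))
    edges.sort(key=lambda e: (e[0], e[1], e[2]))
    # Kruskal with explicit deterministic tie-break
    parent = {h.id: h.id for h in haps}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    mst = nx.Graph()
    mst.add_nodes_from(G.nodes(data=True))
    for d, u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            mst.add_edge(u, v, steps=d)
    if connection_limit is not None:
        if connection_limit == "parsimony-95":
            if aligned_length is None:
                raise ValueError("parsimony-95 requires aligned_length")
            limit = parsimony_limit(aligned_length)
        else:
            limit = int(connection_limit)
        drop = [(u, v) for u, v, d in mst.edges(data="steps") if d > limit]
        mst.remove_edges_from(drop)
        mst.graph["connection_limit"] = limit
    return mst


def write_nexus(
    haps: list[Haplotype],
    gm: GenotypeMatrix,
    path,
    groups: list[str] | None = None,
) -> None:
    """PopART-compatible NEXUS with DATA and TRAITS blocks.

    Sequences are the haplotype allele vectors rendered as the first base
    of each allele; the TRAITS block carries per-group member counts.
    """
    keep = (gm.calls != MISSING).all(axis=1)
    variants = [v for v, k in zip(gm.variants, keep) if k]
    if groups is None:
        groups = sorted({g for h in haps for g in h.group_counts})
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN TAXA;\n")
        fh.write(f"DIMENSIONS NTAX={len(haps)};\nTAXLABELS\n")
        for h in haps:
            fh.write(f"{h.id}\n")
        fh.write(";\nEND;\n\nBEGIN CHARACTERS;\n")
        nchar = len(variants)
        fh.write(f"DIMENSIONS NCHAR={nchar};\n")
        fh.write("FORMAT DATATYPE=DNA MISSING=? GAP=-;\nMATRIX\n")
        for h in haps:
            seq = []
            for v, c in zip(variants, h.vector):
                allele = v.ref if c == 0 else v.alts[c - 1]
                seq.append(allele[0])
            fh.write(f"{h.id} {''.join(seq)}\n")
        fh.write(";\nEND;\n\nBEGIN TRAITS;\n")
        fh.write(f"Dimensions NTRAITS={len(groups)};\n")
        fh.write("Format labels=yes missing=? separator=Comma;\n")
        fh.write("TraitLabels " + " ".join(groups) + ";\nMatrix\n")
        for h in haps:
            row = ",".join(str(h.group_counts.get(g, 0)) for g in groups)
            fh.write(f"{h.id} {row}\n")
        fh.write(";\nEND;\n")


def network_to_edge_frame(G: nx.Graph):
    import pandas as pd

    return pd.DataFrame(
        [
            {"hap_a": u, "hap_b": v, "steps": d}
            for u, v, d in sorted(G.edges(data="steps"))
        ]
    )
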