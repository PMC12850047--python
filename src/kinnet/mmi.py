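"""Module-module interaction (MMI) network statistics.

An MMI between modules A and B asks whether the number of co-expressed
gene pairs bridging A and B (adjacency weight above a threshold) is
larger than expected given how often A's genes are co-expressed with the
rest of the network.  With

* m = co-expressed pairs between A and B,
* n = |A|*|B| possible pairs between A and B,
* M = co-expressed pairs between A's genes and all genes outside A,
* N = possible such pairs,

the significance is the hypergeometric upper tail
p = P(X >= m), X ~ Hypergeom(N, M, n) = 1 - sum_{i<m} C(M,i) C(N-M,n-i) / C(N,n).
Both orientations A->B and B->A are computed; an edge is significant if
either tail is <= alpha.

Also here: generic over-representation analysis (ORA) against GMT gene
sets with Benjamini-Hochberg FDR, the pathway-guided subnetwork trimming
rule (keep anchors + neighbors, then the top-k modules per pathway), and
gene-network edge trimming (weight threshold, top edges per node).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coexpression import UNASSIGNED, AdjacencyGraph, ModulePartition

__all__ = [
    "PairCounts",
    "count_coexpressed_pairs",
    "hypergeom_upper_tail",
    "mmi_pvalue",
    "build_mmi_network",
    "ora_enrichment",
    "extract_subnetwork",
    "trim_gene_network",
]

_TINY = np.nextafter(0.0, 1.0)


@dataclass(frozen=True)
class PairCounts:
    """Ordered-pair co-expression counts feeding the hypergeometric tail."""

    module_a: str
    module_b: str
    m: int
    n: int
    M: int
    N: int

    def __post_init__(self) -> None:
        if not (0 <= self.m <= self.n <= self.N):
            raise ValueError("require 0 <= m <= n <= N")
        if not (self.m <= self.M <= self.N):
            raise ValueError("require m <= M <= N")


def count_coexpressed_pairs(
    adj: AdjacencyGraph, part: ModulePartition, tau: float = 0.01
) -> list[PairCounts]:
    """Count co-expressed gene pairs for every ordered module pair.

    A pair (g in A, h in B) is co-expressed iff its adjacency weight
    exceeds ``tau``.  For orientation (A, B): m and n are the co-expressed
    and possible pairs between A and B; M and N are the co-expressed and
    possible pairs between A's genes and all assigned genes outside A.
    Unassigned genes are excluded.
    """
    labels = part.labels.reindex(adj.genes)
    assigned = labels[labels.notna() & (labels != UNASSIGNED)]
    n_excluded = len(adj.genes) - len(assigned)
    if n_excluded:
        warnings.warn(f"excluding {n_excluded} unassigned gene(s) from MMI counting")
    modules = sorted(assigned.unique())
    if len(modules) < 2:
        raise ValueError("need >= 2 modules for MMI counting")

    genes = list(assigned.index)
    gpos = {g: i for i, g in enumerate(genes)}
    member = {mod: np.array([gpos[g] for g in assigned.index[assigned == mod]]) for mod in modules}

    b = (adj.weights.loc[genes, genes].values > tau)
    sizes = {mod: member[mod].size for mod in modules}
    total = len(genes)

    # cross-block co-expressed counts for every unordered pair
    cross = {}
    for i, a in enumerate(modules):
        for bmod in modules[i + 1:]:
            cross[(a, bmod)] = int(b[np.ix_(member[a], member[bmod])].sum())

    out = []
    for a in modules:
        M = sum(cross[(a, o)] if (a, o) in cross else cross[(o, a)]
                for o in modules if o != a)
        N = sizes[a] * (total - sizes[a])
        for o in modules:
            if o == a:
                continue
            m = cross[(a, o)] if (a, o) in cross else cross[(o, a)]
            out.append(PairCounts(module_a=a, module_b=o, m=m, n=sizes[a] * sizes[o], M=M, N=N))
    return out


def hypergeom_upper_tail(m: int, n: int, M: int, N: int) -> float:
    """P(X >= m) for X ~ Hypergeom(population N, successes M, draws n).

    Empty sum convention: m = 0 gives p = 1.  Never returns 0; the
    smallest representable positive tail is used as a floor.
    """
    if m <= 0:
        return 1.0
    p = float(stats.hypergeom.sf(m - 1, N, M, n))
    return max(p, _TINY)


def mmi_pvalue(counts: PairCounts) -> float:
    """Hypergeometric tail significance of an ordered module pair."""
    return hypergeom_upper_tail(counts.m, counts.n, counts.M, counts.N)


def build_mmi_network(
    all_counts: Sequence[PairCounts],
    alpha: float = 0.05,
    part: ModulePartition | None = None,
) -> nx.Graph:
    """Assemble the undirected MMI network from ordered pair counts.

    Each unordered module pair carries both orientation tails (p_ab,
    p_ba); the edge is kept iff either tail is <= ``alpha``.  Node
    attribute ``size`` is filled from ``part`` when given.  Graph-level
    attributes record node/edge counts.
    """
    by_pair: dict[tuple[str, str], dict[str, float]] = {}
    modules = set()
    for c in all_counts:
        modules.update((c.module_a, c.module_b))
        key = tuple(sorted((c.module_a, c.module_b)))
        d = by_pair.setdefault(key, {})
        d["p_ab" if c.module_a == key[0] else "p_ba"] = mmi_pvalue(c)

    g = nx.Graph()
    for mod in sorted(modules):
        size = int((part.labels == mod).sum()) if part is not None else None
        g.add_node(mod, size=size)
    for (a, b), d in sorted(by_pair.items()):
        if "p_ab" not in d or "p_ba" not in d:
            raise ValueError(f"missing orientation for module pair {a}-{b}")
        significant = min(d["p_ab"], d["p_ba"]) <= alpha
        if significant:
            g.add_edge(a, b, p_ab=d["p_ab"], p_ba=d["p_ba"], significant=True)
    g.graph["n_modules"] = g.number_of_nodes()
    g.graph["n_mmi"] = g.number_of_edges()
    g.graph["alpha"] = alpha
    return g


def ora_enrichment(
    module_genes: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
    universe: Sequence[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in named sets.

    One-sided upper-tail p per set (overlap >= observed) with
    Benjamini-Hochberg FDR q-values; rows sorted by p.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    mod = set(module_genes) & uni
    if not mod:
        raise ValueError("module has no genes in the universe")
    rows = []
    for name, members in gene_sets.items():
        s = set(members) & uni
        if not s:
            continue
        k = len(mod & s)
        p = hypergeom_upper_tail(k, len(mod), len(s), len(uni))
        rows.append((name, len(s), k, p))
    if not rows:
        raise ValueError("no gene set overlaps the universe")
    df = pd.DataFrame(rows, columns=["gene_set", "set_size", "overlap", "p"])
    df["q"] = multipletests(df["p"].values, method="fdr_bh")[1]
    return df.sort_values("p", kind="mergesort").reset_index(drop=True)


def extract_subnetwork(
    net: nx.Graph,
    anchor_genes: Sequence[str],
    part: ModulePartition,
    pathway_names: Sequence[str],
    enrichment: Mapping[str, Mapping[str, float]],
    top_k: int | float = 2,
) -> nx.Graph:
    """Anchor-centred, pathway-trimmed MMI subnetwork.

    Modules containing the anchor genes and their network neighbors are
    selected; of those, only modules ranking among the ``top_k`` most
    significantly enriched (smallest p) for at least one named pathway
    are retained — anchor modules are always kept.  ``enrichment`` maps
    module -> pathway -> p-value.  Returns the induced subgraph.
    """
    anchors = []
    for g in anchor_genes:
        if g not in part.labels.index or part.labels[g] == UNASSIGNED:
            raise ValueError(f"anchor gene {g!r} is not assigned to a module")
        anchors.append(part.labels[g])
    anchors = sorted(set(anchors))

    candidates = set(anchors)
    for a in anchors:
        if a in net:
            candidates.update(net.neighbors(a))

    if math.isinf(top_k):
        keep = candidates
    else:
        keep = set(anchors)
        for pw in pathway_names:
            scored = sorted(
                (
                    (enrichment.get(mod, {}).get(pw, np.inf), mod)
                    for mod in candidates
                    if np.isfinite(enrichment.get(mod, {}).get(pw, np.inf))
                ),
            )
            keep.update(mod for _, mod in scored[: int(top_k)])
        keep &= candidates
        keep.update(anchors)

    return net.subgraph(sorted(keep)).copy()


def trim_gene_network(
    adj: AdjacencyGraph,
    tau: float = 0.01,
    max_edges_per_node: int = 50,
    keep_genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Threshold-and-cap edge trimming for gene-network visualisation.

    Drops edges with weight <= ``tau``; each node nominates its
    ``max_edges_per_node`` heaviest remaining edges and an edge survives
    when either endpoint nominates it.  Optionally restricted to
    ``keep_genes``.  Returns columns ``gene_a, gene_b, weight`` sorted by
    descending weight.
    """
    w = adj.weights
    if keep_genes is not None:
        sel = [g for g in w.index if g in set(keep_genes)]
        w = w.loc[sel, sel]
    genes = list(w.index)
    a = w.values
    iu, ju = np.triu_indices(len(genes), k=1)
    mask = a[iu, ju] > tau
    iu, ju, wts = iu[mask], ju[mask], a[iu, ju][mask]

    nominated = np.zeros(iu.size, dtype=bool)
    per_node_edges: dict[int, list[int]] = {i: [] for i in range(len(genes))}
    for e in range(iu.size):
        per_node_edges[iu[e]].append(e)
        per_node_edges[ju[e]].append(e)
    for node, edges in per_node_edges.items():
        edges.sort(key=lambda e: -wts[e])
        for e in edges[:max_edges_per_node]:
            nominated[e] = True

    out = pd.DataFrame(
        {
            "gene_a": [genes[i] for i in iu[nominated]],
            "gene_b": [genes[j] for j in ju[nominated]],
            "weight": wts[nominated],
        }
    )
    return out.sort_values("weight", ascending=False, kind="mergesort").reset_index(drop=True)
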