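"""Replication and enrichment statistics for causal protein networks.

Overlap of network edges with an undirected protein-protein interaction
(PPI) reference against a random-network null (z-score), cross-network edge
overlap by Fisher's exact test over the shared pair universe, per-regulator
target overlap by hypergeometric tests with Storey q-values, and pairwise
subnetwork similarity (eigenprotein correlation plus target-set Jaccard)
with shared hierarchical-clustering leaf order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .eigenassoc import Eigenprotein
from .netbuild import Subnetwork
from .pqtl import storey_qvalues

__all__ = [
    "OverlapStats",
    "ppi_overlap_z",
    "edge_overlap_fisher",
    "target_overlap_hypergeom",
    "subnetwork_similarity",
    "load_ppi_table",
]


@dataclass
class OverlapStats:
    observed: int
    random_mean: float
    random_sd: float
    z: float
    p: float
    degenerate: bool = False


def load_ppi_table(path, confidence: str | float | None = None) -> set:
    """Read a 2-column (+ optional score) gene-pair TSV into an unordered
    pair set. ``confidence`` may be a float cutoff or the named presets
    "medium" (score > 0.63) / "high" (score > 0.72)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = list(df.columns)
    if confidence is not None and len(cols) >= 3:
        cut = {"medium": 0.63, "high": 0.72}.get(confidence, confidence)
        df = df[df[cols[2]] > float(cut)]
    return {frozenset((a, b)) for a, b in zip(df[cols[0]], df[cols[1]]) if a != b}


def ppi_overlap_z(
    network_edges,
    ppi_pairs: set,
    protein_universe: list,
    n_random: int = 10,
    seed: int = 0,
    gene_map: dict | None = None,
) -> OverlapStats:
    """Observed PPI overlap of the network versus equal-size random networks.

    Network edges are matched direction-agnostically at gene level. The null
    draws ``n_random`` random networks with the same number of edges by
    sampling unordered protein pairs uniformly without replacement from the
    universe; z = (obs - mean)/sd and p = 1 - Phi(z). A zero null sd yields
    a degenerate result with a warning flag rather than an error.
    """
    gene = (lambda a: gene_map.get(a, a)) if gene_map else (lambda a: a)
    net_pairs = {frozenset((gene(e[0]), gene(e[1]))) for e in network_edges if gene(e[0]) != gene(e[1])}
    observed = sum(1 for pr in net_pairs if pr in ppi_pairs)
    n_edges = len(net_pairs)

    rng = np.random.default_rng(seed)
    uni = sorted(set(protein_universe))
    n_uni = len(uni)
    max_pairs = n_uni * (n_uni - 1) // 2
    counts = []
    for _ in range(n_random):
        chosen: set = set()
        k = min(n_edges, max_pairs)
        while len(chosen) < k:
            i, j = rng.integers(0, n_uni, size=2)
            if i != j:
                chosen.add(frozenset((uni[i], uni[j])))
        counts.append(sum(1 for pr in chosen if pr in ppi_pairs))
    mean = float(np.mean(counts)) if counts else 0.0
    sd = float(np.std(counts, ddof=1)) if len(counts) > 1 else 0.0
    if sd == 0:
        return OverlapStats(observed, mean, sd, np.nan, np.nan, degenerate=True)
    z = (observed - mean) / sd
    return OverlapStats(observed, mean, sd, float(z), float(stats.norm.sf(z)))


def edge_overlap_fisher(edges_a, edges_b, shared_universe: list) -> tuple[float, float]:
    """Fisher's exact test of directed-edge overlap between two networks.

    The background is all ordered non-self pairs over the shared protein
    universe; the 2x2 table classifies each pair by membership in A and B.
    Returns (odds ratio, two-sided p); a table with an empty margin gives an
    infinite or zero odds ratio as reported by the exact test.
    """
    uni = sorted(set(shared_universe))
    if not uni or len(uni) < 2:
        raise ValueError("shared universe must contain at least 2 proteins")
    uset = set(uni)
    ea = {(a, b) for a, b in ((e[0], e[1]) for e in edges_a) if a in uset and b in uset and a != b}
    eb = {(a, b) for a, b in ((e[0], e[1]) for e in edges_b) if a in uset and b in uset and a != b}
    n_pairs = len(uni) * (len(uni) - 1)
    both = len(ea & eb)
    only_a = len(ea) - both
    only_b = len(eb) - both
    neither = n_pairs - both - only_a - only_b
    odds, p = stats.fisher_exact([[both, only_a], [only_b, neither]], alternative="two-sided")
    return float(odds), float(p)


def target_overlap_hypergeom(
    pairs: list,
    universe: list,
    min_shared: int = 2,
) -> pd.DataFrame:
    """Upper-tail hypergeometric target-set overlap with Storey q-values.

    ``pairs`` is a list of (name, targets_a, targets_b); only pairs sharing
    at least ``min_shared`` targets are tested. Both target sets must lie
    inside the universe.
    """
    uset = set(universe)
    n_uni = len(uset)
    rows = []
    for name, ta, tb in pairs:
        ta, tb = set(ta), set(tb)
        if ta - uset or tb - uset:
            raise ValueError(f"{name}: target set not contained in universe")
        k = len(ta & tb)
        if k < min_shared:
            continue
        # P(X >= k), X ~ Hypergeom(N, |A|, |B|)
        p = float(stats.hypergeom.sf(k - 1, n_uni, len(ta), len(tb)))
        rows.append({"name": name, "n_a": len(ta), "n_b": len(tb), "shared": k, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = storey_qvalues(df["p"].to_numpy()).qvalues
    return df


def subnetwork_similarity(
    subnetworks: list[Subnetwork], eigenproteins: list[Eigenprotein]
) -> dict:
    """Pairwise eigenprotein Pearson correlation and target-set Jaccard.

    Both matrices share the leaf order of an average-linkage hierarchical
    clustering on correlation distance (1 - r), so negatively correlated
    subnetworks with similar target sets sit together in the Jaccard view.
    """
    eig = {e.subnetwork: e.scores for e in eigenproteins}
    names = [s.regulator for s in subnetworks if s.regulator in eig]
    subs = {s.regulator: s.targets for s in subnetworks}
    n = len(names)
    if n < 2:
        raise ValueError("need at least 2 subnetworks with eigenproteins")
    S = np.column_stack([eig[x] for x in names])
    corr = np.corrcoef(S.T)
    jac = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            u = subs[names[i]] | subs[names[j]]
            jac[i, j] = jac[j, i] = len(subs[names[i]] & subs[names[j]]) / len(u) if u else 0.0
    dist = squareform(np.clip(1.0 - corr, 0.0, 2.0), checks=False)
    link = hierarchy.linkage(dist, method="average")
    order = hierarchy.leaves_list(link)
    leaf_names = [names[i] for i in order]
    return {
        "correlation": pd.DataFrame(corr, index=names, columns=names).loc[leaf_names, leaf_names],
        "jaccard": pd.DataFrame(jac, index=names, columns=names).loc[leaf_names, leaf_names],
        "leaf_order": leaf_names,
        "linkage": link,
    }
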