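"""From edge scores to the causal protein network.

Selection at a global FDR (one minus the mean posterior probability over the
selected set), the minimum-target regulator filter, representative-aptamer
deduplication, LD-block formation among instruments and the target-overlap
(I ratio) pleiotropy resolution, and subnetwork extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .pqtl import CisInstrument
from .synthio import SnpPanel

__all__ = [
    "CausalNetwork",
    "LDBlock",
    "Subnetwork",
    "select_edges_global_fdr",
    "filter_regulators",
    "dedup_aptamers",
    "build_ld_blocks",
    "resolve_ld_block",
    "extract_subnetworks",
]


@dataclass
class CausalNetwork:
    """Selected edge set at a global FDR target.

    ``edges`` holds the selected edges (a, b, pp) sorted by pp descending;
    ``fdr_realized`` is 1 - mean(pp) over the selection (0 for an empty one).
    """

    edges: pd.DataFrame  # columns a, b, pp
    fdr_target: float
    fdr_realized: float
    unresolved: dict = field(default_factory=dict)  # label -> collapsed target union

    @property
    def regulators(self) -> list:
        return sorted(self.edges["a"].unique())

    def targets_of(self, regulator: str) -> set:
        return set(self.edges.loc[self.edges["a"] == regulator, "b"])

    def out_degrees(self) -> pd.Series:
        return self.edges.groupby("a").size().sort_values(ascending=False)

    def edge_set(self) -> set:
        return set(zip(self.edges["a"], self.edges["b"]))

    def copy(self) -> "CausalNetwork":
        return CausalNetwork(
            self.edges.copy(), self.fdr_target, self.fdr_realized, dict(self.unresolved)
        )

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for a, b, pp in self.edges[["a", "b", "pp"]].itertuples(index=False):
            g.add_edge(a, b, pp=float(pp))
        return g


@dataclass
class LDBlock:
    """Regulators whose instruments are shared or in LD (r^2 >= threshold)."""

    members: list
    lead_snps: dict  # regulator -> snp id
    r2: pd.DataFrame  # pairwise instrument dosage r^2
    resolution: dict = field(default_factory=dict)  # regulator -> "independent" | "collapsed-unresolved"
    i_values: pd.DataFrame | None = None


@dataclass
class Subnetwork:
    regulator: str
    targets: set

    @property
    def size(self) -> int:
        return len(self.targets)

    @property
    def members(self) -> set:
        return {self.regulator} | self.targets


def select_edges_global_fdr(edge_scores: pd.DataFrame, target_fdr: float = 0.01) -> CausalNetwork:
    """Longest pp-descending prefix whose 1 - mean(pp) stays <= target_fdr.

    Ties in pp break lexically on (a, b) for determinism. Self-edges are
    never candidates. An empty selection is a valid (empty) network.
    """
    df = edge_scores.loc[edge_scores["a"] != edge_scores["b"], ["a", "b", "pp"]]
    df = df.sort_values(["pp", "a", "b"], ascending=[False, True, True], kind="stable")
    pp = df["pp"].to_numpy(float)
    if pp.size:
        prefix_fdr = 1.0 - np.cumsum(pp) / np.arange(1, pp.size + 1)
        ok = np.flatnonzero(prefix_fdr <= target_fdr + 1e-12)  # FP-safe boundary
        n_sel = int(ok[-1]) + 1 if ok.size else 0
    else:
        n_sel = 0
    selected = df.iloc[:n_sel].reset_index(drop=True)
    realized = float(1.0 - selected["pp"].mean()) if n_sel else 0.0
    return CausalNetwork(edges=selected, fdr_target=target_fdr, fdr_realized=realized)


def filter_regulators(network: CausalNetwork, min_targets: int = 10) -> CausalNetwork:
    """Keep only regulators with at least ``min_targets`` selected targets."""
    deg = network.edges.groupby("a")["b"].size()
    keep = set(deg.index[deg >= min_targets])
    edges = network.edges[network.edges["a"].isin(keep)].reset_index(drop=True)
    realized = float(1.0 - edges["pp"].mean()) if len(edges) else 0.0
    return CausalNetwork(edges, network.fdr_target, realized, dict(network.unresolved))


def dedup_aptamers(network: CausalNetwork, annotation: pd.DataFrame) -> CausalNetwork:
    """One representative regulator aptamer per gene: the one with the most
    targets; ties break to the lexically smaller aptamer id. Dropped aptamers
    remain eligible as targets."""
    gene_of = dict(zip(annotation["aptamer_id"], annotation["gene"]))
    deg = network.edges.groupby("a")["b"].size()
    best: dict[str, str] = {}
    for apt in sorted(deg.index):  # lexical scan makes the tie rule explicit
        gene = gene_of.get(apt, apt)
        cur = best.get(gene)
        if cur is None or deg[apt] > deg[cur]:
            best[gene] = apt
    keep = set(best.values())
    edges = network.edges[network.edges["a"].isin(keep)].reset_index(drop=True)
    realized = float(1.0 - edges["pp"].mean()) if len(edges) else 0.0
    return CausalNetwork(edges, network.fdr_target, realized, dict(network.unresolved))


def build_ld_blocks(
    instruments: list[CisInstrument],
    snp_panel: SnpPanel,
    regulators: list | None = None,
    r2_threshold: float = 0.5,
) -> list[LDBlock]:
    """Group regulators whose lead pSNPs are identical or in LD.

    An undirected graph over regulators links two whenever their instruments
    share the SNP id or have dosage r^2 >= threshold; blocks are its
    connected components (single-linkage closure). Requires genotypes for
    every instrument.
    """
    inst = {i.aptamer_id: i for i in instruments}
    if regulators is None:
        regulators = sorted(inst)
    missing = [r for r in regulators if r not in inst]
    if missing:
        raise ValueError(f"no instrument for regulators {missing[:5]}")
    snp_ids = {r: inst[r].snp_id for r in regulators}
    for r in regulators:
        if snp_ids[r] not in snp_panel.snp_ids:
            raise ValueError(f"missing genotype for instrument {snp_ids[r]}")
    dos = {r: snp_panel.dosage[:, snp_panel.snp_index(snp_ids[r])] for r in regulators}

    g = nx.Graph()
    g.add_nodes_from(regulators)
    regs = list(regulators)
    for i, x in enumerate(regs):
        for y in regs[i + 1 :]:
            if snp_ids[x] == snp_ids[y]:
                g.add_edge(x, y, r2=1.0)
                continue
            r = np.corrcoef(dos[x], dos[y])[0, 1]
            if np.isfinite(r) and r * r >= r2_threshold:
                g.add_edge(x, y, r2=float(r * r))

    blocks = []
    for comp in sorted(nx.connected_components(g), key=lambda c: sorted(c)[0]):
        members = sorted(comp)
        r2 = pd.DataFrame(1.0, index=members, columns=members)
        for i, x in enumerate(members):
            for y in members[i + 1 :]:
                rr = 1.0 if snp_ids[x] == snp_ids[y] else float(np.corrcoef(dos[x], dos[y])[0, 1] ** 2)
                r2.loc[x, y] = r2.loc[y, x] = rr
        blocks.append(LDBlock(members=members, lead_snps={m: snp_ids[m] for m in members}, r2=r2))
    return blocks


def target_jaccard(tx: set, ty: set) -> float:
    """I ratio: intersection of target sets over their union."""
    union = tx | ty
    return len(tx & ty) / len(union) if union else 0.0


def resolve_ld_block(
    block: LDBlock, network: CausalNetwork, i_threshold: float = 0.6
) -> LDBlock:
    """Decide independence within an LD block from target-set overlap.

    A member is independent iff its I ratio is strictly below the threshold
    against every other member; members failing that are merged into one
    collapsed-unresolved pseudo-network holding the union of their targets.
    Any two members that are mutual targets of each other are unresolved
    outright, regardless of I. The outcome is order-independent.
    """
    members = sorted(block.members)
    targets = {m: network.targets_of(m) for m in members}
    edge_set = network.edge_set()
    n = len(members)
    ivals = pd.DataFrame(np.nan, index=members, columns=members)
    unresolved = set()
    for i, x in enumerate(members):
        for y in members[i + 1 :]:
            i_xy = target_jaccard(targets[x], targets[y])
            ivals.loc[x, y] = ivals.loc[y, x] = i_xy
            if not (i_xy < i_threshold):
                unresolved |= {x, y}
            if (x, y) in edge_set and (y, x) in edge_set:
                unresolved |= {x, y}
    block.resolution = {
        m: ("collapsed-unresolved" if m in unresolved else "independent") for m in members
    }
    block.i_values = ivals
    return block


def extract_subnetworks(
    network: CausalNetwork, blocks: list[LDBlock] | None = None
) -> tuple[list[Subnetwork], dict]:
    """One subnetwork per independent regulator.

    Regulators marked collapsed-unresolved in their LD block are pooled per
    block into a pseudo-network (union of targets) returned separately and
    excluded from downstream causal claims.
    """
    collapsed: dict[str, set] = {}
    dropped = set()
    if blocks:
        for blk in blocks:
            bad = [m for m, r in blk.resolution.items() if r == "collapsed-unresolved"]
            if bad:
                dropped |= set(bad)
                label = "+".join(sorted(bad))
                union: set = set()
                for m in bad:
                    union |= network.targets_of(m)
                collapsed[label] = union
    subs = [
        Subnetwork(regulator=r, targets=network.targets_of(r))
        for r in network.regulators
        if r not in dropped
    ]
    return subs, collapsed
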