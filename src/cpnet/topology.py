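"""Network hierarchy and structure analyses.

Greedy DAG construction over regulator-regulator edges, root/level
assignment by shortest path from roots, transitive reduction, loop-motif
counts, hub-removal robustness, subsampling ROC/PR robustness against the
full-sample network, and target-correlation enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import precision_recall_curve, roc_auc_score

from .causal import score_all_pairs
from .netbuild import CausalNetwork, Subnetwork
from .pqtl import CisInstrument
from .synthio import ProteinPanel, SnpPanel

__all__ = [
    "DagLayout",
    "regulator_subgraph",
    "greedy_dag",
    "assign_levels",
    "classify_reintroduced_edges",
    "transitive_reduction",
    "count_motifs",
    "hub_robustness",
    "subsample_robustness",
    "target_correlation_enrichment",
]


@dataclass
class DagLayout:
    kept: list  # (a, b, pp)
    removed: list  # (a, b, pp)
    levels: dict = field(default_factory=dict)
    edge_classes: dict = field(default_factory=dict)  # (a, b) -> class label


def regulator_subgraph(network: CausalNetwork) -> pd.DataFrame:
    """Edges whose source and target are both network regulators."""
    regs = set(network.regulators)
    mask = network.edges["a"].isin(regs) & network.edges["b"].isin(regs)
    return network.edges.loc[mask, ["a", "b", "pp"]].reset_index(drop=True)


def _reachable(adj: dict, src, dst) -> bool:
    """DFS reachability src -> dst over dict-of-sets adjacency."""
    if src == dst:
        return True
    stack, seen = [src], {src}
    while stack:
        u = stack.pop()
        for v in adj.get(u, ()):
            if v == dst:
                return True
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return False


def greedy_dag(edges_with_pp) -> DagLayout:
    """Iterate edges by pp descending (ties lexical) and keep each edge
    unless it would close a directed cycle; removed edges are recorded."""
    if isinstance(edges_with_pp, pd.DataFrame):
        rows = list(edges_with_pp[["a", "b", "pp"]].itertuples(index=False, name=None))
    else:
        rows = [(a, b, float(pp)) for a, b, pp in edges_with_pp]
    rows.sort(key=lambda e: (-e[2], e[0], e[1]))
    adj: dict = {}
    kept, removed = [], []
    for a, b, pp in rows:
        if _reachable(adj, b, a):
            removed.append((a, b, pp))
        else:
            adj.setdefault(a, set()).add(b)
            kept.append((a, b, pp))
    return DagLayout(kept=kept, removed=removed)


def assign_levels(dag: DagLayout) -> dict:
    """Level = shortest edge count from any root (node without incoming kept
    edges), by multi-source BFS. Raises on cyclic input."""
    g = nx.DiGraph()
    for a, b, _ in dag.kept:
        g.add_edge(a, b)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("input is not acyclic")
    roots = [n for n in g.nodes if g.in_degree(n) == 0]
    levels = {r: 0 for r in roots}
    frontier = list(roots)
    d = 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for v in g.successors(u):
                if v not in levels:
                    levels[v] = d
                    nxt.append(v)
        frontier = nxt
    dag.levels = levels
    return levels


def classify_reintroduced_edges(dag: DagLayout) -> dict:
    """Label each removed-then-reintroduced edge by the level difference
    level(child) - level(parent): 0 same-level, -1 one-above, -2 two-above,
    >= 1 below (the hierarchical direction)."""
    if not dag.levels:
        assign_levels(dag)
    classes = {}
    for a, b, _ in dag.removed:
        if a not in dag.levels or b not in dag.levels:
            classes[(a, b)] = "unplaced"
            continue
        diff = dag.levels[b] - dag.levels[a]
        if diff == 0:
            label = "same-level"
        elif diff == -1:
            label = "one-above"
        elif diff == -2:
            label = "two-above"
        elif diff >= 1:
            label = "below"
        else:
            label = f"{-diff}-above"
        classes[(a, b)] = label
    dag.edge_classes = classes
    return classes


def transitive_reduction(edges) -> list:
    """Unique minimal edge set of a DAG preserving reachability.

    Edge (u, v) is removed iff an alternative directed path u -> v exists.
    Input is an iterable of (u, v) pairs (extra fields preserved); raises on
    cyclic input.
    """
    pairs = [tuple(e) for e in edges]
    g = nx.DiGraph()
    g.add_edges_from((e[0], e[1]) for e in pairs)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("input is not acyclic")
    adj = {u: set(g.successors(u)) for u in g.nodes}
    kept = []
    for e in pairs:
        u, v = e[0], e[1]
        adj[u].discard(v)
        if not _reachable(adj, u, v):
            adj[u].add(v)
            kept.append(e)
    return kept


def count_motifs(edges) -> dict:
    """Counts of 2-node feedback, 3-node feedback and feed-forward loops.

    FFL: ordered triple with x->y, y->z, x->z (counted once per role
    assignment); 2-node feedback: x<->y pairs; 3-node feedback: directed
    3-cycles, each cycle counted once.
    """
    eset = {(e[0], e[1]) for e in edges}
    succ: dict = {}
    pred: dict = {}
    for u, v in eset:
        succ.setdefault(u, set()).add(v)
        pred.setdefault(v, set()).add(u)
    fb2 = sum(1 for (u, v) in eset if u < v and (v, u) in eset)
    ffl = 0
    for x, z in eset:
        ffl += len((succ.get(x, set()) & pred.get(z, set())) - {x, z})
    fb3 = 0
    for x, y in eset:
        # cycles x -> y -> w -> x; each directed 3-cycle seen 3 times
        fb3 += len((succ.get(y, set()) & pred.get(x, set())) - {x, y})
    assert fb3 % 3 == 0
    return {"feedback_2": fb2, "feedback_3": fb3 // 3, "feedforward": ffl}


def hub_robustness(edges, k_max: int = 10, rank_by: str = "out") -> pd.DataFrame:
    """Largest weakly connected component fraction after removing top hubs.

    Hubs are ranked by out-degree (configurable to total degree), ties
    lexical; for each k = 0..k_max the top-k hubs are removed and the size of
    the largest weakly connected component is reported as a fraction of the
    original node count.
    """
    g = nx.DiGraph()
    g.add_edges_from((e[0], e[1]) for e in edges)
    n0 = g.number_of_nodes()
    if n0 == 0:
        return pd.DataFrame(columns=["k", "removed", "largest_wcc_fraction"])
    if rank_by == "out":
        degree = dict(g.out_degree())
    elif rank_by == "total":
        degree = dict(g.degree())
    else:
        raise ValueError(f"unknown rank_by {rank_by!r}")
    hubs = sorted(degree, key=lambda u: (-degree[u], u))
    rows = []
    h = g.copy()
    removed: list = []
    for k in range(0, min(k_max, len(hubs)) + 1):
        if k:
            h.remove_node(hubs[k - 1])
            removed.append(hubs[k - 1])
        frac = (
            max((len(c) for c in nx.weakly_connected_components(h)), default=0) / n0
        )
        rows.append({"k": k, "removed": list(removed), "largest_wcc_fraction": frac})
    return pd.DataFrame(rows)


def subsample_robustness(
    panel: ProteinPanel,
    snp_panel: SnpPanel,
    instruments: list[CisInstrument],
    ground_truth: CausalNetwork,
    sizes=(500, 1000, 2000, 3000, 4000, 5000),
    reps: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """ROC/PR of subsample posterior probabilities against the full network.

    The full-sample network is flattened to a binary vector over all scored
    candidate pairs; each subsample re-scores the same pairs (same
    instruments) and is evaluated against that vector with ROC AUC and
    precision-recall. Returns one row per (size, rep) with the AUC and the
    PR curve arrays.
    """
    n = panel.n_samples
    truth_edges = ground_truth.edge_set()
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        if size > n:
            raise ValueError(f"subsample size {size} exceeds n={n}")
        for rep in range(reps):
            idx = np.sort(rng.choice(n, size=size, replace=False))  # stable summation order
            sub_panel = ProteinPanel(
                [panel.sample_ids[i] for i in idx],
                panel.aptamer_ids,
                panel.levels[idx],
                panel.annotation,
            )
            sub_snps = SnpPanel(
                [snp_panel.sample_ids[i] for i in idx],
                snp_panel.snp_ids,
                snp_panel.chrom,
                snp_panel.pos,
                snp_panel.dosage[idx],
                snp_panel.maf,
                snp_panel.instrument_snps,
            )
            scores = score_all_pairs(instruments, sub_panel, sub_snps)
            y_true = np.array([(a, b) in truth_edges for a, b in zip(scores["a"], scores["b"])])
            pp = scores["pp"].to_numpy()
            if y_true.any() and not y_true.all():
                auc = float(roc_auc_score(y_true, pp))
                prec, rec, _ = precision_recall_curve(y_true, pp)
            else:
                auc, prec, rec = np.nan, np.array([]), np.array([])
            rows.append(
                {"size": size, "rep": rep, "auc": auc, "precision": prec, "recall": rec}
            )
    return pd.DataFrame(rows)


def target_correlation_enrichment(
    subnetworks: list[Subnetwork],
    panel: ProteinPanel,
    n_random: int = 100,
    seed: int = 0,
) -> dict:
    """Are within-subnetwork target correlations stronger than random groups?

    Pools absolute pairwise Pearson correlations of targets within each
    subnetwork and compares them against size-matched random protein groups
    with a Kruskal-Wallis test.
    """
    rng = np.random.default_rng(seed)
    col = {a: j for j, a in enumerate(panel.aptamer_ids)}
    lv = panel.levels

    def group_abs_corr(members: list) -> np.ndarray:
        idx = [col[m] for m in members if m in col]
        if len(idx) < 2:
            return np.array([])
        c = np.corrcoef(lv[:, idx].T)
        return np.abs(c[np.triu_indices_from(c, k=1)])

    observed, null = [], []
    for sub in subnetworks:
        members = sorted(sub.targets)
        observed.append(group_abs_corr(members))
        k = len(members)
        for _ in range(n_random):
            rand = rng.choice(panel.aptamer_ids, size=min(k, panel.n_aptamers), replace=False)
            null.append(group_abs_corr(list(rand)))
    obs = np.concatenate(observed) if observed else np.array([])
    nul = np.concatenate(null) if null else np.array([])
    if obs.size == 0 or nul.size == 0:
        return {"statistic": np.nan, "p": 1.0, "observed_median": np.nan, "random_median": np.nan}
    if np.array_equal(np.sort(obs), np.sort(nul)):
        return {"statistic": 0.0, "p": 1.0, "observed_median": float(np.median(obs)),
                "random_median": float(np.median(nul))}
    stat, p = stats.kruskal(obs, nul)
    return {
        "statistic": float(stat),
        "p": float(p),
        "observed_median": float(np.median(obs)),
        "random_median": float(np.median(nul)),
    }
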