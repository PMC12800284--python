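"""Model/Results front end for causal protein network inference.

``CausalProteinNetwork`` holds the aligned inputs (genotypes, protein
panel, covariates and optionally phenotypes plus a simulation ground
truth); ``fit()`` runs preprocessing, cis-instrument selection, pairwise
causal scoring, global-FDR edge selection, regulator filtering, aptamer
deduplication and LD-block pleiotropy resolution, and returns a
``CPNResults`` carrying the network, its subnetworks and diagnostics, with
downstream analyses (topology, eigenproteins, trait association and
ranking, robustness, variance partitioning) as results methods.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import io as cpio
from . import netbuild, pqtl, topology, varexp
from .causal import score_all_pairs
from .eigenassoc import associate_all, compute_eigenprotein, rank_networks
from .preprocess import preprocess_panel
from .synthio import (
    CovariateTable,
    PhenotypeTable,
    ProteinPanel,
    SimTruth,
    SnpPanel,
    simulate_cohort,
)

__all__ = ["CausalProteinNetwork", "CPNResults", "DEFAULT_CONFIG"]

DEFAULT_CONFIG = {
    "half_window": 150_000,
    "pqtl_q": 0.05,
    "edge_fdr": 0.01,
    "min_targets": 10,
    "ld_r2": 0.5,
    "i_threshold": 0.6,
    "eigen_variance": 0.15,
    "eigen_p_threshold": 0.00027,
    "eigen_rule": "fixed",
    "rank_cut": 7,
    "boxcox": True,
}


class CausalProteinNetwork:
    """Directed protein-network model instrumented by cis-pQTLs.

    Parameters
    ----------
    snp_panel, protein_panel : aligned genotype and protein containers.
    covariates : age/sex table used for adjustment and association models.
    phenotypes : optional trait table for association and ranking.
    truth : optional simulation ground truth enabling recovery metrics.
    config : threshold overrides merged over ``DEFAULT_CONFIG``.
    """

    def __init__(
        self,
        snp_panel: SnpPanel,
        protein_panel: ProteinPanel,
        covariates: CovariateTable,
        phenotypes: PhenotypeTable | None = None,
        truth: SimTruth | None = None,
        config: dict | None = None,
    ):
        self.snp_panel = snp_panel
        self.protein_panel = protein_panel
        self.covariates = covariates
        self.phenotypes = phenotypes
        self.truth = truth
        self.config = {**DEFAULT_CONFIG, **(config or {})}

    @classmethod
    def from_files(cls, config: dict) -> "CausalProteinNetwork":
        snps, proteins, covs, phenos = cpio.load_inputs(config)
        return cls(snps, proteins, covs, phenos, config=config.get("thresholds"))

    @classmethod
    def from_simulation(cls, seed: int = 0, config: dict | None = None, **sim_kwargs):
        snps, truth, proteins, covs, phenos = simulate_cohort(seed=seed, **sim_kwargs)
        return cls(snps, proteins, covs, phenos, truth=truth, config=config)

    def fit(self, preprocess: bool = True) -> "CPNResults":
        cfg = self.config
        panel = (
            preprocess_panel(self.protein_panel, self.covariates, boxcox=cfg["boxcox"])
            if preprocess
            else self.protein_panel
        )
        instruments = pqtl.find_instruments(
            self.snp_panel, panel, half_window=cfg["half_window"], q_threshold=cfg["pqtl_q"]
        )
        scores = score_all_pairs(instruments, panel, self.snp_panel)
        net = netbuild.select_edges_global_fdr(scores, target_fdr=cfg["edge_fdr"])
        selection_fdr = net.fdr_realized  # bounded by the target, pre-filter
        net = netbuild.filter_regulators(net, min_targets=cfg["min_targets"])
        net = netbuild.dedup_aptamers(net, panel.annotation)
        if net.regulators:
            blocks = netbuild.build_ld_blocks(
                instruments, self.snp_panel, regulators=net.regulators, r2_threshold=cfg["ld_r2"]
            )
            blocks = [netbuild.resolve_ld_block(b, net, cfg["i_threshold"]) for b in blocks]
        else:
            blocks = []
        subnets, collapsed = netbuild.extract_subnetworks(net, blocks)
        net.unresolved = collapsed
        return CPNResults(
            model=self,
            panel=panel,
            instruments=instruments,
            scores=scores,
            network=net,
            blocks=blocks,
            subnetworks=subnets,
            selection_fdr=selection_fdr,
        )


@dataclass
class CPNResults:
    """Fitted causal protein network with diagnostics and downstream analyses."""

    model: CausalProteinNetwork
    panel: ProteinPanel
    instruments: list
    scores: pd.DataFrame
    network: netbuild.CausalNetwork
    blocks: list
    subnetworks: list
    selection_fdr: float = 0.0  # realized FDR of the global selection, pre-filter
    _eigen_cache: dict = field(default_factory=dict, repr=False)

    # -- basic accessors ----------------------------------------------------

    @property
    def regulators(self) -> list:
        return [s.regulator for s in self.subnetworks]

    @property
    def n_edges(self) -> int:
        return len(self.network.edges)

    @property
    def realized_fdr(self) -> float:
        return self.network.fdr_realized

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Causal protein network",
            "=" * 48,
            f"samples                 {self.panel.n_samples}",
            f"proteins (aptamers)     {self.panel.n_aptamers}",
            f"instrumented A-proteins {len(self.instruments)}",
            f"candidate edges scored  {len(self.scores)}",
            f"global FDR target       {cfg['edge_fdr']:.3f}",
            f"realized FDR            {self.realized_fdr:.4f}",
            f"edges selected          {self.n_edges}",
            f"network regulators      {len(self.subnetworks)}"
            f" (min {cfg['min_targets']} targets)",
            f"collapsed/unresolved    {len(self.network.unresolved)}",
        ]
        if self.model.truth is not None:
            ev = self.evaluate()
            lines.append(f"ROC AUC vs truth        {ev['auc']:.4f}")
        return "\n".join(lines)

    # -- recovery against simulation truth ---------------------------------

    def evaluate(self, mode: str = "direct") -> dict:
        """ROC AUC of the posterior scores against the simulated truth.

        ``mode="direct"`` (default) takes the structural edges as positives;
        ``mode="ancestor"`` scores every pair with a directed path as a
        positive, which credits the (genuine) indirect total effects the
        P2*P5 product also detects but penalizes undetectably weak
        long-range paths.
        """
        truth = self.model.truth
        if truth is None:
            raise ValueError("no simulation truth attached to this model")
        adj = truth.adjacency(self.panel.aptamer_ids, mode=mode)
        y = np.array([adj.loc[a, b] for a, b in zip(self.scores["a"], self.scores["b"])])
        pp = self.scores["pp"].to_numpy()
        auc = float(roc_auc_score(y, pp)) if 0 < y.sum() < y.size else float("nan")
        sel = self.network.edge_set()
        true_edges = {(a, b) for (a, b) in sel if adj.loc[a, b]}
        fdp = 1.0 - len(true_edges) / len(sel) if sel else 0.0
        return {"auc": auc, "n_positive": int(y.sum()), "fdp": float(fdp)}

    # -- topology -----------------------------------------------------------

    def topology_summary(self) -> dict:
        reg_edges = topology.regulator_subgraph(self.network)
        dag = topology.greedy_dag(reg_edges)
        topology.assign_levels(dag)
        topology.classify_reintroduced_edges(dag)
        reduced = topology.transitive_reduction([(a, b) for a, b, _ in dag.kept])
        motifs_all = topology.count_motifs(self.network.edge_set())
        motifs_reg = topology.count_motifs(set(zip(reg_edges["a"], reg_edges["b"])))
        return {
            "regulator_edges": len(reg_edges),
            "dag_kept": len(dag.kept),
            "dag_removed": len(dag.removed),
            "transitive_reduced": len(reduced),
            "levels": dag.levels,
            "edge_classes": dag.edge_classes,
            "motifs_all": motifs_all,
            "motifs_regulator_only": motifs_reg,
            "hub_robustness": topology.hub_robustness(self.network.edge_set()),
        }

    def robustness(self, sizes=(500, 1000, 2000), reps: int = 3, seed: int = 0) -> pd.DataFrame:
        return topology.subsample_robustness(
            self.panel, self.model.snp_panel, self.instruments, self.network,
            sizes=sizes, reps=reps, seed=seed,
        )

    # -- eigenproteins and trait association --------------------------------

    def eigenproteins(self, variance_threshold: float | None = None) -> dict:
        thr = variance_threshold if variance_threshold is not None else self.model.config["eigen_variance"]
        key = ("eig", thr)
        if key not in self._eigen_cache:
            self._eigen_cache[key] = {
                s.regulator: compute_eigenprotein(s, self.panel, variance_threshold=thr)
                for s in self.subnetworks
                if len(s.members) >= 2
            }
        return self._eigen_cache[key]

    def associate_traits(self, traits: list | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
        phenos = self.model.phenotypes
        if phenos is None:
            raise ValueError("no phenotypes attached to this model")
        col = {a: j for j, a in enumerate(self.panel.aptamer_ids)}
        reg_exp = {r: self.panel.levels[:, col[r]] for r in self.regulators}
        reg_res = associate_all(reg_exp, phenos, self.model.covariates, unit="regulator", traits=traits)
        eig = self.eigenproteins()
        eig_exp = {name: e.scores for name, e in eig.items()}
        eig_res = associate_all(eig_exp, phenos, self.model.covariates, unit="eigenprotein", traits=traits)
        return reg_res, eig_res

    def rank(self, traits: list | None = None):
        phenos = self.model.phenotypes
        traits = traits if traits is not None else phenos.trait_names()
        reg_res, eig_res = self.associate_traits(traits)
        eig_valid = {name: e.valid for name, e in self.eigenproteins().items()}
        return rank_networks(
            reg_res, eig_res, eig_valid, traits,
            eigen_p_threshold=self.model.config["eigen_p_threshold"],
            eigen_rule=self.model.config["eigen_rule"],
            top_cut=self.model.config["rank_cut"],
        )

    # -- variance explained --------------------------------------------------

    def variance_explained(self) -> tuple[pd.DataFrame, list]:
        """Forward-selected cis SNP sets per regulator and the parental-cis
        model over targets; returns (regulator table, target results)."""
        snps = self.model.snp_panel
        inst = {i.aptamer_id: i for i in self.instruments}
        cfg = self.model.config
        col = {a: j for j, a in enumerate(self.panel.aptamer_ids)}
        sel: dict[str, list] = {}
        rows = []
        for r in self.regulators:
            if r not in inst:
                continue
            chosen = varexp.forward_select_cis(
                snps, self.panel.levels[:, col[r]], inst[r].snp_id,
                half_window=cfg["half_window"],
            )
            r2 = varexp.cis_variance_explained(self.panel.levels[:, col[r]], snps, chosen)
            sel[r] = chosen
            rows.append({"regulator": r, "n_snps": len(chosen), "r2_cis": r2})
        reg_table = pd.DataFrame(rows)

        dropped = set()
        for blk in self.blocks:
            dropped |= {m for m, res in blk.resolution.items() if res == "collapsed-unresolved"}
        parents_of: dict[str, dict] = {}
        for a, b in self.network.edge_set():
            if a in sel and a not in dropped:
                parents_of.setdefault(b, {})[a] = sel[a]
        results = []
        for tgt, parents in sorted(parents_of.items()):
            own = []
            if tgt in inst:
                own = varexp.forward_select_cis(
                    snps, self.panel.levels[:, col[tgt]], inst[tgt].snp_id,
                    half_window=cfg["half_window"],
                )
            results.append(
                varexp.parental_cis_variance(
                    tgt, self.panel.levels[:, col[tgt]], snps, parents, own
                )
            )
        return reg_table, results

    # -- plotting ------------------------------------------------------------

    def plot_degree_distributions(self, ax=None):
        """Out-degree (regulators) and in-degree (targets) histograms."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(1, 2, figsize=(9, 3.5))
        out_deg = self.network.out_degrees()
        in_deg = self.network.edges.groupby("b").size()
        ax[0].hist(out_deg, bins=30, color="tab:blue")
        ax[0].set_xlabel("targets per regulator")
        ax[0].set_ylabel("regulators")
        ax[1].hist(in_deg, bins=30, color="tab:orange")
        ax[1].set_xlabel("regulators per target")
        ax[1].set_ylabel("targets")
        return ax

    def plot_robustness(self, robustness_table: pd.DataFrame, ax=None):
        """Mean subsample ROC AUC against subsample size."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3.5))
        mean_auc = robustness_table.groupby("size")["auc"].mean()
        ax.plot(mean_auc.index, mean_auc.values, marker="o")
        ax.set_xlabel("subsample size")
        ax.set_ylabel("mean ROC AUC vs full-sample network")
        ax.set_ylim(0, 1.02)
        return ax

    # -- export --------------------------------------------------------------

    def save(self, run_dir) -> None:
        """Write the run's artifacts (edge list, instruments, manifest)."""
        run_dir = Path(run_dir)
        run_dir.mkdir(parents=True, exist_ok=True)
        self.network.edges.to_csv(run_dir / "edges.tsv", sep="\t", index=False)
        self.scores.to_csv(run_dir / "edge_scores.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {"aptamer_id": i.aptamer_id, "snp_id": i.snp_id, "beta": i.beta,
                 "se": i.se, "p_adj": i.p, "q": i.q}
                for i in self.instruments
            ]
        ).to_csv(run_dir / "instruments.tsv", sep="\t", index=False)
        manifest = {
            "config": self.model.config,
            "n_samples": self.panel.n_samples,
            "n_proteins": self.panel.n_aptamers,
            "n_instruments": len(self.instruments),
            "n_edges": self.n_edges,
            "n_regulators": len(self.subnetworks),
            "realized_fdr": self.realized_fdr,
        }
        with open(run_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)

    def to_graphml(self, path) -> None:
        import networkx as nx

        g = self.network.to_graph()
        try:
            levels = topology.assign_levels(topology.greedy_dag(topology.regulator_subgraph(self.network)))
            nx.set_node_attributes(g, levels, "level")
        except ValueError:
            pass
        nx.write_graphml(g, path)
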