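"""Variance-partitioning models for cis-genetic control.

Forward selection of conditionally independent cis SNPs around each lead
variant (individual-level analogue of summary-statistic conditional
selection), adjusted R^2 of the local cis component, the parental-cis model
for targets (variance explained by the regulators' instruments on top of
the target's own), and the relation between in-degree and parental variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthio import SnpPanel

__all__ = [
    "CisVarianceResult",
    "forward_select_cis",
    "cis_variance_explained",
    "parental_cis_variance",
    "variance_vs_indegree",
]


@dataclass
class CisVarianceResult:
    protein: str
    selected_snps: list
    r2_local: float
    r2_local_plus_parental: float
    delta: float
    n_regulators: int = 0
    parent_snps: list = field(default_factory=list)


def _ols_stats(X: np.ndarray, y: np.ndarray):
    """Joint OLS (with intercept): coefficient p-values and adjusted R^2."""
    n = y.size
    D = np.column_stack([np.ones(n), X])
    beta, _, rank, _ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    rss = resid @ resid
    tss = ((y - y.mean()) ** 2).sum()
    k = D.shape[1] - 1
    dof = n - D.shape[1]
    if dof <= 0 or tss == 0:
        return np.full(k, 1.0), 0.0, 0.0
    sigma2 = rss / dof
    XtX_inv = np.linalg.pinv(D.T @ D)
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2, 1e-300))
    t = beta / se
    pvals = 2 * stats.t.sf(np.abs(t[1:]), df=dof)
    r2 = 1.0 - rss / tss
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    return pvals, r2, adj


def forward_select_cis(
    snp_panel: SnpPanel,
    protein_levels: np.ndarray,
    lead_snp: str,
    tss: int | None = None,
    chrom: str | None = None,
    half_window: int = 150_000,
    p_threshold: float = 0.00763,
    collinearity_r2: float = 0.9,
) -> list[str]:
    """Forward selection of independent cis SNPs, seeded at the lead SNP.

    The window is +/- ``half_window`` around the lead variant (or an
    explicitly supplied TSS). At each step the candidate with the smallest
    conditional p-value in the joint refit is added if that p-value is below
    ``p_threshold`` and its dosage r^2 with every already-selected SNP is
    below ``collinearity_r2``; selection stops otherwise.
    """
    li = snp_panel.snp_index(lead_snp)
    lead_dos = snp_panel.dosage[:, li]
    if lead_dos.var() == 0:
        raise ValueError(f"lead SNP {lead_snp} is monomorphic")
    anchor = int(snp_panel.pos[li]) if tss is None else int(tss)
    c = snp_panel.chrom[li] if chrom is None else str(chrom)
    in_win = (
        (snp_panel.chrom == c)
        & (snp_panel.pos >= anchor - half_window)
        & (snp_panel.pos <= anchor + half_window)
    )
    window = [snp_panel.snp_ids[i] for i in np.flatnonzero(in_win)]
    y = np.asarray(protein_levels, dtype=float)
    obs = ~np.isnan(y)
    y = y[obs]

    selected = [lead_snp]
    sel_dos = [snp_panel.dosage[obs, li]]
    while True:
        best_snp, best_p = None, np.inf
        for s in window:
            if s in selected:
                continue
            d = snp_panel.dosage[obs, snp_panel.snp_index(s)]
            if d.var() == 0:
                continue
            if any(np.corrcoef(d, sd)[0, 1] ** 2 >= collinearity_r2 for sd in sel_dos):
                continue
            pvals, _, _ = _ols_stats(np.column_stack(sel_dos + [d]), y)
            p_cond = pvals[-1]
            if p_cond < best_p:
                best_p, best_snp = p_cond, s
        if best_snp is None or best_p >= p_threshold:
            break
        selected.append(best_snp)
        sel_dos.append(snp_panel.dosage[obs, snp_panel.snp_index(best_snp)])
    return selected


def cis_variance_explained(
    protein_levels: np.ndarray, snp_panel: SnpPanel, selected_snps: list
) -> float:
    """Adjusted R^2 of the protein on the selected dosages (0 if none)."""
    if not selected_snps:
        return 0.0
    y = np.asarray(protein_levels, dtype=float)
    obs = ~np.isnan(y)
    X = np.column_stack([snp_panel.dosage[obs, snp_panel.snp_index(s)] for s in selected_snps])
    _, _, adj = _ols_stats(X, y[obs])
    return float(adj)


def parental_cis_variance(
    target: str,
    target_levels: np.ndarray,
    snp_panel: SnpPanel,
    parent_snp_sets: dict,
    own_snp_set: list,
) -> CisVarianceResult:
    """Local versus local-plus-parental cis variance for one target protein.

    ``parent_snp_sets`` maps each parent regulator to its independent cis
    SNPs; the local component is 0 when the target has no cis pQTL of its
    own; delta is the difference of the two adjusted R^2 values.
    """
    r2_local = cis_variance_explained(target_levels, snp_panel, list(own_snp_set))
    parent_snps = sorted({s for snps in parent_snp_sets.values() for s in snps})
    union = sorted(set(own_snp_set) | set(parent_snps))
    r2_both = cis_variance_explained(target_levels, snp_panel, union) if union else 0.0
    return CisVarianceResult(
        protein=target,
        selected_snps=list(own_snp_set),
        r2_local=float(r2_local),
        r2_local_plus_parental=float(r2_both),
        delta=float(r2_both - r2_local),
        n_regulators=len(parent_snp_sets),
        parent_snps=parent_snps,
    )


def variance_vs_indegree(results: list[CisVarianceResult]):
    """Spearman correlation between in-degree and parental-cis delta.

    Returns (rho, p); (nan, nan) when either quantity is constant.
    """
    deg = np.array([r.n_regulators for r in results], dtype=float)
    delta = np.array([r.delta for r in results], dtype=float)
    if deg.size < 3 or np.ptp(deg) == 0 or np.ptp(delta) == 0:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(deg, delta)
    return float(rho), float(p)
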