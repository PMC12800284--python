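"""cis-pQTL mapping and lead-instrument selection.

For every protein, SNPs within a +/-150 kb window around the TSS of the
encoding gene are tested against the protein level by simple regression; the
window minimum p-value is Bonferroni-adjusted for the number of SNPs in the
window, q-values are computed across proteins with the Storey-Tibshirani
procedure, and proteins passing q <= 0.05 keep their lowest-p SNP as the
lead protein-regulatory SNP (pSNP), the instrumental variable for causal
testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthio import ProteinPanel, SnpPanel

logger = logging.getLogger(__name__)

__all__ = [
    "CisInstrument",
    "QValueFit",
    "map_cis_pqtls",
    "storey_qvalues",
    "select_lead_psnp",
    "find_instruments",
]


@dataclass
class CisInstrument:
    """A protein's lead cis instrument and its association statistics."""

    aptamer_id: str
    snp_id: str
    beta: float
    se: float
    p: float  # window-adjusted p-value
    q: float
    window: tuple  # (chrom, start, end), 1-based inclusive


@dataclass
class QValueFit:
    pi0: float
    lambda_grid: np.ndarray
    qvalues: np.ndarray


def _marginal_regression(dosage: np.ndarray, y: np.ndarray):
    """Vectorized per-SNP OLS of y on dosage (+ intercept): beta, se, p."""
    obs = ~np.isnan(y)
    y = y[obs]
    d = dosage[obs]
    n = y.size
    dc = d - d.mean(axis=0)
    yc = y - y.mean()
    ss_d = (dc**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = dc.T @ yc / ss_d
        rss = (yc**2).sum() - beta**2 * ss_d
        sigma2 = rss / (n - 2)
        se = np.sqrt(sigma2 / ss_d)
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isfinite(t), p, 1.0)
    return beta, se, p


def map_cis_pqtls(
    snp_panel: SnpPanel,
    protein_panel: ProteinPanel,
    half_window: int = 150_000,
) -> pd.DataFrame:
    """Per-protein cis-window association scan.

    Returns a tidy frame with one row per (protein, SNP in window) holding
    beta, se and the raw p, plus per-protein columns ``p_min`` and the
    Bonferroni window-adjusted ``p_adj = min(1, m * p_min)`` where m is the
    number of SNPs in the window. Proteins whose window holds no SNP are
    excluded with a log entry.
    """
    ann = protein_panel.annotation.set_index("aptamer_id")
    rows = []
    for j, apt in enumerate(protein_panel.aptamer_ids):
        chrom = str(ann.loc[apt, "chrom"])
        tss = int(ann.loc[apt, "tss"])
        lo, hi = tss - half_window, tss + half_window
        in_win = (snp_panel.chrom == chrom) & (snp_panel.pos >= lo) & (snp_panel.pos <= hi)
        m = int(in_win.sum())
        if m == 0:
            logger.info("protein %s: empty cis window [%s:%d-%d], excluded", apt, chrom, lo, hi)
            continue
        y = protein_panel.levels[:, j]
        beta, se, p = _marginal_regression(snp_panel.dosage[:, in_win], y)
        snp_idx = np.flatnonzero(in_win)
        p_min = float(p.min())
        for k, si in enumerate(snp_idx):
            rows.append(
                {
                    "aptamer_id": apt,
                    "snp_id": snp_panel.snp_ids[si],
                    "chrom": chrom,
                    "pos": int(snp_panel.pos[si]),
                    "beta": beta[k],
                    "se": se[k],
                    "p": p[k],
                    "m_window": m,
                    "p_min": p_min,
                    "p_adj": min(1.0, m * p_min),
                    "window_start": lo,
                    "window_end": hi,
                }
            )
    return pd.DataFrame(rows)


def storey_qvalues(p_values: np.ndarray, lambda_grid: np.ndarray | None = None) -> QValueFit:
    """Storey-Tibshirani q-values.

    pi0 is estimated on a lambda grid as #{p > lambda} / (m (1 - lambda)) and
    smoothed with a cubic polynomial evaluated at the largest lambda (the
    smoother-toward-1 device), clipped to [0, 1]; q_i is the usual running
    minimum of pi0 * m * p / rank over the sorted tail.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    if lambda_grid is None:
        lambda_grid = np.arange(0.05, 0.96, 0.05)
    m = p.size
    if m < 100:
        # grid estimate is unstable at small m; fall back to conservative pi0=1
        pi0 = 1.0
    else:
        pi0_l = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambda_grid])
        coef = np.polyfit(lambda_grid, pi0_l, deg=3)
        pi0 = float(np.polyval(coef, lambda_grid.max()))
        pi0 = float(np.clip(pi0, 0.0, 1.0))
        if pi0 == 0.0:
            pi0 = float(min(1.0, pi0_l.min())) or 1e-8
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return QValueFit(pi0=pi0, lambda_grid=lambda_grid, qvalues=q)


def select_lead_psnp(candidates: pd.DataFrame, q_threshold: float = 0.05) -> list[CisInstrument]:
    """Pick one lead pSNP per protein at the cross-protein q-value cut.

    Proteins with q <= q_threshold keep the SNP with the smallest raw p in
    their window; ties break to the smaller position, then the lexically
    smaller SNP id. Returns instruments sorted by aptamer id (possibly empty).
    """
    if candidates.empty:
        return []
    per_protein = candidates.drop_duplicates("aptamer_id")[["aptamer_id", "p_adj"]]
    fit = storey_qvalues(per_protein["p_adj"].to_numpy())
    qmap = dict(zip(per_protein["aptamer_id"], fit.qvalues))
    out = []
    for apt, grp in candidates.groupby("aptamer_id", sort=True):
        q = qmap[apt]
        if q > q_threshold:
            continue
        best = grp.sort_values(["p", "pos", "snp_id"], kind="stable").iloc[0]
        out.append(
            CisInstrument(
                aptamer_id=apt,
                snp_id=best["snp_id"],
                beta=float(best["beta"]),
                se=float(best["se"]),
                p=float(best["p_adj"]),
                q=float(q),
                window=(best["chrom"], int(best["window_start"]), int(best["window_end"])),
            )
        )
    return out


def find_instruments(
    snp_panel: SnpPanel,
    protein_panel: ProteinPanel,
    half_window: int = 150_000,
    q_threshold: float = 0.05,
) -> list[CisInstrument]:
    """Map cis windows and select lead pSNPs in one call."""
    cand = map_cis_pqtls(snp_panel, protein_panel, half_window)
    return select_lead_psnp(cand, q_threshold)
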