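"""Pairwise causal tests and posterior edge probabilities.

For an instrumented exposure protein A with lead pSNP genotype E and any
candidate target B, two nested-OLS log-likelihood ratios are computed on
rank-inverse-normal data:

* secondary linkage (P2): B ~ genotype-class means vs B ~ 1 — is E
  associated with B at all (which, for a valid instrument, can only happen
  through A);
* controlled test (P5): B ~ genotype-class means + shared slope on A vs
  B ~ genotype-class means — do A and B stay dependent after adjusting for
  E, excluding the case where E affects both independently.

Each LLR has an exact finite-sample null (a Beta law on the incremental
R^2), the resulting p-values are pooled per test family and converted to
posterior probabilities of the alternative with an empirical-null local-FDR
fit, and the edge score is the product PP = PP2 * PP5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from .pqtl import CisInstrument, storey_qvalues
from .synthio import ProteinPanel, SnpPanel

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeScore",
    "PosteriorFit",
    "genotype_classes",
    "pairwise_llrs",
    "llr_to_pvalue",
    "fit_posterior",
    "score_all_pairs",
]

_DENSITY_CAP = 1e300


@dataclass
class EdgeScore:
    a_aptamer: str
    b_aptamer: str
    llr2: float
    llr5: float
    p2: float
    p5: float
    pp2: float
    pp5: float

    @property
    def pp(self) -> float:
        return self.pp2 * self.pp5


def genotype_classes(e_dosage: np.ndarray, min_class_size: int = 2) -> np.ndarray:
    """Round dosage to {0,1,2} and merge classes with < min_class_size samples
    into their nearest neighbouring class. Raises if only one class remains."""
    g = np.clip(np.rint(np.asarray(e_dosage, dtype=float)), 0, 2).astype(int)
    # merge sparse classes: 0 into 1, 2 into 1, then 1 into whichever remains
    for cls, repl in ((0, 1), (2, 1)):
        n_cls = (g == cls).sum()
        if 0 < n_cls < min_class_size:
            g[g == cls] = repl
    counts = {c: (g == c).sum() for c in np.unique(g)}
    if 1 in counts and counts[1] < min_class_size and len(counts) > 1:
        others = [c for c in counts if c != 1]
        g[g == 1] = others[0]
    if np.unique(g).size < 2:
        raise ValueError("invalid instrument: genotype is monomorphic after class merging")
    return g


def pairwise_llrs(
    e_dosage: np.ndarray, a_levels: np.ndarray, b_levels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int]:
    """Secondary-linkage and controlled LLRs (nats) for one A against B.

    ``b_levels`` may be a vector or a samples x targets matrix; the return is
    (llr2, llr5, k) with k the number of genotype classes used. The genotype
    enters as a categorical with per-class means of B; the controlled model
    adds one shared linear coefficient on A.
    """
    g = genotype_classes(e_dosage)
    B = np.atleast_2d(np.asarray(b_levels, dtype=float).T).T  # n x t
    a = np.asarray(a_levels, dtype=float)
    n = a.size
    classes = np.unique(g)
    k = classes.size

    onehot = (g[:, None] == classes[None, :]).astype(float)  # n x k
    cls_n = onehot.sum(axis=0)

    Bc = B - B.mean(axis=0)
    rss0 = (Bc**2).sum(axis=0)
    cls_means_b = (onehot.T @ B) / cls_n[:, None]  # k x t
    resid_b = B - onehot @ cls_means_b
    rss_e = (resid_b**2).sum(axis=0)

    a_mean_cls = (onehot.T @ a) / cls_n
    resid_a = a - onehot @ a_mean_cls
    ss_a = (resid_a**2).sum()
    if ss_a <= 0:
        # A perfectly determined by genotype classes: controlled slope undefined
        rss_ea = rss_e
    else:
        cross = resid_a @ resid_b
        rss_ea = rss_e - cross**2 / ss_a

    with np.errstate(divide="ignore", invalid="ignore"):
        llr2 = 0.5 * n * np.log(np.maximum(rss0, 1e-300) / np.maximum(rss_e, 1e-300))
        llr5 = 0.5 * n * np.log(np.maximum(rss_e, 1e-300) / np.maximum(rss_ea, 1e-300))
    llr2 = np.maximum(llr2, 0.0)
    llr5 = np.maximum(llr5, 0.0)
    if np.ndim(b_levels) == 1:
        return float(llr2[0]), float(llr5[0]), k
    return llr2, llr5, k


def llr_to_pvalue(llr, n: int, df_extra: int, df_full: int):
    """Exact null p-value for a nested-OLS LLR.

    Under the Gaussian null, the incremental R^2 = 1 - exp(-2 llr / n) of the
    wider model follows Beta(df_extra/2, (n - df_full)/2); the p-value is its
    survival function. Exactness (not just the chi-square asymptote) matters
    because the posterior fit pools millions of p-values into its tails.
    """
    llr_arr = np.asarray(llr, dtype=float)
    if np.any(llr_arr < 0):
        raise ValueError("llr must be non-negative")
    if n <= df_full:
        raise ValueError(f"need n > df_full, got n={n}, df_full={df_full}")
    r2 = -np.expm1(-2.0 * llr_arr / n)
    p = stats.beta.sf(r2, df_extra / 2.0, (n - df_full) / 2.0)
    return p if np.ndim(llr) else float(p)


@dataclass
class PosteriorFit:
    """Monotone map p -> PP(alternative) from a pooled p-value family.

    The p-value density is estimated on quantile chunks of the order
    statistics, regularized to be non-increasing (isotonic / Grenander
    style), and converted to a local-FDR posterior
    PP(p) = clip(1 - pi0 / f(p), 0, 1).
    """

    pi0: float
    edges: np.ndarray  # chunk upper edges, ascending; implicit lower edge 0
    density: np.ndarray  # fitted non-increasing density per chunk
    pp: np.ndarray  # posterior per chunk

    def __call__(self, p_values) -> np.ndarray:
        p = np.asarray(p_values, dtype=float)
        idx = np.searchsorted(self.edges, p, side="left")
        out = np.where(idx < self.pp.size, self.pp[np.minimum(idx, self.pp.size - 1)], 0.0)
        return out


def fit_posterior(
    p_values: np.ndarray, min_pvalues: int = 1000, chunk: int = 20, shrink_alpha: float = 0.001
) -> PosteriorFit:
    """Fit the local-FDR posterior map from a pooled family of p-values.

    The density is measured on order-statistic chunks of ``chunk`` p-values.
    Each chunk's count is shrunk to its lower Poisson confidence bound at
    level ``shrink_alpha`` before forming the density, so a lone null
    fluctuation in a narrow tail chunk (observed/expected of a few at count
    20) cannot mimic signal, while genuine signal chunks — whose densities
    exceed the null by orders of magnitude — are barely attenuated.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    m = p.size
    if m < min_pvalues:
        raise ValueError(
            f"need >= {min_pvalues} p-values to fit the posterior (got {m}); "
            "pool families across pairs"
        )
    pi0 = storey_qvalues(p).pi0
    p_sorted = np.sort(p)
    k = chunk
    n_chunks = max(1, m // k)
    bounds = [min(i * k, m) for i in range(1, n_chunks)] + [m]
    edges, counts = [], []
    prev_idx = 0
    for b in bounds:
        e = p_sorted[b - 1]
        edges.append(e)
        counts.append(b - prev_idx)
        prev_idx = b
    edges = np.asarray(edges)
    counts = np.asarray(counts, dtype=float)
    widths = np.diff(np.concatenate([[0.0], edges]))
    with np.errstate(divide="ignore", over="ignore"):
        density = np.where(widths > 0, counts / (m * np.maximum(widths, 1e-320)), _DENSITY_CAP)
    density = np.minimum(density, _DENSITY_CAP)
    if density.size > 1:
        iso = IsotonicRegression(increasing=False)
        # weight by width so wide (well-populated) chunks dominate the fit
        density = iso.fit_transform(
            np.arange(density.size), density, sample_weight=np.maximum(widths, 1e-320)
        )
    # shrink each isotonic block by the lower Poisson confidence bound of its
    # pooled count: pooled moderate-density regions (thousands of p-values)
    # keep their graded level, an isolated narrow fluctuation does not
    block_id = np.concatenate([[0], np.cumsum(np.diff(density) != 0)])
    block_counts = np.bincount(block_id, weights=counts)
    theta = stats.gamma.ppf(shrink_alpha, block_counts) / np.maximum(block_counts, 1e-320)
    density = density * theta[block_id]
    with np.errstate(divide="ignore", invalid="ignore"):
        pp = 1.0 - pi0 / np.maximum(density, 1e-320)
    pp = np.clip(pp, 0.0, 1.0)
    pp = np.minimum.accumulate(pp)  # guard monotonicity against numerics
    return PosteriorFit(pi0=float(pi0), edges=edges, density=density, pp=pp)


def score_all_pairs(
    instruments: list[CisInstrument],
    protein_panel: ProteinPanel,
    snp_panel: SnpPanel,
) -> pd.DataFrame:
    """EdgeScore table for every instrumented A x every other protein B.

    LLR p-values are pooled across all pairs separately for the P2 and P5
    families before the posterior fit; the final score is pp = pp2 * pp5.
    """
    apts = protein_panel.aptamer_ids
    levels = protein_panel.levels
    col = {a: j for j, a in enumerate(apts)}

    rows_a, rows_b, llr2_all, llr5_all = [], [], [], []
    p2_all, p5_all = [], []
    n = protein_panel.n_samples
    for inst in instruments:
        if inst.aptamer_id not in col:
            continue
        ja = col[inst.aptamer_id]
        e = snp_panel.dosage[:, snp_panel.snp_index(inst.snp_id)]
        try:
            b_idx = [j for j in range(len(apts)) if j != ja]
            llr2, llr5, k = pairwise_llrs(e, levels[:, ja], levels[:, b_idx])
        except ValueError as err:
            logger.warning("skipping instrument for %s: %s", inst.aptamer_id, err)
            continue
        p2 = llr_to_pvalue(llr2, n, df_extra=k - 1, df_full=k)
        p5 = llr_to_pvalue(llr5, n, df_extra=1, df_full=k + 1)
        rows_a.extend([inst.aptamer_id] * len(b_idx))
        rows_b.extend([apts[j] for j in b_idx])
        llr2_all.append(llr2)
        llr5_all.append(llr5)
        p2_all.append(p2)
        p5_all.append(p5)

    if not rows_a:
        return pd.DataFrame(
            columns=["a", "b", "llr2", "llr5", "p2", "p5", "pp2", "pp5", "pp"]
        )
    p2 = np.concatenate(p2_all)
    p5 = np.concatenate(p5_all)
    fit2 = fit_posterior(p2)
    fit5 = fit_posterior(p5)
    pp2 = fit2(p2)
    pp5 = fit5(p5)
    return pd.DataFrame(
        {
            "a": rows_a,
            "b": rows_b,
            "llr2": np.concatenate(llr2_all),
            "llr5": np.concatenate(llr5_all),
            "p2": p2,
            "p5": p5,
            "pp2": pp2,
            "pp5": pp5,
            "pp": pp2 * pp5,
        }
    )
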