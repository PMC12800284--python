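"""Protein-matrix preprocessing.

Order of operations in the standard pipeline: per-aptamer Box-Cox with
maximum-likelihood lambda followed by center/scale to z-units, a single
global outlier threshold derived from per-aptamer percentile cutoffs,
per-aptamer linear adjustment for age and sex, and a rank-based
inverse-normal transform applied immediately before causal testing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

from .synthio import CovariateTable, ProteinPanel

__all__ = [
    "boxcox_standardize",
    "flag_outliers",
    "adjust_covariates",
    "rank_inverse_normal",
    "preprocess_panel",
]


def boxcox_standardize(panel: ProteinPanel, shift_nonpositive: bool = True) -> ProteinPanel:
    """Per-aptamer Box-Cox (ML lambda) then center/scale to mean 0, sd 1.

    Columns with nonpositive values are shifted by c = 1 - min(x) before the
    transform when ``shift_nonpositive`` is set. Constant columns cannot be
    transformed; they are left centered at 0 and recorded in
    ``panel.annotation["constant_flag"]``.
    """
    out = panel.copy()
    p = out.n_aptamers
    constant = np.zeros(p, dtype=bool)
    lambdas = np.full(p, np.nan)
    for j in range(p):
        x = out.levels[:, j]
        obs = ~np.isnan(x)
        v = x[obs]
        if v.size == 0 or np.ptp(v) == 0:
            constant[j] = True
            out.levels[obs, j] = 0.0
            continue
        if v.min() <= 0:
            if not shift_nonpositive:
                raise ValueError(f"nonpositive values in column {out.aptamer_ids[j]}")
            v = v + (1.0 - v.min())
        t, lam = stats.boxcox(v)
        lambdas[j] = lam
        t = (t - t.mean()) / t.std()
        out.levels[obs, j] = t
    ann = out.annotation.set_index("aptamer_id")
    ann["constant_flag"] = pd.Series(constant, index=out.aptamer_ids)
    ann["boxcox_lambda"] = pd.Series(lambdas, index=out.aptamer_ids)
    out.annotation = ann.reset_index()
    return out


def flag_outliers(
    panel: ProteinPanel, protein_pct: float = 99.0, global_pct: float = 99.5
) -> np.ndarray:
    """Global upper-tail outlier rule.

    Each aptamer's ``protein_pct`` percentile is computed; the ``global_pct``
    percentile of that distribution of cutoffs becomes one global threshold,
    and every value above it is flagged (returned as a boolean mask, True =
    outlier). Operates on the already-standardized matrix so the cutoffs are
    comparable across aptamers.
    """
    if panel.levels.size == 0:
        return np.zeros_like(panel.levels, dtype=bool)
    cutoffs = np.nanpercentile(panel.levels, protein_pct, axis=0)
    threshold = np.nanpercentile(cutoffs, global_pct)
    with np.errstate(invalid="ignore"):
        return panel.levels > threshold


def apply_mask(panel: ProteinPanel, mask: np.ndarray) -> ProteinPanel:
    """Return a copy with masked entries set to NaN."""
    out = panel.copy()
    out.levels[mask] = np.nan
    return out


def adjust_covariates(panel: ProteinPanel, covariates: CovariateTable) -> ProteinPanel:
    """Per-aptamer OLS residuals of level ~ 1 + age + sex.

    Missing entries are propagated. Raises on a rank-deficient design, naming
    the offending covariate.
    """
    if list(covariates.table.index) != list(panel.sample_ids):
        covariates = CovariateTable(covariates.table.loc[panel.sample_ids])
    D = covariates.design()
    for name, col in (("age", D[:, 1]), ("sex", D[:, 2])):
        if np.ptp(col[~np.isnan(col)]) == 0:
            raise ValueError(f"covariate {name!r} is constant: design is rank-deficient")
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("covariate design is rank-deficient (age/sex collinear)")
    out = panel.copy()
    for j in range(out.n_aptamers):
        y = out.levels[:, j]
        obs = ~np.isnan(y)
        if obs.sum() < 4:
            continue
        beta, *_ = np.linalg.lstsq(D[obs], y[obs], rcond=None)
        out.levels[obs, j] = y[obs] - D[obs] @ beta
    return out


def rank_inverse_normal(x: np.ndarray, offset: float = 0.5) -> np.ndarray:
    """Map values to normal quantiles of their ranks.

    value_i = Phi^-1((rank_i - offset) / n) over the non-missing entries,
    with ties sharing their average rank; NaNs are propagated. The default
    offset 0.5 is the (r - 0.5)/n convention; Blom's (r - 3/8)/(n + 1/4) is
    available via offset="blom".
    """
    x = np.asarray(x, dtype=float)
    out = np.full_like(x, np.nan)
    obs = ~np.isnan(x)
    n = int(obs.sum())
    if n < 3:
        raise ValueError(f"need >= 3 non-missing values, got {n}")
    ranks = stats.rankdata(x[obs], method="average")
    if offset == "blom":
        q = (ranks - 0.375) / (n + 0.25)
    else:
        q = (ranks - offset) / n
    out[obs] = special.ndtri(q)
    return out


def rank_inverse_normal_panel(panel: ProteinPanel, fill_missing: bool = True) -> ProteinPanel:
    """Rank-inverse-normal transform each aptamer column.

    With ``fill_missing`` the NaNs left by the outlier rule are set to 0 (the
    post-transform mean) so downstream matrix operations see complete data.
    """
    out = panel.copy()
    for j in range(out.n_aptamers):
        col = out.levels[:, j]
        if np.isnan(col).all() or np.nanmax(col) == np.nanmin(col):
            continue
        out.levels[:, j] = rank_inverse_normal(col)
    if fill_missing:
        out.levels[np.isnan(out.levels)] = 0.0
    return out


def preprocess_panel(
    panel: ProteinPanel,
    covariates: CovariateTable,
    boxcox: bool = True,
    outlier_protein_pct: float = 99.0,
    outlier_global_pct: float = 99.5,
    rank_transform: bool = True,
) -> ProteinPanel:
    """Full preprocessing chain used by the pipeline."""
    out = boxcox_standardize(panel) if boxcox else panel.copy()
    mask = flag_outliers(out, outlier_protein_pct, outlier_global_pct)
    out = apply_mask(out, mask)
    out = adjust_covariates(out, covariates)
    if rank_transform:
        out = rank_inverse_normal_panel(out)
    out.latent = panel.latent
    return out
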