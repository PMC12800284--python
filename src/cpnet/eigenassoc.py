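"""Eigenproteins, trait association models, and subnetwork ranking.

An eigenprotein is the first principal component of a subnetwork's member
profiles (regulator plus targets), valid when PC1 explains more than 15% of
the member variance, sign-oriented to correlate positively with the
regulator's own level. Associations with traits use linear regression
(continuous), logistic regression (prevalent) or Cox proportional hazards
(incident), always adjusted for age and sex. Subnetworks are ranked per
trait: +1 if the regulator passes BH FDR < 0.05 within the regulator/trait
family, +1 if the (valid) eigenprotein passes a fixed Bonferroni-style
threshold; the total over six traits flags top subnetworks at >= 7.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import stats
from sklearn.decomposition import PCA

from .netbuild import Subnetwork
from .synthio import CovariateTable, PhenotypeTable, ProteinPanel

__all__ = [
    "Eigenprotein",
    "AssociationResult",
    "RankScore",
    "compute_eigenprotein",
    "associate",
    "associate_all",
    "bh_fdr",
    "rank_networks",
    "score_rank_table",
    "baseline_table",
]


@dataclass
class Eigenprotein:
    subnetwork: str
    scores: np.ndarray  # standardized PC1 projection per sample
    loadings: np.ndarray
    variance_fraction: float
    valid: bool


@dataclass
class AssociationResult:
    unit: str  # "regulator" | "eigenprotein"
    name: str
    trait: str
    model: str  # "linear" | "logistic" | "cox"
    estimate: float
    se: float
    p: float
    converged: bool = True
    note: str = ""


@dataclass
class RankScore:
    subnetwork: str
    sub_scores: dict  # trait -> 0/1/2
    total: int
    top_ranked: bool


def compute_eigenprotein(
    subnetwork: Subnetwork,
    panel: ProteinPanel,
    variance_threshold: float = 0.15,
    include_regulator: bool = True,
) -> Eigenprotein:
    """PC1 of the standardized member matrix; valid iff its variance fraction
    strictly exceeds the threshold. The score's sign is flipped when its
    correlation with the regulator level is negative, and scores are
    standardized."""
    members = sorted(subnetwork.targets)
    if include_regulator:
        members = sorted(subnetwork.members)
    col = {a: j for j, a in enumerate(panel.aptamer_ids)}
    idx = [col[m] for m in members if m in col]
    if len(idx) < 2:
        raise ValueError(f"subnetwork {subnetwork.regulator} has < 2 members with data")
    X = panel.levels[:, idx]
    sd = X.std(axis=0)
    if np.all(sd == 0):
        raise ValueError("all member profiles are constant")
    keep = sd > 0
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    pca = PCA(n_components=1)
    scores = pca.fit_transform(X)[:, 0]
    var_frac = float(pca.explained_variance_ratio_[0])
    loadings = pca.components_[0]
    if subnetwork.regulator in col:
        reg = panel.levels[:, col[subnetwork.regulator]]
        r = np.corrcoef(scores, reg)[0, 1]
        if np.isfinite(r) and r < 0:
            scores, loadings = -scores, -loadings
    scores = (scores - scores.mean()) / scores.std()
    return Eigenprotein(
        subnetwork=subnetwork.regulator,
        scores=scores,
        loadings=loadings,
        variance_fraction=var_frac,
        valid=bool(var_frac > variance_threshold),
    )


def _trait_arrays(phenotypes: PhenotypeTable, trait: str):
    kind = phenotypes.trait_spec[trait]
    t = phenotypes.table
    if kind == "incident":
        return kind, t[f"time_{trait}"].to_numpy(float), t[f"event_{trait}"].to_numpy(int)
    return kind, t[trait].to_numpy(float), None


def associate(
    x: np.ndarray,
    phenotypes: PhenotypeTable,
    trait: str,
    covariates: CovariateTable,
    unit: str = "regulator",
    name: str = "",
) -> AssociationResult:
    """Age- and sex-adjusted association of one exposure with one trait.

    Continuous traits: OLS with Wald p; prevalent: logistic regression;
    incident: Cox partial likelihood with Efron tie handling. Non-convergence
    or separation yields a flagged (converged=False) result rather than an
    exception.
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x[~np.isnan(x)]) == 0:
        raise ValueError("exposure has no variance")
    kind, y, event = _trait_arrays(phenotypes, trait)
    age, sex = covariates.age, covariates.sex
    obs = ~np.isnan(x) & ~np.isnan(y)
    model_name = {"continuous": "linear", "prevalent": "logistic", "incident": "cox"}[kind]
    try:
        if kind == "continuous":
            X = sm.add_constant(np.column_stack([x[obs], age[obs], sex[obs]]))
            fit = sm.OLS(y[obs], X).fit()
            est, se, p = fit.params[1], fit.bse[1], fit.pvalues[1]
            conv, note = True, ""
        elif kind == "prevalent":
            X = sm.add_constant(np.column_stack([x[obs], age[obs], sex[obs]]))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y[obs], X).fit(disp=0, maxiter=100)
            est, se, p = fit.params[1], fit.bse[1], fit.pvalues[1]
            conv = bool(fit.mle_retvals.get("converged", True)) and np.isfinite(se)
            note = "" if conv else "logistic fit did not converge (possible separation)"
        else:
            df = pd.DataFrame(
                {"time": y[obs], "event": event[obs], "x": x[obs], "age": age[obs], "sex": sex[obs]}
            )
            cph = CoxPHFitter()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time", event_col="event")  # Efron ties (default)
            est = float(cph.params_["x"])
            se = float(cph.standard_errors_["x"])
            p = float(cph.summary.loc["x", "p"])
            conv, note = True, ""
    except Exception as err:  # flagged, not fatal: pipelines fit thousands of these
        return AssociationResult(unit, name, trait, model_name, np.nan, np.nan, 1.0, False, str(err))
    return AssociationResult(unit, name, trait, model_name, float(est), float(se), float(p), conv, note)


def associate_all(
    exposures: dict,
    phenotypes: PhenotypeTable,
    covariates: CovariateTable,
    unit: str,
    traits: list | None = None,
) -> pd.DataFrame:
    """Associate every named exposure vector with every trait; tidy frame."""
    traits = traits if traits is not None else phenotypes.trait_names()
    rows = []
    for name, x in exposures.items():
        for trait in traits:
            r = associate(x, phenotypes, trait, covariates, unit=unit, name=name)
            rows.append(dataclasses_to_row(r))
    return pd.DataFrame(rows)


def dataclasses_to_row(r: AssociationResult) -> dict:
    return {
        "unit": r.unit,
        "name": r.name,
        "trait": r.trait,
        "model": r.model,
        "estimate": r.estimate,
        "se": r.se,
        "p": r.p,
        "converged": r.converged,
        "note": r.note,
    }


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out


def rank_networks(
    regulator_results: pd.DataFrame,
    eigen_results: pd.DataFrame,
    eigen_valid: dict,
    traits: list,
    reg_fdr: float = 0.05,
    eigen_p_threshold: float = 0.00027,
    eigen_rule: str = "fixed",
    top_cut: int = 7,
) -> list[RankScore]:
    """Per-trait 0/1/2 sub-scores and the total ranking score.

    For each trait: +1 when the regulator association passes BH FDR <
    ``reg_fdr`` within the regulator x trait family (adjusted across
    subnetworks per trait); +1 when the subnetwork's eigenprotein is valid
    and significant — under the canonical ``eigen_rule="fixed"`` its raw p
    must fall below ``eigen_p_threshold``, under ``eigen_rule="bh"`` its BH
    FDR within the eigenprotein x trait family must fall below ``reg_fdr``.
    Missing results count as non-significant. Total >= ``top_cut`` flags the
    subnetwork top-ranked.
    """
    def per_trait_bh(results: pd.DataFrame) -> pd.DataFrame:
        out = results.copy()
        out["fdr_bh"] = np.nan
        for trait in traits:
            mask = out["trait"] == trait
            if mask.any():
                out.loc[mask, "fdr_bh"] = bh_fdr(out.loc[mask, "p"].to_numpy())
        return out

    reg = per_trait_bh(regulator_results)
    reg_sig = {
        (r["name"], r["trait"]): bool(r["fdr_bh"] < reg_fdr) for _, r in reg.iterrows()
    }
    if eigen_rule == "fixed":
        eig_sig = {
            (r["name"], r["trait"]): bool(
                r["p"] < eigen_p_threshold and eigen_valid.get(r["name"], False)
            )
            for _, r in eigen_results.iterrows()
        }
    elif eigen_rule == "bh":
        eig = per_trait_bh(eigen_results)
        eig_sig = {
            (r["name"], r["trait"]): bool(
                r["fdr_bh"] < reg_fdr and eigen_valid.get(r["name"], False)
            )
            for _, r in eig.iterrows()
        }
    else:
        raise ValueError(f"unknown eigen_rule {eigen_rule!r}")
    out = []
    for name in sorted(reg["name"].unique()):
        subs = {}
        for trait in traits:
            s = int(reg_sig.get((name, trait), False)) + int(eig_sig.get((name, trait), False))
            subs[trait] = s
        total = sum(subs.values())
        out.append(RankScore(name, subs, total, total >= top_cut))
    return out


def score_rank_table(sub_scores: pd.DataFrame, top_cut: int = 7) -> pd.DataFrame:
    """Total and top-ranked flag from an already-scored sub-score table.

    ``sub_scores`` has one row per subnetwork and one 0/1/2 column per trait
    (index = subnetwork name). Used to re-score published ranking tables.
    """
    bad = ~sub_scores.isin([0, 1, 2]).all(axis=None)
    if bad:
        raise ValueError("sub-scores must be 0, 1 or 2")
    out = sub_scores.copy()
    out["total"] = sub_scores.sum(axis=1).astype(int)
    out["top_ranked"] = out["total"] >= top_cut
    return out


def baseline_table(
    variables: pd.DataFrame,
    group: np.ndarray,
    categorical: list | None = None,
    skewed: list | None = None,
) -> pd.DataFrame:
    """Two-group baseline characteristics table.

    Continuous variables are summarized as mean (SD) with a two-sample
    t-test, or median [IQR] with a Wilcoxon rank-sum test when flagged
    skewed; categorical variables as N (%) with a chi-square test. Two-sided
    p-values throughout.
    """
    categorical = set(categorical or [])
    skewed = set(skewed or [])
    group = np.asarray(group).astype(bool)
    rows = []
    for var in variables.columns:
        x = variables[var]
        g0, g1 = x[~group], x[group]
        if var in categorical:
            tab = pd.crosstab(x, group)
            if tab.shape[0] < 2 or tab.shape[1] < 2:
                p = 1.0
            else:
                p = float(stats.chi2_contingency(tab.to_numpy())[1])
            summ0 = f"{int((g0 == 1).sum())} ({100 * (g0 == 1).mean():.1f}%)"
            summ1 = f"{int((g1 == 1).sum())} ({100 * (g1 == 1).mean():.1f}%)"
            kind = "categorical"
        elif var in skewed:
            p = float(stats.mannwhitneyu(g0.dropna(), g1.dropna(), alternative="two-sided")[1])
            q0 = g0.quantile([0.5, 0.25, 0.75]).to_numpy()
            q1 = g1.quantile([0.5, 0.25, 0.75]).to_numpy()
            summ0 = f"{q0[0]:.2f} [{q0[1]:.2f}, {q0[2]:.2f}]"
            summ1 = f"{q1[0]:.2f} [{q1[1]:.2f}, {q1[2]:.2f}]"
            kind = "skewed"
        else:
            p = float(stats.ttest_ind(g0.dropna(), g1.dropna(), equal_var=False)[1])
            summ0 = f"{g0.mean():.2f} ({g0.std():.2f})"
            summ1 = f"{g1.mean():.2f} ({g1.std():.2f})"
            kind = "continuous"
        rows.append(
            {"variable": var, "kind": kind, "group0": summ0, "group1": summ1, "p": p}
        )
    return pd.DataFrame(rows)
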