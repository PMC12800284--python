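"""Seeded synthetic cohorts with a known causal protein network.

This module generates everything the inference pipeline consumes: genotype
dosages with local LD structure, a sparse directed acyclic ground-truth
network among proteins with heavy-tailed out-degrees, protein levels from a
linear structural model with cis-genetic control, shared hidden confounders
and covariate effects, and downstream phenotypes (continuous, prevalent
binary, incident time-to-event with censoring).

All outputs are pure functions of their parameters and the seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SnpPanel",
    "ProteinPanel",
    "CovariateTable",
    "PhenotypeTable",
    "SimTruth",
    "simulate_genotypes",
    "simulate_truth_network",
    "simulate_proteins",
    "simulate_phenotypes",
    "simulate_cohort",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class SnpPanel:
    """Genotype dosages (samples x SNPs) with per-SNP map information.

    ``dosage`` holds values in [0, 2]; ``maf`` is the generating minor-allele
    frequency in (0, 0.5]. Positions are 1-based and strictly increasing
    within each chromosome.
    """

    sample_ids: list
    snp_ids: list
    chrom: np.ndarray
    pos: np.ndarray
    dosage: np.ndarray
    maf: np.ndarray
    instrument_snps: list = field(default_factory=list)  # designated per-locus lead SNPs

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def snp_index(self, snp_id: str) -> int:
        return self.snp_ids.index(snp_id)

    def dosage_df(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.sample_ids, columns=self.snp_ids)

    def validate(self) -> None:
        if self.dosage.min() < 0 or self.dosage.max() > 2:
            raise ValueError("dosage values outside [0, 2]")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on chrom {c}")


@dataclass
class ProteinPanel:
    """Samples x aptamers level matrix with per-aptamer annotation.

    ``annotation`` must cover every aptamer with columns
    ``aptamer_id, gene, chrom, tss``. Missing values are NaN in ``levels``.
    """

    sample_ids: list
    aptamer_ids: list
    levels: np.ndarray
    annotation: pd.DataFrame
    latent: np.ndarray | None = None  # standardized structural signal (simulation only)

    @property
    def n_samples(self) -> int:
        return self.levels.shape[0]

    @property
    def n_aptamers(self) -> int:
        return self.levels.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.levels)

    def levels_df(self) -> pd.DataFrame:
        return pd.DataFrame(self.levels, index=self.sample_ids, columns=self.aptamer_ids)

    def copy(self) -> "ProteinPanel":
        return ProteinPanel(
            list(self.sample_ids),
            list(self.aptamer_ids),
            self.levels.copy(),
            self.annotation.copy(),
            None if self.latent is None else self.latent.copy(),
        )

    def validate(self) -> None:
        missing = set(self.aptamer_ids) - set(self.annotation["aptamer_id"])
        if missing:
            raise ValueError(f"annotation missing for {sorted(missing)[:5]} ...")


@dataclass
class CovariateTable:
    """Per-sample age (years) and sex (binary; 1 = female)."""

    table: pd.DataFrame  # index = sample ids, columns: age, sex

    @property
    def age(self) -> np.ndarray:
        return self.table["age"].to_numpy(float)

    @property
    def sex(self) -> np.ndarray:
        return self.table["sex"].to_numpy(float)

    def design(self) -> np.ndarray:
        """Intercept + age + sex design matrix."""
        n = len(self.table)
        return np.column_stack([np.ones(n), self.age, self.sex])


@dataclass
class PhenotypeTable:
    """Traits per sample; incident traits carry time_<name>/event_<name> columns.

    ``trait_spec`` maps trait name -> "continuous" | "prevalent" | "incident".
    """

    table: pd.DataFrame
    trait_spec: dict

    def trait_names(self, kind: str | None = None) -> list:
        if kind is None:
            return list(self.trait_spec)
        return [t for t, k in self.trait_spec.items() if k == kind]


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort.

    ``true_edges`` is a list of (parent aptamer, child aptamer, beta) on the
    standardized-protein scale and forms a DAG by construction.
    """

    true_edges: list
    regulators: list
    cis_effects: pd.DataFrame  # aptamer, snp_id, h2_target, gamma, h2_realized
    phenotype_effects: dict  # trait -> {"type": ..., "effects": {aptamer: coef}}
    confounder_loadings: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    def edge_set(self) -> set:
        return {(a, b) for a, b, _ in self.true_edges}

    def targets_of(self, regulator: str) -> set:
        return {b for a, b, _ in self.true_edges if a == regulator}

    def topological_order(self, aptamer_ids: list) -> list:
        # proteins are generated in index order, which is a topological order
        return list(aptamer_ids)

    def adjacency(self, aptamer_ids: list, mode: str = "ancestor") -> pd.DataFrame:
        """Boolean adjacency over aptamers.

        mode="direct" marks only structural edges; mode="ancestor" marks every
        (A, B) with a directed path A -> ... -> B, i.e. every pair with a
        nonzero total causal effect — the appropriate positive set when scoring
        a method that detects total (direct plus mediated) effects.
        """
        idx = {a: i for i, a in enumerate(aptamer_ids)}
        n = len(aptamer_ids)
        adj = np.zeros((n, n), dtype=bool)
        for a, b, _ in self.true_edges:
            adj[idx[a], idx[b]] = True
        if mode == "ancestor":
            reach = adj.copy()
            # proteins are indexed in topological order: sweep once backwards
            for i in range(n - 1, -1, -1):
                for j in np.flatnonzero(reach[i]):
                    reach[i] |= reach[j]
            adj = reach
        elif mode != "direct":
            raise ValueError(f"unknown adjacency mode {mode!r}")
        return pd.DataFrame(adj, index=aptamer_ids, columns=aptamer_ids)


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(
    n_samples: int,
    n_loci: int,
    snps_per_locus: int = 5,
    maf_range: tuple = (0.05, 0.5),
    ld_rho: float = 0.6,
    seed: int = 0,
    n_chromosomes: int = 22,
    locus_spacing: int = 1_000_000,
    snp_spacing: int = 5_000,
) -> SnpPanel:
    """Hardy-Weinberg genotypes with Markov-chain LD within each locus.

    Each locus carries ``snps_per_locus`` SNPs sharing one MAF drawn from
    ``maf_range``; adjacent SNPs on a haplotype have Pearson allele
    correlation ``ld_rho`` (a first-order Markov chain), so adjacent dosages
    have correlation ~ ld_rho and r^2 ~ ld_rho^2. The middle SNP of each locus
    is designated the causal instrument candidate. Loci are spaced
    ``locus_spacing`` bp apart so +/-150 kb cis windows never overlap.
    """
    if n_samples < 2 or n_loci < 0 or snps_per_locus < 1:
        raise ValueError("n_samples must be >= 2 and counts non-negative")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must lie in (0, 0.5], got {maf_range}")
    if not (0 <= ld_rho < 1):
        raise ValueError(f"ld_rho must be in [0, 1), got {ld_rho}")

    rng = np.random.default_rng(seed)
    sample_ids = [f"S{i:05d}" for i in range(n_samples)]

    mafs = rng.uniform(lo, hi, size=n_loci)
    loci_per_chrom = -(-n_loci // n_chromosomes) if n_loci else 1

    snp_ids, chrom, pos, maf_out, instruments = [], [], [], [], []
    dosages = np.empty((n_samples, n_loci * snps_per_locus))
    col = 0
    for locus in range(n_loci):
        p = mafs[locus]
        c = locus // loci_per_chrom + 1
        within = locus % loci_per_chrom
        base = 1_000_000 + within * locus_spacing
        # two haplotypes per sample, Markov chain over SNPs in the locus
        hap = np.empty((2, n_samples, snps_per_locus))
        hap[:, :, 0] = rng.random((2, n_samples)) < p
        for k in range(1, snps_per_locus):
            prev = hap[:, :, k - 1]
            p_cond = np.where(prev == 1, p + ld_rho * (1 - p), p * (1 - ld_rho))
            hap[:, :, k] = rng.random((2, n_samples)) < p_cond
        dosages[:, col : col + snps_per_locus] = hap.sum(axis=0)
        lead = snps_per_locus // 2
        for k in range(snps_per_locus):
            sid = f"rs{locus:05d}_{k}"
            snp_ids.append(sid)
            chrom.append(str(c))
            pos.append(base + k * snp_spacing)
            maf_out.append(p)
            if k == lead:
                instruments.append(sid)
        col += snps_per_locus

    panel = SnpPanel(
        sample_ids,
        snp_ids,
        np.array(chrom),
        np.array(pos, dtype=int),
        dosages,
        np.array(maf_out),
        instruments,
    )
    panel.validate()
    return panel


# ---------------------------------------------------------------------------
# truth network

_TRAIT_TEMPLATE = (
    ("trait_c1", "continuous"),
    ("trait_c2", "continuous"),
    ("prev_d1", "prevalent"),
    ("prev_d2", "prevalent"),
    ("inc_d1", "incident"),
    ("inc_d2", "incident"),
)


def simulate_truth_network(
    n_proteins: int,
    n_regulators: int,
    mean_out_degree: float = 8.0,
    degree_tail_exponent: float = 2.5,
    seed: int = 0,
    beta_magnitude: tuple = (0.3, 1.2),
    beta_loc: float = 0.6,
    beta_scale: float = 0.25,
    cis_h2_range: tuple = (0.1, 0.4),
    cis_background: float = 0.7,
    n_trait_drivers: int = 3,
    trait_effect: float = 0.3,
    min_out_degree: int = 1,
) -> SimTruth:
    """Sample a DAG with heavy-tailed out-degrees and cis-genetic control.

    Regulator out-degrees follow a Pareto law with tail exponent
    ``degree_tail_exponent`` rescaled to ``mean_out_degree``, giving the
    scale-free-like profile where a few regulators control many targets.
    Edge effects have random sign and truncated-normal magnitudes in
    ``beta_magnitude``. Regulators always receive a cis effect with h^2 drawn
    from ``cis_h2_range``; other proteins receive one with probability
    ``cis_background``. Trait effects are planted on random regulators.
    """
    if n_regulators > n_proteins:
        raise ValueError("n_regulators cannot exceed n_proteins")
    if degree_tail_exponent <= 2:
        raise ValueError("degree_tail_exponent must exceed 2 for a finite mean")
    rng = np.random.default_rng(seed)
    aptamers = [f"APT{j:05d}" for j in range(n_proteins)]

    reg_idx = np.sort(rng.choice(n_proteins, size=n_regulators, replace=False))
    regulators = [aptamers[i] for i in reg_idx]

    edges = []
    if n_regulators and mean_out_degree > 0:
        alpha = degree_tail_exponent
        w = (1 - rng.random(n_regulators)) ** (-1.0 / (alpha - 1))  # Pareto(alpha-1), w >= 1
        mean_w = (alpha - 1) / (alpha - 2)
        degrees = np.maximum(min_out_degree, np.rint(w * mean_out_degree / mean_w)).astype(int)
        a_mag, b_mag = beta_magnitude
        tn = stats.truncnorm(
            (a_mag - beta_loc) / beta_scale, (b_mag - beta_loc) / beta_scale,
            loc=beta_loc, scale=beta_scale,
        )
        for i, d in zip(reg_idx, degrees):
            avail = n_proteins - 1 - i  # targets must come later in topological order
            d_eff = min(d, avail)
            if d_eff <= 0:
                continue
            targets = rng.choice(np.arange(i + 1, n_proteins), size=d_eff, replace=False)
            mags = tn.rvs(size=d_eff, random_state=rng)
            signs = rng.choice([-1.0, 1.0], size=d_eff)
            for t, m, s in zip(targets, mags, signs):
                edges.append((aptamers[i], aptamers[t], float(m * s)))

    # cis-genetic control
    is_reg = np.zeros(n_proteins, dtype=bool)
    is_reg[reg_idx] = True
    has_cis = is_reg | (rng.random(n_proteins) < cis_background)
    h2 = np.where(has_cis, rng.uniform(*cis_h2_range, size=n_proteins), np.nan)
    cis = pd.DataFrame(
        {
            "aptamer_id": aptamers,
            "h2_target": h2,
            "gamma": np.nan,
            "h2_realized": np.nan,
        }
    )

    # phenotype effects on random regulators (or random proteins if no regulators)
    pool = regulators if regulators else aptamers
    phenotype_effects = {}
    for name, kind in _TRAIT_TEMPLATE:
        k = min(n_trait_drivers, len(pool))
        chosen = rng.choice(pool, size=k, replace=False) if k else []
        signs = rng.choice([-1.0, 1.0], size=k)
        phenotype_effects[name] = {
            "type": kind,
            "effects": {str(a): float(trait_effect * s) for a, s in zip(chosen, signs)},
        }

    return SimTruth(
        true_edges=edges,
        regulators=regulators,
        cis_effects=cis,
        phenotype_effects=phenotype_effects,
        params={
            "n_proteins": n_proteins,
            "n_regulators": n_regulators,
            "mean_out_degree": mean_out_degree,
            "degree_tail_exponent": degree_tail_exponent,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# proteins


def simulate_proteins(
    snp_panel: SnpPanel,
    truth: SimTruth,
    n_confounders: int = 3,
    confounder_sd: float = 0.3,
    confounder_density: float = 0.3,
    noise_sd: float = 1.0,
    covariate_effect_sd: float = 0.1,
    seed: int = 0,
    output_scale: str = "lognormal",
) -> tuple[ProteinPanel, CovariateTable]:
    """Evaluate the linear structural model in topological order.

    X_j = gamma_j E_j + sum_i beta_ij X_i + delta_j' C + a_j age + s_j sex + eps_j,
    where E_j is the designated instrument SNP of protein j's locus, parents
    X_i enter standardized, C are shared latent confounders loading on random
    protein subsets, and gamma_j is chosen so the realized cis-h^2 matches the
    truth's target. With ``output_scale="lognormal"`` the emitted levels are
    exp(0.5 X_std + b_j) (positive, skewed, for the Box-Cox step); the
    standardized signal is retained on ``panel.latent``.
    """
    rng = np.random.default_rng(seed)
    n = snp_panel.n_samples
    aptamers = list(truth.cis_effects["aptamer_id"])
    p = len(aptamers)
    n_loci = len(snp_panel.instrument_snps)
    if n_loci < p:
        raise ValueError(f"need >= {p} loci for {p} proteins, panel has {n_loci}")

    age = rng.normal(76.6, 5.6, size=n)
    sex = (rng.random(n) < 0.57).astype(float)
    age_z = (age - age.mean()) / age.std()
    covs = CovariateTable(
        pd.DataFrame({"age": age, "sex": sex}, index=snp_panel.sample_ids)
    )

    C = rng.standard_normal((n, n_confounders)) if n_confounders else np.zeros((n, 0))
    load_mask = rng.random((p, n_confounders)) < confounder_density
    loadings = np.where(load_mask, rng.normal(0.0, confounder_sd, size=(p, n_confounders)), 0.0)

    a_cov = rng.normal(0.0, covariate_effect_sd, size=p)
    s_cov = rng.normal(0.0, covariate_effect_sd, size=p)

    parents: dict[int, list] = {j: [] for j in range(p)}
    idx = {a: j for j, a in enumerate(aptamers)}
    for a, b, beta in truth.true_edges:
        parents[idx[b]].append((idx[a], beta))

    X_std = np.empty((n, p))
    gamma_out = np.full(p, np.nan)
    h2_out = np.full(p, np.nan)
    h2_target = truth.cis_effects["h2_target"].to_numpy(float)

    for j in range(p):
        base = loadings[j] @ C.T + a_cov[j] * age_z + s_cov[j] * sex
        base = base + rng.normal(0.0, noise_sd, size=n)
        for i, beta in parents[j]:
            if i >= j:
                raise RuntimeError("truth edges are not in topological order")
            base = base + beta * X_std[:, i]
        x = base
        if np.isfinite(h2_target[j]) and h2_target[j] > 0:
            e = snp_panel.dosage[:, snp_panel.snp_index(snp_panel.instrument_snps[j])]
            var_e = e.var()
            if var_e > 0:
                h2 = h2_target[j]
                gamma = np.sqrt(h2 / (1 - h2) * base.var() / var_e)
                cis_term = gamma * (e - e.mean())
                x = base + cis_term
                gamma_out[j] = gamma
                h2_out[j] = cis_term.var() / x.var()
        X_std[:, j] = (x - x.mean()) / x.std()

    truth.confounder_loadings = loadings
    truth.cis_effects["gamma"] = gamma_out
    truth.cis_effects["h2_realized"] = h2_out

    if output_scale == "lognormal":
        baseline = rng.normal(8.0, 0.5, size=p)
        levels = np.exp(0.5 * X_std + baseline)
    elif output_scale == "linear":
        levels = X_std.copy()
    else:
        raise ValueError(f"unknown output_scale {output_scale!r}")

    instr = snp_panel.instrument_snps
    ann = pd.DataFrame(
        {
            "aptamer_id": aptamers,
            "gene": [f"GENE{j:05d}" for j in range(p)],
            "chrom": [snp_panel.chrom[snp_panel.snp_index(instr[j])] for j in range(p)],
            "tss": [int(snp_panel.pos[snp_panel.snp_index(instr[j])]) for j in range(p)],
        }
    )
    panel = ProteinPanel(list(snp_panel.sample_ids), aptamers, levels, ann, latent=X_std)
    panel.validate()
    return panel, covs


# ---------------------------------------------------------------------------
# phenotypes


def simulate_phenotypes(
    protein_panel: ProteinPanel,
    covariates: CovariateTable,
    truth: SimTruth,
    censoring_rate: float = 0.3,
    seed: int = 0,
    baseline_hazard: float = 0.02,
    prevalence_intercept: float = -1.4,
    age_effect: float = 0.2,
) -> PhenotypeTable:
    """Draw phenotypes from the planted per-trait linear predictors.

    Continuous traits are linear with unit Gaussian noise; prevalent traits
    are Bernoulli(logistic(eta)); incident traits have exponential
    proportional-hazards event times with independent uniform censoring
    calibrated to the requested overall censoring fraction.
    """
    if not (0 <= censoring_rate < 1):
        raise ValueError(f"censoring_rate must be in [0, 1), got {censoring_rate}")
    rng = np.random.default_rng(seed)
    n = protein_panel.n_samples
    if protein_panel.latent is not None:
        X = protein_panel.latent
    else:
        lv = protein_panel.levels
        X = (lv - np.nanmean(lv, axis=0)) / np.nanstd(lv, axis=0)
    idx = {a: j for j, a in enumerate(protein_panel.aptamer_ids)}
    age_z = (covariates.age - covariates.age.mean()) / covariates.age.std()

    cols, spec = {}, {}
    for trait, info in truth.phenotype_effects.items():
        eta = age_effect * age_z
        for apt, coef in info["effects"].items():
            if apt not in idx:
                raise ValueError(f"phenotype effect references unknown protein {apt}")
            eta = eta + coef * X[:, idx[apt]]
        kind = info["type"]
        spec[trait] = kind
        if kind == "continuous":
            cols[trait] = eta + rng.standard_normal(n)
        elif kind == "prevalent":
            prob = 1.0 / (1.0 + np.exp(-(prevalence_intercept + eta)))
            cols[trait] = (rng.random(n) < prob).astype(int)
        elif kind == "incident":
            t_event = rng.exponential(1.0 / (baseline_hazard * np.exp(eta)))
            if censoring_rate == 0:
                time, event = t_event, np.ones(n, dtype=int)
            else:
                def frac_censored(log_u: float) -> float:
                    u = np.exp(log_u)
                    return np.mean(np.minimum(t_event / u, 1.0)) - censoring_rate

                log_u = optimize.brentq(frac_censored, -10.0, 25.0)
                c = rng.uniform(0.0, np.exp(log_u), size=n)
                event = (t_event <= c).astype(int)
                time = np.minimum(t_event, c)
            cols[f"time_{trait}"] = time
            cols[f"event_{trait}"] = event
        else:
            raise ValueError(f"unknown trait type {kind!r}")

    table = pd.DataFrame(cols, index=protein_panel.sample_ids)
    return PhenotypeTable(table, spec)


# ---------------------------------------------------------------------------
# convenience


def simulate_cohort(
    n_samples: int = 5000,
    n_proteins: int = 300,
    n_regulators: int = 50,
    mean_out_degree: float = 8.0,
    n_confounders: int = 3,
    censoring_rate: float = 0.3,
    seed: int = 0,
    output_scale: str = "lognormal",
    **truth_kwargs,
):
    """One-call default experiment: genotypes, truth, proteins, phenotypes.

    Seeds for the four stages are derived deterministically from ``seed``.
    Returns (snp_panel, truth, protein_panel, covariates, phenotypes).
    """
    ss = np.random.SeedSequence(seed).spawn(4)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    snps = simulate_genotypes(n_samples, n_loci=n_proteins, seed=seeds[0])
    truth = simulate_truth_network(
        n_proteins, n_regulators, mean_out_degree=mean_out_degree, seed=seeds[1],
        **truth_kwargs,
    )
    proteins, covs = simulate_proteins(
        snps, truth, n_confounders=n_confounders, seed=seeds[2],
        output_scale=output_scale,
    )
    phenos = simulate_phenotypes(proteins, covs, truth, censoring_rate, seed=seeds[3])
    return snps, truth, proteins, covs, phenos
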