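# Methods

## Scope and model

`cpnet` infers directed causal relations among circulating proteins by
instrumental-variable reasoning: a protein's *cis*-acting lead pQTL is a
randomized "natural experiment" on that protein's level, so downstream
association of the instrument with another protein's level is evidence of a
directed effect. The pipeline is: preprocessing → cis-instrument selection →
pairwise causal scoring → global-FDR edge selection → regulator filtering,
aptamer deduplication and LD-block resolution → topology, eigenprotein,
trait-association, replication and variance-partitioning analyses. A
synthetic-cohort generator with a known structural model closes the loop for
validation.

## Preprocessing

Protein levels are Box-Cox transformed per aptamer (maximum-likelihood λ;
columns with nonpositive values are shifted by c = 1 − min(x); constant
columns are flagged and skipped), then centered/scaled. Outliers are removed
with a single global rule: the 99th percentile of each aptamer defines a
distribution of cutoffs, and values above the 99.5th percentile of that
distribution are set missing. The rule operates on the standardized matrix —
percentile cutoffs are only comparable across aptamers after
standardization; applying it per-value (not per-sample) keeps the remaining
measurements of an affected sample. Levels are then adjusted to OLS
residuals of `level ~ 1 + age + sex`, and rank-inverse-normal transformed,
Φ⁻¹((r − ½)/n) with average ranks for ties (Blom offsets available), before
causal testing. Remaining missing entries are set to the post-transform mean
(zero) so the vectorized pair scoring sees complete data.

## cis-pQTL instruments

For each protein, every SNP within ±150 kb of the encoding gene's TSS is
tested by marginal OLS. The window minimum p-value is Bonferroni-adjusted
for the number of SNPs in the window (a simple, conservative reading of
per-window multiplicity correction); q-values across proteins come from the
Storey–Tibshirani estimator (λ-grid 0.05–0.95, cubic-polynomial smoothing of
π̂0(λ) evaluated at the largest λ, clipped to [0, 1]; with fewer than 100
p-values the estimator is unstable and π0 = 1 is used). Proteins with
q ≤ 0.05 keep their lowest-p SNP as the lead pSNP; ties break to the smaller
position, then the lexically smaller SNP id. Dosages are used as-is, with no
hard-call rounding at this stage.

## Pairwise causal tests

The instrument enters the pair tests as a 3-class categorical (rounded
dosage; classes with fewer than 2 samples are merged into the neighboring
class, and a monomorphic instrument is an error). With n samples and k
genotype classes:

- llr2 = (n/2)·ln(RSS₀/RSS_E), comparing `B ~ 1` against per-class means —
  the secondary-linkage statistic;
- llr5 = (n/2)·ln(RSS_E/RSS_{E,A}), where the wider model adds one shared
  linear coefficient on A to the class means — the controlled statistic.
  A single shared slope (rather than per-class slopes) is the default; the
  formula is isolated behind `pairwise_llrs` so variants can be swapped.

Both statistics have exact finite-sample nulls: the incremental
R² = 1 − exp(−2·llr/n) follows Beta(df_extra/2, (n − df_full)/2) under the
Gaussian null, which the test suite verifies by KS uniformity at n = 500
over 10⁴ simulations. Exactness matters because the posterior fit pools tens
of thousands of p-values and is driven by their extreme tail.

## Posterior probabilities and edge selection

Each test family (P2, P5) is pooled across all pairs and converted to a
posterior probability by an empirical-null local-FDR fit:
PP(p) = clip(1 − π0/f̂(p), 0, 1), with π0 from the Storey estimator and f̂ a
monotone non-increasing density estimate. The density is measured on
order-statistic chunks of 20 p-values, regularized by isotonic regression
(weighted by chunk width), and each isotonic block's density is multiplied
by the lower 0.1% Poisson confidence bound of its pooled count divided by
that count. The shrinkage term is what makes the estimate safe at the
extreme left tail: a lone null fluctuation in a narrow chunk (observed/
expected of ~2–3 at count 20) is pushed below the uniform level and maps to
PP ≈ 0, while genuine signal chunks exceed the null density by many orders
of magnitude and lose almost nothing. On pure-uniform input the maximum PP
stays below 0.1 at 10⁵ p-values; a 30% strong-signal mixture yields mean
PP ≈ 0.30. The fit requires at least 1000 pooled p-values.

The edge score is PP = PP2·PP5. Edges are sorted by PP (ties lexical on the
pair) and the longest prefix with 1 − mean(PP) ≤ the target (default 1%) is
selected; the realized FDR of the selection is reported. The construction
guarantees realized ≤ target. Because the posterior is deliberately
conservative, the realized FDR typically undershoots the target and the
selection errs toward precision over recall.

## Network refinement

Regulators keep their subnetworks only with ≥ 10 selected targets. For genes
measured by multiple aptamers, the aptamer with the most targets represents
the gene (ties lexical). Regulators whose lead pSNPs are identical or whose
instrument dosages have r² ≥ 0.5 form LD blocks by single-linkage closure
(the connected components of the pairwise relation; transitivity is a
documented choice, as medium-LD chains are rare with well-separated loci).
Within a block, the pairwise target-overlap ratio I = |T_x ∩ T_y|/|T_x ∪ T_y|
decides resolution: a member is independent iff I < 0.6 (strictly) against
every other member; failing members are collapsed into one unresolved
pseudo-network holding the union of their targets, and mutual-target pairs
are unresolved outright. Collapsed pseudo-networks are excluded from
eigenprotein, ranking and variance analyses by default.

## Topology

The regulator-only subgraph is converted to a DAG by a greedy heuristic:
edges are visited by descending PP (ties lexical) and kept unless they close
a directed cycle; removed edges can be reintroduced and classified by the
level difference of their endpoints (same-level, one-above, two-above,
below). Levels are the minimum edge count from any root (node without
incoming kept edges) by multi-source BFS. Transitive reduction removes an
edge iff an alternative directed path exists (unique for DAGs; verified
against brute-force reachability and networkx). Motif counts cover 2-node
feedback (x⇄y), 3-node feedback (directed 3-cycles, one count per cycle)
and feed-forward loops (ordered triples x→y, y→z, x→z). Hub robustness
removes the top-k out-degree hubs (ties lexical; total degree is a config
option) and tracks the largest weakly connected component as a fraction of
the original node count. Subsampling robustness re-scores the same candidate
pairs and instruments on random subsamples and reports ROC AUC /
precision-recall of the subsample PPs against the full-sample network as a
flattened binary vector.

## Eigenproteins, association, ranking

An eigenprotein is PC1 of the standardized member matrix (regulator plus
targets — including the regulator is a documented, configurable choice),
valid iff its variance fraction strictly exceeds 0.15 (a stricter 0.30
sensitivity mode is available via the same argument). The score's sign is
oriented to correlate positively with the regulator's level and the scores
are standardized. Associations with traits use OLS (continuous), logistic
regression (prevalent) or Cox proportional hazards with Efron tie handling
(incident), always adjusted for age and sex; non-convergence or separation
is flagged on the result rather than raised. Per-trait sub-scores are
0/1/2: +1 if the regulator passes Benjamini-Hochberg FDR < 0.05 within the
regulator × trait family, +1 if the valid eigenprotein's raw p is below a
fixed Bonferroni-style threshold of 0.00027 (the scoring rule treats the
fixed-threshold variant as canonical; a per-trait FDR variant for
eigenproteins exists in the literature of this design and can be configured).
Totals ≥ 7 flag top-ranked subnetworks.

## Replication and enrichment

PPI overlap compares the network's unordered gene pairs against an
undirected reference pair set; the null re-draws networks of the same edge
count uniformly over unordered pairs of the measured-protein universe (10
draws by default), and z = (obs − mean)/sd with one-sided normal p. Edge
replication between two cohorts' networks uses Fisher's exact test over all
ordered non-self pairs of the shared protein universe. Per-regulator target
overlap uses upper-tail hypergeometric tests (requiring ≥ 2 shared targets)
with Storey q-values across regulators. Subnetwork similarity combines
eigenprotein Pearson correlations and target-set Jaccard indices under a
shared average-linkage leaf order on correlation distance, which makes
negatively correlated subnetworks with shared targets visually adjacent.

## Variance partitioning

Independent cis SNPs per protein come from forward selection seeded at the
lead SNP within ±150 kb: each step adds the candidate with the smallest
conditional p-value in the joint OLS refit if p < 0.00763 and its dosage r²
with every selected SNP is < 0.9. Conditional p-values come from the full
individual-level joint refit (no summary-statistic approximation — the
package has individual-level data by design). The cis variance component is
the adjusted R² of the protein on the selected dosages (0 with none
selected). The parental-cis model regresses each target on the union of its
regulators' independent cis SNPs plus its own, reporting the delta over the
own-cis-only model, and the Spearman correlation of delta with in-degree.

## Synthetic cohort generator

Genotypes: two haplotypes per sample; within a locus, alleles follow a
first-order Markov chain with Pearson correlation `ld_rho` (default 0.6)
between adjacent SNPs and one MAF per locus drawn from (0.05, 0.5), so
adjacent dosage r² ≈ ld_rho². Each locus (5 SNPs, 5 kb apart; loci 1 Mb
apart across 22 chromosomes) carries one designated instrument SNP flanked
by LD decoys, exercising both pQTL mapping and LD-block logic. Truth
network: regulator out-degrees follow a Pareto law (tail exponent 2.5)
rescaled to mean 8, giving the scale-free-like profile where a few
regulators control many targets; targets are drawn uniformly among proteins
later in a fixed topological order; effects have random sign and
truncated-normal magnitudes in [0.3, 1.2] (location 0.6, scale 0.25).
Regulators always receive a cis effect with h² ~ U(0.1, 0.4); other proteins
with probability 0.7 — leaving a realistic minority of targets without their
own pQTL for the parental-cis analyses. Proteins: evaluated in topological
order as X_j = γ_j E_j + Σ β_ij X_i + δ_j'C + a_j·age + s_j·sex + ε_j with
parents standardized, 3 shared confounders loading on random 30% subsets
(N(0, 0.3) loadings), unit noise, and γ_j set so the realized cis-h² matches
its target. Emitted levels are exp(0.5·X_std + b_j) by default (positive,
skewed — so Box-Cox is genuinely exercised); a linear scale is available.
Covariates mimic an elderly cohort (age ~ N(76.6, 5.6), 57% female).
Phenotypes: six traits (two continuous, two prevalent, two incident), each
driven by 3 random regulators with ±0.3 coefficients plus an age effect;
prevalent traits are Bernoulli(logistic(η)), incident traits have
exponential proportional-hazards times (baseline 0.02/yr) with independent
uniform censoring whose scale is solved numerically to hit the requested
censoring fraction (default 0.3).

What the generator does **not** emulate: assay noise beyond additive
Gaussian, batch effects, realistic recombination maps or genotype
imputation error, nonlinear or threshold effects, time-varying hazards, and
the long-range LD of real genomes. Passing tests therefore demonstrate that
the machinery is correct under its stated structural model, not that the
statistical power or FDR calibration transfers verbatim to real cohort data.

## Evaluation conventions and numerical choices

- Recovery ROC AUC scores every scored candidate pair against the
  generator's direct structural edges ("true adjacency"); an ancestor mode
  (any directed path counts as positive) is available, since the P2·P5
  product genuinely detects total effects — it trades credit for indirect
  detections against penalties for undetectably weak multi-hop paths.
- Default problem sizes — 5000 samples × 300 proteins × 50 regulators for
  the main experiment, 2000 × 200 × 50 for null-calibration batches — are
  the package's standard desk-scale study conditions; all sizes are plain
  function arguments.
- Determinism: every stage funnels randomness through numpy Generators
  seeded from a single user seed; ties break lexically everywhere (edge
  sorting, hub ranking, aptamer dedup, SNP selection).
- Degenerate inputs: empty networks are valid results, not errors; a zero-sd
  PPI null is flagged degenerate; constant exposures and monomorphic
  instruments raise informative errors; Cox/logistic non-convergence is
  flagged on the result.
- Coordinates are 1-based inclusive throughout; genomic windows are closed
  intervals.

## Known limitations

The posterior conversion is a transparent local-FDR construction, not a
bit-compatible reimplementation of any particular tool's internal mixture
fit; acceptance is calibration-based. The conservative Poisson shrinkage
trades recall for FDR safety near the selection boundary. LD-block closure
is single-linkage; with dense LD structures a block can chain together
regulators whose instruments are only indirectly correlated. The forward
selection re-fits the full joint model each step, which is quadratic in the
number of selected SNPs and intended for cis windows, not genome-wide use.
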