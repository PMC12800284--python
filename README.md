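# cpnet — causal protein network inference from cis-pQTL instruments

`cpnet` reconstructs a directed network of regulator → target relationships
among circulating proteins measured in a population cohort, using each
protein's *cis*-acting protein quantitative trait locus (pQTL) as a genetic
instrument. It is aimed at proteogenomics researchers who have a genotype
matrix, a serum/plasma protein panel and clinical phenotypes, and want to go
from those inputs to a causal protein network (CPN), its hierarchical
topology, eigenprotein summaries of each subnetwork, trait-association
rankings, and replication statistics — plus a fully synthetic cohort
generator with known ground truth so every step can be validated offline.

## The model

For an exposure protein *A* with lead *cis* pSNP genotype *E* and a candidate
target *B* (rank-inverse-normal transformed), two nested-OLS log-likelihood
ratios are computed:

- **secondary linkage (P2)** — `B ~ genotype-class means` vs `B ~ 1`: is *E*
  associated with *B* at all? For a valid instrument this can only happen
  through *A*.
- **controlled test (P5)** — `B ~ genotype-class means + β·A` vs
  `B ~ genotype-class means`: do *A* and *B* remain dependent after adjusting
  for *E*, excluding the case where *E* affects both independently?

Each LLR has an exact finite-sample null (a Beta law on the incremental R²);
the p-values are pooled per test family and converted to posterior
probabilities of a real effect with an empirical-null local-FDR fit, and the
edge score is the product **PP = PP2 · PP5**. Edges are selected at a
**global FDR** = 1 − mean(PP) over the selected set; regulators with ≥ 10
targets define subnetworks; regulators whose instruments are shared or in LD
(r² ≥ 0.5) are resolved by the target-overlap ratio *I* =
|T_x ∩ T_y| / |T_x ∪ T_y| (independent iff *I* < 0.6, otherwise collapsed).
Each subnetwork's **eigenprotein** is the first principal component of its
member profiles (valid when it explains > 15% of the variance), and
subnetworks are ranked 0/1/2 per trait (regulator and/or eigenprotein
significant) across six cardiometabolic traits.

## Worked example

```python
from cpnet import CausalProteinNetwork

model = CausalProteinNetwork.from_simulation(seed=7)   # 5000 samples, 300 proteins
results = model.fit()
print(results.summary())
```

```
Causal protein network
================================================
samples                 5000
proteins (aptamers)     300
instrumented A-proteins 221
candidate edges scored  66079
global FDR target       0.010
realized FDR            0.0054
edges selected          349
network regulators      12 (min 10 targets)
collapsed/unresolved    0
ROC AUC vs truth        0.9893
```

Of the 300 simulated proteins, 221 obtain a *cis* instrument at q ≤ 0.05;
all 221 × 299 ordered pairs are scored, and 349 edges pass the 1% global
FDR (realized 0.54%). The 12 regulators retaining ≥ 10 targets define
subnetworks, and the posterior scores separate true from false directed
edges with ROC AUC 0.989 against the generator's ground truth. Downstream:

```python
results.evaluate()                   # {'auc': 0.989..., 'fdp': ...}
results.topology_summary()           # DAG levels, motifs, hub robustness
eig = results.eigenproteins()        # PC1 per subnetwork, validity flags
ranks = results.rank()               # 0/1/2-per-trait scores per subnetwork
```

A thin CLI mirrors this: `cpnet simulate`, `cpnet run --simulate --seed 7`,
`cpnet report <run_dir>`.

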