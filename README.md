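# icluf — iterative cluster fusion for multiomic patient stratification

`icluf` partitions a patient cohort into molecular subtypes by integrating
two or more omic layers (e.g. mRNA expression, miRNA expression, DNA
methylation) measured on the same patients. It is aimed at researchers who
have per-patient feature matrices and want unsupervised subtypes whose
quality can be judged both internally (silhouette) and clinically
(survival separation), together with an estimate of how much each omic
layer contributed to the result.

## Method

The pipeline has three phases.

**Phase 1 — per-omic patient similarity.** For each omic *o* with patient
profiles *p<sub>i</sub><sup>o</sup>*, a Gaussian interaction-profile
kernel converts Euclidean distances into similarities:

&nbsp;&nbsp;&nbsp;&nbsp;*A<sup>o</sup><sub>ij</sub>* = exp(−α ‖p<sub>i</sub><sup>o</sup> − p<sub>j</sub><sup>o</sup>‖²),&nbsp;&nbsp;α = 1.5 by default.

**Phase 2 — neighborhood reweighting.** Each omic's current matrix is
clustered (spectral clustering at the user's K), patients are represented
by their similarity profiles, and the matrix is reweighted by cluster
geometry:

&nbsp;&nbsp;&nbsp;&nbsp;*Ā<sub>ij</sub>* = 2 (*A<sub>ij</sub>*)² / [ D(c<sub>i</sub>, c<sub>j</sub>) · (µ + d̄<sub>c<sub>i</sub></sub> + d̄<sub>c<sub>j</sub></sub>) ]

where d̄<sub>c</sub> is the mean member-to-centroid distance of cluster
*c*, and the inter-cluster separation
D(c<sub>i</sub>, c<sub>j</sub>) = exp(β ‖v<sub>i</sub> − v<sub>j</sub>‖² / (η + 1))
grows with the distance between centroids (η is a scale normalizer; µ > 0
guards the denominator when all members coincide with their centroids).
Pairs inside tight, well-separated clusters are boosted; pairs split
across distant clusters are damped.

**Phase 3 — cross-omic message passing.** Each omic's matrix is updated
from every *other* omic's matrix, sandwiched by an operator built from its
own neighborhood matrix, A<sup>o</sup> ← Σ<sub>o′≠o</sub> R<sup>o</sup> A<sup>o′</sup> R<sup>oT</sup>,
and renormalized; after the configured number of iterations (default 7)
the per-omic matrices are averaged into one integrated matrix and K-means
on its rows yields the final subtypes. See `docs/methods.md` for the
operator normalization and its rationale.

The package also provides the evaluation metrics used to judge the
clustering (silhouette, adjusted Rand index, Fowlkes–Mallows, K-sample
log-rank test, Kaplan–Meier curves, cluster-subset survival comparisons),
a random-forest Gini-importance analysis of per-omic contributions, and a
synthetic multiomic cohort generator with planted subtypes and matched
survival for testing.

## Worked example

A complementary-signal cohort: three planted patient groups, one omic that
only separates groups {0,1} from {2}, one that only separates {0} from
{1,2}, and one pure-noise layer. No single omic resolves all three
groups; the fused clustering does.

```python
from icluf import (FusionConfig, adjusted_rand_index, complementary_spec,
                   generate_multiomic, generate_survival, logrank_test,
                   run_icluf, silhouette_score)

layers, truth = generate_multiomic(complementary_spec(seed=1))
result = run_icluf(layers, FusionConfig(k=3, seed=1))

print("ARI vs planted groups :", round(adjusted_rand_index(result.assignment, truth), 3))
print("silhouette (integrated):", round(silhouette_score(result.integrated, result.assignment), 3))
print("silhouette per iteration:", [round(s, 3) for s in result.per_iteration_silhouette])

surv = generate_survival(truth, hazards=[0.5, 1.0, 2.0], censor_rate=0.2, seed=1)
stat, df, p = logrank_test(surv, result.assignment)
print(f"log-rank: chi2={stat:.2f}, df={df}, p={p:.2e}")
```

Output:

```
ARI vs planted groups : 1.0
silhouette (integrated): 0.907
silhouette per iteration: [0.642, 0.822, 0.887, 0.903, 0.906, 0.907, 0.907]
log-rank: chi2=18.49, df=2, p=9.65e-05
```

The fused subtypes match the planted groups exactly (ARI 1.0); for
comparison, the best single-omic spectral clustering on this design
reaches ARI ≈ 0.49. The silhouette trace rises monotonically over the
seven fusion iterations, and the predicted subtypes separate the
cluster-specific exponential survival distributions (hazards 0.5 / 1.0 /
2.0) at p < 10⁻⁴.

The same pipeline is available from the shell:

```bash
icluf simulate --preset complementary --seed 1 --outdir sim/
icluf run --omic mRNA=sim/mRNA.csv --omic miRNA=sim/miRNA.csv \
          --omic methylation=sim/methylation.csv \
          --k 3 --seed 1 --truth sim/truth_labels.csv \
          --survival sim/survival.csv --outdir out/
```

which writes `labels.csv`, `integrated_matrix.csv`,
`silhouette_trace.json`, `evaluation.json`, and a `manifest.yaml` that
reproduces the run bit-identically via `icluf run --config
out/manifest.yaml`. Subcommands `evaluate` and `importance` run the
metrics and the per-omic contribution analysis standalone.

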