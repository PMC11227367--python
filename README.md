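# diogene

Gene-specific optimization of motif-prior integration strength for
regression-based gene regulatory network (GRN) inference.

## The problem

Regression-based GRN inference predicts each target gene's expression from
the expression of candidate regulators (transcription factors), then ranks
regulator–target pairs by variable importance and keeps the strongest edges.
Transcription-factor binding motifs (TFBMs) found in target promoters are a
natural prior: regulators with a motif in a target's promoter are more
plausible regulators of it. But motif evidence is noisy and incomplete, and
its relevance varies from gene to gene — integrating it with one global
strength can degrade the models of many genes while helping others.

This package implements DIOgene: a hypothesis-driven, *per-gene* calibration
of the integration strength, for two integrative engines:

- **weightedRF** — a random forest in which the candidate variables at each
  decision node are sampled with probabilities proportional to prior-derived
  weights;
- **weightedLASSO** — an L1-penalized linear model with per-regulator
  penalty factors (with a bootstrap layer and cross-validated
  regularization).

Motif evidence is encoded as Π(r, t) ∈ {0, ½, 1} (absent / motif unknown /
present), and a scalar α ∈ [0, 1] tunes integration through the weight
w = (1 − α) + α·Π: at α = 0 the prior is ignored, at α = 1 only
motif-supported regulators can enter a model.

For each target gene t and each α on a grid, N repeated fits give the
normalized out-of-sample MSE (1.0 = variance of the target) and the
*effective data integration* EDI — the mean rank, by increasing importance,
of the motif-supported regulators. The same is measured on a simulated null
dataset in which regulator expression profiles are deranged among regulator
identities, so motifs and expression share no information. The gain at α is
the Student statistic

T(α) = (μ_MSE − μ_MSE0) / √((σ²_MSE + σ²_MSE0)/N),

where the null moments are interpolated at the true EDI reached at α, and T
is referred to a Student distribution with 2N − 2 degrees of freedom.
P-values are one-sided (improvement only) and FDR-adjusted over the grid;

α_opt = 0 if min p_adj > 0.05, else argmin p_adj.

Finally, one model per gene at its α_opt yields importances that are pooled
and thresholded at a target density D, keeping E = ⌊D·R·(T−1)⌋ edges, and
the network can be scored (precision/recall) against a partial gold
standard and mined for hub regulators by out-degree.

## Worked example

The package ships a synthetic benchmark generator (known ground-truth
network, expression driven by it, motif prior with controlled error rates,
partial gold standard), so everything runs without external data:

```python
import diogene as dg
from diogene.optimizer import DIOgene
from diogene.network import precision_recall

system = dg.generate(n_regulators=8, n_targets=6, n_samples=30,
                     density=0.15, unknown_frac=0.0, seed=7)
model = DIOgene(engine="weightedLASSO", grid=dg.default_grid(0.5),
                n_repetitions=5, random_state=42).fit(system.data, system.prior)
print(model.optima_.to_string(index=False))
```

```
target  alpha_opt  alpha_min_mse          reason  min_p_adj
  T001        1.0            1.0       optimized   0.001917
  T002        0.5            0.5       optimized   0.002495
  T003        1.0            1.0       optimized   0.002697
  T004        0.0            1.0 not_significant   0.569733
  T005        1.0            1.0       optimized   0.011045
  T006        0.5            0.5       optimized   0.014911
```

Five of the six targets integrate the motif prior (α_opt > 0) because their
prediction error diverges significantly below the permuted-null reference;
T004 does not reach the 5% adjusted threshold and falls back to expression
alone — even though its raw MSE would have been minimized at α = 1
(`alpha_min_mse`), the divergence from the null is not significant, which is
exactly the case the null hypothesis is there to catch.

```python
grn = model.infer_network(density=0.1)   # E = floor(0.1 * 8 * 5) = 4 edges
truth = dg.GoldStandard(edges=system.truth.pairs(),
                        studied_regulators=set(system.data.regulator_ids))
res = precision_recall(grn, truth)
print(f"precision={res.precision:.2f} recall={res.recall:.2f}")
# precision=1.00 recall=0.67
```

All four selected edges are true edges of the generating network, and they
recover 67% of the evaluable gold-standard interactions. The median
normalized MSE across genes is 0.249 at the per-gene α_opt versus 0.313 at
the global α = 0.

The same pipeline is available from the shell:

```bash
diogene simulate --out sim --seed 7 --n-regulators 8 --n-targets 6 --n-samples 30
diogene optimize --expression sim/expression.tsv --regulators sim/regulators.txt \
    --targets sim/targets.txt --prior sim/prior.tsv \
    --engine weightedLASSO --n-reps 5 --seed 42 --out opt
diogene infer --optimize-dir opt --density 0.1 --out grn.tsv
diogene evaluate --grn grn.tsv --gold sim/gold.tsv \
    --profiles opt/profiles.tsv --optima opt/optima.tsv --out eval
```

`optimize` caches one JSON file per gene and resumes interrupted runs; all
outputs are TSV plus a resolved-config YAML snapshot.

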