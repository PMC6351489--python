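# mprnmf

Gene Ontology (GO) function prediction for long non-coding RNAs (lncRNAs)
by **multi-view partially regularized nonnegative matrix factorization**,
with graph-propagation baselines, instability-based rank selection and a
threshold-swept Fmax evaluation protocol.

Most lncRNAs have no experimentally validated function, while most
protein-coding genes do. The package transfers functional knowledge from
genes to lncRNAs through several heterogeneous sources of lncRNA–gene
association — co-expression (Pearson correlation of expression profiles)
and shared disease links (Jaccard index of associated disease sets) —
*without* collapsing them into a single fused network. It is aimed at
computational biologists who have expression matrices, a protein–protein
interaction (PPI) network, disease association lists and partial GO
annotations, and want ranked lncRNA–term predictions plus the standard
protein-centric evaluation.

## The model

Let `X` (n_o × (n_l + n_g)) be the known binary term–entity annotation
matrix, lncRNA columns first. Each association view `i` provides a
nonnegative lncRNA–gene matrix `Y_i`, embedded into a coupling matrix

    C_i* = [[0, Y_i], [Y_i', 0]] .

The factorization solves

    min  J(B, F) = ||X − B F||_F²  −  α Σ_i tr(F C_i* F')
    s.t. B ≥ 0,  F ≥ 0,  each column of F on the k-simplex,

where `B` (n_o × k) holds term loadings on k latent function groups and
`F` (k × n) the per-entity feature distributions. Because only the
cross-class blocks `Y_i` enter the regularizer (the within-class networks
do not), the regularization is *partial*; the trace term rewards agreement
between the latent features of coupled lncRNAs and genes, and each view is
regularized separately rather than fused. Optimization alternates the
multiplicative updates

    B ← B ⊙ (X F') / (B F F')
    F ← F ⊙ (B'X + α Σ_i F C_i*) / (B'B F),  then column renormalization,

for 100 rounds by default. Predicted lncRNA–term scores are `B · F_l`
(the lncRNA column block of `F`), min–max scaled to [0, 1].

Also included, as reference predictors: label propagation on a single
network, label propagation on the bi-colored (two-class) network
`C = [[W_l, Y], [Y', W_g]]`, dual label propagation, and a truncated KATZ
path-counting scorer. The rank k is chosen by refitting from random starts
and minimizing the instability Υ(k) — the mean pairwise dissimilarity of
basis matrices across restarts — and predictions are evaluated by
micro-averaged Recall/Precision/Fmax over a score-threshold sweep.

## Worked example

Everything runs on coupled synthetic data with planted function modules
(shared expression signals, overlapping disease pools, dense in-module PPI
wiring and block-structured annotations), so no external databases are
needed:

```python
from mprnmf import (RunConfig, generate_instance, build_from_instance,
                    fit, predict_lncrna_scores, select_rank)
from mprnmf.model_selection import evaluate_model_on_bundle
from mprnmf.pipeline import heldout_bundle

inst = generate_instance(n_l=50, n_g=150, n_o=40, planted_k=6,
                         noise=0.1, mask_fraction=0.2, seed=11)
cfg = RunConfig(k=6, alpha=0.05, seed=0)
built = build_from_instance(inst, cfg)

best_k, curve = select_rank(built.X, built.couplings, alpha=0.05,
                            k_grid=[2, 4, 6, 8, 10], tau=10, seed=0,
                            config=cfg.with_overrides(iterations=300, tol=1e-8))
print("instability:", {k: round(u, 3) for k, u in zip(curve.k_values, curve.upsilon)})
print("selected rank:", best_k)

model = fit(built.X, built.couplings, cfg.with_overrides(k=best_k))
scores = predict_lncrna_scores(model)
grid = [round(0.01 * i, 10) for i in range(101)]
report = evaluate_model_on_bundle(scores, heldout_bundle(inst, built, grid))
print("held-out Fmax = %.3f at threshold %.2f" % (report.fmax, report.best_t))
```

prints

```
instability: {2: 0.561, 4: 0.274, 6: 0.077, 8: 0.096, 10: 0.172}
selected rank: 6
held-out Fmax = 0.852 at threshold 0.54
```

The instability curve bottoms out at the planted number of modules (6):
restarts at the true rank reproduce the same basis columns up to
permutation, while smaller ranks merge modules inconsistently and larger
ranks split them arbitrarily. The held-out Fmax is computed only on the
20% of lncRNA annotations hidden before fitting, with training positives
excluded from the candidate predictions.

The same stages are available from the shell:

```bash
mprnmf simulate --out-dir run/ --seed 11
mprnmf build    --in-dir run/ --out-dir run/build
mprnmf fit      --in-dir run/ --out-dir run/fit --k 6 --alpha 0.05 --seed 0
mprnmf select-k --in-dir run/ --out-dir run/sk --k-grid 2,4,6,8,10 --tau 10
mprnmf baseline --in-dir run/ --out-dir run/bl --method bicolored
mprnmf evaluate --predictions run/fit/predictions.tsv \
                --truth run/annotations_truth.tsv --out-dir run/eval
```

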