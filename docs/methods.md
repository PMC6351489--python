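# Methods

## Model and procedure

The package predicts GO term associations for lncRNAs by factorizing the
joint term–entity annotation matrix `X` (terms × [lncRNAs | genes], binary)
as `X ≈ B F` with nonnegative factors, while pulling the feature matrix
`F` toward each lncRNA–gene association view through coupling matrices
`C_i* = [[0, Y_i], [Y_i', 0]]`:

    J(B, F) = ||X − B F||_F² − α Σ_i tr(F C_i* F'),
    B ≥ 0, F ≥ 0, columns of F on the k-simplex.

Two remarks on the orientation of the regularizer, which is the one
genuinely open modeling decision here. First, written with a plus sign the
trace term would *penalize* feature agreement between coupled lncRNAs and
genes, which contradicts both the purpose of the coupling (features should
reflect the association structure) and the multiplicative update whose
fixed point requires the α-term in the numerator. We therefore use the
minus (reward) orientation; its Karush–Kuhn–Tucker multiplicative update is

    F ← F ⊙ (B'X + α Σ_i F C_i*) / (B'B F),

which is the update we implement, with the standard Lee–Seung orientation
(numerator = negative part of the gradient) and an epsilon guard (1e−12)
in every denominator. The α = 0 fixed-point tests pin this orientation
down: at `X = BF` exactly, one round changes no entry beyond 1e−10.
Second, the identity `tr(F C_i* F') = 2 tr(F_l Y_i F_g')` (by the block
layout of `C_i*`) means the reward acts only through the cross-class
blocks — the within-class networks never enter the regularizer, which is
what "partial" regularization means; the identity is verified numerically
to 1e−10 in the tests.

The simplex constraint (each entity's feature column sums to 1) bounds the
reward term, yields sparse feature profiles, and is enforced by explicit
column renormalization after each F update; a column that collapses to
zero is reset to uniform 1/k with a warning. Renormalization can break the
classical per-iteration monotonicity of multiplicative updates; the
descent property is therefore stated and tested in two forms: without
renormalization (plain NMF, α = 0) the objective never increases within
1e−9, and with renormalization and α > 0 the final objective is below the
initial one in ≥ 95% of seeded runs. An optional damped variant
(`update_variant="sqrt"`) takes the element-wise square root of each
update ratio.

Prediction: scores are `B · F_l`, min–max scaled to [0, 1] over the whole
matrix (`scale_scores` config flag) so a single threshold sweep applies.
The alternative reading "split B into lncRNA/gene row blocks" is
dimensionally impossible — `B` is terms × rank and has no entity rows — so
`B · F_l` is the only consistent interpretation, and we use it.

## Network construction

* `W_l`: lncRNA co-expression, Pearson r thresholded at `coexpr_threshold`
  (default 0.5; no canonical value exists, 0.5 yields sparse but connected
  synthetic networks). Negative correlations are dropped, not
  absolute-valued, because the factorization requires nonnegative
  adjacencies; `use_absolute_correlation` exposes the alternative. Edge
  weights keep the correlation value rather than being binarized.
  A 1e−12 slack is applied at the threshold so r = t survives float
  round-off.
* `W_g`: the PPI network, restricted to its largest connected component
  (ties broken toward the smallest first-entity index). Only the PPI is
  filtered; lncRNAs are never dropped for connectivity, and views,
  expression and annotation columns are re-indexed to the surviving genes.
* Views: `Y_1` = cross Pearson correlation (same threshold), `Y_2` =
  Jaccard index of disease sets, with two empty sets defined as 0
  (absence of evidence is non-association).
* Normalization: `W̄ = D^{−1/2} W D^{−1/2}` with zero rows for isolated
  vertices; Laplacian `L = I − W̄`.
* Entity order everywhere: lncRNAs first, then genes, in input order.
* Whether expression should be log-transformed before correlation has no
  canonical answer; `log_transform_expression` (default off) exposes it.

## Baselines

Label propagation minimizes `θ tr(X̂ L X̂') + (1−θ)||X̂ − X||²`; closed form
`X̂ = (1−θ) X (θL + (1−θ)I)^{−1}` and the iteration
`X̂ ← θ X̂ W̄ + (1−θ) X` (tolerance 1e−10) are both implemented and agree to
1e−8. The bi-colored variant applies the same solver to the normalized
two-class adjacency so gene labels flow into lncRNA columns through `Y`.
Dual label propagation is implemented exactly as its objective is written:
the two entity classes decouple, `X̂_l = X_l (γL_l + I)^{−1}` and
`X̂_g = X_g (βL_g + I)^{−1}` — it contains no cross-class coupling, and the
documentation says so rather than silently adding one. The KATZ scorer
truncates `Σ_p β^p C^p` at `max_len` (default 3, β = 0.01; conventional
defaults, none are canonical) and converts to term scores as
`X_g · S_gl`, i.e. each lncRNA inherits the annotations of the genes it is
path-close to; an untruncated closed form is available when
`β · spectral_radius(C) < 1`.

## Rank selection

For each candidate k the model is refit τ times (default 10; 45 pairs give
a stable mean) from random starts; dissimilarity of two basis matrices is
`(1/2k)(2k − Σ_j max_i h_ij − Σ_i max_j h_ij)` with `h_ij` the Pearson
correlation between columns ("cross correlation" read as Pearson;
zero-variance columns correlate 0; negative correlations are not clipped —
the row/column maxima handle sign). Instability Υ(k) is the mean over
unordered pairs and the argmin (ties → smallest k) is selected. The
default grid is 40–64 in steps of 4, matching the method's published
protocol; synthetic experiments use grids around the planted rank.
Instability is computed on B, not F. Rank-selection refits use a tighter
convergence budget (300 iterations, relative tolerance 1e−8) than
prediction fits: the dissimilarity statistic compares converged bases, and
restarts at the true rank still drift measurably after 100 rounds, which
inflates Υ at exactly the rank the curve is supposed to single out.

## Evaluation

Per lncRNA and threshold t, `P_i(t)` = terms scoring ≥ t; TP/FP/FN are
summed over all evaluated lncRNAs *before* forming recall and precision
(micro-averaging — deliberately different from CAFA's macro-averaged Fmax,
because the printed protocol sums counts first), and Fmax is the maximum
harmonic mean over the sweep (default grid 0–1 step 0.01; smallest
maximizing t on ties). Degenerate denominators use total conventions
(precision 1 when nothing predicted, recall 0 when nothing true) so the
sweep is always defined; both are logged when triggered. Only lncRNAs with
at least one true term are evaluated, and the term universe is an explicit
input. The companion count metric reports lncRNAs with ≥ 1 true positive
at the maximizing threshold.

Held-out evaluation masks a fraction of lncRNA annotations before fitting
(exactly `floor(fraction × positives)`, uniform without replacement, gene
columns untouched), then scores only the hidden pairs, excluding training
positives from the candidate set.

## Synthetic data

The generator plants `k` latent function modules shared by lncRNAs and
genes; every module has ≥ 1 member of each class and a disjoint block of
ontology terms annotated to all members. Module-mates share a latent
expression profile (30 samples, standard normal; entity profile = latent +
noise × independent normal — 30 samples balances correlation stability
against run time), draw diseases from a module pool of 8 (each member
carries a fraction `1 − noise·U(0, 0.5)` of the pool, so the pool is
complete at noise 0 and graded at higher noise, plus Poisson(noise × 3)
background diseases), and genes are wired within modules with probability
0.6 and across with 0.02, keeping the largest PPI component near-spanning
so the connectivity filter is exercised but not destructive. At noise 0
and mask 0 the instance is exactly block-structured.

What this emulates — and does not. The generator reproduces the
correlational structure the method assumes (co-expression, disease
overlap, PPI density and annotations all aligned with the same latent
modules) but none of the empirical marginals of real databases: real GO
annotations are hierarchical and shallow, real PPI degree distributions
are heavy-tailed, and real views are only partially redundant. Passing
tests therefore demonstrate internal correctness and qualitative behavior
(rank recovery, held-out recovery, integration not hurting), not
real-data accuracy levels.

A consequence worth stating plainly: in these instances the gene
annotation block of `X` already determines the module structure, so the
association views are largely redundant with the data term and the
held-out-optimal α is small. Experiments therefore calibrate α by the
package's own held-out Fmax sweep (grid spanning 0.01–1, ties toward the
smallest α) on a calibration instance before comparing view
configurations — the same protocol the method prescribes for real data,
where the published sweep over 0.1–2 selected α = 1. At the calibrated α
the two-view model matches or exceeds each single-view model on held-out
Fmax in ≈ 9/10 replicates, mostly by ties at the performance ceiling;
the synthetic setting shows integration does not hurt, while the
published real-data comparison is where integration actively helps.

Default study sizes for experiments: 50 lncRNAs, 150 genes, 40 terms, 6
modules, noise 0.1, 20% masking — small enough that the full acceptance
run finishes in well under a minute, large enough that rank recovery and
held-out recovery are non-trivial.

## Known limitations

* The factorization objective is unbounded in α for fixed data: past a
  data-dependent scale the reward term dominates and reconstruction
  degrades sharply; α must be chosen by the sweep, not transplanted
  between datasets.
* No GO-hierarchy (true-path) propagation of annotations is performed
  anywhere, by design.
* More than two views are supported structurally, but all views share a
  single α; there is no per-view weight learning.
* The iterative propagation solver assumes the normalized adjacency has
  spectral radius ≤ 1 (true for the symmetric normalization used).
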