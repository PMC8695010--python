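# Methods

`dysmod` implements a dysfunction-module discovery pipeline for case/control
expression studies: moderated-t differential expression, weighted
coexpression module detection with topological overlap, hypergeometric
functional enrichment per module, and a hypergeometric "pivot" scan that
identifies ncRNA and transcription-factor regulators of modules. A
synthetic-data generator with planted ground truth makes every stage
testable without external data.

## Synthetic data model

The generator emulates a microarray-style case/control study of an
apoptosis-related gene panel. Defaults define the study conditions and are
not tuned per run:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 4571 | analyzed gene panel |
| `n_case` / `n_control` | 90 / 90 | sample groups |
| `module_sizes` | 11 modules, 60–400 genes | planted coexpression blocks |
| `loading` | 0.8 | factor loading of module genes |
| `noise_sd` | 0.6 | additive Gaussian noise SD (expression units) |
| `de_fraction` / `de_effect` | 0.1 / 1.0 | share of genes shifted in cases, shift size |
| `targets_per_regulator` / `in_module_fraction` | 10 / 0.8 | planted regulator target sets |
| `term_size` / term in-module share | 50 / 0.8 | planted annotation terms |

Each module m has one latent factor `f_{m,s} ~ N(0,1)` per sample; gene g in
m has `x_{g,s} = loading * f_{m,s} + eps`, `eps ~ N(0, noise_sd^2)`;
background genes are pure noise. The population within-module correlation is
`loading^2/(loading^2 + noise_sd^2)` = 0.64 at the defaults, and the
generator's tests verify the sample correlations against this closed form.
Differential genes receive `+de_effect` in case samples only. Planted
regulators draw `round(in_module_fraction * targets_per_regulator)` targets
from their home module and the remainder uniformly from the other genes, so
an in-module fraction of 0 reduces exactly to null (uniform) sampling; null
regulators and null annotation terms sample uniformly. ncRNA edges carry
scores uniform in [0.5, 1] (so the default score filter is exercised but
non-destructive; `score_jitter` adds sub-0.5 edges to test removal), while
TF edges are unscored, mirroring scored ncRNA-interaction resources versus
curated TF-target tables. A `core_modules` option plants one regulator with
full-strength target sets in several modules, and `shared_factor_pairs`
lets two modules share a latent factor to exercise the module-relationship
network.

What the generator does *not* emulate: probe-level intensities, batch and
array effects, heavy-tailed or count-like noise, correlated latent factors,
or realistic regulator biology. Passing recovery tests therefore demonstrate
the pipeline's correctness under a clean block-correlation model, not its
power on real microarray data.

## Differential expression

Expression is quantile-normalized (every column is mapped onto the mean
empirical distribution; ties receive the mean of the reference values over
their rank range — the map is idempotent and rank-preserving). The
two-group test is the empirical-Bayes moderated t: with per-gene pooled
variance s_g^2 on d = n1 + n2 − 2 degrees of freedom, the log-variances

    e_g = log s_g^2 − ψ(d/2) + log(d/2)

have excess variance ψ′(d0/2) under a scaled inverse-χ² prior (d0, s0²).
The moment estimator solves ψ′(d0/2) = Var(e) − ψ′(d/2) by a monotone
Newton iteration on the trigamma inverse; when the right-hand side is
non-positive the prior is degenerate (d0 = ∞) and s0² is the plain mean of
the variances. The posterior variance s̃_g² = (d0·s0² + d·s_g²)/(d0 + d)
yields t̃_g = (x̄_case − x̄_ctrl)/sqrt(s̃_g²(1/n1 + 1/n2)) referred to
Student's t with d0 + d degrees of freedom (normal when d0 = ∞). The
implementation is cross-checked against Bioconductor limma on a seeded
fixture and against a parameter-recovery simulation (d0 = 4, s0² = 1
recovered within 20%/10% at 10 000 genes). Differential genes are gated on
raw p < 0.01 (strict inequality; BH q-values are reported alongside). The
direction is fixed as case minus control.

## Coexpression modules

The unsigned weighted network is `a_ij = |cor(x_i, x_j)|^beta`. The soft
power beta is the smallest grid value (default 1..20) whose connectivity
distribution fits a scale-free law with R² ≥ 0.85, where R² is the squared
correlation of log10(frequency) vs log10(mean k) over 10 equal-width
connectivity bins. Two guardrails make the selection robust on block-
structured data: powers whose mean connectivity falls below 1 are not
eligible (the topological-overlap signal degenerates in that regime even as
the log-log fit keeps creeping upward), and when no eligible power reaches
the cut the conventional unsigned default beta = 6 is used — the standard
recommendation for this sample-size range. Under the default synthetic
conditions the fit saturates slowly and the fallback engages; beta = 6
recovers the planted modules exactly.

Cohesion is the unsigned topological overlap,

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    l_ij = Σ_{u≠i,j} a_iu a_uj,

validated entrywise against a brute-force triple-loop oracle. Genes are
clustered by average linkage on 1 − TOM and flat clusters are read off at a
static height cut (default 0.99 on the [0, 1] dissimilarity scale). This
replaces adaptive tree cutting with a reproducible rule: pure-noise genes,
whose pairwise dissimilarities concentrate near 1, fall out as singletons
and are labeled gray, while planted blocks merge well below the cut.
Clusters smaller than `min_module_size` (default 30) are relabeled gray and
survivors are renumbered 1..M by decreasing size.

Each module's eigengene is the first principal component of its
gene-standardized submatrix, scaled to unit variance and sign-oriented so
its mean correlation with module genes is nonnegative. The hub gene
maximizes |kME| (correlation with the eigengene), with exact ties broken
lexicographically; intramodular connectivity is available as an alternative
criterion. Module-module edges connect eigengenes with |cor| ≥ 0.5 by
default.

## Enrichment and pivots

Term over-representation in a module uses the hypergeometric upper tail

    p = Σ_{x=k}^{min(K,n)} C(K,x) C(N−K,n−x) / C(N,n)

computed in log space (gammaln + logsumexp) and validated exhaustively
against exact enumeration for all N ≤ 20. The universe defaults to analyzed
genes carrying at least one annotation. Only terms with overlap k ≥ 1 are
tested; BH correction runs within each module × category family, and a
record must clear both cutoffs (GO-style 0.01/0.01, pathway-style 0.05/0.2
by default).

A pivot is a regulator with at least two targets inside a module whose
target-module overlap is hypergeometrically significant at raw p < 0.01 (no
multiplicity correction by default, matching the screening character of the
analysis; a BH mode exists). Scored edges are pre-filtered at score ≥ 0.5
(inclusive); unscored TF edges pass. The background universe defaults to
the union of same-type targets intersected with analyzed genes; with few
regulators this union is degenerate, so small simulated studies should use
the full analyzed-gene universe (`pivot_background: all`, used by the
reproduction script). Module genes are restricted to the background before
computing K. Core pivots are regulators ranked by the number of modules they
significantly regulate, ties broken by best p then id.

## Numerical and design notes

- All randomness flows from a single seed; identical configurations are
  bit-identical, and end-to-end reruns produce byte-identical result tables.
- Result tables carry a `# dysmod config=<hash>` header; the hash covers the
  scientific parameterization but not the output location.
- p = 1 is returned exactly for zero overlap; −log10(p) edge weights floor p
  at 1e-300; hypergeometric inputs are validated against their support.
- Constant-expression genes are excluded from correlation with a warning;
  rows with missing values are dropped at load time.
- Coexpression can run on all samples (default) or cases only
  (`coexpression_samples: case`); the DE and module stages are independent.
- Problem sizes in the test suite: kernel oracles run at N ≤ 20 / ≤ 12
  genes; calibrations at 5 000–10 000 genes; module recovery at the full
  default scale (4571 × 180); the byte-identity check runs a reduced study
  (1200 genes, 40+40 samples, 5 modules), since determinism does not depend
  on scale.

## Known limitations

- Average-linkage + static cut does not reproduce adaptive tree-cut module
  boundaries on real data with nested or weak modules.
- The moderated test covers two-group designs only (no covariates, pairing,
  or probe-to-gene collapsing).
- Quantile normalization assumes comparable global distributions; strong,
  asymmetric global shifts (e.g. a large planted case effect) leak small
  artifacts into null genes, visibly inflating the DEG count above the
  planted truth in the default end-to-end run.
- The scale-free fit is histogram-based and sensitive to binning for highly
  skewed connectivity distributions; it is a diagnostic, not an estimator.
- Dense matrices throughout: ~20 000 genes is a practical upper bound.
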