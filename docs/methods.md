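# Methods

## Model and assumptions

The package implements a presence/pseudo-absence ensemble SDM. The central
assumption is distribution–environment equilibrium: occupied locations are
treated as a probability sample of environmentally suitable space, so a
classifier separating presences from background cells estimates a monotone
transform of suitability. Pseudo-absences are drawn uniformly from the
modellable mask excluding presence cells, which makes the negative class a
background sample rather than confirmed absences; predicted probabilities
are therefore relative suitability indices, not occupancy probabilities.

The ensemble combines only skill-gated members. With member TSS values
*a*ᵢ, weights are *W*ᵢ = *a*ᵢ / Σ *a*ₖ and the habitat suitability index is
the convex combination HSI = Σᵢ *W*ᵢ *P*ᵢ, so HSI is always bounded by the
member-wise envelope and lives in [0, 1]. The invasion risk index is the
cellwise difference IRI = HSI_invader − HSI_native, bounded in [−1, 1];
positive values flag invader-favoured habitat.

## Tunable parameters

| parameter | default | meaning |
| --- | --- | --- |
| collinearity threshold | 0.7 | greedy elimination until all kept pairs have \|Pearson r\| < 0.7 over mask cells |
| pseudo-absence design | 3 sets × 5000 cells | independent uniform background samples, no overlap with presence cells |
| train fraction | 0.75 | stratified per class, round-half-to-even per-class counts |
| repetitions | 10 | re-drawn 75/25 splits within each pseudo-absence set |
| algorithms | RF, GBM, GLM | 500-tree random forest; 500-tree gradient boosting, learning rate 0.05, depth 3; unpenalized binomial GLM (logit link) on standardized degree-2 polynomial features |
| TSS gate | 0.9 | inclusive; a 1e-9 epsilon keeps exact-boundary values in under floating point |
| class thresholds | 0.3 / 0.5 / 0.7 | half-open intervals; level k covers [tₖ, tₖ₊₁) |
| risk threshold | 0 | high risk strictly above 0 (sign interpretation of IRI) |

All learners receive balanced sample weights so presences (hundreds) and
pseudo-absences (thousands) carry equal total influence; without this the
fitted probabilities are compressed toward the background class. GBM's
capacity (500 trees at rate 0.05) was set as a fixed, documented default
giving validation skill indistinguishable from larger tree counts on the
package's virtual species at a fraction of the cost; all hyperparameters
are overridable per algorithm through the config. Six further algorithm
names (ANN, CTA, FDA, GAM, MARS, SRE) are registered but deliberately
unimplemented and raise `NotImplementedError`.

Seed management: a master seed fans out through `numpy.random.SeedSequence`
keyed by (stage, pseudo-absence set, repetition, algorithm), so any run is
reproducible in isolation and no hidden global state exists.

## Evaluation

AUC is computed in the Mann–Whitney rank form (ties count one half), which
equals trapezoidal ROC integration exactly; the tests cross-check against
scikit-learn's trapezoidal implementation to 1e-12. TSS is maximized over
the midpoints of consecutive distinct scores plus the endpoints — TSS is
piecewise constant between observed scores, so this scan attains the exact
optimum; ties break toward the lower cutoff. Score ≥ cutoff counts as
predicted presence. Evaluation always uses the held-out 25% only.

The ensemble's own skill is scored out-of-fold: each row's ensemble score
is the TSS-weighted average over gated members whose *validation* set
contained that row, so no member contributes scores for rows it trained
on. Rows never held out are excluded from the pooled score.

## The virtual-species generator

Layers are Gaussian-filtered white noise fields (sigma 6 cells) mixed with
a shared latent field; with mixing weight *c* the expected pairwise
inter-layer correlation is *c* (default 0.3, matching moderately redundant
bioclimate-style stacks). Each layer gets a distinct affine scale so
variables occupy different numeric ranges. The "coastal" mask keeps a
meandering band of roughly 60% of cells, emulating a coastal study strip.

A niche is a product of per-variable response curves (Gaussian bell or
logistic), rescaled to maximum 1 on the mask; presences are sampled without
replacement with probability proportional to truth and placed at cell
centres, optionally with sub-cell jitter duplicates so fishnet thinning has
work to do. The canonical `demo_scenario` uses two species responding to
env01 and env03 with the invader's env01 optimum shifted one layer standard
deviation upward (overlapping but diverging niches), 500 presences and 100
jitter duplicates each, plus a near-duplicate layer (`env_dup`) that the
collinearity screen must remove. Niche breadths are roughly one sixth of a
layer's spread — concentrated enough that single-model validation TSS sits
near 0.9, the regime the gating logic is designed for.

What the generator does *not* emulate: spatial sampling bias, positional
error, dispersal limitation, biotic interactions, temporal non-equilibrium
and projection to novel climates. Passing recovery tests therefore show the
pipeline machinery is correct under its own assumptions, not that those
assumptions hold for any real occurrence archive.

Prevalence and sampling bias are exposed as parameters (`n_presence`,
niche breadth, jitter count) rather than fixed, since realistic values are
species- and survey-specific.

## Variable contributions and response curves

The contribution of a variable is 1 − Pearson *r* between ensemble
predictions on the original design rows and on rows with that variable's
column permuted, averaged over permutations and clipped to [0, 1] — the
permutation convention common in ensemble SDM tooling. This is the
package's single largest methodological convention: no canonical definition
of "contribution rate" exists for weighted ensembles. A variable used by no
member is exactly 0 (the permuted predictions are bit-identical, skipping
the correlation); a constant-prediction ensemble yields all-zero
importances with a warning. Raw importances are normalized to percentages
summing to 100 (±0.05 after rounding), sorted descending and accumulated;
key variables are the smallest prefix reaching 90% cumulative.

Response curves use the evaluation-strip method: the focal variable is
swept over its observed range (default 50 grid points) with all other
variables at their per-cell values, averaging predicted HSI over at most
10⁴ seeded-subsampled mask cells. The "best suitable range" is the
contiguous interval around the global maximum where the mean response stays
at or above half the curve maximum (default), or above an absolute HSI of
0.5 (alternative criterion); non-contiguous qualifying sets raise a
multimodality flag and report the block containing the global maximum.
Because predicted probability is a saturating transform of true
suitability, the modelled curve's half-max interval is systematically wider
than the truth's half-max interval; the recovery guarantees tested are
therefore (a) exact interval extraction on constructed curves and (b)
optimum location recovery on modelled curves.

## Numerical choices and degenerate inputs

- Cell assignment uses half-open intervals [edge, edge + res) with
  cell-centre representatives; thinning is idempotent by construction.
  When the fishnet is coarser than the analysis grid, the representative
  analysis cell within a fishnet cell is the first on-mask member in
  row-major order.
- Constant layers (undefined Pearson r) are dropped from screening with a
  warning; which member of a violating pair is dropped follows a user
  priority list (default: input order, earlier wins), recorded for audit.
- Stratified split counts use round-half-to-even per class; classes absent
  from either side raise an error advising more rows.
- GLM failures (separation, singular designs) are captured as runs with
  status "failed" and excluded downstream, never crashes.
- Weights require strictly positive member TSS (guaranteed post-gate);
  empty ensembles carry an explicit warning status and downstream stages
  refuse to predict from them.
- Regressions of IRI on HSI with constant HSI are reported as degenerate
  rather than fitted.

## Problem sizes

The default protocol (3 algorithms × 10 repetitions × 3 pseudo-absence
sets of 5000 on a 128 × 128 coastal grid) runs in a few minutes on one
core and is exercised end-to-end in the test suite. Replicated stochastic
checks (dominant-variable ranking, ensemble-versus-member skill) use 20
replicates at 64 × 64 with 300 presences, 600 pseudo-absences and RF + GLM
members — sizes chosen so each replicate fits in seconds while keeping
validation sets large enough (≈225 rows) for stable TSS. The replicate
experiments gate at TSS 0.7 because small validation sets make the 0.9
gate needlessly brittle there; the gate itself is tested separately at its
0.9 default.

## Known limitations

- Pseudo-absence contamination (background cells that are truly suitable)
  biases probabilities downward in high-prevalence scenarios; the package
  does not correct for it.
- The contribution and best-suitable-range conventions are documented
  choices, not community standards; both expose alternatives.
- No spatial cross-validation: repeated random splits share spatial
  autocorrelation between train and validation, so reported TSS/AUC are
  optimistic for spatially structured data.
- Raster I/O is deliberately lightweight (single-band float32 TIFF with a
  JSON sidecar carrying geotransform and no-data); no CRS handling or
  reprojection is attempted, and stacks must be pre-aligned — alignment is
  verified, not fixed.
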