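# Methods

## Problem and model

Given two views measured on the same n samples — a compositional table X
(taxon counts or relative abundances, p features) and a second view Y
(q features, either non-compositional such as metabolite sub-pathway
abundances, or another compositional table) — sparse canonical
correlation analysis (sCCA) seeks coefficient vectors a and b maximizing
the sample correlation between the scores Y a and Z b, where
Z = log X.  Because sequencing depth is an artifact, only log-ratios of
compositional features are interpretable.  Constraining the
log-abundance coefficients to the zero-sum hyperplane

    B_p = { b : sum_j b_j = 0 }

makes b' Z invariant to per-sample rescaling of X and is equivalent to
log-ratio modeling without designating a reference taxon.  As in the
penalized-matrix-decomposition family of high-dimensional CCA methods,
the within-view covariances are replaced by the identity, leaving the
biconvex problem

    min_{a,b}  -a' S b + lam_a ||a||_1 + lam_b ||b||_{1,w}
    s.t.  ||a||_2 <= 1,  ||b||_2 <= 1,  b in B_p,

with S the sample cross-covariance of (Y, Z) and ||b||_{1,w} a weighted
l1 norm.  In the two-sided variant both views are log-compositional and
a is constrained to B_q as well.

## Updates and the constrained prox

The alternating scheme initializes a at the leading left singular vector
of S and iterates:

* b-step: b ∝ g(S'a, lam_b, w), where
  g(h, lam, w) = argmin_{b in B_p} ½||h-b||² + lam Σ w_j |b_j|,
  followed by l2 normalization;
* a-step (unconstrained side): a ∝ soft-threshold(S b, lam_a),
  normalized; a degenerates to the zero vector once lam_a ≥ ||S b||_∞.
  On a compositional a side the b-step operator is used instead.

Only the binding-l2-constraint branch of the updates is implemented: the
goal is a direction maximizing covariance, so interior solutions (which
arise only in degenerate settings) are not searched.

g is evaluated by an augmented Lagrangian method: the zero-sum equality
enters through a quadratic penalty (step mu1 = 1) plus a scalar dual d
updated by gradient ascent (step mu2 = 1); each subproblem is minimized
by cyclic coordinate descent with the closed-form update

    b_j <- S(h_j - mu1 (Σ_{i≠j} b_i + d), lam w_j) / (1 + mu1),

kept O(1) per coordinate by carrying the running sum of b.  The dual is
refreshed once per ALM step (after the inner loop converges), the
literal reading of the update scheme.  Convergence declares when
max(|1'b|, ||b - b_prev||_∞) < 1e-8 (caps: 1000 sweeps, 1000 ALM steps;
exhaustion raises an error carrying the last iterate).  At lam = 0 the
operator reduces to the exact hyperplane projection h - mean(h) and is
computed in closed form.  The problem is strictly convex, so the warm
start (previous outer iterate, else the projection of h) affects speed
only.  The inner loop is jit-compiled with numba when available.

Outer convergence uses the max-norm change of both directions with
tolerance 1e-6 and a 200-iteration cap.  Sign indeterminacy of (a, b) is
resolved by making the largest-magnitude entry of a positive (ties to
the lowest index); a degenerate side reports a zero vector and a
correlation of 0.

## Adaptive and group-adaptive weights

Penalty weights on a compositional side are re-estimated each outer
iteration by minimizing Σ_j (w_j |b_j| - log h(w_j; gamma)) over a
constraint set M, where h(w; gamma) = exp(w^{1-1/gamma}/(1-1/gamma)) for
0 < gamma < 1 and h(w; 1) = w.  The closed forms are

* elementwise (M = [0, C_U]^p):  w_j = |b_j|^{-gamma}, w_j = C_U at
  b_j = 0;
* grouped (M = M_group, one shared weight per taxonomic group S_d):
  w_j = (mean_{i in S_d} |b_i|)^{-gamma}, C_U when the whole group is
  zero.

Weights are clipped at C_U (default 1e5) even for tiny nonzero
coefficients so they stay inside M.  Weights start at all-ones, so the
first iteration coincides with the uniform-weight fit.  In the one-sided
adaptive variants the non-compositional a side uses elementwise adaptive
thresholds with the same gamma and cap.  The stopping rule monitors
(a, b) only, not the weights; the weights are a deterministic function
of b, so they stabilize with it.

## Two-stage cross-validated tuning

Penalties are chosen by K-fold CV (default K = 5) on the criterion
CV(lam_a, lam_b) = mean_k Corr(Y_k a_{-k}, Z_k b_{-k}).  To remove the
shrinkage bias of penalized coefficients, each fold is scored in two
stages: stage 1 fits at the candidate penalties on the training folds
and records the surviving features; stage 2 refits on the training folds
restricted to those features with penalties (0, 0) — retaining the
zero-sum constraint on compositional sides — and the held-out Pearson
correlation of the refit scores enters the average.  Folds whose stage-1
support is empty (or a single zero-sum coefficient, which can only be
zero) contribute 0, penalizing over-sparse grid points consistently.
The maximizing triple wins, first-in-grid on ties; optionally the
criterion is averaged over several independent fold partitions first.

### Default penalty grids

The default grids are data-driven.  Penalty ceilings come from
explicit degeneracy bounds: on a zero-sum side g(h, lam, w) vanishes
once lam ≥ max(h) - min(h) (uniform weights); on an unconstrained side
the soft threshold kills everything at lam = ||v||_∞.  Grid values are
log-spaced fractions of these ceilings:

* uniform-weight methods: 6 fractions from 0.05 to 0.8;
* adaptive methods: 8 fractions from 0.003 to 0.8, crossed with the
  gamma grid (default: the single classic adaptive-lasso exponent
  gamma = 1).

The adaptive grid reaches two orders of magnitude deeper because
re-weighting multiplies effective per-feature penalties by |b_j|^{-gamma}
(often 5-15x at unit-norm scale), compressing the informative part of
the path toward small lam.  The single-exponent default is a deliberate
choice: at the simulation's signal strengths the two-stage CV surface is
nearly flat between the true-support fit and both over-dense fits
(admitted by small gamma, whose weights are close to uniform) and
half-support fits (at coarse lam spacing), so with single-partition CV
the argmax wanders among near-ties; gamma = 1 with dense lam resolution
keeps the selection stable.  Other gamma grids and spans are available
through the ``gammas``/``frac_min``/``n_lam`` arguments.

## Preprocessing conventions

For real tables: optional prevalence filtering (e.g. keep genera present
in at least a quarter of samples), replacement of exact zeros by a
pseudocount (0.5 on the count scale; user-supplied for relative
abundances), natural log, then column centering.  Per-column unit
variance scaling is optional: it is the convention for metabolite data
and available (off by default) for the log-compositional view, since the
simulations are fit on the raw log scale.  Missing values are rejected,
not imputed.  Cross-covariances use the unbiased 1/(n-1) scaling; every
solver output is invariant to a positive scalar on S (updates
renormalize to unit l2), so this choice is consequence-free.

## Synthetic data

The generator draws one latent factor nu_i ~ N(0, sigma_nu²) per sample
and sets log X_i = nu_i ω_X + ε (and Y_i = nu_i ω_Y + ε, log-scale in
the two-sided setups) with isotropic N(0, sigma_eps²) noise,
sigma_eps = 1.  Loading patterns:

* S1/S3 block: ω_X = 0.85/10 · (1 ×9, -9, 0…) — nine small loadings
  balanced by one large negative one;
* S2/S4 split: ω_X = 0.85/6 · (1,1,1,0,0,1,1,-5,0,0, 0…) — signal
  straddling two groups that also contain nulls (a deliberately
  imperfect grouping);
* non-compositional ω_Y: 0.85 × ten equally spaced values from 0.08 to
  0.12; S3's compositional ω_Y: 0.85 × (0.08, 0.085, …, 0.12, -0.9, 0…).

Compositional loadings sum to zero exactly, so the cross-view
association is mediated purely through log-ratios.  The compositional
features form 20 contiguous equal-sized groups (size 5 at p = 100, 10 at
p = 200).  The reference sample size is n = 100 per replicate: the study
whose tables this harness regenerates does not state one, and 100 is of
the same order as the real cohort (241 samples) and typical of the
comparison literature; it is a config field so sensitivity can be
checked.  Experiment summaries average TPR/FPR/MCC/Precision of the
recovered supports and the sign-aligned RMSE to ω/||ω||₂ over 30
replicates per cell (20 for the signal-strength sweeps at reduced
dimensions), a Monte-Carlo size chosen so each cell runs in minutes on
one core; the per-cell means carry Monte-Carlo standard errors of
roughly sd/√30.

What the generator does not emulate: zero inflation and the
count-sampling layer (data are generated directly on the log scale),
library-size variation, overdispersed or correlated noise, and
phylogenetic correlation within groups.  Passing tests therefore
demonstrate correctness of the estimators and tuning under the stated
latent-factor model, not robustness to those real-data features.

## Numerical choices and degenerate inputs

* MCC is defined as 0 whenever a factor under its square root is 0;
  Precision is 0 when nothing is selected; a degenerate (all-zero)
  direction scores TPR = FPR = MCC = Precision = 0 and its RMSE is
  computed against the target as-is.
* RMSE resolves the global sign by taking the smaller of the two values
  over ±estimate (the model identifies directions only up to sign).
* The boundary lam_a = ||v||_∞ is assigned to the degenerate branch.
* h(w; gamma) at w = 0 with gamma < 1 is a limit never reached: the
  weight updates return values in (0, C_U].
* Fold partition: a seeded permutation split into K nearly equal blocks
  (sizes differ by at most one).

## Known limitations

* Single canonical pair only; no deflation for further pairs.
* Within-view covariances are treated as identity throughout; the full
  covariance variant is out of scope.
* The zero-sum device addresses relative-abundance data; when absolute
  microbial load matters the model is mis-specified by construction.
* Group weighting assumes a flat partition of taxa; hierarchical or
  tree-smoothed weight sets are not implemented.
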