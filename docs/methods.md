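# Methods

## Model

The observed taxa × samples abundance matrix *D* ∈ ℝ₊^(p×N) is treated as
the sum of a low-rank matrix *L* (abundance structure shared across
samples: the non-differential bulk of the community) and a sparse matrix
*S* (the perturbation contributed by the few taxa that respond to the
phenotype). Entries of *S* may be positive or negative — a responding taxon
can be enriched or depleted — and a taxon's differential-abundance score is
the l1 mass of its row of *S*. The decomposition is the convex Principal
Component Pursuit program

    minimize ‖L‖★ + λ‖S‖₁   subject to  D = L + S,

whose solution provably coincides with the true pair when *L* is
incoherent (its singular vectors are not aligned with the coordinate axes)
and the support of *S* is not too large and spread out. Real abundance
matrices satisfy these assumptions only approximately; the recovered *S*
is best read as "what the best low-rank background cannot explain".

Detection is fully unsupervised: class labels never enter the
decomposition, the scoring, or the top-*m* selection. Labels are used only
by the optional direction annotation and by the evaluation protocol.

## Solver

Augmented Lagrangian iteration on
l(L, S, Y) = ‖L‖★ + λ‖S‖₁ + ⟨Y, D−L−S⟩ + (μ/2)‖D−L−S‖²_F. Each outer
iteration applies the two closed-form proximal updates and a dual ascent
step:

- L ← 𝒟_{1/μ}(D − S + Y/μ)   (singular-value thresholding),
- S ← 𝒮_{λ/μ}(D − L + Y/μ)   (elementwise soft thresholding),
- Y ← Y + μ(D − L − S),

with μ multiplied by ρ after each outer iteration (capped at 10⁷·μ₀).
Two schemes are provided:

- `inexact_single_update` (default): one L and one S update per multiplier
  step. This is the standard inexact ALM for PCP and is almost always the
  right choice.
- `exact_inner_loop`: the L/S alternation repeats until the inner change of
  S falls below `inner_tol_factor·‖D‖_F` (default 1e-6, at most
  `max_inner=100` sweeps) before each multiplier update.

Stopping: the inexact scheme stops when the relative feasibility residual
‖D−L−S‖_F/‖D‖_F falls below `tol`. For the exact scheme feasibility alone
is a weak certificate — the sub-problem iterate can still be moving when
the constraint is nearly met, which leaves spurious near-threshold entries
in *S* — so it additionally requires the outer S iterate to have settled
(relative change ≤ `tol`). Hitting `max_iter` reports `converged=False`
with diagnostics rather than raising.

### Parameter defaults

| parameter | default | meaning / rationale |
|---|---|---|
| λ | 1/√max(p, N) | sparsity weight; the scaling under which PCP exact-recovery guarantees hold, and the value to perturb first when the sparse part looks too dense or too thin |
| μ₀ | 1.25/σ₁(D) | initial penalty; standard inexact-ALM practice, makes the first SVT threshold slightly smaller than σ₁ |
| ρ | 1.5 | μ growth per outer iteration; larger is faster but sloppier |
| tol | 1e-7 | relative Frobenius feasibility threshold |
| max_iter | 1000 | outer-iteration cap |
| Y₀ | D / max(σ₁(D), ‖D‖∞/λ) | dual-feasible warm start; Y₀ = 0 also converges, just more slowly |

The matrix is decomposed as given (relative abundances). A
`--log-transform` (log10(x + pseudocount), shifted to keep entries
nonnegative) preprocessing flag exists for users whose signal is
multiplicative, but it defaults off.

Numerical details: SVT uses a thin LAPACK `gesdd` SVD and remultiplies only
the components above the threshold; `rank_L` counts singular values above
1e-8·σ₁(L); `nnz_S` counts exact nonzeros (soft thresholding produces exact
zeros, so this is meaningful). For D = 0 the relative residual is replaced
by the absolute one and the solver exits immediately at the zero fixed
point.

## Biomarker scoring

v = [Σⱼ|s₁ⱼ|, …, Σⱼ|s_pⱼ|]ᵀ; the top-*m* scores win. Ties are broken by
input (row) order, which makes rankings deterministic — important because
the stability protocol compares selections across hundreds of runs.
Direction annotation compares class means of the **original** matrix *D*
(not *S*): a marker is `up_in_positive` when its mean abundance in the
positive class is strictly higher. Using *D* rather than *S* is a
documented choice; per-class sign patterns of *S* would be a reasonable
alternative, but class means are directly interpretable in abundance
units.

## Evaluation protocol

For k = 1…K: draw ⌈rN⌉ training samples without replacement (default
K=500, r=0.8 — at typical study sizes this gives a few dozen held-out
samples per replicate); run the selector on the training columns only;
select the top-*m* taxa; fit one centroid per class (arithmetic mean of
the class's training columns restricted to the selected taxa); classify
each held-out sample by nearest centroid under l1 (NCC-1) or l2 (NCC-2)
distance, ties going to the lexicographically smaller class label.

Consistency is the average Kuncheva index over all K(K−1)/2 pairs of
selections. The index's T²/p correction centers random agreement at zero;
it is undefined at T = 0 or T = p, and those sizes are rejected rather
than defined by continuity. Classification metrics are plain averages of
per-replicate accuracy/sensitivity/specificity; a replicate whose test set
lacks one class yields an undefined class-specific metric, which is
excluded from the mean and counted in the report (`n_sensitivity` etc.)
rather than being treated as zero.

Subsampling is stratified by class when labels are supplied (per-class
counts ⌈r·N_c⌉, trimmed from the largest class to total ⌈rN⌉); this keeps
small classes represented — with 10 control animals and r=0.8, plain
uniform subsampling would occasionally produce train sets with almost no
controls. Plain uniform subsampling is available (`stratify=False`).
Replicate k draws its randomness from a child seed derived
deterministically from (master seed, k), so any single replicate can be
reproduced in isolation and replicates are independent of execution order.

Selectors are callables `(train_matrix, rng) -> ranked taxa` returning a
full descending ranking; the protocol slices the top-*m* prefix for every
requested size, so one PCP solve per training subset serves the whole size
grid. Shipped selectors: `rpca_selector` (the method), `random_selector`
(chance-level reference) and `constant_selector` (perfect-consistency
reference). External selectors plug in through the same signature.

## Synthetic generator

Emulates the generative model the method assumes, with ground truth:

- Background L0 = |A·Bᵀ| with A (p×rank), B (N×rank) standard normal,
  columns scaled to sum to 1. The absolute value keeps abundances
  nonnegative at the price of inflating the numerical rank well above the
  nominal `rank`; recovery statements therefore always compare against the
  stored L0 rather than a nominal rank. Defaults: p=300, 40+40 samples,
  rank 3.
- Planted markers: `n_markers` (default 20) uniformly chosen rows receive
  a positive-class-only shift. Each affected entry is drawn as
  effect·U(0.5, 1.5) — mean `effect` (default 0.02, about 6× the mean
  background entry), varying per sample. The variation matters: real
  differential abundance differs between subjects, and a perfectly
  constant shift would form a rank-1 block that the convex program
  correctly books as background rather than as a sparse perturbation,
  making "markers" that no low-rank+sparse method should be expected to
  find. With `mixed_signs`, each marker's shift direction is drawn ±1.
- Optional elementwise Gaussian noise (`noise_sd`, default 0 so recovery
  tests are exact); `nonneg` clips negatives and renormalizes columns.
  Without `nonneg`, negative entries (possible only with noise or mixed
  signs) are clipped at 0 so the result is a valid abundance matrix.

What passing tests on this generator do **not** show: robustness to
compositional closure effects, zero inflation, sequencing-depth variation,
overdispersed counts, or phylogenetically correlated backgrounds — none of
which the generator produces. Results on it certify the optimization and
the protocol plumbing, not field performance.

## Problem sizes in the shipped tests

Exact-recovery checks run on 200×100 instances (rank 5, 5% sparse support,
5 seeds, both schemes); the end-to-end protocol check runs the generator
defaults with K=50 subsample replicates at r=0.8. These sizes exercise
every code path at comfortably interactive runtimes; all quantities scale
to larger K or p without code changes.

## Known limitations

- PCP has no explicit dense-noise term; heavy elementwise noise ends up
  split between L and S and degrades scores gracefully but without
  guarantees (a stable-PCP variant with a quadratic slack is out of scope).
- λ, μ₀, ρ are theory-motivated defaults, not data-driven; on matrices with
  badly non-incoherent backgrounds the λ default may need manual tuning.
- The Kuncheva index requires equal-size sets; the protocol compares only
  fixed-size selections.
- Direction annotation is a two-class mean comparison; no effect size,
  p-value or FDR is computed (deliberately — the detector is a ranking
  method, not a hypothesis test).
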