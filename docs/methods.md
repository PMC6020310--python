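# Methods

## Model

Per-base ChIP-seq fragment counts are modelled as negative binomial,
`y_i ~ NB(mu_i, theta)` with variance `mu + mu^2/theta` (Poisson limit
as `theta -> inf`; this parameterization is fixed package-wide). The
log mean is additive in smooth functions of genomic position:

    log mu_i = o_i + sum_k f_k(x_i) z_{j_i,k}

`o_i` is a known offset (log size factor of sample `j_i`), and the
binary matrix `Z` encodes the factorial design: column `k` marks the
samples to which smooth `k` contributes. With
`Z = [[1,0],[1,1]]` the second smooth is the log fold-change of
treatment over control at every base.

Each smooth is a cubic B-spline expansion on a uniform knot grid.
All smooths share the same basis `X_k`, so the full design is the
Kronecker product `X = Z (x) X_k`, laid out sample-major (all positions
of sample 1, then sample 2, ...). Coefficients maximize

    l_NB(beta; y, theta) - lambda * beta' (S_full + eps I) beta

where `S_full` is block-diagonal with one second-order difference
penalty `S = D'D` per smooth. The penalty's null space (constant and
linear coefficient vectors) is untouched by `lambda`, which is why flat
data is fitted exactly at its log mean regardless of smoothing; the
ridge `eps I` removes the remaining indeterminacy in long zero-count
stretches.

## Estimation

For fixed `(lambda, theta)` the objective is concave. Newton–Raphson
iterates

    beta <- beta - H^{-1} grad,
    grad = X'u - 2 lambda (S_full + eps I) beta,
    H    = X'WX - 2 lambda (S_full + eps I),

with `u_i = y_i - (y_i + theta) mu_i / (mu_i + theta)` and full-Newton
curvature `W_ii = -theta mu_i (y_i + theta) / (mu_i + theta)^2`
(the observed second derivative in the linear predictor, not its
expectation — i.e. not Fisher scoring). Both formulas are gated by
finite-difference tests. The step solves the banded sparse system with
a direct sparse LU factorization; the inverse is never materialized.
Safeguards and numerical choices:

* initialization: penalized least squares of `log(y+1) - o` on `X`;
* step halving (max 20) if a full step would decrease the objective —
  rarely triggered, but it makes the objective provably monotone;
* convergence when the gradient max-norm falls below 1e-6 **or** the
  relative objective change falls below 1e-8, whichever first;
  max 50 iterations (typical tiles converge in 3–6);
* linear predictors are clipped at ±50 before exponentiation, with a
  warning — this only activates on degenerate inputs;
* default `eps = 1e-3`.

## Standard errors via the sparse inverse subset

The coefficient covariance is `(-H_k)^{-1}` per smooth, where `H_k` is
the corresponding diagonal block of `H`. The pointwise variance
`sigma_i^2 = diag(X_k (-H_k)^{-1} X_k')_i` touches only entries
`(l, j)` of the inverse for which some row `i` has `X_il X_ij != 0`;
every such pair is a nonzero of `X_k'X_k` and hence of `H_k`. Since the
nonzeros of a matrix's lower triangle are contained in its Cholesky
factor's pattern, the entries of the inverse on the factor's fill
pattern suffice.

Those entries come from the Takahashi recursion run backwards over the
fill pattern of `L` (from `A = -H_k = L L'`): with unit factor
`L~ = L diag(L)^{-1}` and `D = diag(L)^2`,

    Z_jj = 1/D_j - sum_k L~_kj Z_kj
    Z_ij = -sum_k L~_kj Z_ik     (i > j in the pattern)

columns processed last to first. Cholesky fill patterns are closed
under the elimination tree, so every right-hand entry is available when
needed; the package verifies pattern sufficiency explicitly at run time
and raises if an entry is missing (that would indicate a bug, not a
data problem). The variance is then contracted without any dense
matrix: the sparse product `X_k Z` is formed once, multiplied
elementwise with `X_k`, and summed over columns.

The sparse Cholesky itself is obtained from a SuperLU factorization in
symmetric mode with diagonal pivoting disabled and a fill-reducing
minimum-degree ordering: for an SPD input, `U = D L'` with positive
`D`, so `L_chol = L sqrt(D)`. Because `H` is negative definite, `-H` is
factorized and signs restored where the inverse of `H` itself is
reported. An independent route — row-batched triangular solves,
`sigma_i^2 = ||L^{-1} x_i||^2` (batch size 256 to bound memory) — is
kept as a cross-check oracle and fallback; it is quadratic-time and is
not the default path. Derivative-of-smooth variances are exposed for
first derivatives only, by substituting differentiated basis rows into
the same contraction.

Pointwise significance is the plain Gaussian z-test `z = f/sigma`,
`p = 2 Phi(-|z|)`; region-level error control is out of scope.

## Spline basis and penalty

Inner knots at `start, start + d, ...` (default spacing `d = 20` bp,
chosen so a default tile carries a few thousand coefficients), with
three extra uniformly spaced knots beyond each boundary so every inner
position carries a full complement of basis functions; the basis
dimension is `(#knots) - 4`. Rows form a partition of unity; values
below 1e-14 are stored as structural zeros so the declared pattern (at
most 4 nonzeros strictly between knots, 5 counting closed supports) is
exact. Coordinates are 0-based half-open, matching BAM/BED conventions.

## Tiling and assembly

Chromosomes are cut into tiles of 24 kb advancing by
`tile_size - overlap` (overlap 3 kb), the last tile pinned to end at
the chromosome end. Each tile is fitted independently — tile fits share
no mutable state, so worker count cannot change results. Final per-base
values come from the tile whose *chunk* (tile interior bounded by
overlap midpoints; terminal chunks extended to the chromosome
boundaries) owns the base: hard ownership, no blending. On simulated
30 kb genomes the joined fit agrees with a global single-tile fit to
better than 1e-4 everywhere outside 50 bp of the join (in practice it
agrees to near machine precision, because chunk boundaries sit far from
tile edges where boundary effects live). Non-converged tiles NaN-mask
their chunk and are reported in the diagnostics table rather than
failing the run.

Results are held in memory by default; the HDF5 backend pre-creates
full-length datasets chunked by chunk length and writes tile results
from a single writer. Exports: HDF5 (bit-exact round trip), dense TSV,
bigWig per smooth/track, and BED runs of bases below a pointwise
p-value threshold.

## Sequencing-depth normalization

Size factors use the median-of-ratios rule on non-overlapping 1 kb
genome bins of raw fragment counts: a bin's pseudo-reference is the
geometric mean across samples; a sample's factor is the median ratio
over bins positive in every sample. Factors are geometric-mean centered
(offsets sum to zero in log space), which fixes the identifiability of
intercept-like components; fitted baseline levels shift accordingly.
A single sample gets factor 1. The estimator is cross-checked in the
tests against an independent DESeq2-family implementation.

## Fragment handling

Paired-end fragments are counted once, at the template midpoint taken
from the leftmost mate; single-end reads are shifted by half a
user-supplied fragment length along their orientation (no
cross-correlation estimation). Secondary/supplementary, unmapped and
QC-fail records are skipped and tallied; duplicates are kept unless
dropped by flag — the counting model treats fragments as events.
Out-of-range centers are clipped to the boundary and tallied.

## Hyperparameter selection

`lambda` and `theta` are global. They maximize the summed out-of-fold
NB log-likelihood over tiles sampled with probability proportional to
total counts (defaults: 20 tiles, 10 folds). Held-out positions come in
20 bp consecutive blocks assigned round-robin after a seeded shuffle,
so a held-out block must be interpolated from flanking data — a test of
smoothing, not memorization. In-fold fits drop held-out rows entirely
(zeroing them would bias the mean downward); the held-out score is the
unpenalized likelihood. The search is Nelder–Mead over
`(log10 lambda, log10 theta)` from seeded multi-starts (3 starts, up to
50–60 evaluations each); a joint search, since the two parameters
interact through the weights. Fold assignments are fixed per tile, so
the whole selection is bit-reproducible from its seed. A fold that
fails to converge scores `-inf` for that candidate.

## Synthetic data

The generator draws NB counts under the exact factorial model with
known truth. True smooths are sums of Gaussian bumps — deliberately not
splines, so the estimator's basis never trivially contains the truth.
Bump heights of order 1 on log scale, widths of hundreds of bp, and
baselines giving roughly 5–20 expected fragments per base mirror
enriched regions in real ChIP-seq at typical depths. Counts can be
expanded to aligned reads (single- or paired-end BAM) whose fragment
centers map back to the originating base, closing the loop with
ingestion; fragments overhanging chromosome ends are shifted inward and
logged, so exact count round-trips hold away from the ends.

What the generator does *not* emulate: mappability and GC artifacts,
copy-number variation, input-vs-IP background structure, non-uniform
fragment lengths, or inter-replicate dispersion heterogeneity. Passing
recovery and coverage tests therefore demonstrate correctness of the
estimator under its own model assumptions, not robustness to these
real-data complications.

## Validation experiment sizes

The test suite runs at desk scale by design: oracle-equivalence checks
use ~20 random tiles with up to ~300 coefficients (dense oracles are
cubic); the tile-join check uses a 30 kb genome; hyperparameter
recovery uses a 24 kb two-condition genome, two CV tiles of 6 kb and
10 folds; coverage uses 1 kb tiles over 20 replicates; scaling checks
run to 4000 coefficients. With these sizes the recovered dispersion
lands within a few percent of the generative value, the CV-selected
`lambda` sits essentially on the ISE-optimal grid point, and pointwise
95% intervals cover the truth at ~0.97.

## Known limitations

* Only the negative binomial family is implemented (no quasi-binomial,
  hence no methylation data).
* No region-level significance testing or peak calling; the pointwise
  z-test is provided as a building block.
* `theta` is global and fixed during fitting (no profiling inside the
  Newton loop); `lambda` is genome-wide, not per-tile.
* Single-end fragment length must be supplied by the user.
* HDF5 writing is single-writer; parallelism is per-tile within one
  process pool.
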