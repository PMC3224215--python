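# Methods

## Model

The predictor is a linear scoring function over a fixed-length peptide's
feature vector, `f(x) = wᵀx + b`, trained by minimizing

```
L(w, b) = (1 − λ₁ − λ₂)/N · Σᵢ μᵢ g(f(xᵢ), mᵢ)  +  λ₁ Σⱼ|wⱼ|  +  λ₂ Σⱼwⱼ²
```

where `mᵢ` are the measured pIC50 values, `μᵢ > 0` are optional per-sample
weights (default 1; exposed because some assays warrant unequal
confidence, but nothing in the default workflow sets them), and
`g` is the *soft loss* `g(f, m) = log(1 + (f − m)²)` (natural logarithm).
The soft loss is bounded above by the squared error and grows only
logarithmically, so single aberrant measurements cannot dominate the fit.
The bias `b` is never penalized. The penalties are the standard Lasso and
ridge power forms `Σ|wⱼ|ᵖ`; a literal p-norm `(Σ|wⱼ|ᵖ)^{1/p}` variant is
kept behind the `literal_norm` flag of `ObjectiveConfig` for comparison
(the objective module computes its value and gradient; the optimizer and
pipeline always use the power forms, whose L2 gradient is linear).

Training is two-step:

1. **Selection.** Minimize `L` with λ₂ = 0. The L1 term pushes irrelevant
   weights toward zero; all features with `|wⱼ| < 10⁻⁸` are removed.
2. **Refit.** Minimize `L` with λ₁ = 0 on the surviving columns only.

λ₁ and λ₂ are chosen sequentially, each by k-times-repeated n-fold cross
validation (defaults k = 5, n = 10; candidate grids
λ₁ ∈ {0.001, 0.005, 0.01, 0.05, 0.08, 0.1, 0.2, 0.3},
λ₂ ∈ {0.0001, 0.001, 0.01, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9,
0.93}). The data-term prefactor `(1 − Σλ)` keeps the trade-off between
data fidelity and penalty on a fixed 0–1 scale, which is why λ values near
1 correspond to near-total shrinkage. A joint 2-D search over (λ₁, λ₂) is
deliberately out of scope: the two penalties serve different purposes in
different stages.

## Feature encoding and normalization

Each residue position contributes three blocks, concatenated per peptide
in the fixed order **[physico-chemical | sparse | BLOSUM]**:

* physico-chemical: the `P` values of the residue's row in a descriptor
  table (user input; the canonical literature collections have P = 643,
  giving 5787 features for 9-mers and 5144 for 8-mers);
* sparse: a 24-long one-hot sub-vector, component order
  `ACDEFGHIKLMNPQRSTVWY` then `* B X Z` (gap, Asn/Asp ambiguity, unknown,
  Gln/Glu ambiguity) — 216/192 features for 9-/8-mers;
* BLOSUM62: the residue's 24-long row of the embedded NCBI BLOSUM62
  matrix (column order `ARNDCQEGHILKMFPSTWYVBZX*`) — again 216/192.

Total `d = (P + 48)·L`; 6219 for nona-peptides and 5528 for octo-peptides
with a 643-property table. Placeholder letters are legal for the sparse
and BLOSUM blocks but rejected by the physico-chemical encoder (they have
no descriptor rows), so the combined encoding requires standard residues.

Columns with training standard deviation below 10⁻¹² are dropped as
uninformative (the tolerance absorbs floating-point noise in constant
columns); the rest are standardized to mean 0 / sd 1 using *training*
statistics with the **population** (denominator-n) standard deviation —
the convention is recorded in the saved model so results are reproducible.
Test data are transformed with the stored parameters and never re-filtered.
Inside cross validation the normalizer is refit on each fold-training
portion by default, so no test-fold information leaks into scaling; a
`global` mode (one normalizer on the full training set) exists for
comparison with protocols that normalize before splitting.

## Optimizer

iRprop⁻ with η⁺ = 1.2, η⁻ = 0.5, initial step Δ₀ = 0.1, step bounds
[10⁻⁹, 50], at most 2000 iterations. Each parameter (every wⱼ and b) keeps
a private step size: agreement in sign of the current and previous partial
derivative grows the step by η⁺, disagreement shrinks it by η⁻, skips that
parameter's update for one iteration and zeroes its stored derivative;
parameters move by `−sign(∂L)·step`. Initialization is `w = 0`,
`b = mean(targets)` — deterministic and on the right scale. The L1
subgradient uses `sign(0) = 0`, so a weight at zero moves only if the data
gradient pushes it.

Stopping: the run ends at `max_iter`, when the objective changes by less
than `tol = 10⁻¹⁰` on two *consecutive* iterations, or when every step
size has reached the 10⁻⁹ floor. The two-in-a-row requirement matters:
iRprop⁻ alternates skip and move phases, and an iteration in which every
active parameter happens to skip leaves the objective exactly unchanged
without being anywhere near a minimum. The floor rule terminates the
terminal oscillation regime, where weights that the exact Lasso solution
would zero out are jittering within ±10⁻⁹ of zero — one decade below the
10⁻⁸ selection threshold, which is why thresholding reproduces the exact
sparse support (verified against coordinate-descent Lasso in the test
suite, at the penalty-scale correspondence `α = λ₁ / (2(1 − λ₁))`).
The best-objective iterate seen is returned, not the last one.

For the squared loss + L2 objective the exact minimizer is computed from
the normal equations `(c·AᵀA + diag(λ₂,…,λ₂,0))θ = c·Aᵀm` with
`A = [X 1]`, `c = (1 − λ₂)/N`, via a Cholesky factorization; tiny pivots
(squared ratio below 10⁻¹²) are treated as collinearity and reported with
the advice to set λ₂ > 0. This solver is the package's primary numerical
oracle: on random problems the Rprop path agrees with it to better than
10⁻⁴ per weight. The hot loop is compiled with numba; the identical
formulas live in pure numpy in the objective module and the two are held
together by the oracle tests.

## Quality measures

`q² = 1 − Σ(m − p)² / Σ(m − ⟨m⟩)²` with the *measured* mean in the
denominator; it is 1 for perfect prediction, 0 for the mean predictor and
unboundedly negative when predictions are systematically off-scale.
Spearman rank correlation uses mid-ranks for ties. The two dissociate
exactly when the training targets are not a representative sample of the
test targets: a constant offset destroys q² but leaves the ranking intact,
which is why both are always reported.

## Synthetic data

The generators emulate the target regime — on the order of 100 random
peptides of length 8–9, descriptor tables with an adjustable fraction of
near-duplicate columns (noisy copies at correlation ≈ 0.995, emulating the
redundancy of literature scale collections), and targets from a planted
sparse linear signal: a handful of standardized feature columns with
coefficients ±1, a pIC50-like intercept drawn from [5, 8], and Gaussian
noise (default sd 0.1). Targets are generated in the *normalized* feature
space so effect sizes are comparable across encoder blocks; real pIC50
values are of course raw. A split variant adds a constant (+3 by default)
to the test targets only, reproducing the range-mismatch scenario.

What passing tests on these fixtures do **not** show: real binding data
have position-specific residue preferences, correlated measurement error
and anchor-position structure none of which the uniform-residue generator
imitates; recovery rates and q² values on the fixtures are therefore
upper bounds on what identical settings achieve on assay data.

An important structural property carries over, though: because all three
encoder blocks are deterministic functions of the residue letters, the
combined feature matrix is redundant *by construction* (rank at most ~20
per position). L1 selection on such a design is composition-arbitrary —
at small λ₁ it keeps correlated proxies alongside, or occasionally instead
of, a planted column. Measured on the standard recovery fixture (100
training peptides, L = 9, P = 8, d = 504, five ±1 coefficients, noise
sd 0.1, default grids, seeds 0–19): the planted support is *fully
contained* in the selection in 19/20 seeds, but *exact* set equality never
occurs; and with signal-to-noise this high the cross-validated λ₂ lands on
0.0001, making stage 2 a near-unregularized refit whose held-out q²
exceeds stage 1's in only about half the seeds. Stage-2 gains require
noise levels where ridge shrinkage actually buys variance reduction.

## Problem sizes and numerical choices

Tests and the acceptance script run at n ≈ 50–100, d ≈ 200–900 — the same
n/d ratio as the motivating datasets, scaled to keep a full pipeline run
(two CV grids × 50 fold-fits each) around ten seconds. Validation error is
the mean soft loss on held-out samples (consistent with the training
objective); a q²-based criterion is available via
`validation_metric="q2"`. CV ties resolve toward the larger λ. Fold sizes
differ by at most one; per-repeat shuffles derive from one master seed via
`numpy.random.SeedSequence` spawning, so every run is reproducible from a
single integer.

## Known limitations

Fixed-length peptides only — no alignment, no variable-length pooling.
Only one λ is active per stage by design. The Rprop path approximates the
L1 optimum; weights are near-zero rather than exactly zero, hence the
thresholding step. Model files embed the descriptor table for
self-containment, which makes them large for 643-property tables (a few
hundred kB of JSON).
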