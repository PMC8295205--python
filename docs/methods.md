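# Methods

## Model

The package predicts log *P* from 2D molecular structure in three
stages: (1) per-atom attributes from a classical force field, (2) a
geometric scattering transform over the molecular graph, (3) an MLP
regressor with histogram-based prediction intervals.

**Graph.** One node per atom (hydrogens included by default, since the
force fields parameterize them), one edge per covalent bond; bond orders
and aromaticity are collapsed to a binary adjacency. No 3D geometry is
used anywhere: typing, charges and adjacency all derive from
connectivity. Multi-fragment inputs (salts, mixtures) are rejected by
default, with an opt-in largest-fragment policy; neither choice is
statistically neutral, so the policy is explicit at the call site.

**Atom attributes.** Each atom contributes charge, LJ radius, LJ well
depth (raw scalars — standardization happens once, after the transform)
and a one-hot atom type. Vocabularies are frozen per provider, compiled
from the force field's shipped parameter table, so feature width never
depends on the dataset seen and trained models stay portable. LJ
conventions (Rmin/2 vs sigma, units) are passed through exactly as each
force field tabulates them; mixing conventions across providers is
impossible because a model records its provider and vocabulary hash and
refuses mismatched inputs. MMFF94 self-interaction parameters are
computed from the tabulated (α, N, A, G) via R\*₍II₎ = A·α^¼ and
ε₍II₎ = 181.16·G²α² / (2√(α/N)·R\*⁶); a test cross-checks these against
RDKit's independent MMFF implementation. Typing failures are per-molecule
skip records with reasons, never crashes: real corpora always contain
molecules a force field cannot type.

**Scattering transform.** P = ½(I + AD⁻¹) is column-stochastic by
construction; Ψⱼ = P^(2^(j−1)) − P^(2^j) is computed by repeated squaring
with the powers cached across scales; moments are plain q-th power sums
over nodes (no normalization by n, no q-th root). Second-order moments
use strictly j < j′. Defaults J = 4 (the established choice for
small-molecule work) and Q = 4 (a reasonable moment depth covering mean
through kurtosis-like statistics; recorded in every saved model's
metadata). The flat feature layout is frozen — channel outermost, then
S₀ | S₁(j) | S₂(j<j′), then q — and exposed through named columns.

## Numerical choices

**Exact permutation invariance.** Floating-point addition is not
associative, so ordinary BLAS contractions are invariant under node
relabeling only up to ~1 ulp. Every contraction in the transform
(matrix squaring, wavelet application, moment sums) instead materializes
its product terms, sorts each contraction fiber, and reduces with
numpy's deterministic pairwise sum. The multiset of terms is
relabeling-invariant, hence the features are bit-identical under any
atom permutation. The cost is O(n² m log m) per contraction instead of
O(n²m) — negligible for molecules (n ≲ 100) and worth an exactness
guarantee that turns an approximate property into an equality test.
Note the guarantee covers the transform given fixed signals; iterative
charge models (Gasteiger) may themselves differ in the last ulp between
atom orderings.

**Degenerate inputs.** Zero-degree nodes make D singular: rejected with
a typed error (molecules never trigger this after hydrogen handling). A
single-atom graph gets P = [[1]]. Zero-variance feature columns (one-hot
channels absent from a curated subset) standardize to exactly 0 and are
flagged on the scaler.

## Training protocol

ReLU MLP trained with Adam (β₁ = 0.9, β₂ = 0.999) on MSE; inverted
dropout on hidden activations; batch size 256; learning rate
0.005 · 0.5^⌊epoch/15⌋; at most 400 epochs, no early stopping. The grid
{2,3,4,5} layers × {300,400,500} units × {0.2,0.4} dropout (24 points)
is searched with 5-fold CV on validation MSE; the standardizer lives
inside the estimator, so each fold's scaling is fit on its training
folds only; ties break toward fewer layers, then smaller width.

The trainer is written directly on numpy arrays. Two initialization
choices matter at small data scales: the readout layer starts at zero
weights with its bias at the target mean, because the step-decayed Adam
schedule bounds total parameter displacement (each weight moves at most
about the summed learning rate), and a centered start removes an offset
the optimizer would otherwise have to traverse. Hidden layers use He
initialization. With a fixed `random_state`, initialization, shuffling
and dropout masks are all drawn from one generator, making final
weights — and therefore prediction files — reproducible bit-for-bit.

## Prediction intervals

ε₉₀ is the smallest upper edge of a 20-bin equal-width histogram over
[0, max reference error] whose cumulative mass reaches the level (0.90).
Reading the quantile off bin upper edges overshoots the true quantile by
at most one bin width, which makes the rule conservative: expected fresh
coverage is the level plus the error density at the quantile times the
overshoot. The exact empirical quantile is available as
`method="quantile"` and is the calibrated variant used when coverage
itself is the quantity under study; tests check the histogram ε against
analytic quantiles (uniform, half-normal) to one bin width and the
calibrated interval's fresh-sample coverage against its nominal level.
Choosing the reference error set (which molecules count as "similar") is
deliberately left to the caller, keeping the statistical rule separate
from curation policy.

## Synthetic data: what it does and does not emulate

The generator assembles SMILES from valence-respecting fragments (alkyl
chains/branches, aryl rings, ethers, ketones, amines, amides,
thioethers, halogenated carbons, and an explicit sulfonyl connector),
concatenated so heteroatoms stay separated — every output parses,
round-trips through canonicalization, and types under all providers.
Planted facts are recorded at construction time: sulfonyl membership,
element sets, duplicate parentage (duplicates are rewritten-SMILES forms
of earlier records), so curation is graded against ground truth that
does not come from the code under test. Regression targets are linear
in the q = 1 zeroth-order moments with Gaussian noise: weights are
rescaled once so the clean signal has a chosen spread (default sd 2.0,
log-P-like), giving a known Bayes error.

What passing these tests shows: the transform computes the intended
quantities exactly, the filters implement the intended set semantics,
the trainer can recover a recoverable signal down to its noise floor,
and the pipeline is deterministic. What it does not show: accuracy on
real chemistry — the fixtures do not mimic the chemical-space
distribution, tautomerism, charge states or measurement noise of real
log *P* corpora, and real targets are not linear in S₀ moments.

## Problem sizes

Default verification runs use: 200 random graphs (n ≤ 10) against a
naive reference implementation; 100 permutation triples; 500 graphs for
operator laws; 100-molecule curation fixtures with 20% planted
duplicates; a 2000-molecule regression fixture (1600 train / 400 test)
searched over a 2×2×1 sub-grid at 80 epochs per fit — sizes at which
the linear planted signal is already fully converged; and 10⁵ reference
errors for interval calibration. The full 24-point grid and 400-epoch
schedule remain the library defaults.

## Known limitations

- GAFF/Ghemical charges come from Open Babel's default charge model for
  those plugins, which is coarser than the AM1-BCC charges GAFF is
  usually paired with.
- The proprietary CGenFF toolchain is supported only through
  pre-computed per-atom attribute tables (CSV), never invoked.
- The AC36-style type coarsening is supported only as a user-supplied
  mapping file; the default one-hot uses all native types (ACall).
- r² is reported as squared Pearson correlation (`r2`), with the
  coefficient of determination alongside (`r2_cod`); the two differ
  under miscalibrated scale or offset.
- Stereochemistry and 3D conformations are out of scope by design.
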