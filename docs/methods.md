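# Methods

## Scope and model overview

`gcri` treats retention-index prediction as a regression over (molecule,
stationary phase) pairs.  Four model families are layered:

* base neural regressors for non-polar SPs (residual MLP over descriptors,
  1-D CNN over the SMILES character grid), both consuming a shared 38-slot
  SP encoding;
* polar regressors obtained by transfer learning from the non-polar nets;
* a second-level ε-SVR for mid-polar phases and GC×GC second-dimension
  times, stacked on the base-model predictions;
* few-parameter linear models (group contributions; greedy phase
  combinations) for phases with very small data sets.

## Featurization

**Descriptors.** A versioned manifest fixes 243 general descriptors (125
RDKit whole-molecule descriptors plus 118 2-D autocorrelation components)
followed by 84 functional-group counters (RDKit fragment SMARTS counts),
for 327 features in a fixed order.  Scaling is affine, `(raw − offset) /
scale`, with offsets (means) and scales (standard deviations, floored at
10⁻⁹) frozen from a fixed 400-analyte reference library and shipped as
`assets/descriptor_scaling.csv`.  Scaling factors are deliberately **not**
refit per data set: feature vectors must be comparable between the corpus a
net was trained on and any later prediction.  A descriptor that evaluates
non-finite (e.g. information-content overflow on large graphs) is imputed
with its offset — scaled value 0 — and logged.

**Compound identity.** `compound_key` is the canonical SMILES after
removing stereo layers and isotope labels.  Optical isomers, cis/trans
isomers and isotopomers share one key; all splits, exclusions and folds
operate on keys, never on records.

**SP encoding.** One length-38 array serves every net so that weights
transfer across phase families.  Non-polar phases are one-hot over 36
catalog slots; polar phases one-hot over 21 slots (20 named types plus
"Other polar" for anything unrecognized).  The non-polar catalog is closed
— an unknown non-polar name is an error, not a fallback.  Catalog order is
load-bearing (it fixes encoding slots and the feature-block layout), so the
registry is a versioned artifact (`assets/phase_registry.yaml`).

**Structure grid.** The CNN consumes a character-level one-hot of the
canonical SMILES over a fixed 40-symbol alphabet; occupied columns sum
to 1, padding columns are zero, and decoding the argmax reproduces the
string exactly (tested by round-trip).  Over-length molecules are rejected
upstream.  The alphabet covers the admission whitelist
{C,H,O,N,S,P,F,Cl,Br,I,Si}; default maximum length 150.

## Base models and training protocol

The training engine is a compact NumPy implementation (dense, residual
addition, same-padded 1-D convolution, global average pooling; manual
backpropagation; Adam, lr 10⁻³) written for exactly these architectures.

* MLP: input 327+38 → dense(width) → N residual blocks (h ← h + relu(Wh))
  → linear head.  Full-scale default: width 512, 3 blocks.
* CNN: grid → conv(k=5, c₁) → relu → conv(k=5, c₂, stride 2) → relu →
  global average pool → concat SP encoding → dense → linear head.
  Full-scale default: channels 64→128, dense 256.

Targets are RI/1000 under mean-absolute-error loss ("iteration" = one
mini-batch update, batch 256).  Before training, 10 % of training
*compounds* are held out; validation MAE is computed every 500 iterations
(configurable) and the best-checkpoint weights are kept alongside the
final-iteration weights.  Schedules: 50,000 iterations for base training,
10,000 for transfer.  Transfer initializes from the *final* (not
best-checkpoint) non-polar weights: the final weights carry the most
optimization state even when a mid-run checkpoint validated best.
Validation score = validation MAE; with an MAE training loss any of the
plausible early-stopping scores order checkpoints almost identically.

**Desk-scale protocol.**  All simulator studies, the test suite and the
acceptance script use reduced architectures chosen so the full pipeline
runs in minutes on one CPU: MLP width 128 / 2 blocks; CNN channels 8→16,
dense 64, grid length 60; base schedules of a few thousand iterations.
These are the package's simulation protocol sizes, configurable via
`NetSpec`/`TrainProtocol`; the full-scale defaults above remain the
constructors' defaults.

## Second-level SVR

Stacked features are `[114 predicted RIs ÷ 1000 | 327 descriptors]` in a
fixed order: 36 non-polar phases through the CNN, 36 through the MLP, 21
polar phases through CNNPolar, 21 through MLPPolar.  Targets (RI, or GC×GC
second-dimension times) are divided by 1000 for fitting and predictions
multiplied back; the unit tag travels with the model.

The kernel is exponential: `exp(−‖x−y‖/σ)` (Laplacian) by default, with
`exp(−‖x−y‖²/2σ²)` selectable.  The dual problem is solved by
scikit-learn's SVR with a precomputed kernel; the fitted support vectors,
dual coefficients and bias live in the package's own model container, and
prediction is an explicit kernel expansion.  Every fit can be audited with
`kkt_report`, which checks the box constraint |α| ≤ C, zero coefficients
strictly inside the ε-tube, and bound support vectors on or outside it.

**Hyperparameter defaults.**  `SVRHyperparams` defaults are kept verbatim
from the reference configuration: σ = 31.0, ε = 0.82, C = 31·10³,
tolerance 2.7.  On ÷1000-scaled labels these ε and tolerance values are
inconsistent — the entire RI range fits inside one ε-tube (the fit
degenerates to a bias-only model) and 2.7 as a convergence tolerance stops
the solver immediately.  They evidently refer to a different label/solver
convention in the reference software.  We keep them as printed rather than
silently "fixing" them, and every experiment in this package passes the
explicit overrides ε = 0.01, tolerance = 10⁻³ (`DESK_SVR`), which are
consistent with scaled labels.

## Linear models

**Group contributions.**  Ordinary least squares of RI on the 84 counters
plus an intercept, fit on the full data set without a train/test split — a
85-parameter linear model has no meaningful capacity to overfit retention
corpora.  Rank-deficient designs fall back to the minimum-norm solution
with a warning.

**Greedy phase combinations.**  The first phase is the candidate with the
highest absolute Pearson correlation (on centered values) with the target;
coefficients are then refit *without* intercept, matching the printed
equation form.  Each subsequent step adds the candidate giving the largest
drop in MAE of the refit model, stopping when the gain falls below a
threshold (default 5 RI units, the conservative end of the "a few units"
stopping rule) or at five terms.  Ties break toward the lowest column
index.  An optional exclusion set operationalizes the rule of not offering
phases of near-identical polarity together — with two interchangeable
candidates, "most correlated" is decided by noise.  A brute-force
best-subset oracle (`best_subset_combination`) provides an independent
check on small candidate sets.

## The simulator

`log k = c + eE + sS + aA + bB + lL` with:

* **Analytes** drawn from 17 family templates (alcohols, diols, esters,
  ketones, aldehydes, ethers, aromatics, phenols, pyridines, halides,
  nitriles, amines, thiols, sulfides, branched alkanes), chain lengths up
  to 18 carbons with occasional methyl branching.  Solute parameters are
  counts-based — L ≈ 0.52·(heavy atoms), A ≈ 0.35·(H-bond donors), B and S
  from heteroatom and aromatic counts, E from polarizable atoms — plus a
  small jitter deterministic in (structure, seed) that vanishes when the
  structural part is zero (so A = 0 exactly for donor-free analytes).  The
  map is deliberately simple so desk-scale nets can learn it.
* **Phases**: five non-polar (s,a,b ≈ 0) and four polar (large s,a,b,
  smaller l), named after catalog entries, plus arbitrary mixtures via
  `make_linear_phase` (the phase vector is the weighted sum, so log k is
  exactly the same weighted sum for every analyte).
* **RI** via the Kováts bracketing formula against a simulated C5–C40
  n-alkane ladder with L(Cₙ) = 0.52 n exactly; the ladder is therefore
  exactly linear in log k and the near-linear RI–log k link emerges from
  the construction rather than being assumed.  Outside the ladder the
  nearest pair extrapolates linearly and the result is flagged.
* **Noise**: records add Gaussian noise to the true RI, default SD 10
  index units — the order of replicate spread in large retention
  databases; replicates draw independently.

Because each phase's ladder is exactly linear with slope 0.52·l and the
Kováts formula cancels the intercept c, RI on a mixture phase is exactly
the intercept-free combination Σ wᵢ·(lᵢ/l_target)·RIᵢ of the base-phase
RIs.  The greedy-recovery study checks recovery of these coefficients to
numerical precision, with candidates restricted to a polarity-diverse
subset (the avoid-similar-polarity rule).

**What the simulator does not emulate:** real Abraham parameters and their
correlations, temperature programming, column-to-column and inter-source
variability, heavy-tailed annotation errors, the size and chemical breadth
of real databases, and SMILES lengths beyond ~60 characters.  Passing
tests demonstrate that the machinery — training, transfer, stacking,
combination recovery, splits, metrics — behaves correctly under a
solvation-consistent ground truth; they do not certify accuracy figures on
real retention data.

## Metrics

MAE, MdAE, RMSE (target units); MPE and MdPE as mean/median of
100·|Δ|/reference; R² = 1 − SSres/SStot (undefined for constant
references: NaN plus a warning); `coverage90` = empirical 90th percentile
of |Δ| with linear interpolation ("90 % of records deviate by less
than...").  Cross-validation aggregates fold metrics with equal fold
weights.

## Study designs in the acceptance pipeline

* **Stacking gain**: the mid-polar target is 0.55·DB-5 + 0.45·DB-WAX in
  solvation space, present in neither catalog.  Test compounds are chosen
  first and excluded from *every* training corpus (non-polar, polar and
  mid-polar), so they are unseen at all stages including early stopping.
  The baseline is the best of the 114 single (net, phase) predicted-RI
  features on the test set — the strongest "use one base model directly"
  predictor.
* **Transfer gain**: polar corpus 10× smaller than the non-polar library;
  transfer-initialized and randomly initialized MLPs share each protocol
  seed (hence the same validation split) and are compared by validation
  MAE at the final iteration, median over three seeds.  The MLP
  architecture keeps the three-seed paired design affordable.
* **Greedy recovery**: noiseless corpus, exact two-phase mixture,
  polarity-diverse candidates; greedy result compared against the
  best-subset oracle and the analytic coefficients.

## Known limitations

* Accuracy numbers produced on the simulator do not transfer to real
  corpora; they demonstrate relative behavior (stacking > single base;
  transfer ≥ scratch) under controlled ground truth.
* The descriptor manifest is RDKit-derived and not numerically identical
  to any other toolkit's 327-descriptor set; models are tied to the
  manifest/scaling version they were trained with.
* The printed SVR ε/tolerance defaults are unusable on scaled labels (see
  above); users fitting real data should pass overrides as the experiments
  do.
* The NumPy training engine is single-threaded BLAS-bound; full-scale
  schedules (50k iterations, width-512/channel-128 nets) are supported but
  slow — the engine is written for desk-scale studies, not GPU-scale
  replication.
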