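# Methods

This note documents the modeling choices, defaults and limitations of
the package, in the order data flows through it.

## Record model and curation

A raw record is one measurement: SMILES, a finite pKa value, and an
acidic/basic label. Standardization proceeds fragment-wise: carbon-free
inputs are rejected as inorganic; carbon-free fragments (counterions,
water) are dropped; a small allow-list of common salt/solvent organics
(acetate, formate, mesylate, tosylate, oxalate, tartrate, fumarate,
ethanol, methanol, glycerol, acetone) is stripped *only when another
organic fragment remains*, so a plain acetate salt still yields acetic
acid as its parent. Two or more distinct surviving organic fragments
reject the input as a mixture. Net-charged parents are neutralized;
zwitterions (net charge zero with internal +/− sites) are deliberately
left as drawn. Nitro mesomers are normalized during cleanup and a
canonical-tautomer step collapses keto–enol pairs. The structure key —
used for deduplication and all joins — is the canonical SMILES of the
standardized parent. Standardization is idempotent on its own output.

Replicates are grouped per structure key and per class, with the sample
standard deviation (n−1 denominator). The three modeling options:

| Option | rule per class | combined set |
|---|---|---|
| 1 | admit a chemical only if every measured class has exactly one value | yes, amphoterics excluded |
| 2 | singletons, plus replicate groups with SD < 2 via their mean | yes, amphoterics excluded |
| 3 | everything: mean when SD ≤ 1, else min (acidic) / max (basic) | not built |

Option 1 uses chemical-level admission and Options 2–3 class-level
admission; this preserves the nesting Option 1 ⊆ 2 ⊆ 3 per subset.
The rules are implemented literally as stated above rather than
reverse-engineered from any published set sizes, whose bookkeeping is
not always internally consistent.

The 75/25 split is "semi-random": entries are stratified on 1-unit pKa
bins crossed with a replicate flag and an amphoteric flag (plus the
acidic/basic label for combined sets), shuffled per stratum by the
seed, and allocated by largest remainder so the global train count is
exact. Small strata can deviate from 75% individually; the pKa
distributions of the two sides agree to a KS statistic well under 0.1
on realistic sets.

## Features

Families (all RDKit, 1D/2D only): ~210 continuous physicochemical/
topological descriptors; MACCS keys (166 bits); circular bits (radius
2, 1024); path-based bits (2048); hashed atom-pair counts (1024);
and ~30 named SMARTS substructure counts centered on ionizable groups.
This stack is smaller than the 1444/9121/5947-column PaDEL stack used
in earlier open pKa work; column parity is explicitly not a goal, and
model statistics shift accordingly. Columns with any missing or
non-finite value are dropped; structures that fail featurization are
excluded and flagged.

The reduction ladder: D1 removes constant columns; D2 then removes the
later member of every column pair with |Pearson r| ≥ 0.95 (greedy scan
in column order, earlier column kept); D3 then removes columns with
variance < 0.01. The correlation and variance cutoffs are package
defaults set at commonly used values.
Min–max scaling maps each training column into [−1, 1]; zero-range
columns map to 0, and test rows may legitimately fall outside the
interval (visible extrapolation).

## Descriptor selection (GA)

Chromosomes are descriptor bitmasks capped at `max_subset_size` (15 by
default). Fitness is the fivefold-CV balanced accuracy of a 5-NN
classifier on the selected, z-scored descriptors, minus 0.001 per
selected descriptor to bias toward compact subsets. Folds are fixed
once per run (stratified, seeded) so all chromosomes are scored on the
same partitions. Defaults: population 100, 200 generations, tournament
size 3, one-point crossover at 0.8, per-bit mutation 1/n, elitism 1 —
all package choices. The z-scoring uses full-candidate-
matrix statistics rather than per-fold statistics; this is a selection
heuristic, not an honest performance estimate, and the router's
reported CV/test numbers are computed independently afterwards. On
pools of ≤ 12 features the GA provably reaches the exhaustive-search
optimum under the test suite's fixed folds.

## Routing

The ionizability gate counts Lipinski-style H-bond donors (any OH/NH)
and standard N/O acceptors; one of either suffices. The 3-class router
is kNN with Euclidean distance on z-scored selected descriptors,
majority vote, ties broken by the single nearest neighbor; k is chosen
by fivefold CV over {1, 3, 5, 7, 9}. The pipeline contract: structures failing the gate never reach the
router or regressors.

## Regression branches

All branches model acidic and basic targets separately, on identical
splits, tuned by (repeated) fivefold-CV RMSE via grid search:

* **SVM** — epsilon-SVR, RBF kernel; grid C ∈ {1, 10, 100}, gamma ∈
  {scale, 0.01, 0.001}, epsilon ∈ {0.1, 0.5}. A deliberately modest
  grid; the classical LibSVM-style 2⁻²…2¹⁰ sweep can be passed in via
  `param_grid` when compute allows.
* **XGB** — histogram tree booster; n_estimators ∈ {200, 400}, depth ∈
  {4, 6}, learning rate 0.1, with optional repeated CV
  (`cv_repeats`; default 1 repeat for runtime). Feature importances
  are exposed for variable-importance reporting.
* **Neural net** — a fully connected network with three hidden layers
  of 256 ReLU units, Adam, early stopping (patience 20, ≤ 500 epochs),
  L2 weight decay tuned in {1e-4, 1e-3}. It is built on scikit-learn's
  MLPRegressor, so regularization is L2 rather than the
  dropout/batch-norm combination used in GPU-framework variants of
  this architecture; training is single-CPU and deterministic per
  seed.

Metrics: RMSE; R² = 1 − SS_res/SS_tot about the observed mean (error
on zero-variance targets); Q² is the same statistic computed purely
from out-of-fold predictions. Q² ≤ fit R² is expected and asserted
in-suite up to small CV noise.

## Applicability domain

Global: leverage of the training-centered query against h* =
3·p/n (classical hat-value rule; the multiplier is a package default).
When p ≥ n the leverage is computed on a PCA projection retaining 95%
variance so XᵀX stays well-conditioned; p is the effective rank, and
training leverages sum to p. Local: mean Tanimoto similarity of the
k = 5 most similar training fingerprints (convention: two empty
fingerprints have similarity 1). The accuracy estimate is the
similarity-weighted mean absolute residual of those neighbors when
training predictions are available, else the similarity-weighted spread
of their experimental values — a documented stand-in for which no
single standard formula exists.

## Concordance benchmarking

Tables are joined on the structure key; rows lacking the class value
are excluded and an empty join is an error. |Δ| ≤ threshold (default
2.0, ties concordant) defines the concordant subset; counts are
symmetric in the two tables while R²/r²/RMSE are labeled with the first
table as reference. Benchmarks average the two concordant predictions
per key. Range filtering ([0, 14] acidic, [−2, 12] basic in typical
use) is idempotent. Confidence intervals are percentile bootstrap
(default 5000 paired resamples); degenerate resamples (zero variance)
are redrawn and logged. BCa was not used; percentile is the simpler, adequate default here.

## Synthetic fixture generator

Templates (12 scaffolds: carboxylic acids, phenol, sulfonamide,
aliphatic/aromatic amines, pyridine, imidazole, piperidine, and three
amphoterics) each carry a base pKa per class; decorations (halogens,
nitro, nitrile, CF₃, alkoxy, alkyl chains) carry signed shifts
(electron-withdrawing negative). The oracle pKa is base + shift,
clipped to [0, 14] acidic / [−2, 12] basic — the spans the models are
meant for. Observed values add N(0, noise_sd²) noise (default 0.4 pKa
units, a realistic inter-laboratory spread); replicate groups
(default 70% singletons, 30% groups of 2–5) have their sample SD forced
exactly into a low/mid/high band (0.1–0.9 / 1.2–1.9 / 2.5–4.0) so the
option rules are exercised deterministically. Salt re-writings,
two-component mixtures and carbon-free species are injected at small
rates (5/3/2%).

What the generator does *not* emulate: real structural diversity (a
few hundred decorated scaffolds, not thousands of heterogeneous
chemicals), microscopic/multi-site ionization, tautomer-dependent
measurement ambiguity, and systematic inter-method bias. Passing tests
therefore demonstrate that the machinery is correct and that learnable
signal is recovered at the injected noise level — not that the models
reach any particular accuracy on real chemical space.

## Problem sizes and numerical choices

The default test suite and the acceptance script run the pipeline at a
few hundred structures with the modest grids above — sizes chosen so a
full from-scratch reproduction is a coffee-break computation on one
CPU; all sizes scale up through configuration without code changes.
Determinism: every stochastic component (splits, folds, GA, boosters,
network init, bootstrap) is driven by an explicit seed; two runs with
the same config and seed produce identical outputs.

Known limitations: macroscopic pKa only (no per-site assignment, no
protonation-state enumeration); the RDKit tautomer canonicalizer does
not reproduce the exact rule sets of the KNIME-based standardization
workflows behind some public compilations, so curated counts on such
files may deviate slightly; the combined-set variant of the regressors is supported but
the routing deployment always uses the separate acidic/basic models.
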