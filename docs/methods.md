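# Methods

## Problem and model

`polysize` models nanoprecipitation: a polymer dissolved in THF is added to
water and collapses into nanoparticles whose z-average hydrodynamic diameter
(measured by DLS) is a smooth function of the repeat-unit chemistry, the
degree of polymerization *Dp*, the polymer stock concentration, and the
surfactant level.  The model is a fused network: a graph convolutional
encoder of the repeat-unit structure, concatenated with the formulation
numerics, regressed by fully connected layers to a single diameter in nm.

### Polymer graph representation

A repeat unit is a SMILES string with exactly two wildcard (`*`) markers.
The markers are removed and their neighboring heavy atoms become the head and
tail attachment sites; units are chained tail→head.  Two builds exist:

* **linear-n** — n units head-to-tail, terminal attachment sites capped with
  implicit hydrogens (terminal groups have little effect on particle size,
  and an implicit-H cap is the simplest neutral choice);
* **cyclic-m** (default m = 10) — the last unit bonds back to the first.
  Every unit then has an identical environment, so each atom's convolved
  features equal those of an atom deep inside an infinite chain.  This
  "pseudo-infinite" representation is exact under two conditions, both
  enforced: no atom feature may encode ring membership (the feature-spec
  validator rejects such featurizers), and the receptive field of the
  network (one hop per convolution layer) must not wrap around the backbone
  cycle (checked at build time; a 10-ring of vinyl-type units has a 20-atom
  backbone cycle, comfortably above the 8-hop range of the default 4
  layers).

Graphs are heavy-atom only; hydrogens enter as a count feature.  The default
atom featurization (27 dims) is element one-hot over
{C,N,O,S,P,F,Cl,Br,I,other}, heavy-degree one-hot 0–5, formal charge,
hybridization one-hot {sp,sp2,sp3,other}, H-count one-hot 0–4, and an
iterative electronegativity-equalization partial charge computed on the
*built* (cyclic or linear) molecule.  Because the charge iteration is
strictly local (12 damped sweeps), the cyclic build is exactly symmetric
and a chain's interior converges exactly to the cyclic values.

### Networks

Convolution: `H' = relu(D̃^{-1/2}(A+I)D̃^{-1/2} H W + b)`, 4 layers of width
64 by default.  Readout: column-wise max concatenated with a gated weighted
sum (per-node logistic gate `σ(w·h + c)` with learned w, c; a plain
unweighted sum is available behind `sum_mode="plain"` for ablation),
producing a 128-length fingerprint independent of graph size.  The weighted
sum is reduced in column-sorted order, which makes the readout bit-exactly
invariant to node relabeling (floating-point addition is otherwise order
sensitive).  The fully connected head is 128+3 → 128 → 64 → 32 → 1 with ReLU
hidden layers and a linear output; no positivity clamp is applied — the
relative loss with positive targets keeps predictions positive, and a
non-positive prediction logs a warning instead of being hidden.

Dropout 0.1 follows every convolutional and hidden FC layer during training
and is disabled at evaluation, so evaluation is deterministic (two forward
passes are bit-identical; all math is float64).

Everything is implemented directly in NumPy with explicit backward passes;
gradients are verified against central finite differences in the test suite.

### Inputs and scaling

The numeric inputs are (Dp, polymer concentration g/L, surfactant
concentration g/L, with 0 meaning no surfactant; a categorical
surfactant-identity slot is deliberately not modeled since the data contain a
single surfactant).  Dp and concentration are log-transformed before
standardization — they span decades ([53, 1013] and [1, 30] in the study
ranges) and act multiplicatively on size, and raw z-scores would make ReLU
extrapolation to high Dp wild — while the surfactant level is standardized
raw.  Statistics come from the training split only and are stored in the
fitted results; transform→inverse-transform round-trips to 1e-12.

### Loss, training, protocol

The loss and headline metric is MAPE (reported in percent; the ×100 factor
is irrelevant to optimization).  Training uses Adam (lr 1e-3), batch 64, up
to 300 epochs with best-validation-epoch checkpointing and early stopping
(patience 40); the 8:2 train/validation split, parameter initialization and
batch shuffling all derive from a single seed, so runs are exactly
reproducible.  Per-epoch history records the running training-mode MAPE/RMSE
(with dropout active, hence typically above the evaluation-mode training
error) and evaluation-mode validation metrics.  The split gives
floor(0.8·n) records to training (2813 → 2250 + 563).

**Leave-one-polymer-out (LOPO)**: for each held-out polymer (or pair), all
its records are removed, the rest is split 8:2 and trained, and the model is
evaluated on the held-out records ("test") and on their union with the
validation split ("all"); an audit asserts no held-out record reaches a
training batch.  The **worst-group decomposition** groups the evaluation
records by exact recorded Dp, concentration, and additive (groups are
discrete formulation batches), finds the group with maximal MAPE across all
keys (ties: larger group, then lexicographic label), and reports MAPE with
and without it.

## Preprocessing

Raw DLS tables (3 replicates × 3 measurements per formulation) are cleaned
in two conserving stages: (1) row-wise invalid filtering — missing size,
PDI > 0.3, size outside [10, 1000] nm; (2) within-formulation outlier
rejection — deviation from the group median by more than 30 % of the median
— followed by dropping formulations with fewer than 3 surviving
measurements.  The exact thresholds of the original study are not public;
these defaults are standard DLS practice and are fully configurable.  Each
rejection carries a reason code, surviving measurements are *not* averaged
(the modeling unit is the measurement), and the pipeline is idempotent and
order-invariant.

## Synthetic study generator

The generator emulates the study's layout: ten methacrylates with carbon-only
ester side chains (methyl … isobornyl), Dp levels (53, 150, 420), stock
concentrations (1, 3, 10, 20, 30) g/L, surfactant ∈ {0, 0.0025} g/L,
3 × 3 replicate structure (2700 measurements).  Ground truth is an invented
law (the real law is exactly what the model is supposed to learn):

    s = 6 · Dp^0.5 · c^(1/3) · (k/7)^0.4 · (1 − 0.2·[surfactant]),

with k the heavy-atom count of the repeat unit — monotone in Dp and c,
structure-dependent only through a graph-computable descriptor, and spanning
≈35–850 nm over the study ranges.  Noise is multiplicative lognormal
(σ_log = 0.05), since DLS errors scale with size.  Planted corruptions:
outliers (size ×3) and invalid rows (PDI 0.45–0.95 or missing size) at 2 %
each, with a bookkeeping table of every planted row.

An optional **extreme-Dp batch** (Dp = 1013 for one unit) emulates a
highest-polymerization batch lying outside the power-law regime: its sizes
deviate from the smooth law by a factor 1.6 (a stand-in for aggregation
effects).  A model trained without these records therefore cannot
extrapolate to them, and the worst-group decomposition should — and does —
single the batch out, with the held-out error remaining moderate overall.

What the generator deliberately does **not** emulate: real nanoprecipitation
physics (no Ouzo-region boundaries, no solvent/antisolvent dependence),
correlated replicate effects, instrument-specific artifact structure, or
polymers outside uncharged carbon-side-chain methacrylates.  Passing tests
therefore demonstrate that the machinery recovers a graph-learnable
multiplicative law under realistic noise and corruption — not that the
learned chemistry transfers to laboratory data.

## Numerical and design notes

* Float64 throughout; evaluation-mode forward passes are bit-deterministic.
* Max-pool ties resolve to the first node index (only gradient routing is
  affected); sorted-order summation makes readouts permutation-exact.
* The cyclic/linear convergence probe compares the cyclic fingerprint
  (weighted-sum half normalized per repeat unit, which by symmetry equals a
  single-unit readout) against the readout over the linear chain's central
  unit — the interior viewpoint the cyclic construction reproduces.  Whole-
  graph fingerprints cannot converge as chains grow (the sum half is
  extensive and chain ends contribute an O(1/n) floor); both modes are
  exposed, and the whole-graph floor is asserted in the tests.
* Checkpoints and model bundles are version-tagged JSON; float64 values
  round-trip bit-exactly through their shortest decimal representation.
* Problem sizes used by the test suite and acceptance script (2000-record
  training runs, 300-epoch cap with early stopping, 100 random oracle
  graphs) were chosen to exercise every protocol at full fidelity on a
  single CPU in minutes.
* Known limitations: single-surfactant encoding; no copolymers, branching,
  stereochemistry or 3D effects; no uncertainty quantification; MAPE-optimal
  training targets the conditional median in relative terms, not the mean.
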