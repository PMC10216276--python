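# Methods

## Problem and model

The package regresses normalized IC50 drug-response values for
(drug, cell line) pairs. A drug is a molecular graph over heavy atoms
(hydrogens implicit; bond order, stereochemistry and isotopes are parsed
but not encoded beyond connectivity); a cell line is a 735-long binary
vector of genomic-mutation indicators. Two classical branches produce
128-dimensional embeddings each; their concatenation (drug block first —
an arbitrary but frozen order) feeds either the quantum depth-infused head
or a two-layer dense head. Both variants share bit-identical trunks when
built from the same seed, which is what makes the hybrid-vs-classical
comparisons controlled.

### Atom features (78 per atom)

Concatenation of four one-hot blocks plus a flag: 44 element slots (43
named elements + "Unknown" fallback), 11 degree slots (0–10), 11
total-hydrogen slots, 11 implicit-valence slots, 1 aromaticity flag.
Charged and isotopic atoms receive the features of their parent element.
Counts outside [0, 10] raise rather than clip: such atoms do not occur in
valid organic molecules, and silent clipping would hide parser issues.

### Cell-line CNN

The convolutional branch is three blocks of (1-D convolution, stride 1,
valid padding -> ReLU -> non-overlapping max-pool), then flatten and a
dense layer to 128. Channel plan (32, 64, 96), kernel width 8, pool width
3. These widths are configuration, not dogma: they follow the scale of the
classical drug-response CNN lineage this architecture descends from, and
every value is overridable in `CellEncoderConfig`. ReLU is applied after
every convolution (a choice; the alternative of activating only once per
block is not exposed). Pooling drops a trailing remainder shorter than the
window. No dropout by default; a rate can be configured and is applied
after the flatten (cell branch) and the hidden dense layer (drug branch)
during training only.

### Drug GCN

Symmetric-normalized graph convolution with self-loops,
`ReLU(D^(-1/2)(A+I)D^(-1/2) X W)`, without bias terms. The channel plan
78 -> 78 -> 156 -> 312 is the only widening plan consistent with the dense
stack 312 -> 1024 -> 128 that follows; global max pooling (per-feature max
over nodes) sits between them. The embedding is invariant under node
relabeling because the propagation rule is permutation-equivariant and max
pooling permutation-invariant; the test suite checks this numerically on
real molecules.

### Quantum depth-infused layer

Geometry: q = 8 qubits, 32 encoding blocks, 5 variational layers before
any encoding and 5 after each block; 8·5 + 8·5·32 = 1320 trainable
rotation angles plus a multiplicative and an additive readout scalar.
Design choices where the architecture description leaves freedom:

* **Trainable rotation axis: RY.** Any single axis yields the same
  parameter count; RY is chosen because it moves population off the Z axis
  so the RZ-encoded features become observable. Configurable (`x`/`y`/`z`).
* **Entangler: linear CNOT chain** 0->1, 1->2, ..., 6->7 (the simplest
  reading of "subsequent" CNOTs); a ring variant is available. Every
  variational layer, including the fifth of each group, ends with the
  chain — uniformity over special-casing the block boundary.
* **Encoding: RZ(scale · feature)** with scale 1 by default; features are
  consumed eight at a time, block b carrying features 8b−7 … 8b.
* **Measurement propagation:** CNOT(k -> 0) for k = 1…7 in ascending k.
  The order is immaterial for ⟨Z₀⟩ (the gates commute on that diagonal
  observable) but frozen for reproducibility.
* **Initialization:** angles ~ Uniform[0, 2π) from a seeded generator;
  readout starts at (scale, shift) = (1, 0).
* **Convention:** little-endian basis labeling — qubit 0 ("the first
  qubit", the measured one) is the least significant bit of the basis
  index. `describe_circuit` prints the full stage-by-stage schedule; stage
  counts are reported under this convention (5 + 32·6 data/variational
  stages plus measurement propagation).

The simulator is a dense statevector engine (2^8 = 256 complex amplitudes)
operating on batches; CNOTs and CNOT chains are precomputed basis
permutations, and an encoding block is applied as one fused diagonal
phase. Unitarity holds to ~1e-15 per gate; the suite enforces 1e-12 after
10,000 random gates.

Gradients use the adjoint method: after one forward pass, a reverse sweep
un-applies each gate while back-propagating the observable, yielding exact
derivatives for all 1320 angles and all 256 features at a cost of a few
forward passes — the property tests confirm agreement with the
parameter-shift identity to ~1e-15 and with central finite differences to
better than 1e-5. Because each feature enters exactly one RZ gate, the
output is a first-order trigonometric polynomial in every single feature;
this is asserted to 1e-9 via 3-point sinusoid fits.

### Heads, normalization, loss

The affine readout maps ⟨Z₀⟩ ∈ [−1, 1] to the target scale with no output
squashing, so predictions may transiently leave (0, 1) during training.
The classical head is dense 256 -> 8 -> 1 with ReLU between (the junction
activation is a choice; ReLU matches every other junction in the trunk).
Parameter accounting is reported **per layer**: hybrid = 1320 angles + 2
readout scalars; classical = 2056 (first dense layer, 256·8 + 8) + 9. The
widely quoted classical count of 2056 equals the first layer alone — the
two-layer total is 2065 — so the package never reports a single
"classical head total" without the split.

IC50 normalization is `norm(y) = 1/(1 + y^0.1)` for y > 0, strictly
decreasing onto (0, 1), with exact inverse `(1/v − 1)^10`. The loader
takes the IC50 column on whatever dose scale the source provides (natural
units vs. log-scale is a property of the export, not of this package) and
rejects non-positive values.

## Training protocol

Records are shuffled once with a seeded generator and split into disjoint
train/test sets — absolute sizes (the reduced-set protocol is 5000/1000)
or an 80/20 fraction. Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) at learning
rate 1.8e-3 minimizes MSE over mini-batches; the training order is
reshuffled every epoch from a per-epoch child seed while the test order
stays frozen. Batch size 64 and 100 epochs are package defaults (both
unconstrained by the study description, both configurable). Per-epoch
train MSE is the average of mini-batch squared errors accumulated while
the parameters evolve; test MSE is evaluated with frozen parameters at
each epoch's end. There is no early stopping by default; an optional
`target_train_mse` stops at the first epoch whose train MSE beats the
threshold, which is how "reaches X within N epochs" checks are run
without always paying for N epochs. The (data seed, init seed, shuffle
seed) triple fully determines a run; reruns are bit-identical.

The size sweep trains both variants from the same trunk initialization
with identical hyperparameters at each training size. Test sizes default
to size/5 but the benchmark triple uses the explicit mapping
(50, 200, 5000) -> (10, 50, 1000). The sweep reports the signed test-MSE
difference (classical − hybrid); no monotone trend is asserted — at these
scales the difference is stochastic and data-dependent, so it is a
report, not a test.

## Synthetic screens

`generate_fixtures` emulates a GDSC-style screen without any download:
real small-molecule SMILES drawn without replacement from a curated
60-molecule pool; cell profiles i.i.d. Bernoulli(0.1) over the 735
anonymous mutation slots (real mutation panels are similarly sparse);
and a planted response over the full drug x cell cross product,

    log(ic50) = 1.5·z_cell + 1.0·z_drug + eps,  eps ~ N(0, noise_sd²),

where z_cell standardizes the count of ones among the first 20 mutation
slots and z_drug standardizes the drug's heavy-atom count. Both branches
therefore carry recoverable signal, and noise_sd (default 0.1) sets the
irreducible error. What the generator does **not** emulate: correlated
mutation structure, drug-class clustering, missing measurements (real
screens are incomplete — a response table need not cover the cross
product, and the loader does not require it), assay noise heteroscedastic
in dose, or any biological relationship between a molecule's structure and
a mutation profile. Passing tests on these fixtures therefore demonstrate
optimization and implementation correctness — that the architecture can
extract a planted signal at small sample sizes — not clinical predictive
power on real screens.

The benchmark experiments run at deliberately small problem sizes chosen
as the package's own test scale: learnability on a 5 x 40 screen (200
pairs, 160 train) and the sweep at training sizes {50, 200}. The
full-scale protocol (5000/1000 from a 172,114-pair screen) is exposed
through the same configuration surface.

## Numerical choices and degenerate inputs

* ReLU subgradient at 0 is 0; max-pool ties break toward the first
  (lowest-index) element. With binary inputs and zero-initialized biases
  these kinks are actually hit at step 0 — finite-difference checks in the
  tests therefore use continuous inputs or smooth parameter subsets,
  while training simply uses the stated subgradients.
* Graph degree normalization never divides by zero (self-loops guarantee
  degree >= 1). Single-atom molecules are valid; empty molecules and
  unparseable SMILES raise with the offending string.
* Fixture standardization with zero variance (e.g. one drug) maps to
  zeros instead of dividing by zero.
* Checkpoints are NumPy archives plus a plain-text manifest of shapes;
  loading validates names and shapes against the target model.
* Training aborts with the epoch/batch named if the loss becomes
  non-finite.

## Known limitations

* The statevector engine is dense: memory and time scale as 2^q. Fine at
  the design point q = 8; not intended for wide registers, and no
  shot-noise or hardware-noise models are included.
* The in-repo NumPy implementation favors auditability over speed; a
  full-scale 5000-sample training run is hours of CPU time, not minutes.
* mRNA-expression features, AUC/dose-slope prediction, bond-typed edge
  attributes and 3-D conformers are out of scope.
* The shallow-wide reformulation of the deep circuit (mathematically
  identical, more qubits, less depth) is not implemented.
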