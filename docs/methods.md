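# Methods

## Problem setting

The package classifies four-component softmax score vectors — the output of
an upstream convolutional network applied to brain-MRI slices — into the
classes no tumor, meningioma, pituitary tumor and glioma (labels 0–3), with
a two-class mode for tumor/non-tumor or high-/low-grade glioma tasks.  The
classifier is a small variational quantum circuit simulated exactly; the
feature-extraction CNN is outside the package's scope, and a synthetic
generator stands in for its outputs.

## Quantum simulation

States are dense complex-double amplitude vectors of length 2^n (n ≤ 12,
the practical cap for a dense representation; the classifier itself uses
n = 4, sixteen amplitudes).  **Convention:** qubit 0 is the leftmost tensor
factor, i.e. the most significant bit of the computational-basis index; on
two qubits, basis index 2 is |10⟩.  This is asserted in the test suite.

Gate set: H, RX, RY, RZ, the general rotation
`Rot(φ, θ, ω) = RZ(ω)·RY(θ)·RZ(φ)` (rotate about z, then y, then z again —
any single-qubit unitary up to global phase), and CNOT.  RY uses the
standard real form with ∓sin(φ/2) off-diagonals: a y-axis rotation must be
a distinct axis from RX for the three-axis Euler decomposition to span the
single-qubit unitaries, so a rendering of RY with −i·sin off-diagonals
(which would duplicate RX) is treated as a typographical slip.  States
differing only by a global phase are physically identical; tests compare
via |⟨a|b⟩| where this matters.

There is no shot sampling and no noise model: probabilities are exact Born
values |amplitude|².  Tolerances are fixed at 1e-10 for invariants (norms,
unitarity) and 1e-12 for matrix identities, both comfortably above the
~1e-16 roundoff of double precision but tight enough to catch any
structural error.

A vectorized engine (`model._batch_probs`) evaluates many circuit variants
simultaneously — all samples of a batch times all ±shifted parameter
copies — and is required by a test to agree with the one-gate-at-a-time
scalar path to 1e-12; the scalar path in turn is checked against an
explicit Kronecker-product full-matrix oracle.

## The classifier

Each of the `n_layers = 6` layers applies `Rot` to every qubit and then a
linear CNOT cascade 0→1→2→3 (no ring closure).  The input enters
*additively*: qubit q's three rotation angles in every layer are
`θ + π·x_q`.  This keeps the trainable parameter count at exactly 12 per
layer (72 total), gives each of the four score components a dedicated
qubit, and re-uploads the data at every layer — the re-uploading is what
lets a four-qubit circuit express non-trivial decision boundaries.  The
factor π maps the score range [0, 1] onto a half-turn of rotation angle.
A score vector shorter than the register (two-class scores on the
four-qubit circuit) is tiled cyclically; any length that does not divide
the register size is rejected.

Readout: the joint marginal of qubits (0, 1) over outcomes {00, 01, 10,
11}, mapped in lexicographic order to classes 0–3 — the simplest surjective
Born-rule mapping of two readout qubits onto four classes.  The two-class
configuration reads the marginal of qubit 0 alone.  Prediction is the
argmax, ties broken toward the lowest class index.

Loss: mean cross-entropy −log(p_true + ε) with ε = 1e-12; the clip only
matters when a class probability underflows and bounds the loss at ≈ 27.6.

Gradients: central finite differences with step h = 1e-6 on the loss is
the baseline definition (truncation error O(h²) ≈ 1e-12; roundoff
≈ 1e-16·|loss|/h, negligible at these loss scales).  The parameter-shift
rule — exact for rotation generators: ∂p/∂θ = [p(θ+π/2) − p(θ−π/2)]/2,
chained through the loss per sample — is implemented as an alternative and
must agree with finite differences to 1e-5 (observed agreement ~1e-7,
dominated by the finite-difference error).  Both cost two circuit
evaluations per parameter per sample; they are batched into a single
vectorized simulation, so one 26-sample gradient is one pass over
26 × 145 sixteen-amplitude statevectors.

## Training

Defaults follow the published configuration: 4 qubits, 6 layers, RMSProp
with learning rate 0.01, batch size 26, 50 epochs.  "50 iterations" is
read as 50 epochs, since the accompanying training curves are per-epoch.
RMSProp internals the configuration leaves open use the standard defaults
ρ = 0.9, ε = 1e-8, with the update
`acc ← ρ·acc + (1−ρ)g²; θ ← θ − lr·g/(√acc + ε)`.  Angles initialize from
uniform(−π, π); the last incomplete batch of an epoch is used, not
dropped.  The recorded loss history is the sample-weighted mean of
pre-update batch losses per epoch.  All randomness (initialization, epoch
shuffles) flows from one integer seed through a single `numpy` generator,
so repeated runs are bitwise identical — this is tested on checkpoints and
metric reports.

Finite differences is the trainer's default gradient method; switching to
parameter-shift changes results only at the ~1e-7 gradient level.

The train/test split is stratified at 70:30: per class,
round(0.7 × class size) samples go to training, the rest to test, under a
seeded shuffle.  Classes with fewer than 2 samples cannot be split and are
rejected.

## Synthetic data

The generator emulates the softmax vectors a trained CNN emits for
labelled images: for true class c, a Dirichlet draw with concentration
`concentration_true` at position c and `concentration_other` elsewhere.
Dirichlet draws live on the probability simplex by construction, and the
concentration ratio is a single separability knob: equal concentrations
give chance-level structure (argmax accuracy ≈ 1/K), large ratios approach
one-hot vectors.  The defaults — concentration 50 on the true class, 1
elsewhere, 200 samples per class — describe a confident but imperfect
upstream network; the Monte-Carlo `bayes_accuracy` oracle puts the argmax
ceiling for this setting above 99%, which is what makes a ≥ 90% end-to-end
accuracy requirement meaningful rather than vacuous.

What the synthetic data does *not* emulate: the geometry of real CNN
feature spaces (correlated errors between visually similar tumor types,
class imbalance, per-dataset calibration differences), or the images
themselves.  Passing end-to-end tests therefore demonstrates that the
circuit, gradients, optimizer and evaluation chain work and can learn a
separable four-class problem at the published configuration — not that the
pipeline reaches any particular accuracy on real MRI data.

## Metrics

Rows of the confusion matrix are true classes, columns predictions.  The
per-class report follows the layout common in this literature: one-vs-rest
accuracy (TP+TN over all samples, in percent — the only standard reading
under which each class has its own accuracy alongside precision/recall),
precision, recall and F1 as unit fractions, plus overall accuracy.
Degenerate 0/0 cells report 0 with a logged warning.  The implementation
is independent of scikit-learn; a test compares it against scikit-learn on
100 random labelings to 1e-12.

## Problem sizes

The shipped test and acceptance runs use 200 samples per class (560
training vectors after the 70:30 split) for the full 50-epoch
configuration, five seeds; smaller unit-test runs use tens of samples and
a few epochs.  These sizes give stable accuracy estimates for a
sixteen-amplitude simulator while keeping a full five-seed sweep in the
low minutes.

## Known limitations

- No hardware backends, noise models, or shot statistics.
- No learning-rate schedules, early stopping, or validation-based model
  selection; training always runs the configured number of epochs.
- The readout-to-class mapping and the loss are design choices of this
  package (the configuration they accompany does not pin them down);
  alternatives (parity readout, fidelity losses) are not implemented.
- Score vectors are assumed calibrated (non-negative, summing to 1 within
  1e-8); raw logits must pass through `drqc.softmax` first.
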