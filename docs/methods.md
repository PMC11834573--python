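# Methods

This note documents the models and procedures implemented in `pairbind`,
the choices made where the design was genuinely open, and what the bundled
synthetic benchmark does and does not demonstrate.

## Problem setting

Given a ligand `L = {a_1..a_m}` (typed atoms with 3D coordinates) and a
protein `P = {r_1..r_n}` (residues with heavy-atom coordinates), the model
predicts the binding affinity `y` in pK units and, per residue, the
probability of belonging to the binding site (any heavy atom strictly
within a cutoff, 6 Å by default, of any ligand atom). The model receives
**no pocket prior and no relative pose**: ligand and protein are encoded
independently and combined without any cross-molecule geometry.

## Invariant molecular featurization

Coordinates enter the model only through two pairwise, rigid-motion
invariant views:

* the distance matrix `D[i,j] = ||x_i − x_j||`;
* the spatial position matrix `P[i,j] = F_i (x_j − x_i)`, the coordinates
  of atom *j* in an orthonormal local frame `F_i` attached to atom *i*.

The frame comes from the chain-neighbour stencil `(i−1, i, i+1)`:
Gram–Schmidt on `v1 = x_i − x_{i−1}` and `v2 = x_{i+1} − x_i`. The third
stencil difference `v3 = x_{i+1} − x_{i−1}` equals `v1 + v2` identically,
so its Gram–Schmidt residual vanishes analytically; the third axis is
completed as `u1 × u2` (right-handed). Boundary atoms reuse the first or
last interior stencil; molecules are *not* re-sorted — the input atom
order defines the chain, which makes featurization reproducible per file.

Degenerate stencils (collinear within sin θ < 1e-6, molecules with < 3
atoms, and the [CLS] token) are flagged. Their position rows are zeroed in
the model-facing featurizer rather than expressed in the world frame: a
world-frame fallback would leak global orientation and break the exact
rigid-motion invariance of the feature tensor. The geometry of such rows is
still fully carried by `D`.

A [CLS] token is prepended with coordinates at the atom centroid; its
distance row therefore encodes every atom's distance to the centroid — a
feature the binding-site head can exploit.

Both matrices are discretized: distances into 0.5 Å bins over [0, 16) plus
an overflow bin (33 bins); each signed position axis into 1 Å bins over
[−10, 10) with underflow/overflow (22 bins). A 1e-9 epsilon inside the
floor keeps analytically-on-edge values (e.g. the identically-zero
in-plane components of stencil neighbours) stable under floating-point
jitter. Bin embeddings (distance + three axes) are concatenated and passed
through Linear → GELU → Linear to form the initial pair representation
`z⁰`. The binning scheme is serialized with every config so featurization
is bit-reproducible.

## Pair-biased transformer

The backbone is a standard pre-norm transformer over the token sequence
([CLS] first) with two modifications per layer:

* **bias in:** `z` is linearly projected to one scalar per head per (i,j)
  and added to the attention logits before the softmax —
  `softmax(QKᵀ/√d_k + bias(z))V`;
* **bias out:** the raw per-head logits are linearly projected back to
  pair width and added onto `z` (residual update), so the pair
  representation is refined layer by layer.

With the bias projection zeroed the layer reduces exactly to vanilla
multi-head attention — a tested property. There are no positional
encodings: the model is permutation-equivariant and all geometry flows
through `z`.

Full-scale configuration: 15 layers, width 512, 4 heads, feed-forward
2048. Desk-scale (used by tests, examples and the acceptance runs):
2 layers, width 64, 4 heads, feed-forward 256, pair width 16. The choice
of GELU for the unnamed activation, and the per-head scalar realization of
the bias, are design decisions recorded here.

## Physics-guided self-supervised pretraining

Each training example corrupts a clean conformer twice:

* **type masking** — a fraction drawn uniformly from [0.1, 0.3] of atoms
  (at least one) is replaced by `[MASK]`; coordinates stay visible.
* **gradient-directed noise** — coordinates move along the gradient of a
  pairwise Lennard-Jones potential
  `V(r) = 4ε[(σ/r)¹² − (σ/r)⁶]`, computed by central finite differences
  (step h = 1e-4 Å, truncation error O(h²)):
  `x_noisy = x + η·∇V/||∇V|| + ξ`. The normalization uses the global
  Frobenius norm, so η is the *total* displacement budget; η is drawn
  uniformly from [0.1, 0.5] Å per molecule and ξ ~ N(0, 0.05² Å²) i.i.d.
  These scales are large against coordinate precision and small against
  bond lengths. The displacement follows the literal uphill gradient; the
  denoising target is the clean structure either way.

ε/σ per element come from a bundled UFF-style van-der-Waals table
(`resources/lj_params.csv`, overridable); pairs combine by
Lorentz–Berthelot. Distances are clamped below at 0.5 Å inside the
potential so the r⁻¹² wall cannot overflow on clashed inputs.

Three heads denoise: a linear classification head over atom types (masked
positions only, cross-entropy); a distance head applying a small MLP with
softplus output to the symmetrized pair representation (smooth-L1 against
clean distances over real-atom pairs); a residual coordinate head
predicting a displacement added to the noisy coordinates (smooth-L1
against clean coordinates). Head weights 1:1:1. The noisy coordinates feed
the featurizer; the clean structure supplies all targets.

## Protein encoding and complex assembly

The protein side is a plug-in interface: n residues in, `(n+1)×d` single
and `(n+1)×(n+1)×d_pair` pair representation out, [CLS] first. The bundled
default is a lightweight geometric encoder — residue-type embeddings plus
the same invariant pair features computed on the Cα trace (residue order
as the chain), run through the same pair-biased transformer. Its [CLS]
sits at the Cα centroid, mirroring the ligand convention. An external
pretrained protein model with matching output contract can be dropped in;
learned linear adapters reconcile differing widths.

Because the bundled protein encoder shares the ligand encoder's
architecture and bin counts, it can be warm-started from the pretrained
ligand encoder: transformer layers and pair-bin embeddings carry over and
only the token embedding is reinitialized for the residue alphabet. This
mirrors the intended design — the protein branch, like the ligand branch,
enters fine-tuning pretrained — and measurably stabilizes downstream
training.

The complex representation concatenates the two tracks ligand-first; the
pair tensor is block-diagonal with **exactly zero** off-diagonal blocks —
the unknown ligand–protein interactions. The assembled input is therefore
invariant to any relative motion of the two molecules, which is the point:
interaction patterns must be inferred, not read off the pose. The
asymmetry of granularity (ligand atoms vs protein residues) in one block
matrix is intentional and implemented literally.

A 4-layer pair-biased trunk (2 layers at desk scale) updates the joint
representation. The two [CLS] rows, concatenated, feed
Linear → GELU → Linear to the scalar pK; the updated protein rows feed
Linear → GELU → Linear → sigmoid to per-residue site probabilities.
Training minimizes `MSE(pK) + λ·BCE(sites)` with λ = 1 jointly by default;
either head can be trained alone, and encoders can be frozen by flag
(default: end-to-end fine-tuning).

## Optimization

Adam (β₁ = 0.9, β₂ = 0.99) with decoupled weight decay 1e-4, linear
warmup followed by linear decay to zero, gradient clipping at global norm
1. Full-scale settings: pretraining lr 1e-4, 10,000 warmup steps, batch
128, ~20 epochs; fine-tuning lr 3e-4, batch 8. Desk-scale runs use
lr 1e-3–2e-3 with tens of warmup steps and batches of 8–16, which the
smaller widths tolerate. All data order and corruption randomness derives
from the run seed through per-epoch seed sequences: loss curves reproduce
exactly, and resuming from a state checkpoint at an epoch boundary
continues identically.

Three stabilizers are available in fine-tuning: the affinity head's output
bias starts at the training-label mean (otherwise the initial squared
error, tens of pK², consumes the whole clipped gradient budget for many
steps); optional Polyak (EMA) weight averaging; and optional tail weight
averaging (mean of epoch-end weights over the second half of training),
which damps the epoch-to-epoch prediction wobble of small-batch Adam. The
protein encoder uses a wider feature grid than the ligand encoder (1 Å
distance bins to 32 Å, 2 Å position bins to ±16 Å) because residue chains
span several times a small molecule's extent; both grids have the same
bin counts.

Everything differentiable runs on reverse-mode automatic differentiation
over NumPy (the `autograd` package) with models as pure functions of a
parameter tree — deterministic, single-CPU, and sized for the desk-scale
experiments this package targets.

## Synthetic benchmark: what it emulates, and what it does not

The generator stands in for the real corpora so every stage is testable
without downloads:

* **Conformers** — self-avoiding 3D walks, step ~N(1.5, 0.1²) Å, minimum
  pair distance 1.0 Å, 6–16 atoms, drug-like element composition. They
  have plausible interatomic distances but no valence, bonds or chemistry.
* **Proteins** — self-avoiding Cα walks (3.8 Å steps, 20–60 residues)
  with 1–4 pseudo heavy atoms per residue within ~2 Å of the Cα. No
  secondary structure, packing or side-chain chemistry.
* **Complexes** — the pocket sits at the protein's core: the ligand
  centroid is placed on the Cα centroid (random offset < 2 Å; the
  most-central residue's Cα is the fallback anchor when the coil's
  centroid lies in empty space) and the ligand is oriented by aligning
  its principal axes to those of the core neighbourhood. This
  docked-style deterministic pose matters twice over: with a uniformly
  random orientation the planted contact count is mostly unlearnable by a
  model that never sees the pose (real docked poses are energy-optimal
  functions of the two structures, not random draws), and anchoring at
  the centroid ties the binding site to each residue's
  distance-to-centroid — a feature the encoder exposes directly through
  the [CLS] distance row. Site labels follow the 6 Å rule by
  construction.
* **Affinity rule** — `pK = 0.05·contacts + 4.0 + N(0, 0.25²)`, clipped
  to [0, 14], where `contacts` counts (residue, ligand-atom) pairs with
  any heavy atom strictly within 6 Å. A noise-free contact fit reaches
  Pearson 1.0 by construction; with noise, the realized held-out ceiling
  of a contact-count linear fit is ≈ 0.99 under these geometry settings.

Passing the benchmark shows the architecture can extract a
contact-determined signal from invariant single-molecule features through
the zero-padded pair assembly — it does **not** show chemical accuracy on
real protein–ligand complexes, which would require the full pretraining
corpus and crystal-structure data.

## Numerical choices and edge cases

* Collinearity tolerance sin θ < 1e-6 for frame fallback; fallback rows
  flagged and zeroed in model-facing features (see above).
* Strict inequality ("below the cutoff") for site labels; a residue at
  exactly the cutoff is negative. Heavy atoms only — hydrogens are often
  absent from crystal structures.
* pK conversion follows the literal `−log10(K/1e9)` (labels quoted in
  nanomolar-equivalent numerals); a molar-input mode (`−log10 K_M`) is
  available because affinity sources disagree on units.
* Gas constant R = 1.98720425864083e-3 kcal/(mol·K) for the ΔG route.
* Spearman uses the classical `1 − 6Σd²/(n(n²−1))` when tie-free and
  Pearson on mid-ranks under ties (they agree exactly when tie-free);
  ROC-AUC uses trapezoids over tied-score groups and equals the
  tie-corrected Mann–Whitney statistic.
* k-fold splits differ in size by at most one; round r tests on fold r
  and validates on fold r+1 (mod k).
* Checkpoints are a flat `.npz` of path-keyed arrays plus a JSON config
  header; optimizer state stays in memory (the resume contract covers
  epoch-boundary resumption within a session).

## Desk-scale problem sizes

Tests and the acceptance script use: 300-molecule pretraining corpus with
the 2-layer/64-wide encoder for 20 epochs; a 64-complex overfit probe for
200 steps; a 500-train/100-test recovery benchmark trained 30 epochs at
batch 16 with both encoders warm-started; and a 150-train/60-test ablation
grid over 3 seeds at 10 epochs. These sizes were chosen so each stage
completes in minutes on one CPU while leaving the planted signal
comfortably recoverable.

## Known limitations

* No dropout; regularization is weight decay plus early selection on a
  validation split.
* The bundled protein encoder sees only the Cα trace; side-chain geometry
  is invisible, which caps binding-site resolution at what backbone
  proximity can explain (on the synthetic data this cap is high; on real
  data it would not be).
* The LJ table is generic van-der-Waals parameters, not a fitted force
  field; it shapes the *direction* of pretraining noise, nothing more.
* Single-conformer molecules; the multi-conformer sampling of the full
  corpus is supported by the data model (one conformer is drawn per epoch)
  but the synthetic generator emits one conformer per molecule.
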