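# Methods

`bbvae` models the conformational ensemble of a single protein with a
graph variational autoencoder over backbone atoms, and ships the
synthetic-ensemble generator, training protocol and evaluation metrics
needed to exercise the model end to end without external data.  This
note records the model, its assumptions, the parameters that matter, and
the design choices made where the design was genuinely open.

## Model

### Graph representation

Each conformation keeps only the N, CA and C atoms (m = 3L nodes for L
residues).  Node features are a 60-way one-hot: the 20 standard residue
types × the three backbone roles, indexed `(residue alphabetical index) × 3
+ role` with roles N = 0, CA = 1, C = 2.  Adjacency is a directed
k-nearest-neighbor graph (default k = 30, saturating at m − 1 on small
chains): each receiver gets edges from its k nearest atoms by Euclidean
distance, ties broken by ascending atom index so the graph is
deterministic.  The graph is rebuilt per conformation and never
symmetrized; aggregation happens at the receiver.

Each directed edge j → i carries 23 features, all invariant to global
rotation and translation:

* 16 Gaussian radial basis values of the distance |x_i − x_j|, means
  uniform on [0, 20] Å.  The basis width is not dictated by the
  architecture; we set γ equal to the grid spacing 20/15 Å (configurable).
* the position of j in i's local atomic frame and of i in j's frame
  (2 × 3 values, raw Å, no normalization);
* one covalent-bond bit (N–CA, CA–C and peptide C–N(+1) pairs).

**Local frames.** The frame of a center atom B with bonded partners A and
C has origin B, z-axis along the normal of the A–B–C plane
(AB × BC, normalized), x-axis along the B→C bond, and y = z × x, giving a
right-handed orthonormal triad.  Interior atoms use their two covalent
backbone neighbors in chain order (N_i: C_{i−1}, N_i, CA_i; CA_i: N_i,
CA_i, C_i; C_i: CA_i, C_i, N_{i+1}).  The chain termini lack one partner
and substitute the remaining same-residue backbone atom: N_1 uses
(C_1, N_1, CA_1) and C_L uses (N_L, C_L, CA_L).  This terminal convention
affects edge features at the two chain ends only.

### Encoder

An embedding layer maps atom types to 64-dimensional vectors, followed by
three edge-gated graph convolutions with residual updates:

    h_ij = v_i ⊕ e_ij ⊕ v_j
    v_i ← v_i + Σ_{j∈N(i)} σ(h_ij W_g + b_g) ⊙ ReLU(h_ij W_c + b_c)

Edge features enter every layer unchanged.  The per-edge products are
evaluated through the mathematically identical decomposition
`(v W_recv)_i + e_ij W_edge + (v W_send)_j`, which avoids materializing
the wide concatenation (this is an implementation detail; the unit tests
pin the arithmetic to the printed update rule).

The residual neighbor sums are unnormalized and grow with the neighbor
count, so the stack output passes through a layer normalization before a
nonlinear dimension-reduction layer (64 → 32, ReLU).  Each residue's
(N, CA, C) atom vectors are concatenated in that fixed order (32 × 3 =
96), mapped through a shared ReLU layer (96 → 64), and two linear heads
produce the per-residue posterior mean and log-variance (64 → d_z = 32
each).  The log-variance is soft-bounded to (−8, 8) with a scaled tanh so
σ = exp(logvar/2) and the KL term stay finite for any activations; the
bias of the log-variance head is initialized at −3 (σ ≈ 0.22) so early
training is not drowned in latent noise while the KL anneal widens the
posterior later.

### Latent sampling

The reparameterization includes a temperature: z = μ + σ·ε·T with ε
i.i.d. standard normal.  Training uses T = 1; the deterministic mean
(T = 0) serves reconstruction and interpolation; generation defaults to
T = 0.02, where the scale is small because sampling is around encoded
conformations (below).

### Decoder

Latents are projected to 64-wide tokens and augmented with sinusoidal
positional encodings and a learned residue-type embedding (both can be
disabled; the model is system-specific, so the sequence is always known).
Three pre-norm transformer blocks follow — multi-head self-attention
(4 heads) and a position-wise feed-forward update module (64 → 128 → 64),
each with residual connection and layer normalization — then a final
layer norm and a linear head to 9 numbers per residue, reshaped to
(N, CA, C) coordinates.  The output lives in an arbitrary global frame;
the loss supplies the invariance, so no output alignment is performed.
No parameter shape depends on L; the default configuration has ≈ 1.8×10⁵
trainable scalars.

## Loss and training

The objective is `L = w_Recon · FAPE + w_KL · KL`.

**FAPE.**  Every backbone atom of prediction and truth is expressed in
every residue's local frame (frames built from each structure's own
N/CA/C via the construction above, origin at CA), and the mean Euclidean
distance over all L × 3L (frame, atom) pairs is taken.  Clamping is off
by default; a config flag caps per-pair distances (the familiar 10 Å
recipe) which shifts weight toward local geometry.  Inside the training
graph the square root carries an epsilon of 1e−12 and frame
normalizations an epsilon guard, for gradient stability near degenerate
intermediate geometries.

**KL.**  The standard closed-form Gaussian divergence to the unit normal,
averaged over entries: mean((μ² + σ² − 1 − log σ²)/2).  It is zero
exactly at (μ, logvar) = (0, 0) and positive otherwise.

**Weight schedule.**  Piecewise-constant stages expressed as fractions of
the total iteration budget so the staging shape survives rescaling:
w_Recon = 10.0 for the first 3/4 and 1.0 for the last 1/4; w_KL is
annealed 1e−4 → 5e−4 → 1e−3 → 5e−3 → 0.01 → 0.05 over six equal stages of
1/8 each, then 0.1 for the final 1/4.  Stage boundaries are
floor(cumulative fraction × total); the last stage absorbs the rounding
remainder; the lookup is right-continuous.  The small early KL weight
protects against posterior collapse; the large late weight shapes the
latent space for sampling.

**Optimizer.**  Adam (β₁ = 0.9, β₂ = 0.999), default step 1e−4, batch 32
at full scale; the desk-scale protocols below use their own documented
settings.  The schedule's step-size rule is constant by default; a cosine
decay to 5 % of the base step is available but measured no better on the
benchmark fixtures, so nothing uses it by default.  Mini-batches are drawn without replacement per iteration; the
batch graphs are concatenated into one disjoint-union graph.  Graphs and
ground-truth frame-local coordinates are featurized once per conformation
and cached.  A master seed is split into independent streams for
initialization, batch selection and latent noise, so two runs with the
same seed produce identical histories.  A non-finite loss aborts with the
iteration index.

**Data split.**  Seeded uniform shuffle, then contiguous slices of
50 % / 25 % / 25 % (floor arithmetic, remainder to train).

## Inference modes

* **Reconstruction** — encode, sample at T (default 0), decode; output
  order matches input order.
* **Generation** — the sampler re-encodes training conformations (drawn
  with replacement, seeded) and decodes z = μ + σ·ε·T around them: the
  latent space is sampled in the neighborhoods the decoder was trained
  on, which is what makes small T meaningful.  A "prior" mode decoding
  z = T·ε around the latent origin is available; at small T it
  necessarily concentrates near a single structure, so it is not the
  default.
* **Interpolation** — a straight line in latent space between the two
  posterior means (T = 0 endpoints), decoded at each step; the endpoints
  therefore equal the deterministic reconstructions bit-for-bit.

## Synthetic ensembles

The generator emulates what the model needs from an MD-derived ensemble
of one protein: φ/ψ torsions drawn from a mixture of Ramachandran basins
(wrapped normal per basin; one basin per conformation for bimodal
ensembles, or per site for disordered ones), ω near-planar trans
(180° ± 5°), and fixed covalent geometry (N–CA 1.458 Å, CA–C 1.525 Å,
C–N 1.329 Å; N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°).  Chains are
built by sequential natural-extension-reference-frame placement, which
honors the sampled torsions exactly (round-trip error < 1e−6°).

It does **not** model side chains, excluded volume, solvent, cis-proline,
or temporal correlation between frames.  Tests passing on these fixtures
therefore demonstrate that the pipeline learns and reproduces
basin-structured backbone statistics at fixture scale — not that it
reproduces any particular force field's ensembles.

## Desk-scale benchmark protocols

Two fixed protocols (`bbvae.protocols`) size the problem so a full run
takes minutes on one CPU core:

* **Reconstruction benchmark** — poly-alanine, L = 6, 32 conformations
  from the single helix basin (φ −63° ± 10°, ψ −43° ± 10°); 600
  iterations, batch 8, step 1e−3.  Measures mean backbone RMSD between
  inputs and T = 0 reconstructions (typically ≈ 0.2 Å, well under the
  1 Å acceptance bound).
* **Generation benchmark** — poly-alanine, L = 12, 500 conformations,
  equal-weight helix + extended (φ −120° ± 15°, ψ 135° ± 15°) basins
  assigned per conformation; 5 500 iterations, batch 8, step 2e−3,
  k = 16.  Trains, samples 500 conformations at T = 0.02, and scores the
  Jensen–Shannon divergence (nats, 50 shared-range bins) of the pooled ω
  torsions and of the Rg distribution against the training set.  The
  larger step size and reduced k reflect the small system and short
  budget; convergence behavior, not the thresholds, dictated them.

## Numerical conventions

* Angles are degrees in the public API; torsions lie in (−180°, 180°].
* ω values are re-centered to (0°, 360°] before histogramming so the
  trans peak at ±180° is not split across the support edges.
* JS divergences use natural log (bounded by ln 2 ≈ 0.693), 50 equal-width
  bins over the common min–max range of the two samples; identical
  constant samples give 0 by convention.
* Rg uses all 3L backbone atoms, unweighted (the three heavy atoms have
  near-equal masses; mass weighting changes values negligibly).
* Kabsch RMSD allows proper rotations only (chirality is preserved).
* "Contact maps" are CA–CA distance maps; no distance threshold is
  applied anywhere.
* K-medoids clustering uses seeded D²-weighted initialization and Voronoi
  iteration on the exact pairwise RMSD matrix; clusters are reported by
  descending size and medoids are real ensemble members.
* All floating point is double precision.

## Known limitations

* The model is system-specific: it must be retrained per sequence, and
  `reconstruct`/`generate` reject sequences that differ from the fitted
  one.
* Desk-scale training budgets reach ≈ 0.3–0.8 Å reconstruction on the
  fixtures; sharper reconstruction requires more iterations, not more
  capacity.
* Prior-mode generation at low temperature collapses by construction (see
  Inference modes) and is provided for completeness.
* Side chains are out of scope end to end: inputs, outputs and metrics
  are backbone-only.
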