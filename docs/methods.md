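# Methods

## Model

A layer's weights are never free parameters. In the relaxed genetic
connectome encoding, input neurons carry identities `X_i ∈ R^{N_i×G}`,
output neurons `X_o ∈ R^{N_o×G}`, genes interact through `O ∈ R^{G×G}`, and

    W = X_i O X_oᵀ.

`rank(W) ≤ G` always: the gene count is the representational budget. The
binary model `W = H(X O Xᵀ)` is kept for connectome-style analyses; we fix
`H(0) = 0`, so the empty ruleset generates the empty connectome, and the
binary output is invariant to any sign-preserving rescaling of the
pre-activations. `O` is dense and unconstrained — no symmetry or sparsity is
imposed on either `X` or `O`.

Training regenerates `W` from the current rules at every batch, evaluates
cross-entropy through it, backpropagates into the rules, and discards the
weights. Regeneration is pure: identical rules produce bitwise-identical
weights.

### Spatial fields (S-GEM)

Neurons are placed on an evenly spaced grid normalized to `[−1, 1]²`
(row-major order; a 28×28 grid for 784-neuron populations). Gene `i` is a
radial Gaussian field; neuron `j` expresses it at

    X[j,i] = exp(−(d_ji / σ_i)²),

`d_ji` the Euclidean distance (in normalized units) to the gene's center.
Two reparameterizations keep the search well-posed, and are exact, not
clipped: centers are stored as raw values mapped through `h·tanh(raw)`, so
no gradient step can move a gene outside the grid; widths are stored as
`σ = exp(raw)`, so they stay strictly positive. `σ` enters as the width of
the squared-distance exponent (a standard deviation, not a variance). Small
non-spatial output heads (a 5- or 10-way readout has no meaningful grid) use
a directly parameterized identity matrix, learnable or frozen at random.

Multi-layer encodings share a single `O` across all layers and give each
hidden neuron one identity used for both its incoming and outgoing weights,
so each hidden population's parameters appear in exactly two weight
matrices. Parameter scalings, all verified by enumeration in
`count_parameters`: direct `Σ_l N_i·N_o`; GEM `G(N_i+N_o+G)`; spatial SLP
`G(G+6)`; multi-layer spatial `G(G+3L)`; random basis `N_i·B` frozen +
`B·N_o` learned.

The spatial-SLP closed form `G(G+6)` counts two 3-scalar field sets per
gene. A directly parameterized 10-way head costs `10G` instead of `3G`; the
budget reporter exposes every component separately so either counting
convention can be read off. The analogous ambiguity in the locally connected
LeNet-5 encodings is handled the same way (`sgem_lenet5_components`).

### Developmental convolution

A classical convolution shares one kernel per feature map; biologically,
weight sharing has no mechanism, so here every output neuron grows its own
kernel. Genes live in the 3-D volume of a feature map — height and width
normalized to `[−1, 1]`, channel index likewise (a single channel sits at
0) — with expression

    g_i(x) = 1 / max(((x − μ_i)ᵀ σ_i)², floor²),      μ_i, σ_i ∈ R³,

exactly the anisotropic, sign-symmetric squared-projection form; the
proportionality constant is 1 and a floor of 1e−3 on the squared projection
guards the singularity (so the maximum expression is 1e6). Centers are not
tanh-bounded in 3-D. For each receptive field `r` (extracted exactly as a
classical convolution would, unrolled row-major over height, width, then
channel; zero padding contributes non-expressing virtual neurons), the
kernel block is

    W_r = Y_r O X_r ∈ R^{C_out × k²C_in},

computed for all `R` fields in one batched matrix product (verified against
the per-field loop to 1e−10). When the fields are constant over height and
width, every `W_r` coincides and the layer reduces to a shared-kernel
convolution — the classical limit, verified against `scipy.signal`
correlation to 1e−6. Average pooling runs twice in parallel with identical
geometry — on activations and on the gene-identity map (per gene channel) —
so identities propagate to the next developmental layer. Only
non-overlapping pooling (stride = window) is supported; nothing in the
encoded architectures needs more.

LeNet-5 accounting uses the classic valid-convolution geometry on a 32×32
input (28×28 digits zero-padded): shared kernels give 61,706 parameters;
learning a separate kernel *and bias* per output neuron in both
convolutional layers gives 423,038 — a ≈7× inflation that the spatial
encoding is designed to undo. Dense encoded layers are bias-free (the
784×10 = 7,840 direct-SLP count implies no bias).

## Training protocols

Presets reproduce the published schedules exactly. Digit tasks: Adam at
1e−3 (the rate is not printed for this setting; 1e−3 matches the printed
meta-learning rate), cross-entropy, batches of 64, cap 30,000 batches,
hold-out evaluation every 1,000 batches, early stop when an evaluation fails
to exceed the best so far by more than 0.005 (absolute accuracy). The
improvement threshold is published; the patience is not — we stop at the
first failure, never before the second evaluation, and the patience is
configurable. The reported figure of a run is the highest hold-out accuracy
measured. LeNet-5 runs: batches of 128 for 200 epochs, evaluated every
epoch. Initialization of relaxed identities and interactions is i.i.d.
Gaussian with std `(1/(3·fan_in·G²))^{1/6}`, chosen so the generated weights
match the entry variance of a standard uniform fan-in initialization of a
direct layer — "a fitting random distribution" made precise enough to
compare naive accuracies.

### Meta-learning

The few-shot harness is MAML with learned per-parameter learning rates: the
inner loop takes `steps` functional gradient steps on the support set,
`θ' = θ − lr_p ⊙ ∇loss`, one learned scalar rate per named parameter tensor
(tensor granularity is the natural reading of "a unique learning rate per
named parameter"); the outer loop minimizes mean post-adaptation query loss
and updates rules and rates together. Meta-gradients are second-order by
default (the backward pass is itself differentiable); a first-order switch
detaches the inner gradients. Inner rates are initialized at 0.1 — the
upper end of the meta-SGD initialization convention — and are not clamped;
the printed 1e−3 is the outer Adam rate. The benchmark preset is 5-way
1-shot, 2 inner steps, meta-batches of 32 episodes, cap 50,000 meta-batches,
evaluation every 250 meta-batches averaged over 10 batches of 64 query
predictions, on a 784-784-784-5 architecture with ReLUs, one shared `O` and
a unique `X` per layer. Gene budgets of 50 and 20 per node reproduce the
≈10× and ≈25× compression labels on that architecture (10.2× and 25.9× by
exact count).

## Synthetic data

Offline tests need data with the structure the encodings exploit; two
generators provide it, both pure functions of their spec.

**Blob tasks** stand in for MNIST: 28×28 images in `[0, 1]` whose class is a
fixed template of 3 spatially localized Gaussian bumps, observed under
i.i.d. pixel noise (default sd 0.1, 1,000 samples per class, 5 classes,
80/20 train/holdout). Localized class structure is deliberate: spatial gene
fields can only help if information is spatially concentrated, as digit
strokes are. At zero noise, classes are linearly separable by construction.

**Glyph pools** stand in for Omniglot: 120 polyline "character" classes of
20 jittered renderings each (the benchmark has 20 drawers per character),
split 75/25 into disjoint train/test class sets. Class templates are
rejection-sampled to pairwise cosine similarity ≤ 0.85 — characters from
real alphabets are mutually distinguishable, and a pool violating that would
misstate the few-shot problem's difficulty. Within-class variation is a
global translation (sd 0.03 in unit coordinates, ≈0.4 px at the default
12×12 grid), per-vertex wobble at half that, and pixel noise (sd 0.03),
mirroring how consistently a drawer reproduces a character.

What these generators do *not* emulate: stroke topology and curvature,
pen-pressure variation, the heavy-tailed class-frequency structure of real
handwriting, or 10-class digit diversity at realistic intra-class variance.
Passing the capability checks therefore demonstrates that the encodings can
represent, train on, and meta-adapt to spatially structured image classes at
these problem sizes — not that they reach any particular accuracy on the
external benchmarks.

## Desk-scale problem sizes

The capability checks run at sizes chosen for a single CPU: dense encodings
(spatial, GEM with 10 genes, direct) on the 5-class blob task for up to
2,000 batches over 3 seeds; the meta-learning check as 3-way 1-shot glyph
episodes, a 144-64-3 GEM with 16 genes and a learned head, meta-batches of
8, up to 2,000 meta-batches, evaluation every 100. The external-benchmark
protocols are available unchanged through the CLI presets; their published
accuracies (93% direct SLP; ≈25% GEM at G=1 rising to 93% at G=9;
98.95 ± 0.07% shared LeNet-5 vs 96.7 ± 0.2% at 2× spatial compression;
89.5 ± 0.2% direct vs 90.5 ± 0.4% 10×-compressed GEM on 5-way 1-shot
Omniglot) are recorded with ±2-point bands in `neurogem.benchmarks` as
documentation for those optional runs, not as test gates.

## Numerical choices and limitations

- All computation is float64 on the package's own reverse-mode autodiff
  engine; backward functions are built from the same primitives, so
  `grad(..., create_graph=True)` yields differentiable gradients (what
  second-order MAML requires). Gather/scatter are mutually adjoint linear
  primitives, covering patch extraction and label indexing.
- Degenerate inputs: `H(0) = 0`; the inverse-square floor caps expression at
  `floor⁻²`; a degenerate `σ = 0` direction yields a constant, finite field;
  non-finite losses abort with the rule-parameter norms in the message.
- Determinism: single-threaded numpy makes runs bitwise reproducible given
  the config seed; histories from identical seeds are identical.
- The rule-fitting harness (`fit_rules_to_connectome`) is Adam least squares
  on the Frobenius residual — a capability probe sharing the training
  differentiation path, not a connectome-inference method. A gene budget at
  or above the target's rank drives the error to ~0; below it, the
  truncated-SVD error is the floor.
- Known limitations: no learned neuron positions, no max pooling or strided
  convolution variants beyond the classic geometry, no sparsity pressure on
  `X` or `O`, and the engine favors clarity over speed — large-scale
  benchmark runs are possible but slow.
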