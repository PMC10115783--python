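# neurogem

Developmental encodings of neural-network weights: instead of learning a
weight matrix, learn the *wiring rules* that generate it.

## The idea

In the Genetic Connectome Model, a circuit of `N` neurons is wired by
biochemistry, not by a lookup table: each neuron carries a gene-expression
identity vector (a row of the `N×G` matrix `X`), genes interact through a
`G×G` compatibility matrix `O`, and the connectome is

```
W = H(X O Xᵀ)          (binary model, H = Heaviside step)
W = X_i O X_oᵀ          (continuous relaxation; feed-forward layer N_i × N_o)
```

`neurogem` turns this into a trainable machine-learning encoding (GEM, the
genetic neuroevolution model): every forward pass regenerates the layer
weights from the current rules, task loss is backpropagated *through the
generation process* into `X` and `O`, and the weights are discarded after
each batch. Training therefore searches over developmental programs — a
model of evolutionary selection for innate behavior — and the rule set is a
compressed genome for the network: a GEM layer costs `G(N_i + N_o + G)`
parameters instead of `N_i · N_o`.

The spatial variant (S-GEM) goes further: neurons sit on a fixed 2-D grid
and each gene is a radial Gaussian field with just 3 learnable scalars
(`μ_x, μ_y, σ`); a neuron's expression of gene `i` is `exp(−(d/σ_i)²)` with
`d` its distance to the gene's center. An encoded layer then costs `G(G+6)`
parameters regardless of how many neurons it wires. The package also
provides:

- **developmental convolutions** — convolution without weight sharing: every
  output neuron's kernel is generated as `W_r = Y_r O X_r` from 3-D
  inverse-square gene fields, with dual average-pooling that propagates both
  activations and gene identities;
- a **MAML few-shot harness** with learned per-parameter inner-loop learning
  rates, where meta-gradients flow through the unrolled adaptation back into
  the wiring rules (second-order by default);
- a **random-basis baseline** (`W = RP`) and exact parameter accounting for
  all encodings, including shared-kernel (61,706) vs locally connected
  (423,038) LeNet-5;
- **synthetic tasks** (noisy Gaussian-bump images; an episodic polyline-glyph
  pool with disjoint train/test classes) so everything is testable offline,
  plus IDX and folder-per-class readers for the real benchmarks.

All differentiation runs on the package's own reverse-mode autodiff engine
over numpy (`neurogem.autodiff`), which supports higher-order gradients —
see `docs/methods.md` for the model details and design choices.

## Worked example

Train a spatially encoded single-layer classifier on the 5-class blob task
and compare its cost against the direct layer:

```python
import neurogem as ng
from neurogem.training import TrainConfig, fit, compression_report

task  = ng.make_blob_task(ng.BlobTaskSpec(seed=1))       # 5 classes, 28×28
model = ng.SGEMMLP([784, 5], genes=10, seed=1)           # spatial encoding
hist  = fit(model, task, TrainConfig(max_batches=2000, eval_every=100, seed=1))
print(f"best holdout accuracy: {hist.best_accuracy:.3f}")
print(compression_report(model))
```

Output:

```
best holdout accuracy: 1.000
{'encoded_total': 180, 'encoded_learned': 180, 'direct_total': 3920,
 'percent_of_direct': 4.591836734693878, 'fold_compression': 21.77777777777778}
```

180 rule parameters (10 genes × 3 field scalars, a 10×10 interaction matrix,
and a directly learned 5-unit head identity of 50) generate and steer all
3,920 weights — a 21.8× compression at full task accuracy. The same budgets at
MNIST scale: `neurogem budgets` prints 7,840 (direct SLP), 2,391 (GEM, 3
genes, ≈30%), and the LeNet-5 pair 61,706 / 423,038 (≈7× fold).

A few-shot run on the synthetic glyph pool (3-way 1-shot, 2 inner steps):

```
neurogem run --task glyphs --encoding gem --genes 16 --seed 1 \
             --max-batches 2000 --out results/glyphs
```

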