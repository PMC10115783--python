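"""Layer constructors: from identities and interactions to network weights.

Dense layers are bilinear products of population identities, W = X_i O X_oᵀ.
Multi-layer chains share one interaction matrix and give every hidden neuron a
single identity used for both its incoming and outgoing weights. The
developmental convolutional layer removes weight sharing: every output neuron
gets its own kernel, generated from the gene identities of its receptive field
and of the output neurons stacked above it, W_r = Y_r O X_r, computed for all
receptive fields with one batched matrix product. Average pooling runs twice
in parallel — once on activations, once on the gene-identity map — so that
identities propagate to the next developmental layer. The random-basis layer
(W = R P, frozen random basis R, learned coefficients P) is the standard
low-parameter baseline the encodings are compared against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, permute, reshape, take_rows, tmean
from .genome_core import ParamBudget, build_layer_weights
from .spatial import GeneField3D, layer_identity_map

__all__ = [
    "mlp_weights_from_rules",
    "conv_output_shape",
    "im2col_indices",
    "extract_receptive_field_identities",
    "dev_conv_weights",
    "DevConvLayer",
    "dev_conv_forward",
    "avg_pool_dual",
    "random_basis_weights",
    "lenet5_parameter_budget",
    "sgem_lenet5_components",
]


def mlp_weights_from_rules(identities, interaction):
    """Chain weights W_l = X_l O X_{l+1}ᵀ from per-population identities.

    ``identities`` holds one identity matrix per neuron population (input,
    each hidden, output); each hidden population's identity therefore appears
    in exactly two weight matrices.
    """
    if len(identities) < 2:
        raise ValueError("need at least input and output populations")
    return [
        build_layer_weights(identities[i], interaction, identities[i + 1])
        for i in range(len(identities) - 1)
    ]


def conv_output_shape(h: int, w: int, k: int, stride: int = 1, padding: int = 0):
    hp, wp = h + 2 * padding, w + 2 * padding
    if k > hp or k > wp:
        raise ValueError(f"kernel {k} exceeds padded input extent {hp}×{wp}")
    return (hp - k) // stride + 1, (wp - k) // stride + 1


def im2col_indices(shape, k: int, stride: int = 1, padding: int = 0):
    """Patch-gather indices into the *padded* flattened volume.

    Returns ``(idx, (h_out, w_out), n_padded)`` where ``idx`` has shape
    (R, k·k·C) and unrolls each window row-major over height, width, then
    channel (the documented order). Padded positions index a synthetic zero
    row appended at ``n_padded``.
    """
    h, w, c = shape
    h_out, w_out = conv_output_shape(h, w, k, stride, padding)
    hp, wp = h + 2 * padding, w + 2 * padding
    n = h * w * c

    # map padded lattice -> flat original index, or n (the appended zero row)
    pad_lookup = np.full((hp, wp, c), n, dtype=np.intp)
    orig = np.arange(h * w * c, dtype=np.intp).reshape(h, w, c)
    pad_lookup[padding : padding + h, padding : padding + w, :] = orig

    idx = np.empty((h_out * w_out, k * k * c), dtype=np.intp)
    r = 0
    for i in range(h_out):
        for j in range(w_out):
            win = pad_lookup[i * stride : i * stride + k, j * stride : j * stride + k, :]
            idx[r] = win.reshape(-1)
            r += 1
    return idx, (h_out, w_out), n


def _with_zero_row(flat: Tensor) -> Tensor:
    """Append a zero row so padded positions can be gathered like real ones."""
    from .autodiff import scatter_rows

    n = flat.shape[0]
    return scatter_rows(flat, np.arange(n), n + 1)


def extract_receptive_field_identities(identity_map, k: int, stride: int = 1,
                                       padding: int = 0) -> Tensor:
    """Stack per-receptive-field identities X_r: (R, G, k²·C_in).

    Mirrors classical patch extraction, but gathers gene vectors instead of
    activations; zero padding corresponds to non-expressing virtual neurons.
    """
    m = as_tensor(identity_map)
    h, w, c, g = m.shape
    idx, _, n = im2col_indices((h, w, c), k, stride, padding)
    flat = reshape(m, (n, g))
    if padding > 0:
        flat = _with_zero_row(flat)
    patches = take_rows(flat, idx)  # (R, K, G)
    return permute(patches, (0, 2, 1))


def dev_conv_weights(y, o, x) -> Tensor:
    """Batched W_r = Y_r O X_r over all receptive fields → (R, C_out, k²·C_in)."""
    y, o, x = as_tensor(y), as_tensor(o), as_tensor(x)
    if y.shape[-1] != o.shape[0] or x.shape[1] != o.shape[1]:
        raise ValueError(
            f"gene dimension mismatch: Y has G={y.shape[-1]}, O is {o.shape}, "
            f"X has G={x.shape[1]}"
        )
    return (y @ o) @ x


@dataclass
class DevConvLayer:
    """Non-weight-shared convolution whose kernels grow from gene fields."""

    k: int
    c_in: int
    c_out: int
    output_field: GeneField3D
    interaction: Tensor
    stride: int = 1
    padding: int = 0
    bias: Tensor | None = None  # per-output-neuron bias (R, C_out) when used

    def parameters(self, prefix: str) -> dict:
        p = self.output_field.parameters(f"{prefix}.field")
        p[f"{prefix}.o"] = self.interaction
        if self.bias is not None:
            p[f"{prefix}.bias"] = self.bias
        return p


def dev_conv_forward(activations, input_identity_map, layer: DevConvLayer):
    """Forward pass of the developmental convolution.

    ``activations``: (B, H, W, C_in); ``input_identity_map``: (H, W, C_in, G).
    Returns output activations (B, H', W', C_out) and the output identity map
    (H', W', C_out, G) evaluated from the layer's 3-D gene field — the pair
    the next developmental layer consumes.
    """
    act = as_tensor(activations)
    m = as_tensor(input_identity_map)
    b, h, w, c = act.shape
    if m.shape[:3] != (h, w, c):
        raise ValueError(
            f"identity map {m.shape[:3]} does not align with activations {(h, w, c)}"
        )
    x_r = extract_receptive_field_identities(m, layer.k, layer.stride, layer.padding)
    idx, (h_out, w_out), n = im2col_indices((h, w, c), layer.k, layer.stride, layer.padding)

    out_map = layer_identity_map((h_out, w_out, layer.c_out), layer.output_field)
    y_r = reshape(out_map, (h_out * w_out, layer.c_out, out_map.shape[-1]))
    weights = dev_conv_weights(y_r, layer.interaction, x_r)  # (R, C_out, K)

    flat = reshape(permute(act, (1, 2, 3, 0)), (n, b))
    if layer.padding > 0:
        flat = _with_zero_row(flat)
    patches = take_rows(flat, idx)  # (R, K, B)
    out = weights @ patches  # (R, C_out, B)
    out = reshape(permute(out, (2, 0, 1)), (b, h_out, w_out, layer.c_out))
    if layer.bias is not None:
        out = out + reshape(layer.bias, (1, h_out, w_out, layer.c_out))
    return out, out_map


def avg_pool_dual(activations, identity_map, window: int, stride: int | None = None):
    """Average-pool activations and gene identities with identical geometry.

    Non-overlapping pooling (stride = window) over spatial extents that the
    window divides exactly — the only case the encoded architectures use.
    """
    stride = window if stride is None else stride
    if stride != window:
        raise ValueError("only non-overlapping pooling (stride == window) is supported")
    act = as_tensor(activations)
    m = as_tensor(identity_map)
    b, h, w, c = act.shape
    if h % window or w % window:
        raise ValueError(f"window {window} does not divide extent {h}×{w}")
    ho, wo = h // window, w // window
    pooled_act = tmean(
        reshape(act, (b, ho, window, wo, window, c)), axis=(2, 4)
    )
    g = m.shape[-1]
    pooled_map = tmean(
        reshape(m, (ho, window, wo, window, c, g)), axis=(1, 3)
    )
    return pooled_act, pooled_map


def random_basis_weights(basis, coefficients) -> Tensor:
    """Random-basis baseline W = R P (N_i×B frozen basis, B×N_o learned)."""
    basis, coefficients = as_tensor(basis), as_tensor(coefficients)
    if basis.shape[1] != coefficients.shape[0]:
        raise ValueError(
            f"basis count mismatch: basis is {basis.shape}, coefficients {coefficients.shape}"
        )
    return basis @ coefficients


# -- LeNet-5 accounting ----------------------------------------------------

_LENET5 = dict(
    input=(32, 32, 1),  # 28×28 MNIST zero-padded to 32×32
    conv1=dict(k=5, c_in=1, c_out=6),  # -> 28×28×6, pool -> 14×14×6
    conv2=dict(k=5, c_in=6, c_out=16),  # -> 10×10×16, pool -> 5×5×16
    dense=[(400, 120), (120, 84), (84, 10)],
)


def lenet5_parameter_budget(locally_connected: bool = False) -> ParamBudget:
    """Enumerate LeNet-5 parameters, shared-kernel or per-neuron kernels.

    The locally connected variant learns a separate kernel and bias for every
    output neuron of each convolutional layer (the biological, no-weight-
    sharing reading); dense layers are identical in both variants.
    """
    counts: dict[str, int] = {}
    spatial = {"conv1": (28, 28), "conv2": (10, 10)}
    for name in ("conv1", "conv2"):
        cfg = _LENET5[name]
        kernel = np.zeros((cfg["c_out"], cfg["k"], cfg["k"], cfg["c_in"]))
        if locally_connected:
            r = spatial[name][0] * spatial[name][1]
            counts[f"{name}.weights"] = np.zeros((r,) + kernel.shape).size
            counts[f"{name}.bias"] = np.zeros((r, cfg["c_out"])).size
        else:
            counts[f"{name}.weights"] = kernel.size
            counts[f"{name}.bias"] = cfg["c_out"]
    for li, (a, b) in enumerate(_LENET5["dense"]):
        counts[f"fc{li + 1}.weights"] = np.zeros((a, b)).size
        counts[f"fc{li + 1}.bias"] = b
    return ParamBudget(
        encoding="dev_conv" if locally_connected else "direct", counts=counts
    )


def sgem_lenet5_components(conv_genes: int = 150, dense_genes: int = 30) -> dict:
    """Per-component counts for one spatial encoding of LeNet-5.

    One interaction matrix per gene namespace (convolutional and dense), 6
    learnables per 3-D conv gene, 3 per 2-D dense gene, and a directly
    parameterized 10-unit head. Exposed per component so alternative counting
    conventions can be read off directly.
    """
    return {
        "O_conv": conv_genes * conv_genes,
        "conv1.fields": 6 * conv_genes,
        "conv2.fields": 6 * conv_genes,
        "O_dense": dense_genes * dense_genes,
        "fc1.fields": 3 * dense_genes,
        "fc2.fields": 3 * dense_genes,
        "head.X_o": 10 * dense_genes,
    }
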