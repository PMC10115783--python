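"""Genetic Connectome Model core: connectivity from identities and interactions.

A circuit of N neurons is generated, not learned: each neuron i carries a
gene-expression identity vector X[i] (length G), genes interact through a
G×G matrix O, and the connectome is W = H(X O Xᵀ) in the binary model or the
continuous relaxation W = X O Xᵀ used for gradient-based training. A
feed-forward layer between distinct input and output populations is
W = X_i O X_oᵀ.

Functions here accept plain numpy arrays or autodiff Tensors interchangeably;
with Tensor inputs the result is differentiable w.r.t. identities and
interactions, which is how task loss reaches the wiring rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor, grad, tsum

__all__ = [
    "ParamBudget",
    "build_connectome",
    "build_layer_weights",
    "count_parameters",
    "fit_rules_to_connectome",
    "gem_init_std",
]


def _data(m):
    return m.data if isinstance(m, Tensor) else np.asarray(m)


def _check_gene_dims(x_rows_genes, o):
    g_x = _data(x_rows_genes).shape[1]
    o_shape = _data(o).shape
    if len(o_shape) != 2 or o_shape[0] != o_shape[1]:
        raise ValueError(f"interaction matrix must be square G×G, got {o_shape}")
    if g_x != o_shape[0]:
        raise ValueError(
            f"gene dimension mismatch: identities carry {g_x} genes, "
            f"interaction matrix is {o_shape[0]}×{o_shape[1]}"
        )


def build_connectome(x, o, binary: bool = False):
    """Recurrent connectome W = X O Xᵀ (N×N), thresholded if ``binary``.

    The Heaviside convention is H(s) = 1 for s > 0 and 0 otherwise, so the
    zero pre-activation maps to "no synapse" and the empty ruleset generates
    the empty connectome.
    """
    _check_gene_dims(x, o)
    if binary:
        pre = _data(x) @ _data(o) @ _data(x).T
        return (pre > 0).astype(np.float64)
    return x @ o @ x.T


def build_layer_weights(x_in, o, x_out):
    """Feed-forward layer weights W = X_i O X_oᵀ, shape N_i × N_o.

    rank(W) ≤ G always: the bilinear form factors through gene space.
    """
    _check_gene_dims(x_in, o)
    g_out = _data(x_out).shape[1]
    if g_out != _data(o).shape[0]:
        raise ValueError(
            f"gene dimension mismatch: output identities carry {g_out} genes, "
            f"interaction matrix is {_data(o).shape[0]} square"
        )
    return x_in @ o @ x_out.T


def gem_init_std(fan_in: int, genes: int) -> float:
    """Initialization scale for relaxed X and O entries.

    I.i.d. zero-mean Gaussian entries of std s give Var(W_ij) = G² s⁶ for
    W = X_i O X_oᵀ. Matching the entry variance 1/(3·fan_in) of a standard
    uniform fan-in initialization of a direct layer gives
    s = (1 / (3·fan_in·G²))^(1/6), so generated and direct networks start from
    comparable weight magnitudes.
    """
    return float((1.0 / (3.0 * fan_in * genes**2)) ** (1.0 / 6.0))


# -- parameter accounting --------------------------------------------------

_ENCODINGS = ("direct", "gem", "sgem_slp", "sgem_ml", "random_basis", "dev_conv")


@dataclass
class ParamBudget:
    """Per-component parameter counts for one encoding of an architecture.

    ``counts`` maps component names to entry counts obtained by enumerating
    the actual array shapes; ``total`` is their sum. ``frozen`` lists the
    components that are fixed at construction (counted in ``total`` when
    ``includes_frozen`` is True, the convention the printed GEM totals use).
    """

    encoding: str
    counts: dict = field(default_factory=dict)
    frozen: tuple = ()
    includes_frozen: bool = True

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def learned_total(self) -> int:
        return int(sum(v for k, v in self.counts.items() if k not in self.frozen))


def count_parameters(
    encoding: str,
    n_in: int = 0,
    n_out: int = 0,
    genes: int = 0,
    layers: int = 1,
    basis: int = 0,
    layer_shapes=None,
    frozen_x_out: bool = False,
) -> ParamBudget:
    """Enumerate the parameters of one encoding and cross-check the closed form.

    Closed forms: direct Σ_l N_i·N_o; GEM G(N_i+N_o+G); spatial SLP G(G+6);
    multi-layer spatial G(G+3L); random basis B·N_o learned (+ N_i·B frozen).
    """
    if encoding not in _ENCODINGS:
        raise ValueError(f"unknown encoding {encoding!r}; expected one of {_ENCODINGS}")
    for v in (n_in, n_out, genes, layers, basis):
        if v < 0 or int(v) != v:
            raise ValueError("sizes must be nonnegative integers")

    counts: dict[str, int] = {}
    frozen: tuple = ()
    if encoding == "direct":
        shapes = layer_shapes if layer_shapes is not None else [(n_in, n_out)]
        for li, (a, b) in enumerate(shapes):
            counts[f"W_{li}"] = np.zeros((a, b)).size
        closed = sum(a * b for a, b in shapes)
    elif encoding == "gem":
        counts["X_i"] = np.zeros((n_in, genes)).size
        counts["O"] = np.zeros((genes, genes)).size
        counts["X_o"] = np.zeros((n_out, genes)).size
        if frozen_x_out:
            frozen = ("X_o",)
        closed = genes * (n_in + n_out + genes)
    elif encoding == "sgem_slp":
        counts["O"] = np.zeros((genes, genes)).size
        counts["input_fields"] = np.zeros((genes, 3)).size
        counts["output_fields"] = np.zeros((genes, 3)).size
        closed = genes * (genes + 6)
    elif encoding == "sgem_ml":
        counts["O"] = np.zeros((genes, genes)).size
        for li in range(layers):
            counts[f"fields_{li}"] = np.zeros((genes, 3)).size
        closed = genes * (genes + 3 * layers)
    elif encoding == "random_basis":
        counts["basis"] = np.zeros((n_in, basis)).size
        counts["coefficients"] = np.zeros((basis, n_out)).size
        frozen = ("basis",)
        closed = n_in * basis + basis * n_out
    else:  # dev_conv: geometry-specific; see encoded_layers.lenet5_parameter_budget
        raise ValueError(
            "dev_conv budgets depend on layer geometry; use "
            "encoded_layers.lenet5_parameter_budget or DevConvLayer.budget"
        )

    budget = ParamBudget(encoding=encoding, counts=counts, frozen=frozen)
    assert budget.total == closed, (budget.total, closed)
    return budget


# -- rule fitting (least-squares harness) ----------------------------------


@dataclass
class RuleFit:
    x_in: np.ndarray
    interaction: np.ndarray
    x_out: np.ndarray
    error: float  # Frobenius norm of W_target − X_i O X_oᵀ


def fit_rules_to_connectome(
    w_target,
    genes: int,
    seed: int = 0,
    iterations: int = 3000,
    lr: float = 0.1,
) -> RuleFit:
    """Gradient-based least-squares fit of (X_i, O, X_o) to a target weight matrix.

    Uses the same differentiation path as training (Adam on the squared
    Frobenius residual). A G ≥ rank(W) budget can drive the error to ~0;
    G below the rank is bounded below by the best rank-G approximation.
    """
    w = np.asarray(w_target, dtype=np.float64)
    if not np.all(np.isfinite(w)):
        raise ValueError("target connectome contains non-finite entries")
    if genes < 1:
        raise ValueError("need at least one gene")
    n_i, n_o = w.shape
    rng = np.random.default_rng(seed)
    s = gem_init_std(max(n_i, 1), genes)
    params = {
        "x_in": Tensor(rng.normal(0.0, s, (n_i, genes)), requires_grad=True),
        "o": Tensor(rng.normal(0.0, s, (genes, genes)), requires_grad=True),
        "x_out": Tensor(rng.normal(0.0, s, (n_o, genes)), requires_grad=True),
    }
    opt = Adam(params, lr=lr)
    target = Tensor(w)
    names = list(params)
    for _ in range(iterations):
        resid = build_layer_weights(params["x_in"], params["o"], params["x_out"]) - target
        loss = tsum(resid * resid)
        gs = grad(loss, [params[k] for k in names])
        opt.step(dict(zip(names, gs)))
    w_hat = params["x_in"].data @ params["o"].data @ params["x_out"].data.T
    return RuleFit(
        x_in=params["x_in"].data,
        interaction=params["o"].data,
        x_out=params["x_out"].data,
        error=float(np.linalg.norm(w - w_hat)),
    )
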