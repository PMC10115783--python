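"""Spatially parameterized gene expression.

Dense spatial encodings (S-GEM) place neurons on a fixed 2-D grid, normalized
to [−1, 1]², and let each gene be a radial Gaussian field: neuron j expresses
gene i at level exp(−(d_ji/σ_i)²), d_ji the Euclidean distance to the gene's
center. Only 3 scalars per gene (μ_x, μ_y, σ) are learned, so the identity
matrix of an arbitrarily large layer costs 3G parameters. Two
reparameterizations keep training well-posed: centers are stored as raw
values passed through tanh (scaled to the grid half-extent), so a gradient
step can never move a gene off the grid; widths are stored as raw values
passed through exp, so they stay strictly positive.

Developmental convolutions use a 3-D variant: genes live in the (height,
width, channel) volume of a feature map, with expression falling off as the
inverse square of a directional projection, g_i(x) = 1/((x−μ_i)ᵀσ_i)². A
small floor on the squared projection guards the singularity at the gene
surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, as_tensor, broadcast_to, exp, maximum_const, reshape, tanh, tsum

__all__ = [
    "NeuronGrid",
    "GeneField2D",
    "GeneField3D",
    "constrain_centers",
    "constrain_widths",
    "gaussian_expression",
    "inverse_square_expression",
    "layer_identity_map",
    "volume_coordinates",
]


@dataclass(frozen=True)
class NeuronGrid:
    """Evenly spaced neuron positions on a rows×cols grid in [−1, 1]²."""

    rows: int
    cols: int
    halfextent: float = 1.0

    def __post_init__(self):
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def n_neurons(self) -> int:
        return self.rows * self.cols

    @property
    def coordinates(self) -> np.ndarray:
        """(N, 2) array of (x, y) positions, row-major over the grid."""
        h = self.halfextent
        ys = np.linspace(-h, h, self.rows) if self.rows > 1 else np.zeros(1)
        xs = np.linspace(-h, h, self.cols) if self.cols > 1 else np.zeros(1)
        gy, gx = np.meshgrid(ys, xs, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel()], axis=1)


class GeneField2D:
    """G Gaussian gene-expression fields over a 2-D grid; 3 learnables per gene."""

    def __init__(self, genes: int, rng: np.random.Generator | None = None,
                 init_sigma: float = 0.5):
        if genes < 1:
            raise ValueError("need at least one gene")
        rng = rng or np.random.default_rng(0)
        self.genes = genes
        # raw centers ~ N(0,1): tanh spreads them over the central grid region
        self.raw_mu = Tensor(rng.normal(0.0, 1.0, (genes, 2)), requires_grad=True)
        self.raw_sigma = Tensor(
            np.log(init_sigma) + 0.1 * rng.normal(size=genes), requires_grad=True
        )

    def parameters(self, prefix: str = "field") -> dict:
        return {f"{prefix}.raw_mu": self.raw_mu, f"{prefix}.raw_sigma": self.raw_sigma}


@dataclass
class GeneField3D:
    """G inverse-square gene fields in a 3-D conv volume; 6 learnables per gene."""

    mu: Tensor
    sigma: Tensor
    floor: float = 1e-3

    @classmethod
    def create(cls, genes: int, rng: np.random.Generator | None = None,
               floor: float = 1e-3) -> "GeneField3D":
        rng = rng or np.random.default_rng(0)
        return cls(
            mu=Tensor(rng.normal(0.0, 1.0, (genes, 3)), requires_grad=True),
            sigma=Tensor(rng.normal(0.0, 1.0, (genes, 3)), requires_grad=True),
            floor=floor,
        )

    @property
    def genes(self) -> int:
        return self.mu.shape[0]

    def parameters(self, prefix: str = "field3d") -> dict:
        return {f"{prefix}.mu": self.mu, f"{prefix}.sigma": self.sigma}


def constrain_centers(raw_mu, grid_halfextent: float = 1.0):
    """Map unconstrained center parameters into (−h, h) via h·tanh(raw)."""
    return tanh(as_tensor(raw_mu)) * float(grid_halfextent)


def constrain_widths(raw_sigma):
    """Map unconstrained width parameters to strictly positive σ = exp(raw)."""
    return exp(as_tensor(raw_sigma))


def gaussian_expression(grid: NeuronGrid, fld: GeneField2D) -> Tensor:
    """Identity matrix X (N×G): X[j, i] = exp(−(d_ji / σ_i)²).

    Differentiable w.r.t. the field's raw parameters; entries lie in (0, 1]
    and are maximal (= 1) for a neuron sitting exactly on a gene center.
    """
    coords = Tensor(grid.coordinates[:, None, :])  # (N, 1, 2), constant
    mu = reshape(constrain_centers(fld.raw_mu, grid.halfextent), (1, fld.genes, 2))
    sigma = reshape(constrain_widths(fld.raw_sigma), (1, fld.genes))
    diff = coords - broadcast_to(mu, (grid.n_neurons, fld.genes, 2))
    d2 = tsum(diff * diff, axis=-1)  # (N, G) squared distances
    return exp(-(d2 / (sigma * sigma)))


def inverse_square_expression(x, fld: GeneField3D, gene: int) -> Tensor:
    """Expression of gene ``gene`` at a 3-D point: 1 / max(((x−μ)ᵀσ)², floor²)."""
    x = as_tensor(np.asarray(x, dtype=np.float64).reshape(3))
    mu = take_gene_row(fld.mu, gene)
    sigma = take_gene_row(fld.sigma, gene)
    dot = tsum((x - mu) * sigma)
    return maximum_const(dot * dot, fld.floor**2) ** -1.0


def take_gene_row(t: Tensor, i: int) -> Tensor:
    from .autodiff import take_rows

    return take_rows(t, np.asarray(i))


def volume_coordinates(shape) -> np.ndarray:
    """Normalized (H·W·C, 3) lattice coordinates of a conv volume.

    Height and width span [−1, 1]; the channel index is likewise normalized to
    [−1, 1] (a single channel sits at 0). Row-major over height, width, channel.
    """
    h, w, c = shape
    hs = np.linspace(-1, 1, h) if h > 1 else np.zeros(1)
    ws = np.linspace(-1, 1, w) if w > 1 else np.zeros(1)
    cs = np.linspace(-1, 1, c) if c > 1 else np.zeros(1)
    gh, gw, gc = np.meshgrid(hs, ws, cs, indexing="ij")
    return np.stack([gh.ravel(), gw.ravel(), gc.ravel()], axis=1)


def layer_identity_map(conv_volume_shape, fld: GeneField3D) -> Tensor:
    """Evaluate all G fields on the volume lattice → identity map (H, W, C, G)."""
    h, w, c = conv_volume_shape
    if h < 1 or w < 1 or c < 1:
        raise ValueError("conv volume dimensions must be positive")
    pts = Tensor(volume_coordinates(conv_volume_shape)[:, None, :])  # (P, 1, 3)
    g = fld.genes
    mu = reshape(fld.mu, (1, g, 3))
    sigma = reshape(fld.sigma, (1, g, 3))
    n = h * w * c
    diff = pts - broadcast_to(mu, (n, g, 3))
    dot = tsum(diff * broadcast_to(sigma, (n, g, 3)), axis=-1)  # (P, G)
    expr = maximum_const(dot * dot, fld.floor**2) ** -1.0
    return reshape(expr, (h, w, c, g))
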