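"""Encoded models: architectures whose weights are regenerated from rules.

Every model exposes the same functional contract:

- ``params``: name → leaf Tensor dict of the *learnable rule parameters*
  (identities, interaction matrices, gene-field raws — never weights);
- ``frozen``: name → constant array dict (e.g. a fixed random output identity
  or a random basis), bitwise immutable across training;
- ``forward(x, params=None)``: regenerate the weight matrices from the given
  (or stored) rule parameters and run the network. Passing an explicit
  ``params`` dict makes the call purely functional, which is what MAML's
  inner loop relies on.

Weights never persist between calls: each forward is a fresh developmental
roll-out of the current rules.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, as_tensor, relu
from .genome_core import ParamBudget, count_parameters, gem_init_std
from .layers import mlp_weights_from_rules, random_basis_weights
from .spatial import GeneField2D, NeuronGrid, gaussian_expression

__all__ = ["RuleModel", "DirectMLP", "GEMMLP", "SGEMMLP", "RandomBasisSLP"]


class RuleModel:
    """Base class: parameter bookkeeping shared by all encodings."""

    def __init__(self, sizes):
        self.sizes = list(sizes)
        self.params: dict[str, Tensor] = {}
        self.frozen: dict[str, np.ndarray] = {}

    # subclasses implement weight regeneration
    def generate_weights(self, params: dict) -> list:
        raise NotImplementedError

    def forward(self, x, params: dict | None = None) -> Tensor:
        p = self.params if params is None else params
        h = as_tensor(np.asarray(x, dtype=np.float64))
        weights = self.generate_weights(p)
        for li, w in enumerate(weights):
            h = h @ w
            if li < len(weights) - 1:
                h = relu(h)
        return h

    def parameters(self) -> dict:
        return self.params

    def direct_parameter_count(self) -> int:
        return sum(a * b for a, b in zip(self.sizes[:-1], self.sizes[1:]))

    def budget(self) -> ParamBudget:
        raise NotImplementedError


class DirectMLP(RuleModel):
    """Unencoded baseline: the weights themselves are the parameters."""

    def __init__(self, sizes, seed: int = 0):
        super().__init__(sizes)
        rng = np.random.default_rng(seed)
        for li, (a, b) in enumerate(zip(sizes[:-1], sizes[1:])):
            bound = 1.0 / np.sqrt(a)
            self.params[f"w{li}"] = Tensor(
                rng.uniform(-bound, bound, (a, b)), requires_grad=True
            )

    def generate_weights(self, params):
        return [params[f"w{li}"] for li in range(len(self.sizes) - 1)]

    def budget(self) -> ParamBudget:
        shapes = list(zip(self.sizes[:-1], self.sizes[1:]))
        return count_parameters("direct", layer_shapes=shapes)


class GEMMLP(RuleModel):
    """GEM encoding: one identity matrix per population, one shared O.

    The output population's identity can be a frozen random matrix (the
    single-layer configuration: learning it adds parameters without accuracy)
    or learned like the rest.
    """

    def __init__(self, sizes, genes: int, seed: int = 0, learn_head: bool = False):
        super().__init__(sizes)
        self.genes = genes
        self.learn_head = learn_head
        rng = np.random.default_rng(seed)
        s = gem_init_std(sizes[0], genes)
        self.params["o"] = Tensor(rng.normal(0.0, s, (genes, genes)), requires_grad=True)
        last = len(sizes) - 1
        for li, n in enumerate(sizes):
            x = rng.normal(0.0, s, (n, genes))
            if li == last and not learn_head:
                self.frozen[f"x{li}"] = x
            else:
                self.params[f"x{li}"] = Tensor(x, requires_grad=True)

    def _identities(self, params):
        out = []
        for li in range(len(self.sizes)):
            key = f"x{li}"
            out.append(params[key] if key in params else Tensor(self.frozen[key]))
        return out

    def generate_weights(self, params):
        return mlp_weights_from_rules(self._identities(params), params["o"])

    def budget(self) -> ParamBudget:
        counts = {f"x{li}": n * self.genes for li, n in enumerate(self.sizes)}
        counts["o"] = self.genes * self.genes
        frozen = () if self.learn_head else (f"x{len(self.sizes) - 1}",)
        return ParamBudget(encoding="gem", counts=counts, frozen=frozen)


class SGEMMLP(RuleModel):
    """Spatial GEM: grid populations get Gaussian gene fields, the small
    output head a directly parameterized (or frozen random) identity."""

    def __init__(self, sizes, genes: int, seed: int = 0, learn_head: bool = True,
                 grid_shapes=None):
        super().__init__(sizes)
        self.genes = genes
        self.learn_head = learn_head
        rng = np.random.default_rng(seed)
        if grid_shapes is None:
            grid_shapes = []
            for n in sizes[:-1]:
                side = int(round(np.sqrt(n)))
                if side * side != n:
                    raise ValueError(
                        f"population of {n} neurons is not a square grid; "
                        "pass grid_shapes explicitly"
                    )
                grid_shapes.append((side, side))
        self.grids = [NeuronGrid(r, c) for r, c in grid_shapes]
        self.fields = [GeneField2D(genes, rng) for _ in self.grids]
        for li, fld in enumerate(self.fields):
            self.params.update(fld.parameters(f"field{li}"))

        s = 1.0 / np.sqrt(genes * sizes[-2])
        self.params["o"] = Tensor(rng.normal(0.0, s, (genes, genes)), requires_grad=True)
        head = rng.normal(0.0, s, (sizes[-1], genes))
        if learn_head:
            self.params["x_head"] = Tensor(head, requires_grad=True)
        else:
            self.frozen["x_head"] = head

    def generate_weights(self, params):
        identities = []
        for li, (grid, fld) in enumerate(zip(self.grids, self.fields)):
            # rebuild the field view from the (possibly adapted) raw params
            view = GeneField2D.__new__(GeneField2D)
            view.genes = self.genes
            view.raw_mu = params[f"field{li}.raw_mu"]
            view.raw_sigma = params[f"field{li}.raw_sigma"]
            identities.append(gaussian_expression(grid, view))
        head = params["x_head"] if "x_head" in params else Tensor(self.frozen["x_head"])
        identities.append(head)
        return mlp_weights_from_rules(identities, params["o"])

    def budget(self) -> ParamBudget:
        counts = {f"fields_{li}": 3 * self.genes for li in range(len(self.grids))}
        counts["o"] = self.genes * self.genes
        counts["x_head"] = self.sizes[-1] * self.genes
        frozen = () if self.learn_head else ("x_head",)
        return ParamBudget(encoding="sgem_ml", counts=counts, frozen=frozen)


class RandomBasisSLP(RuleModel):
    """Baseline W = R P: frozen random basis, learned coefficients."""

    def __init__(self, n_in: int, n_out: int, basis: int, seed: int = 0):
        super().__init__([n_in, n_out])
        self.basis_count = basis
        rng = np.random.default_rng(seed)
        self.frozen["basis"] = rng.normal(0.0, 1.0 / np.sqrt(n_in), (n_in, basis))
        bound = 1.0 / np.sqrt(basis)
        self.params["coefficients"] = Tensor(
            rng.uniform(-bound, bound, (basis, n_out)), requires_grad=True
        )

    def generate_weights(self, params):
        return [random_basis_weights(Tensor(self.frozen["basis"]), params["coefficients"])]

    def budget(self) -> ParamBudget:
        return count_parameters(
            "random_basis", n_in=self.sizes[0], n_out=self.sizes[1], basis=self.basis_count
        )
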