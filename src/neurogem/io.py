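"""Plain-text serialization for matrices, gene fields and training histories.

Matrices round-trip through whitespace-delimited text with a ``.meta``
sidecar of ``key=value`` lines recording shape and encoding tag; a ``.npy``
binary container is also accepted for large arrays. Training histories are
CSV with a ``key=value`` run summary.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

__all__ = [
    "save_matrix",
    "load_matrix",
    "write_sidecar",
    "read_sidecar",
    "save_gene_field",
    "load_gene_field",
    "save_history_csv",
    "save_summary",
]


def write_sidecar(path, entries: dict) -> None:
    lines = [f"{k}={v}" for k, v in entries.items()]
    Path(str(path) + ".meta").write_text("\n".join(lines) + "\n")


def read_sidecar(path) -> dict:
    out = {}
    for line in Path(str(path) + ".meta").read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def save_matrix(path, values: np.ndarray, encoding: str = "relaxed",
                binary_container: bool = False) -> None:
    values = np.asarray(values)
    path = Path(path)
    if binary_container:
        np.save(path.with_suffix(".npy"), values)
        target = path.with_suffix(".npy")
    else:
        np.savetxt(path, np.atleast_2d(values), fmt="%.17g")
        target = path
    write_sidecar(target, {
        "shape": "x".join(map(str, values.shape)),
        "encoding": encoding,
        "container": "npy" if binary_container else "text",
    })


def load_matrix(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    meta = read_sidecar(path)
    if meta.get("container") == "npy":
        values = np.load(path)
    else:
        values = np.loadtxt(path)
    shape = tuple(int(s) for s in meta["shape"].split("x") if s)
    return np.asarray(values).reshape(shape), meta


def save_gene_field(path, field, grid_shape=None) -> None:
    """Serialize a 2-D or 3-D gene field as key=value lines."""
    lines = []
    if hasattr(field, "raw_mu"):  # 2-D Gaussian field
        lines.append("kind=gaussian2d")
        lines.append("normalization=[-1,1]^2")
        if grid_shape is not None:
            lines.append(f"grid={grid_shape[0]}x{grid_shape[1]}")
        for i in range(field.genes):
            mx, my = field.raw_mu.data[i]
            lines.append(f"gene{i}.raw_mu={float(mx)!r},{float(my)!r}")
            lines.append(f"gene{i}.raw_sigma={float(field.raw_sigma.data[i])!r}")
    else:  # 3-D inverse-square field
        lines.append("kind=invsq3d")
        lines.append(f"floor={field.floor!r}")
        for i in range(field.genes):
            lines.append("gene%d.mu=%s" % (i, ",".join(repr(float(v)) for v in field.mu.data[i])))
            lines.append("gene%d.sigma=%s" % (i, ",".join(repr(float(v)) for v in field.sigma.data[i])))
    Path(path).write_text("\n".join(lines) + "\n")


def load_gene_field(path):
    from .autodiff import Tensor
    from .spatial import GeneField2D, GeneField3D

    entries = {}
    for line in Path(path).read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            entries[k] = v
    genes = sum(1 for k in entries if k.endswith(".raw_sigma") or k.endswith(".sigma"))
    if entries["kind"] == "gaussian2d":
        fld = GeneField2D(genes)
        mu = np.array([
            [float(x) for x in entries[f"gene{i}.raw_mu"].split(",")] for i in range(genes)
        ])
        sg = np.array([float(entries[f"gene{i}.raw_sigma"]) for i in range(genes)])
        fld.raw_mu = Tensor(mu, requires_grad=True)
        fld.raw_sigma = Tensor(sg, requires_grad=True)
        return fld
    mu = np.array([[float(x) for x in entries[f"gene{i}.mu"].split(",")] for i in range(genes)])
    sg = np.array([[float(x) for x in entries[f"gene{i}.sigma"].split(",")] for i in range(genes)])
    return GeneField3D(
        mu=Tensor(mu, requires_grad=True),
        sigma=Tensor(sg, requires_grad=True),
        floor=float(entries["floor"]),
    )


def save_history_csv(path, history) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["batch", "split", "loss", "accuracy"])
        for row in history.records:
            writer.writerow(row)


def save_summary(path, config, history) -> None:
    lines = [f"{k}={v}" for k, v in vars(config).items()] if not isinstance(config, dict) \
        else [f"{k}={v}" for k, v in config.items()]
    lines.append(f"best_accuracy={history.best_accuracy!r}")
    lines.append(f"stopped_early={history.stopped_early}")
    if history.budget is not None:
        lines.append(f"budget_total={history.budget.total}")
        lines.append(f"budget_learned={history.budget.learned_total}")
        for k, v in history.budget.counts.items():
            lines.append(f"budget.{k}={v}")
    Path(path).write_text("\n".join(lines) + "\n")
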