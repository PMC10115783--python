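"""Published benchmark accuracies for the optional external-data experiments.

These figures require downloading MNIST / CIFAR-10 / Omniglot and hours of
compute, so they are *not* part of the test suite; they document what the
presets in :mod:`neurogem.cli` are expected to reproduce when run against the
real datasets, each with a ±2-percentage-point band around the published
mean. Values are percentages.
"""

from __future__ import annotations

#: experiment name -> dict(expected=%, tolerance=percentage points, notes)
REFERENCE_ACCURACIES: dict[str, dict] = {
    "mnist-slp-direct": {"expected": 93.0, "tolerance": 2.0,
                         "notes": "784→10 linear classifier, trained weights"},
    "mnist-slp-gem-g1": {"expected": 25.0, "tolerance": 2.0,
                         "notes": "GEM encoding, 1 gene per neuron"},
    "mnist-slp-gem-g5": {"expected": 80.0, "tolerance": 2.0,
                         "notes": "GEM encoding, 5 genes; lower bound of the band"},
    "mnist-slp-gem-g9": {"expected": 93.0, "tolerance": 2.0,
                         "notes": "GEM matches the trained classifier at 9 genes"},
    "mnist-lenet5-direct": {"expected": 98.95, "tolerance": 2.0,
                            "notes": "shared-kernel LeNet-5, 61,706 parameters"},
    "mnist-lenet5-sgem-2x": {"expected": 96.7, "tolerance": 2.0,
                             "notes": "spatial encoding at 2× compression "
                                      "(150 conv genes, 30 dense genes)"},
    "cifar-lenet5-direct": {"expected": 50.6, "tolerance": 2.0,
                            "notes": "shared-kernel LeNet-5 on CIFAR-10"},
    "cifar-lenet5-sgem": {"expected": 52.5, "tolerance": 2.0,
                          "notes": "spatial encoding, 229 conv genes"},
    "omniglot-maml-direct": {"expected": 89.5, "tolerance": 2.0,
                             "notes": "784-784-784-5 MLP, 5-way 1-shot"},
    "omniglot-maml-gem-10x": {"expected": 90.5, "tolerance": 2.0,
                              "notes": "GEM, 50 genes per node (10× compression)"},
    "omniglot-maml-gem-25x": {"expected": 89.3, "tolerance": 2.0,
                              "notes": "GEM, 20 genes per node (25× compression)"},
    "omniglot-maml-sgem-500x": {"expected": 86.1, "tolerance": 2.0,
                                "notes": "spatial GEM, 43 genes per layer"},
    "omniglot-maml-sgem-1000x": {"expected": 83.2, "tolerance": 2.0,
                                 "notes": "spatial GEM, 28 genes per layer"},
}
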