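"""A small worked example: three undirected, unweighted layers on five nodes.

Useful for demonstrations and as a fast regression fixture.  The five
dependency scenarios exercise every structural case: independent layers,
an acyclic chain of full dependencies, a fractional self-dependency, a
negative dependency weight, and a dependency cycle.
"""

from __future__ import annotations

import warnings

import numpy as np

from .network import DependencyMatrix, MultilayerNetwork, validate_dependency_matrix

__all__ = ["three_layer_example", "dependency_scenarios"]

_A1 = [
    [0, 1, 1, 0, 0],
    [1, 0, 1, 1, 0],
    [1, 1, 0, 0, 0],
    [0, 1, 0, 0, 1],
    [0, 0, 0, 1, 0],
]
_A2 = [
    [0, 1, 1, 0, 0],
    [1, 0, 0, 0, 0],
    [1, 0, 0, 1, 1],
    [0, 0, 1, 0, 1],
    [0, 0, 1, 1, 0],
]
_A3 = [
    [0, 1, 1, 1, 0],
    [1, 0, 0, 1, 0],
    [1, 0, 0, 0, 1],
    [1, 1, 0, 0, 1],
    [0, 0, 1, 1, 0],
]


def three_layer_example() -> MultilayerNetwork:
    """The 3-layer, 5-node example network."""
    return MultilayerNetwork(
        [np.array(_A1, float), np.array(_A2, float), np.array(_A3, float)]
    )


def dependency_scenarios() -> dict[str, DependencyMatrix]:
    """The five dependency structures exercised on the example network.

    - ``independent``: identity (every layer case A);
    - ``chain``: layer 2 fully dependent on layer 1, layer 3 on layer 2;
    - ``mixed``: layer 3 half self-dependent, half dependent on layer 2;
    - ``negative``: layer 3 self-weight 1.2 with weight -0.2 on layer 2;
    - ``cycle``: every layer fully dependent on another, forming a cycle.
    """
    raw = {
        "independent": np.eye(3),
        "chain": [[1, 0, 0], [1, 0, 0], [0, 1, 0]],
        "mixed": [[1, 0, 0], [1, 0, 0], [0, 0.5, 0.5]],
        "negative": [[1, 0, 0], [1, 0, 0], [0, -0.2, 1.2]],
        "cycle": [[0, 0, 1], [1, 0, 0], [0, 1, 0]],
    }
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # the negative scenario warns by design
        for name, mat in raw.items():
            out[name] = validate_dependency_matrix(np.asarray(mat, float))
    return out
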