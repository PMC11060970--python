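"""Core data types for multilayer networks and inter-layer dependency structures.

A multilayer (multiplex) network is a collection of ``k`` edge-weighted,
possibly directed graphs ("layers") over the same ``p`` nodes, with no
inter-layer edges.  Inter-layer constraints on *adjacent node importance* are
encoded separately by a ``k x k`` dependency matrix whose rows sum to 1: entry
``(i, j)`` is the weight with which the importance of nodes adjacent in layer
``i`` is taken from the node-importance vector of layer ``j``.  Negative
weights are permitted (inverse dependencies) as long as each row still sums
to 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "MultilayerNetwork",
    "DependencyMatrix",
    "LayerCase",
    "LayerDiagnostics",
    "CycleReport",
    "validate_dependency_matrix",
    "classify_layer",
    "requires_iteration",
    "validate_network",
    "NegativeDependencyWarning",
]

#: Tolerance for the row-sum-equals-1 constraint on dependency matrices.
ROW_SUM_TOL = 1e-9


class NegativeDependencyWarning(UserWarning):
    """Raised when a dependency matrix contains negative weights.

    Negative inter-layer dependencies are supported but can produce negative
    centrality values and may slow convergence of the interleaved iteration.
    """


class LayerCase(Enum):
    """Dependency classification of a single layer.

    - ``A``: self-weight 1 -- the layer is an independent eigenvalue problem.
    - ``B``: self-weight 0 -- the layer's centrality is a pure linear
      function of other layers' centralities.
    - ``C``: fractional self-weight -- a mixed pseudo-eigenvalue problem
      requiring iterative solution.
    """

    A = "A"
    B = "B"
    C = "C"


@dataclass(frozen=True)
class MultilayerNetwork:
    """``k`` square layer adjacency matrices over ``p`` shared nodes.

    Entry ``layers[j][l, m]`` is the weight of the edge *from* node ``l``
    *to* node ``m`` in layer ``j``.  Node identity across layers is
    positional; labels are metadata.
    """

    layers: tuple[np.ndarray, ...]
    node_labels: tuple[str, ...] = ()
    layer_labels: tuple[str, ...] = ()

    def __init__(
        self,
        layers: Sequence[np.ndarray],
        node_labels: Sequence[str] | None = None,
        layer_labels: Sequence[str] | None = None,
    ):
        mats = tuple(np.asarray(a, dtype=float) for a in layers)
        if len(mats) == 0:
            raise ValueError("a multilayer network needs at least one layer")
        p = mats[0].shape[0] if mats[0].ndim == 2 else -1
        for j, a in enumerate(mats):
            if a.ndim != 2 or a.shape[0] != a.shape[1]:
                raise ValueError(f"layer {j + 1} adjacency matrix is not square: shape {a.shape}")
            if a.shape[0] != p:
                raise ValueError(
                    f"layer {j + 1} has {a.shape[0]} nodes but layer 1 has {p}; "
                    "all layers must share the same node set"
                )
            if not np.all(np.isfinite(a)):
                raise ValueError(f"layer {j + 1} contains non-finite edge weights")
        if node_labels is None:
            node_labels = tuple(f"n{i + 1}" for i in range(p))
        if layer_labels is None:
            layer_labels = tuple(f"layer{j + 1}" for j in range(len(mats)))
        node_labels = tuple(str(s) for s in node_labels)
        layer_labels = tuple(str(s) for s in layer_labels)
        if len(node_labels) != p:
            raise ValueError("node_labels length does not match layer dimension")
        if len(layer_labels) != len(mats):
            raise ValueError("layer_labels length does not match number of layers")
        if len(set(node_labels)) != p:
            raise ValueError("duplicate node labels")
        if len(set(layer_labels)) != len(mats):
            raise ValueError("duplicate layer labels")
        object.__setattr__(self, "layers", mats)
        object.__setattr__(self, "node_labels", node_labels)
        object.__setattr__(self, "layer_labels", layer_labels)

    @property
    def k(self) -> int:
        """Number of layers."""
        return len(self.layers)

    @property
    def p(self) -> int:
        """Number of nodes per layer."""
        return self.layers[0].shape[0]

    def transposed(self) -> "MultilayerNetwork":
        """Network with every layer transposed (for left centrality)."""
        return MultilayerNetwork(
            [a.T.copy() for a in self.layers], self.node_labels, self.layer_labels
        )


@dataclass(frozen=True)
class DependencyMatrix:
    """Validated ``k x k`` inter-layer dependency matrix.

    Entry ``(i, j)`` is the strength with which adjacent-node importance in
    layer ``i`` draws on node importance in layer ``j``.  Every row sums to 1
    (within :data:`ROW_SUM_TOL`); negative entries are allowed.

    Construct via :func:`validate_dependency_matrix`.
    """

    weights: np.ndarray
    has_negative: bool = field(default=False, compare=False)

    @property
    def k(self) -> int:
        return self.weights.shape[0]

    def is_identity(self, tol: float = ROW_SUM_TOL) -> bool:
        """True when all layers are independent (dependency matrix == I)."""
        return bool(np.allclose(self.weights, np.eye(self.k), atol=tol))


def validate_dependency_matrix(
    D: np.ndarray | Sequence[Sequence[float]], tol: float = ROW_SUM_TOL
) -> DependencyMatrix:
    """Validate a raw ``k x k`` matrix as an inter-layer dependency matrix.

    Parameters
    ----------
    D
        Square matrix of dependency weights.
    tol
        Allowed deviation of each row sum from 1.

    Returns
    -------
    DependencyMatrix
        The validated matrix.  A :class:`NegativeDependencyWarning` is
        emitted (and ``has_negative`` set) when any entry is negative.

    Raises
    ------
    ValueError
        If ``D`` is not square, contains non-finite entries, or any row sum
        differs from 1 by more than ``tol``.
    """
    W = np.asarray(D, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"dependency matrix must be square, got shape {W.shape}")
    if not np.all(np.isfinite(W)):
        raise ValueError("dependency matrix contains non-finite entries")
    row_sums = W.sum(axis=1)
    bad = np.nonzero(np.abs(row_sums - 1.0) > tol)[0]
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"dependency matrix row {i + 1} sums to {row_sums[i]:.12g}, expected 1"
        )
    has_negative = bool(np.any(W < 0))
    if has_negative:
        warnings.warn(
            "dependency matrix contains negative weights; centrality values may be "
            "negative and convergence may be slow",
            NegativeDependencyWarning,
            stacklevel=2,
        )
    return DependencyMatrix(weights=W.copy(), has_negative=has_negative)


def classify_layer(D: DependencyMatrix, i: int) -> LayerCase:
    """Classify layer ``i`` (1-based) of a dependency matrix as case A, B or C."""
    if not 1 <= i <= D.k:
        raise IndexError(f"layer index {i} out of range 1..{D.k}")
    d = D.weights[i - 1, i - 1]
    if d == 1.0:
        return LayerCase.A
    if d == 0.0:
        return LayerCase.B
    return LayerCase.C


@dataclass(frozen=True)
class CycleReport:
    """Result of the does-the-system-need-iteration test."""

    required: bool
    case_c_layers: tuple[int, ...]  # 1-based indices of case-C layers
    cycle: tuple[int, ...]  # one witnessing directed cycle (1-based), or ()

    def __bool__(self) -> bool:
        return self.required


def requires_iteration(D: DependencyMatrix) -> CycleReport:
    """Decide whether the coupled system needs the interleaved iteration.

    Iteration is required iff some layer has a fractional self-weight
    (case C) or the directed graph on layers whose edges are the nonzero
    off-diagonal dependencies contains a directed cycle.  Self-dependencies
    are excluded from the cycle test: a case-C self-weight triggers
    iteration on its own.
    """
    import networkx as nx

    k = D.k
    case_c = tuple(i for i in range(1, k + 1) if classify_layer(D, i) is LayerCase.C)
    g = nx.DiGraph()
    g.add_nodes_from(range(1, k + 1))
    for i in range(k):
        for j in range(k):
            if i != j and D.weights[i, j] != 0.0:
                g.add_edge(i + 1, j + 1)
    cycle: tuple[int, ...] = ()
    try:
        edges = nx.find_cycle(g, orientation="original")
        cycle = tuple(e[0] for e in edges)
    except nx.NetworkXNoCycle:
        pass
    return CycleReport(required=bool(case_c) or bool(cycle), case_c_layers=case_c, cycle=cycle)


@dataclass(frozen=True)
class LayerDiagnostics:
    """Structural diagnostics for one layer (flags, never rejections)."""

    dimension: int
    symmetric: bool
    nonnegative: bool
    strongly_connected: bool


def validate_network(net: MultilayerNetwork) -> list[LayerDiagnostics]:
    """Report per-layer structural diagnostics.

    Disconnected or negatively weighted layers are flagged, not rejected;
    strong connectivity matters because the Perron-Frobenius guarantee of a
    unique positive principal eigenvector only holds for irreducible
    nonnegative matrices.
    """
    import networkx as nx

    out = []
    for a in net.layers:
        g = nx.from_numpy_array(a != 0, create_using=nx.DiGraph)
        out.append(
            LayerDiagnostics(
                dimension=a.shape[0],
                symmetric=bool(np.array_equal(a, a.T)),
                nonnegative=bool(np.all(a >= 0)),
                strongly_connected=bool(nx.is_strongly_connected(g)) if a.shape[0] > 0 else True,
            )
        )
    return out
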