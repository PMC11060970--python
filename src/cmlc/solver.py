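"""Solvers for the coupled layer-centrality system.

Layer-specific centrality vectors ``x_1 .. x_k`` are defined jointly by

    A_j c(j) = lambda_j x_j,        c(j) = sum_i  d[j, i] * x_i,

one equation per layer, where ``A_j`` is the layer-``j`` adjacency matrix and
``d`` the inter-layer dependency matrix.  When ``d`` is the identity this is
``k`` independent eigenvalue problems (plain per-layer eigenvector
centrality); otherwise each equation is a pseudo-eigenvalue problem because
the vector multiplied by ``A_j`` differs from the one on the right-hand side.

Three solution paths are provided and dispatched automatically by
:func:`solve`:

- ``independent``: per-layer power iteration (dependency == identity);
- ``direct-acyclic``: two-step direct solution when every layer has
  self-weight 0 or 1 and the inter-layer dependency digraph is acyclic;
- ``interleaved``: simultaneous power-iteration sweeps over all layers,
  recomputing every layer's adjacent-importance mixture each sweep, until
  the per-layer relative change in the (pseudo-)eigenvalue estimates falls
  below tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .network import (
    DependencyMatrix,
    LayerCase,
    MultilayerNetwork,
    NegativeDependencyWarning,
    classify_layer,
    requires_iteration,
)

__all__ = [
    "SolverOptions",
    "CentralityState",
    "SolveResult",
    "ConvergenceWarning",
    "adjacent_importance",
    "power_iteration_single",
    "interleaved_power_iteration",
    "solve_acyclic_direct",
    "solve",
    "residuals",
]

#: Below this, a (pseudo-)eigenvalue estimate is treated as numerically zero.
_LAMBDA_FLOOR = 1e-12


class ConvergenceWarning(UserWarning):
    """Iteration hit the sweep limit before meeting the tolerance."""


@dataclass(frozen=True)
class SolverOptions:
    """Options shared by all solver paths.

    Parameters
    ----------
    tol
        Convergence threshold on the relative sequential change of the
        (pseudo-)eigenvalue estimates.
    max_iter
        Sweep limit.
    per_layer_convergence
        If True, require every layer's relative delta to fall below ``tol``;
        otherwise (default) the mean delta across layers is used.
    init_mode
        ``"uniform"`` starts every vector at ``1/sqrt(p)`` per entry
        (deterministic); ``"seeded-random"`` draws a random start from
        ``seed``.
    transpose
        Solve on transposed layers, giving left instead of right centrality.
    update_schedule
        ``"simultaneous"`` computes every layer's mixture from the previous
        sweep's vectors (layer-order invariant, default); ``"in-sweep"``
        uses already-updated vectors within the sweep (Gauss-Seidel style).
    """

    tol: float = 1e-6
    max_iter: int = 10_000
    per_layer_convergence: bool = False
    init_mode: Literal["uniform", "seeded-random"] = "uniform"
    seed: int | None = None
    transpose: bool = False
    update_schedule: Literal["simultaneous", "in-sweep"] = "simultaneous"

    def __post_init__(self):
        if not self.tol > 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
        if self.init_mode == "seeded-random" and self.seed is None:
            raise ValueError("seeded-random initialization requires a seed")
        if self.init_mode not in ("uniform", "seeded-random"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")
        if self.update_schedule not in ("simultaneous", "in-sweep"):
            raise ValueError(f"unknown update_schedule {self.update_schedule!r}")


@dataclass
class CentralityState:
    """Per-sweep state of the interleaved iteration."""

    X: list[np.ndarray]  # unit-length centrality vector per layer
    lambdas: np.ndarray  # current (pseudo-)eigenvalue estimate per layer
    deltas: np.ndarray  # relative sequential eigenvalue change per layer
    iteration: int


@dataclass(frozen=True)
class SolveResult:
    """Converged (or best-effort) solution of the coupled system."""

    X: tuple[np.ndarray, ...]
    lambdas: np.ndarray
    iterations: int
    converged: bool
    method: str
    residuals: np.ndarray
    node_labels: tuple[str, ...] = ()
    layer_labels: tuple[str, ...] = ()

    def stacked(self) -> np.ndarray:
        """All per-layer vectors concatenated into one length-``k*p`` vector."""
        return np.concatenate(self.X)


def _init_vectors(k: int, p: int, opts: SolverOptions) -> list[np.ndarray]:
    if opts.init_mode == "uniform":
        return [np.full(p, 1.0 / np.sqrt(p)) for _ in range(k)]
    rng = np.random.default_rng(opts.seed)
    out = []
    for _ in range(k):
        v = rng.random(p) + 0.1  # keep away from the zero vector
        out.append(v / np.linalg.norm(v))
    return out


def _sign_fix(x: np.ndarray) -> np.ndarray:
    """Flip the vector so the sum of its entries is nonnegative."""
    return -x if x.sum() < 0 else x


def adjacent_importance(i: int, D: DependencyMatrix, X: Sequence[np.ndarray]) -> np.ndarray:
    """Adjacent-node importance mixture for layer ``i`` (1-based).

    Returns the weighted sum of the per-layer centrality vectors with the
    weights of dependency-matrix row ``i``; no normalization is applied.
    """
    if len(X) != D.k:
        raise ValueError(f"expected {D.k} vectors, got {len(X)}")
    p = len(X[0])
    if any(len(x) != p for x in X):
        raise ValueError("centrality vectors have inconsistent lengths")
    row = D.weights[i - 1]
    c = np.zeros(p)
    for w, x in zip(row, X):
        if w != 0.0:
            c = c + w * np.asarray(x, dtype=float)
    return c


def power_iteration_single(
    A: np.ndarray, opts: SolverOptions = SolverOptions()
) -> tuple[np.ndarray, float, int]:
    """Principal eigenvector of a single square matrix by power iteration.

    Returns ``(x, lam, iterations)`` where ``x`` has unit Euclidean length
    and its entry sum is nonnegative.  Stops when the relative change in the
    eigenvalue estimate drops below ``opts.tol`` or at ``opts.max_iter``.

    Raises
    ------
    ValueError
        If the iterate collapses to the zero vector (e.g. the zero matrix,
        or a start vector in the nullspace).
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("matrix must be square")
    p = A.shape[0]
    x = _init_vectors(1, p, opts)[0]
    lam_prev = np.nan
    it = 0
    for it in range(1, opts.max_iter + 1):
        y = A @ x
        lam = float(np.linalg.norm(y))
        if lam < _LAMBDA_FLOOR:
            raise ValueError("power iteration collapsed to the zero vector (degenerate matrix)")
        x = _sign_fix(y / lam)
        if np.isfinite(lam_prev):
            delta = abs(lam_prev - lam) / lam
            if delta <= opts.tol:
                lam_prev = lam
                break
        lam_prev = lam
    return x, float(lam_prev), it


def interleaved_power_iteration(
    net: MultilayerNetwork, D: DependencyMatrix, opts: SolverOptions = SolverOptions()
) -> SolveResult:
    """Solve the coupled system by interleaved power iteration.

    Each sweep updates every layer: ``y_j = A_j c(j)`` with the mixture
    ``c(j)`` built from the current vectors, ``lambda_j = ||y_j||`` and
    ``x_j = y_j / lambda_j`` (sign-fixed so entries sum nonnegative).
    Convergence is declared when the mean -- or, with
    ``per_layer_convergence``, every -- relative sequential eigenvalue
    change falls below ``opts.tol``.
    """
    if D.k != net.k:
        raise ValueError(f"dependency matrix is {D.k}x{D.k} but network has {net.k} layers")
    if D.has_negative:
        warnings.warn(
            "negative dependency weights: centrality entries may be negative and "
            "convergence may be slow",
            NegativeDependencyWarning,
            stacklevel=2,
        )
    layers = [a.T for a in net.layers] if opts.transpose else list(net.layers)
    k, p = net.k, net.p
    state = CentralityState(
        X=_init_vectors(k, p, opts),
        lambdas=np.full(k, np.nan),
        deltas=np.full(k, np.inf),
        iteration=0,
    )
    converged = False
    for sweep in range(1, opts.max_iter + 1):
        lam_prev = state.lambdas.copy()
        source = [x.copy() for x in state.X] if opts.update_schedule == "simultaneous" else state.X
        for j in range(k):
            c = adjacent_importance(j + 1, D, source)
            y = layers[j] @ c
            lam = float(np.linalg.norm(y))
            if lam < _LAMBDA_FLOOR:
                raise ValueError(
                    f"layer {j + 1} update collapsed to the zero vector (degenerate layer)"
                )
            state.X[j] = _sign_fix(y / lam)
            state.lambdas[j] = lam
        with np.errstate(invalid="ignore"):
            deltas = np.abs(lam_prev - state.lambdas) / state.lambdas
        deltas = np.where(np.isfinite(deltas), deltas, np.inf)
        # guard: a vanishing pseudo-eigenvalue makes the relative delta meaningless
        deltas = np.where(state.lambdas < _LAMBDA_FLOOR, np.inf, deltas)
        state.deltas = deltas
        state.iteration = sweep
        if opts.per_layer_convergence:
            converged = bool(np.all(deltas <= opts.tol))
        else:
            converged = bool(np.mean(deltas) <= opts.tol)
        if converged:
            break
    if not converged:
        warnings.warn(
            f"interleaved iteration did not converge in {opts.max_iter} sweeps "
            f"(deltas: {state.deltas})",
            ConvergenceWarning,
            stacklevel=2,
        )
    result = SolveResult(
        X=tuple(state.X),
        lambdas=state.lambdas.copy(),
        iterations=state.iteration,
        converged=converged,
        method="interleaved",
        residuals=np.zeros(k),
        node_labels=net.node_labels,
        layer_labels=net.layer_labels,
    )
    return replace(result, residuals=residuals(net, D, result, transpose=opts.transpose))


def solve_acyclic_direct(
    net: MultilayerNetwork, D: DependencyMatrix, opts: SolverOptions = SolverOptions()
) -> SolveResult:
    """Two-step direct solution for acyclic case-A/B dependency structures.

    Independent (case-A) layers are solved by single-matrix power
    iteration.  Case-B layers are then solved in dependency order as
    ``x_j = A_j c(j) / lambda_j`` with ``lambda_j`` the norm of the
    unnormalized product, so each ``x_j`` has unit length.

    Raises
    ------
    ValueError
        If the dependency structure actually requires iteration (a case-C
        layer or a dependency cycle).
    """
    import networkx as nx

    report = requires_iteration(D)
    if report.required:
        raise ValueError(
            "dependency structure requires the interleaved iteration "
            f"(case-C layers: {report.case_c_layers}, cycle: {report.cycle})"
        )
    if D.k != net.k:
        raise ValueError(f"dependency matrix is {D.k}x{D.k} but network has {net.k} layers")
    layers = [a.T for a in net.layers] if opts.transpose else list(net.layers)
    k, p = net.k, net.p
    X: list[np.ndarray | None] = [None] * k
    lambdas = np.zeros(k)
    total_iter = 0
    for j in range(k):
        if classify_layer(D, j + 1) is LayerCase.A:
            x, lam, it = power_iteration_single(layers[j], opts)
            X[j], lambdas[j] = x, lam
            total_iter = max(total_iter, it)
    # order case-B layers so every dependency is solved before its dependents:
    # edge i -> j means "layer i draws importance from layer j"
    g = nx.DiGraph()
    g.add_nodes_from(range(k))
    for i in range(k):
        for j in range(k):
            if i != j and D.weights[i, j] != 0.0:
                g.add_edge(i, j)
    for j in reversed(list(nx.topological_sort(g))):
        if X[j] is not None:
            continue
        c = adjacent_importance(j + 1, D, [x if x is not None else np.zeros(p) for x in X])
        y = layers[j] @ c
        lam = float(np.linalg.norm(y))
        if lam < _LAMBDA_FLOOR:
            raise ValueError(f"layer {j + 1} direct solution collapsed to the zero vector")
        X[j] = _sign_fix(y / lam)
        lambdas[j] = lam
    result = SolveResult(
        X=tuple(X),  # type: ignore[arg-type]
        lambdas=lambdas,
        iterations=total_iter,
        converged=True,
        method="direct-acyclic",
        residuals=np.zeros(k),
        node_labels=net.node_labels,
        layer_labels=net.layer_labels,
    )
    return replace(result, residuals=residuals(net, D, result, transpose=opts.transpose))


def solve(
    net: MultilayerNetwork, D: DependencyMatrix, opts: SolverOptions = SolverOptions()
) -> SolveResult:
    """Dispatch to the cheapest applicable solver.

    Identity dependency -> independent per-layer power iteration; acyclic
    case-A/B structure -> two-step direct solution; anything else ->
    interleaved power iteration.  With ``opts.transpose`` the whole
    procedure runs on transposed layers (left centrality).
    """
    if D.k != net.k:
        raise ValueError(f"dependency matrix is {D.k}x{D.k} but network has {net.k} layers")
    if D.is_identity():
        layers = [a.T for a in net.layers] if opts.transpose else list(net.layers)
        xs, lams, its = [], [], 0
        for a in layers:
            x, lam, it = power_iteration_single(a, opts)
            xs.append(x)
            lams.append(lam)
            its = max(its, it)
        result = SolveResult(
            X=tuple(xs),
            lambdas=np.array(lams),
            iterations=its,
            converged=True,
            method="independent",
            residuals=np.zeros(net.k),
            node_labels=net.node_labels,
            layer_labels=net.layer_labels,
        )
        return replace(result, residuals=residuals(net, D, result, transpose=opts.transpose))
    if not requires_iteration(D):
        return solve_acyclic_direct(net, D, opts)
    return interleaved_power_iteration(net, D, opts)


def residuals(
    net: MultilayerNetwork,
    D: DependencyMatrix,
    result: SolveResult,
    transpose: bool = False,
) -> np.ndarray:
    """Per-layer residual norms ``||A_j c(j) - lambda_j x_j||`` of a solution."""
    layers = [a.T for a in net.layers] if transpose else list(net.layers)
    out = np.zeros(net.k)
    for j in range(net.k):
        c = adjacent_importance(j + 1, D, list(result.X))
        out[j] = np.linalg.norm(layers[j] @ c - result.lambdas[j] * result.X[j])
    return out
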