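"""Gene–gene interaction networks and random walks with restart (RWR).

The network is an undirected, weighted graph over gene identifiers. All
diffusion operations run on its column-stochastic transition matrix B,
obtained by normalizing each column of the symmetric adjacency matrix A to
sum to one. Isolated (zero-degree) nodes get a uniform teleport column so
that B stays stochastic.

The RWR equilibrium solves v = (1 - p) B v + p w, where w is the restart
distribution and p in (0, 1] the restart probability. Both a power
iteration and a direct LU solve of (I - (1 - p) B) v = p w are provided;
the LU factorization is reused across restart vectors, which makes the
per-gene smoothing matrix (one RWR per expressed gene) a single
factorization plus triangular solves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla


class ConvergenceError(RuntimeError):
    """Power iteration failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate: np.ndarray, residual: float):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.residual = residual


@dataclass
class GeneNetwork:
    """Weighted undirected gene network.

    Parameters
    ----------
    node_ids
        Ordered, unique gene identifiers; position defines the matrix index.
    adjacency
        Dense symmetric adjacency matrix with zero diagonal and
        non-negative weights.
    """

    node_ids: list[str]
    adjacency: np.ndarray

    def __post_init__(self):
        n = len(self.node_ids)
        if n < 1:
            raise ValueError("no nodes")
        if len(set(self.node_ids)) != n:
            raise ValueError("duplicate node identifiers")
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency shape does not match node count")
        if not np.allclose(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("self-loops are not allowed in the adjacency")
        if np.any(self.adjacency < 0):
            raise ValueError("edge weights must be positive")

    @classmethod
    def from_edges(
        cls,
        edges,
        weight_threshold: float | None = None,
    ) -> "GeneNetwork":
        """Build a network from (gene_a, gene_b, weight) triples.

        Self-loops are dropped with a warning. Duplicate pairs keep the
        maximum weight (warned). Node order is lexicographic, which makes
        every downstream result reproducible from the edge list alone.
        """
        best: dict[tuple[str, str], float] = {}
        n_self = 0
        n_dup = 0
        nodes: set[str] = set()
        for ga, gb, w in edges:
            ga, gb = str(ga), str(gb)
            w = float(w)
            if w <= 0:
                raise ValueError(f"non-positive edge weight {w} on {ga}--{gb}")
            if weight_threshold is not None and w < weight_threshold:
                continue
            if ga == gb:
                n_self += 1
                continue
            nodes.update((ga, gb))
            key = (ga, gb) if ga < gb else (gb, ga)
            if key in best:
                n_dup += 1
                best[key] = max(best[key], w)
            else:
                best[key] = w
        if n_self:
            warnings.warn(f"dropped {n_self} self-loop(s)")
        if n_dup:
            warnings.warn(f"merged {n_dup} duplicate edge(s), keeping max weight")
        if not nodes:
            raise ValueError("no nodes")
        node_ids = sorted(nodes)
        index = {g: i for i, g in enumerate(node_ids)}
        A = np.zeros((len(node_ids), len(node_ids)))
        for (ga, gb), w in best.items():
            A[index[ga], index[gb]] = w
            A[index[gb], index[ga]] = w
        return cls(node_ids=node_ids, adjacency=A)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def weighted_degree(self) -> np.ndarray:
        """Sum of incident edge weights per node."""
        return self.adjacency.sum(axis=0)

    def index_of(self, genes) -> np.ndarray:
        index = {g: i for i, g in enumerate(self.node_ids)}
        try:
            return np.array([index[g] for g in genes], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"gene {exc.args[0]!r} not in network") from exc


@dataclass
class TransitionMatrix:
    """Column-stochastic transition matrix B derived from a network."""

    B: np.ndarray
    node_ids: list[str]
    _lu_cache: dict = field(default_factory=dict, repr=False)
    _global_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def lu(self, p: float):
        """LU factorization of (I - (1 - p) B), cached per p."""
        if p not in self._lu_cache:
            n = self.n_nodes
            self._lu_cache[p] = sla.lu_factor(np.eye(n) - (1.0 - p) * self.B)
        return self._lu_cache[p]


@dataclass
class EquilibriumVector:
    """RWR equilibrium distribution over network nodes."""

    v: np.ndarray
    iterations_used: int
    converged: bool


@dataclass
class SmoothingMatrix:
    """Per-gene RWR profiles restricted to the expressed gene set.

    Column i is the equilibrium distribution of a walk restarting at gene
    i, restricted to the genes shared between network and expression data
    and renormalized to sum to one.
    """

    V: np.ndarray
    shared_genes: list[str]

    @property
    def n_shared(self) -> int:
        return len(self.shared_genes)


def build_transition(network: GeneNetwork) -> TransitionMatrix:
    """Normalize each adjacency column to sum to one.

    Zero-degree nodes receive a uniform column (teleport), keeping B
    stochastic.
    """
    if network.n_nodes == 0:
        raise ValueError("no nodes")
    A = network.adjacency
    colsum = A.sum(axis=0)
    B = np.zeros_like(A)
    nz = colsum > 0
    B[:, nz] = A[:, nz] / colsum[nz]
    if np.any(~nz):
        B[:, ~nz] = 1.0 / network.n_nodes
    return TransitionMatrix(B=B, node_ids=list(network.node_ids))


def _check_restart(w: np.ndarray, n: int) -> np.ndarray:
    w = np.asarray(w, dtype=float).ravel()
    if w.shape[0] != n:
        raise ValueError("restart vector length does not match network")
    if np.any(w < 0):
        raise ValueError("restart vector must be non-negative")
    s = w.sum()
    if not np.isclose(s, 1.0, atol=1e-12):
        raise ValueError("restart vector must sum to 1")
    return w


def rwr(
    B: TransitionMatrix,
    w: np.ndarray,
    p: float = 0.5,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> EquilibriumVector:
    """Power-iterate v <- (1 - p) B v + p w to the fixed point.

    Convergence is declared when the L1 norm of successive iterates drops
    below ``tol``. Raises :class:`ConvergenceError` after ``max_iter``.
    """
    if not (0 < p <= 1):
        raise ValueError("restart probability p must be in (0, 1]")
    w = _check_restart(w, B.n_nodes)
    v = w.copy()
    for it in range(1, max_iter + 1):
        v_next = (1.0 - p) * (B.B @ v) + p * w
        resid = np.abs(v_next - v).sum()
        v = v_next
        if resid < tol:
            return EquilibriumVector(v=v, iterations_used=it, converged=True)
    raise ConvergenceError(
        f"RWR did not converge in {max_iter} iterations (L1 residual {resid:.3e})",
        last_iterate=v,
        residual=resid,
    )


def rwr_direct(B: TransitionMatrix, w: np.ndarray, p: float = 0.5) -> EquilibriumVector:
    """Solve (I - (1 - p) B) v = p w directly via the cached LU factors."""
    if not (0 < p <= 1):
        raise ValueError("restart probability p must be in (0, 1]")
    w = _check_restart(w, B.n_nodes)
    v = sla.lu_solve(B.lu(p), p * w)
    return EquilibriumVector(v=v, iterations_used=0, converged=True)


def smoothing_matrix(
    network: GeneNetwork,
    expressed_genes,
    p: float = 0.5,
    B: TransitionMatrix | None = None,
) -> SmoothingMatrix:
    """Per-gene RWR profiles over the genes shared with the expression data.

    One LU factorization of (I - (1 - p) B) is reused for all restart
    columns; solving against the identity yields every per-gene
    equilibrium at once. Rows outside the shared set are removed and each
    column renormalized to sum to one.
    """
    expressed = set(expressed_genes)
    shared = [g for g in network.node_ids if g in expressed]
    if not shared:
        raise ValueError("no overlap between expression and network")
    if B is None:
        B = build_transition(network)
    n = network.n_nodes
    # columns of p * inv(I - (1-p)B) are the per-node equilibria v_i
    full = sla.lu_solve(B.lu(p), p * np.eye(n))
    idx = network.index_of(shared)
    V = full[np.ix_(idx, idx)]
    V = V / V.sum(axis=0, keepdims=True)
    return SmoothingMatrix(V=V, shared_genes=shared)


def global_equilibrium(B: TransitionMatrix, p: float = 0.5) -> EquilibriumVector:
    """RWR equilibrium with uniform restart over all nodes (cached per p)."""
    if p not in B._global_cache:
        w = np.full(B.n_nodes, 1.0 / B.n_nodes)
        B._global_cache[p] = rwr_direct(B, w, p)
    return B._global_cache[p]
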