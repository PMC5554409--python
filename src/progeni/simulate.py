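"""Synthetic networks, expression matrices and drug-response vectors.

The generator plants the statistical structure the prioritization method
assumes: network neighbors are co-expressed (each gene loads on the latent
factor of its network region) and the response is linear in a small set of
latent drivers. Three scenarios:

- ``direct_drivers``: the response is a linear combination of the driver
  genes' expression; drivers share one signal factor.
- ``hidden_driver``: a designated gene g* carries no response signal
  (low marginal correlation with the response) while its direct network
  neighbors load strongly, and the rest of its co-expression region
  weakly, on the factor that drives the response. g* remains co-expressed
  with its region through the shared background factor, so only a
  network-aware ranking can recover it.
- ``null``: the response is independent of the expression matrix.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .network import GeneNetwork
from .prioritize import ResponseVector

SCENARIOS = ("direct_drivers", "hidden_driver", "null")

#: loading of a hidden driver's direct neighbor on the response factor
NEIGHBOR_LOADING = 0.8
#: loading of the rest of the hidden driver's region on the response factor
REGION_LOADING = 0.3
#: loading of every gene on its region's latent (co-expression) factor
BACKGROUND_LOADING = 0.5


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset."""

    scenario: str
    driver_genes: list[str] = field(default_factory=list)
    hidden_driver: str | None = None
    effect_size: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "driver_genes": list(self.driver_genes),
            "hidden_driver": self.hidden_driver,
            "effect_size": self.effect_size,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }


def _gene_labels(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"G{str(i).zfill(width)}" for i in range(n)]


def generate_network(
    n_genes: int = 500,
    model: str = "scale_free",
    seed: int = 0,
    **params,
) -> GeneNetwork:
    """Random connected gene network with weights in (0, 1].

    Models: ``scale_free`` (Barabási–Albert, param ``m_attach``, default 3),
    ``small_world`` (connected Watts–Strogatz, params ``k`` default 6 and
    ``rewire_p`` default 0.1), ``block`` (planted partition, params
    ``n_blocks`` 5, ``p_in`` 0.2, ``p_out`` 0.01).
    """
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    rng = np.random.default_rng(seed)
    nx_seed = int(rng.integers(2**31 - 1))
    if model == "scale_free":
        m_attach = int(params.pop("m_attach", 3))
        g = nx.barabasi_albert_graph(n_genes, m_attach, seed=nx_seed)
    elif model == "small_world":
        k = int(params.pop("k", 6))
        rewire_p = float(params.pop("rewire_p", 0.1))
        g = nx.connected_watts_strogatz_graph(n_genes, k, rewire_p, seed=nx_seed)
    elif model == "block":
        n_blocks = int(params.pop("n_blocks", 5))
        p_in = float(params.pop("p_in", 0.2))
        p_out = float(params.pop("p_out", 0.01))
        g = nx.planted_partition_graph(
            n_blocks, n_genes // n_blocks, p_in, p_out, seed=nx_seed
        )
    else:
        raise ValueError(f"unknown network model {model!r}")
    if params:
        raise ValueError(f"unknown parameters for model {model!r}: {sorted(params)}")
    # stitch any disconnected components together deterministically
    comps = [sorted(c) for c in nx.connected_components(g)]
    for a, b in zip(comps, comps[1:]):
        g.add_edge(a[0], b[0])
    labels = _gene_labels(g.number_of_nodes())
    edges = []
    for u, v in sorted(g.edges()):
        w = 1.0 - rng.random()  # uniform on (0, 1]
        edges.append((labels[u], labels[v], w))
    return GeneNetwork.from_edges(edges)


def _assign_regions(network: GeneNetwork, anchors: list[int]) -> np.ndarray:
    """Partition nodes into connected regions grown from the anchors.

    Regions expand breadth-first in round-robin order (one node per region
    per turn), which keeps their sizes roughly balanced — emulating
    pathway-sized co-expression modules rather than one giant neighborhood
    per high-degree anchor.
    """
    n = network.n_nodes
    region = np.full(n, -1, dtype=int)
    queues = []
    for k, a in enumerate(anchors):
        region[a] = k
        queues.append(deque([a]))
    neighbors = [np.flatnonzero(network.adjacency[i]) for i in range(n)]
    active = True
    while active:
        active = False
        for k, q in enumerate(queues):
            while q:
                u = q.popleft()
                free = [v for v in neighbors[u] if region[v] < 0]
                if not free:
                    continue
                v = free[0]
                region[v] = k
                q.append(v)
                if len(free) > 1:
                    q.appendleft(u)  # u still has unclaimed neighbors
                active = True
                break
    region[region < 0] = 0  # unreachable nodes (none if connected)
    return region


def _pick_hidden_driver(network: GeneNetwork, n_drivers: int) -> int:
    """Node whose degree is closest to n_drivers; ties by gene ID."""
    degree = (network.adjacency > 0).sum(axis=0)
    eligible = np.flatnonzero(degree >= 2)
    if eligible.size == 0:
        raise ValueError("network has no node with degree >= 2")
    gap = np.abs(degree[eligible] - n_drivers)
    best = eligible[gap == gap.min()]
    return int(best.min())  # node order is lexicographic by construction


def generate_dataset(
    network: GeneNetwork,
    n_samples: int = 120,
    scenario: str = "hidden_driver",
    effect_size: float = 1.0,
    noise_sd: float = 1.0,
    n_drivers: int = 5,
    seed: int = 0,
    n_regions: int | None = None,
) -> tuple[ExpressionMatrix, ResponseVector, SimulationTruth]:
    """Simulate expression and response with planted drivers.

    Expression: each node belongs to a network region (nearest of
    ``n_regions`` BFS anchors, default n_genes // 25) and loads on that
    region's latent factor with loading 0.5 plus idiosyncratic noise, so
    network neighbors are co-expressed. Signal genes override this:

    - direct drivers express ``F_s + noise_sd * eps`` (one shared signal
      factor), and the response is ``effect_size * sum(driver expr) +
      noise_sd * eps``;
    - in the hidden-driver scenario g*'s direct neighbors load 0.8 and the
      rest of g*'s region loads 0.3 on F_s (on top of their region
      factor); g* keeps its plain background expression, and the response
      is ``effect_size * F_s + noise_sd * eps``;
    - in the null scenario the response is standard normal, independent
      of expression.

    Everything is reproducible bit-for-bit from ``seed``.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    if n_drivers > network.n_nodes:
        raise ValueError("n_drivers exceeds number of genes")
    rng = np.random.default_rng(seed)
    n = network.n_nodes
    genes = list(network.node_ids)
    if n_regions is None:
        n_regions = max(1, n // 25)
    anchors = sorted(rng.choice(n, size=min(n_regions, n), replace=False))
    region = _assign_regions(network, list(anchors))
    factors = rng.standard_normal((n_samples, max(region) + 1))
    eps = rng.standard_normal((n_samples, n))
    rho = BACKGROUND_LOADING
    expr = rho * factors[:, region] + np.sqrt(1 - rho**2) * eps

    F_s = rng.standard_normal(n_samples)
    truth = SimulationTruth(
        scenario=scenario, effect_size=effect_size, noise_sd=noise_sd, seed=seed
    )

    if scenario == "direct_drivers":
        drivers = sorted(rng.choice(n, size=n_drivers, replace=False))
        expr[:, drivers] = (
            F_s[:, None] + noise_sd * rng.standard_normal((n_samples, n_drivers))
        )
        d = effect_size * expr[:, drivers].sum(axis=1) + noise_sd * rng.standard_normal(
            n_samples
        )
        truth.driver_genes = [genes[i] for i in drivers]
    elif scenario == "hidden_driver":
        g_star = _pick_hidden_driver(network, n_drivers)
        neigh = np.flatnonzero(network.adjacency[g_star] > 0)
        # response loading on top of the region co-expression: strong on
        # g*'s direct neighbors, weak on the rest of its region; g* itself
        # keeps plain background expression and stays co-expressed with
        # its region without carrying any response signal
        signal = np.union1d(np.flatnonzero(region == region[g_star]), neigh)
        signal = np.setdiff1d(signal, [g_star])
        lam = np.where(np.isin(signal, neigh), NEIGHBOR_LOADING, REGION_LOADING)
        idio = np.sqrt(1.0 - rho**2 - lam**2)
        expr[:, signal] = (
            rho * factors[:, region[signal]]
            + lam * F_s[:, None]
            + idio * rng.standard_normal((n_samples, signal.size))
        )
        d = effect_size * F_s + noise_sd * rng.standard_normal(n_samples)
        truth.driver_genes = [genes[i] for i in signal]
        truth.hidden_driver = genes[g_star]
    else:  # null
        d = rng.standard_normal(n_samples)

    samples = _sample_labels(n_samples)
    X = ExpressionMatrix(
        data=pd.DataFrame(expr, index=samples, columns=genes), stage="raw"
    )
    response = ResponseVector(
        pd.Series(d, index=samples), treatment_id=f"sim_{scenario}"
    )
    return X, response, truth


def _sample_labels(n_samples: int) -> list[str]:
    return [f"S{str(i).zfill(len(str(n_samples - 1)))}" for i in range(n_samples)]


def generate_multi_treatment(
    network: GeneNetwork,
    n_samples: int = 120,
    n_treatments: int = 4,
    n_drivers: int = 5,
    effect_size: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    n_regions: int | None = None,
) -> tuple[ExpressionMatrix, dict[str, ResponseVector], dict[str, SimulationTruth]]:
    """One expression matrix with several responses on disjoint driver sets.

    Expression carries only the background region co-expression; each
    treatment's response is ``effect_size * sum(driver expr) + noise_sd *
    eps`` over its own ``n_drivers`` genes, with driver sets disjoint
    across treatments. This is the input for specificity analyses: each
    treatment's informative genes are distinct by construction.
    """
    if n_treatments * n_drivers > network.n_nodes:
        raise ValueError("driver sets exceed the number of genes")
    rng = np.random.default_rng(seed)
    n = network.n_nodes
    genes = list(network.node_ids)
    if n_regions is None:
        n_regions = max(1, n // 25)
    anchors = sorted(rng.choice(n, size=min(n_regions, n), replace=False))
    region = _assign_regions(network, list(anchors))
    factors = rng.standard_normal((n_samples, max(region) + 1))
    eps = rng.standard_normal((n_samples, n))
    rho = BACKGROUND_LOADING
    expr = rho * factors[:, region] + np.sqrt(1 - rho**2) * eps

    all_drivers = rng.choice(n, size=n_treatments * n_drivers, replace=False)
    samples = _sample_labels(n_samples)
    X = ExpressionMatrix(
        data=pd.DataFrame(expr, index=samples, columns=genes), stage="raw"
    )
    responses: dict[str, ResponseVector] = {}
    truths: dict[str, SimulationTruth] = {}
    for t in range(n_treatments):
        name = f"drug{t}"
        drivers = np.sort(all_drivers[t * n_drivers : (t + 1) * n_drivers])
        d = effect_size * expr[:, drivers].sum(axis=1) + noise_sd * rng.standard_normal(
            n_samples
        )
        responses[name] = ResponseVector(pd.Series(d, index=samples), treatment_id=name)
        truths[name] = SimulationTruth(
            scenario="direct_drivers",
            driver_genes=[genes[i] for i in drivers],
            effect_size=effect_size,
            noise_sd=noise_sd,
            seed=seed,
        )
    return X, responses, truths
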