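"""Ground-truth test instances: a source network, a noisy relabeled copy,
and a similarity matrix concentrated on the true mapping.

The generator emulates the situation network aligners face in practice — a
pair of related interactomes plus noisy cross-species sequence evidence —
in its minimal form: the target network is a randomly relabeled copy of the
source with optional extra nodes (attached preferentially by degree), a
fraction of copied edges rewired to random non-edges, and a similarity
matrix that is 1 on the surviving true pairs, 0 on a dropout fraction of
them, and small uniform noise elsewhere. Because rewiring never reinserts
the image of a source edge, the number of source edges conserved by the
true mapping is exactly |E1| minus the number of rewired edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io_formats import Network, GOAnnotation

__all__ = ["NoiseParams", "SyntheticPair", "generate_network",
           "generate_pair", "generate_annotations", "MODELS"]

MODELS = ("erdos_renyi", "preferential_attachment", "duplication_divergence")


@dataclass
class NoiseParams:
    """Perturbations applied when deriving the target network.

    n_extra : target-only nodes appended after copying.
    rewire_p : fraction of copied edges replaced by random non-edges.
    sim_noise : magnitude of uniform off-true-pair similarity noise.
    sim_dropout : fraction of true-pair similarities zeroed.
    """

    n_extra: int = 0
    rewire_p: float = 0.0
    sim_noise: float = 0.0
    sim_dropout: float = 0.0

    def __post_init__(self):
        if self.n_extra < 0:
            raise ValueError("n_extra must be >= 0")
        if not 0.0 <= self.rewire_p <= 1.0:
            raise ValueError("rewire_p must be in [0, 1]")
        if self.sim_noise < 0.0:
            raise ValueError("sim_noise must be >= 0")
        if not 0.0 <= self.sim_dropout <= 1.0:
            raise ValueError("sim_dropout must be in [0, 1]")


@dataclass
class SyntheticPair:
    """A generated instance with its ground truth."""

    net1: Network
    net2: Network
    true_map: np.ndarray     # length net1.n, injective into net2
    B: np.ndarray            # (net1.n, net2.n) similarity scores
    n_rewired: int = 0


def generate_network(model: str, n: int, param: float,
                     seed: int | None = None) -> Network:
    """Random simple undirected graph from one of three growth families.

    erdos_renyi : each pair is an edge independently with probability
        ``param``.
    preferential_attachment : Barabási–Albert growth attaching
        ``max(1, round(param))`` edges per new node.
    duplication_divergence : each new node duplicates a random existing
        node, retaining each parental edge independently with probability
        ``param``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if model == "erdos_renyi":
        g = nx.gnp_random_graph(n, param, seed=seed)
    elif model == "preferential_attachment":
        m_attach = max(1, int(round(param)))
        g = nx.barabasi_albert_graph(n, m_attach, seed=seed)
    elif model == "duplication_divergence":
        g = nx.duplication_divergence_graph(n, param, seed=seed)
    else:
        raise ValueError(f"unknown model {model!r}; choose one of {MODELS}")
    labels = [f"a{i}" for i in range(n)]
    return Network(labels, g.edges())


def generate_pair(net1: Network, noise: NoiseParams | None = None,
                  seed: int | None = None) -> SyntheticPair:
    """Derive a noisy target copy of ``net1`` with a known true mapping.

    Steps, all driven by one seeded generator: (1) copy net1's edges under a
    random injective relabeling into n1 + n_extra target indices; (2) rewire
    ``floor(rewire_p * m1)`` copied edges to uniformly random non-edges,
    never reinserting the image of any source edge; (3) attach each extra
    node by one degree-preferential edge; (4) build B with 1 at true pairs
    (a sim_dropout fraction zeroed) over uniform(0, sim_noise) background.
    """
    if noise is None:
        noise = NoiseParams()
    rng = np.random.default_rng(seed)
    n1 = net1.n
    n2 = n1 + noise.n_extra

    true_map = rng.choice(n2, size=n1, replace=False).astype(np.int64)

    def key(u, v):
        return (u, v) if u < v else (v, u)

    image_edges = {key(int(true_map[u]), int(true_map[v]))
                   for u, v in net1.edge_array}
    edges2 = set(image_edges)

    n_rewire = math.floor(noise.rewire_p * net1.m)
    if n_rewire:
        victims = rng.choice(net1.m, size=n_rewire, replace=False)
        for idx in victims:
            u, v = net1.edge_array[idx]
            edges2.discard(key(int(true_map[u]), int(true_map[v])))
        added = 0
        while added < n_rewire:
            u, v = rng.choice(n2, size=2, replace=False)
            k = key(int(u), int(v))
            if k in edges2 or k in image_edges:
                continue
            edges2.add(k)
            added += 1

    extra_nodes = sorted(set(range(n2)) - set(int(t) for t in true_map))
    if extra_nodes:
        deg = np.zeros(n2, dtype=np.int64)
        for u, v in edges2:
            deg[u] += 1
            deg[v] += 1
        for x in extra_nodes:
            weights = deg.astype(float) + 1.0
            weights[x] = 0.0
            partner = int(rng.choice(n2, p=weights / weights.sum()))
            k = key(x, partner)
            if k not in edges2:
                edges2.add(k)
                deg[x] += 1
                deg[partner] += 1

    net2 = Network([f"b{j}" for j in range(n2)], edges2)

    if noise.sim_noise > 0:
        B = rng.uniform(0.0, noise.sim_noise, size=(n1, n2))
    else:
        B = np.zeros((n1, n2))
    B[np.arange(n1), true_map] = 1.0
    n_drop = math.floor(noise.sim_dropout * n1)
    if n_drop:
        dropped = rng.choice(n1, size=n_drop, replace=False)
        B[dropped, true_map[dropped]] = 0.0

    return SyntheticPair(net1=net1, net2=net2, true_map=true_map, B=B,
                         n_rewired=n_rewire)


def generate_annotations(pair: SyntheticPair, terms_per_pair: int = 3,
                         dropout: float = 0.2, seed: int | None = None
                         ) -> tuple[GOAnnotation, GOAnnotation]:
    """Assign each true pair a shared GO term set with per-term dropout.

    True pair i gets terms ``GO:i:k`` for k < terms_per_pair on both sides;
    each term is independently dropped from each side with probability
    ``dropout``, so aligned true pairs have high but imperfect Jaccard
    overlap. Extra target nodes are left unannotated.
    """
    rng = np.random.default_rng(seed)
    t1: dict[str, set[str]] = {}
    t2: dict[str, set[str]] = {}
    for i, j in enumerate(pair.true_map):
        terms = [f"GO:{i:04d}:{k}" for k in range(terms_per_pair)]
        s1 = {t for t in terms if rng.uniform() >= dropout}
        s2 = {t for t in terms if rng.uniform() >= dropout}
        if s1:
            t1[pair.net1.labels[i]] = s1
        if s2:
            t2[pair.net2.labels[int(j)]] = s2
    return GOAnnotation(t1), GOAnnotation(t2)
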