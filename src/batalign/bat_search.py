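"""Discrete bat-swarm search for the conserved-edge alignment objective.

An alignment ("position") is an injective vector mapping each source node to
a distinct target node. Each bat carries a position, a binary velocity (1 =
the node's assignment may be redrawn, 0 = kept), a loudness gating the
acceptance of improving moves, and a pulse rate gating local search.

One iteration of one bat:

1. draw a frequency f in [f_min, f_max] and binarize it at the midpoint;
2. update the velocity dimension-wise: dimensions agreeing with the global
   best keep their velocity, disagreeing dimensions that were flying take
   the binarized frequency, frozen dimensions stay frozen;
3. global search: flying dimensions are reassigned uniformly at random
   (without replacement) from the targets not pinned by frozen dimensions;
4. with probability 1 - rate, also build a local-search candidate that
   permutes the targets currently held by the flying dimensions, and keep
   whichever candidate conserves more edges;
5. accept the candidate only if it strictly improves the objective AND the
   loudness exceeds a uniform draw; on acceptance the loudness decays
   geometrically (A <- theta * A), the rate follows r0 * (1 - exp(-gamma*t)),
   and the velocity is re-derived from the new position (endpoints of
   conserved edges freeze, all other nodes fly).

The population shares the similarity-guided greedy core of the initial
alignment; only the random completion of sources with no usable similarity
differs between bats. The swarm stops after ``max_iters`` iterations or
``patience`` consecutive iterations without strict improvement of the best
objective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .io_formats import Network

__all__ = [
    "Bat",
    "BatParams",
    "AlignResult",
    "conserved_edges",
    "conserved_edge_mask",
    "check_alignment",
    "greedy_init_position",
    "init_velocity",
    "draw_frequency",
    "binarize_frequency",
    "update_velocity",
    "global_search",
    "local_search",
    "accept_step",
    "step_bat",
    "align",
]


@dataclass
class BatParams:
    """Swarm hyper-parameters.

    pop_size, max_iters and patience default to the recommended operating
    point (population 40, up to 1000 iterations, stop after 10 stagnant
    iterations); f_min/f_max span [0, 1]. theta (loudness decay), gamma
    (pulse-rate growth), loudness0 and rate0 are the canonical bat-algorithm
    settings.
    """

    pop_size: int = 40
    max_iters: int = 1000
    patience: int = 10
    f_min: float = 0.0
    f_max: float = 1.0
    theta: float = 0.9
    gamma: float = 0.9
    loudness0: float = 1.0
    rate0: float = 0.5
    seed: int | None = None

    def __post_init__(self):
        if self.pop_size < 1:
            raise ValueError("pop_size must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.max_iters < 0:
            raise ValueError("max_iters must be >= 0")
        if self.f_min > self.f_max:
            raise ValueError("f_min must be <= f_max")
        if not 0.0 < self.theta < 1.0:
            raise ValueError("theta must be in (0, 1)")
        if self.gamma <= 0.0:
            raise ValueError("gamma must be positive")
        if self.loudness0 <= 0.0:
            raise ValueError("loudness0 must be positive")
        if not 0.0 <= self.rate0 <= 1.0:
            raise ValueError("rate0 must be in [0, 1]")


@dataclass
class Bat:
    """One candidate solution with its search state."""

    position: np.ndarray   # injective target indices, length n1
    velocity: np.ndarray   # 0/1, length n1
    loudness: float
    rate: float
    objective: int         # cached conserved-edge count of `position`


@dataclass
class AlignResult:
    """Outcome of a swarm run: best alignment plus its objective trace."""

    alignment: np.ndarray
    objective: int
    trace: list[int] = field(default_factory=list)
    n_iter: int = 0


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def check_alignment(target_of: np.ndarray, n1: int, n2: int) -> None:
    """Raise ValueError unless ``target_of`` is a valid injective alignment."""
    target_of = np.asarray(target_of)
    if target_of.shape != (n1,):
        raise ValueError(f"alignment length {target_of.shape} != ({n1},)")
    if n1 and (target_of.min() < 0 or target_of.max() >= n2):
        raise ValueError("alignment entries out of target range")
    if len(np.unique(target_of)) != n1:
        raise ValueError("alignment is not injective")


def conserved_edge_mask(target_of: np.ndarray, net1: Network,
                        net2: Network) -> np.ndarray:
    """Boolean mask over net1.edge_array: True where the edge's endpoint
    images are adjacent in net2."""
    if net1.m == 0:
        return np.zeros(0, dtype=bool)
    e = net1.edge_array
    fu = target_of[e[:, 0]]
    fv = target_of[e[:, 1]]
    lo = np.minimum(fu, fv)
    hi = np.maximum(fu, fv)
    keys = lo * net2.n + hi
    packed = net2.packed_edges
    pos = np.searchsorted(packed, keys)
    pos_clipped = np.minimum(pos, len(packed) - 1) if len(packed) else pos
    if len(packed) == 0:
        return np.zeros(net1.m, dtype=bool)
    return packed[pos_clipped] == keys


def conserved_edges(target_of: np.ndarray, net1: Network,
                    net2: Network) -> int:
    """Number of source edges whose endpoint images are adjacent in the
    target network — the search objective."""
    return int(conserved_edge_mask(target_of, net1, net2).sum())


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _greedy_core(S: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Similarity-guided greedy assignment; -1 marks sources left for the
    random completion phase.

    Repeatedly aligns the globally best-scoring available (row, column)
    pair — ties broken uniformly at random — until every remaining source
    row is all-zero against the remaining targets.
    """
    n1, n2 = S.shape
    work = np.array(S, dtype=float, copy=True)
    partial = np.full(n1, -1, dtype=np.int64)
    for _ in range(n1):
        mx = work.max() if work.size else 0.0
        if mx <= 0.0:
            break
        cand = np.argwhere(work == mx)
        i, j = cand[rng.integers(len(cand))]
        partial[i] = j
        work[i, :] = -np.inf
        work[:, j] = -np.inf
    return partial


def _complete_randomly(partial: np.ndarray, n2: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Assign the unaligned sources uniformly at random (without
    replacement) among unused targets."""
    out = partial.copy()
    open_rows = np.flatnonzero(out == -1)
    if len(open_rows):
        used = out[out != -1]
        free = np.setdiff1d(np.arange(n2, dtype=np.int64), used)
        out[open_rows] = rng.choice(free, size=len(open_rows), replace=False)
    return out


def greedy_init_position(S: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """Greedy argmax-with-deletion seeding followed by random completion of
    sources with no remaining similarity."""
    n1, n2 = S.shape
    if n1 > n2:
        raise ValueError(f"source network larger than target ({n1} > {n2})")
    return _complete_randomly(_greedy_core(S, rng), n2, rng)


def init_velocity(target_of: np.ndarray, net1: Network,
                  net2: Network) -> np.ndarray:
    """Velocity from a position: 0 for every endpoint of a conserved edge,
    1 for all other nodes."""
    fly = np.ones(net1.n, dtype=np.int8)
    mask = conserved_edge_mask(target_of, net1, net2)
    if mask.any():
        kept = net1.edge_array[mask]
        fly[kept[:, 0]] = 0
        fly[kept[:, 1]] = 0
    return fly


# ---------------------------------------------------------------------------
# per-iteration operators
# ---------------------------------------------------------------------------

def draw_frequency(params: BatParams, rng: np.random.Generator) -> float:
    """f = f_min + (f_max - f_min) * beta with beta ~ U[0, 1]."""
    return params.f_min + (params.f_max - params.f_min) * rng.uniform()


def binarize_frequency(f_i: float, params: BatParams) -> int:
    """1 iff the drawn frequency exceeds the band midpoint
    0.5 * (f_max - f_min) (strict)."""
    return 1 if f_i > 0.5 * (params.f_max - params.f_min) else 0


def update_velocity(bat: Bat, best: np.ndarray, f_bin: int) -> np.ndarray:
    """Dimensions matching the global best keep their velocity; flying
    dimensions that disagree take the binarized frequency; frozen
    dimensions stay frozen."""
    agree = bat.position == best
    flipped = np.where(bat.velocity == 1, np.int8(f_bin), np.int8(0))
    return np.where(agree, bat.velocity, flipped).astype(np.int8)


def global_search(position: np.ndarray, velocity: np.ndarray, n2: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Reassign flying dimensions uniformly at random, without replacement,
    from the pool of targets not held by a frozen dimension."""
    out = position.copy()
    fly_idx = np.flatnonzero(velocity == 1)
    if len(fly_idx) == 0:
        return out
    pinned = position[velocity == 0]
    pool = np.setdiff1d(np.arange(n2, dtype=np.int64), pinned)
    out[fly_idx] = rng.choice(pool, size=len(fly_idx), replace=False)
    return out


def local_search(position: np.ndarray, velocity: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Permute, uniformly at random, the targets currently assigned to the
    flying dimensions; the overall target set is unchanged."""
    out = position.copy()
    fly_idx = np.flatnonzero(velocity == 1)
    if len(fly_idx) == 0:
        return out
    held = position[fly_idx]
    out[fly_idx] = held[rng.permutation(len(fly_idx))]
    return out


def accept_step(bat: Bat, candidate: np.ndarray, candidate_obj: int, t: int,
                params: BatParams, rng: np.random.Generator,
                net1: Network, net2: Network) -> Bat:
    """Loudness-gated strict-improvement acceptance.

    On acceptance: loudness decays by theta, the pulse rate follows
    rate0 * (1 - exp(-gamma * t)), and the velocity is re-derived from the
    accepted position. Otherwise the bat keeps its position, loudness and
    rate (its velocity update from this iteration is retained).
    """
    if candidate_obj > bat.objective and bat.loudness > rng.uniform():
        return replace(
            bat,
            position=candidate,
            objective=candidate_obj,
            loudness=params.theta * bat.loudness,
            rate=params.rate0 * (1.0 - math.exp(-params.gamma * t)),
            velocity=init_velocity(candidate, net1, net2),
        )
    return bat


def step_bat(bat: Bat, best: np.ndarray, t: int, net1: Network,
             net2: Network, params: BatParams,
             rng: np.random.Generator) -> Bat:
    """One full iteration of one bat: velocity update, global search,
    rate-gated local search, and gated acceptance."""
    f_i = draw_frequency(params, rng)
    f_bin = binarize_frequency(f_i, params)
    velocity = update_velocity(bat, best, f_bin)
    bat = replace(bat, velocity=velocity)

    candidate = global_search(bat.position, velocity, net2.n, rng)
    candidate_obj = conserved_edges(candidate, net1, net2)
    if rng.uniform() > bat.rate:
        local = local_search(bat.position, velocity, rng)
        local_obj = conserved_edges(local, net1, net2)
        if local_obj > candidate_obj:
            candidate, candidate_obj = local, local_obj
    return accept_step(bat, candidate, candidate_obj, t, params, rng,
                       net1, net2)


# ---------------------------------------------------------------------------
# swarm loop
# ---------------------------------------------------------------------------

def align(net1: Network, net2: Network, S: np.ndarray,
          params: BatParams | None = None) -> AlignResult:
    """Run the discrete bat swarm and return the best alignment found.

    All bats share the greedy core determined by ``S``; their random
    completions are independent. The per-iteration best objective is
    recorded in ``trace`` (entry 0 is the initial population best); the
    trace is non-decreasing because only strict improvements replace the
    incumbent best.
    """
    if params is None:
        params = BatParams()
    if net1.n == 0:
        raise ValueError("source network is empty")
    if net1.n > net2.n:
        raise ValueError(f"source network larger than target "
                         f"({net1.n} > {net2.n})")
    if S.shape != (net1.n, net2.n):
        raise ValueError("similarity matrix shape mismatch")

    rng = np.random.default_rng(params.seed)
    core = _greedy_core(S, rng)
    # initial pulse rate is the t=0 value of the growth law, i.e. 0
    bats: list[Bat] = []
    for _ in range(params.pop_size):
        pos = _complete_randomly(core, net2.n, rng)
        bats.append(Bat(
            position=pos,
            velocity=init_velocity(pos, net1, net2),
            loudness=params.loudness0,
            rate=params.rate0 * (1.0 - math.exp(0.0)),
            objective=conserved_edges(pos, net1, net2),
        ))

    best_idx = int(np.argmax([b.objective for b in bats]))
    best_pos = bats[best_idx].position.copy()
    best_obj = bats[best_idx].objective
    trace = [best_obj]

    stagnant = 0
    n_iter = 0
    for t in range(1, params.max_iters + 1):
        for k in range(params.pop_size):
            bats[k] = step_bat(bats[k], best_pos, t, net1, net2, params, rng)
        it_idx = int(np.argmax([b.objective for b in bats]))
        if bats[it_idx].objective > best_obj:
            best_obj = bats[it_idx].objective
            best_pos = bats[it_idx].position.copy()
            stagnant = 0
        else:
            stagnant += 1
        trace.append(best_obj)
        n_iter = t
        if stagnant >= params.patience:
            break

    return AlignResult(alignment=best_pos, objective=best_obj,
                       trace=trace, n_iter=n_iter)
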