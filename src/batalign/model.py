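"""Model/Results interface over the discrete bat aligner.

``BatAlign`` holds the data of one alignment problem — the two networks and
the blended node-similarity matrix; ``fit`` runs the swarm and returns a
``BatAlignResults`` carrying the alignment, the objective trace and the
quality metrics, with a ``summary()`` table in the style of statistical
modelling packages.

Example
-------
>>> from batalign import BatAlign, synthetic
>>> net1 = synthetic.generate_network("erdos_renyi", 30, 0.15, seed=0)
>>> pair = synthetic.generate_pair(net1, seed=0)
>>> model = BatAlign(pair.net1, pair.net2, similarity=pair.B, alpha=1.0)
>>> res = model.fit(seed=0)
>>> res.objective == pair.net1.m
True
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np

from . import metrics as _metrics
from .bat_search import AlignResult, BatParams, align
from .io_formats import (GOAnnotation, Network, read_edgelist,
                         read_similarity, write_alignment)
from .similarity import DEFAULT_ALPHA, blended_similarity

__all__ = ["BatAlign", "BatAlignResults"]


class BatAlign:
    """A pairwise global network-alignment problem.

    Parameters
    ----------
    net1, net2 : Network
        Source (smaller) and target network; ``net1.n <= net2.n``.
    similarity : ndarray, optional
        Raw cross-network scores (rows = net1, columns = net2), e.g. BLAST
        bit-scores. Omitted, an all-zero matrix is used: initialization is
        then purely random and the search purely topological.
    alpha : float
        Convex weight of the sequence term against the neighbor-sum
        topology term when blending the guidance matrix; 1 means sequence
        only. Default 0.4.
    """

    def __init__(self, net1: Network, net2: Network,
                 similarity: np.ndarray | None = None,
                 alpha: float = DEFAULT_ALPHA):
        if net1.n > net2.n:
            raise ValueError(f"source network larger than target "
                             f"({net1.n} > {net2.n})")
        self.net1 = net1
        self.net2 = net2
        self.alpha = alpha
        if similarity is None:
            similarity = np.zeros((net1.n, net2.n))
        self.B = np.asarray(similarity, dtype=float)
        self.S = blended_similarity(self.B, net1, net2, alpha=alpha)

    @classmethod
    def from_files(cls, net1_path, net2_path, sim_path=None,
                   alpha: float = DEFAULT_ALPHA) -> "BatAlign":
        """Build the model from edge-list files and an optional similarity
        score file."""
        net1 = read_edgelist(net1_path)
        net2 = read_edgelist(net2_path)
        B = None
        if sim_path is not None:
            B = read_similarity(sim_path, net1, net2)
        return cls(net1, net2, similarity=B, alpha=alpha)

    def fit(self, pop_size: int = 40, max_iters: int = 1000,
            patience: int = 10, f_min: float = 0.0, f_max: float = 1.0,
            theta: float = 0.9, gamma: float = 0.9, loudness0: float = 1.0,
            rate0: float = 0.5, seed: int | None = None
            ) -> "BatAlignResults":
        """Run the discrete bat swarm and return the fitted results."""
        params = BatParams(pop_size=pop_size, max_iters=max_iters,
                           patience=patience, f_min=f_min, f_max=f_max,
                           theta=theta, gamma=gamma, loudness0=loudness0,
                           rate0=rate0, seed=seed)
        result = align(self.net1, self.net2, self.S, params)
        return BatAlignResults(self, params, result)


class BatAlignResults:
    """Fitted alignment: the best mapping found, its trace and metrics."""

    def __init__(self, model: BatAlign, params: BatParams,
                 result: AlignResult):
        self.model = model
        self.params = params
        self.alignment = result.alignment
        self.objective = result.objective
        self.objective_trace = result.trace
        self.n_iter = result.n_iter

    @property
    def mapping(self) -> dict[str, str]:
        """The alignment as a source-label → target-label dict."""
        n1, n2 = self.model.net1, self.model.net2
        return {n1.labels[i]: n2.labels[int(j)]
                for i, j in enumerate(self.alignment)}

    def evaluate(self, annot1: GOAnnotation | None = None,
                 annot2: GOAnnotation | None = None,
                 true_map: np.ndarray | None = None
                 ) -> _metrics.AlignmentReport:
        """Quality metrics of the fitted alignment (EC, ICS, S3; GOC when
        annotations are supplied; node correctness when a ground-truth
        mapping is supplied)."""
        return _metrics.evaluate_alignment(
            self.alignment, self.model.net1, self.model.net2,
            annot1=annot1, annot2=annot2, true_map=true_map)

    def save_alignment(self, path) -> None:
        write_alignment(self.alignment, self.model.net1, self.model.net2,
                        path)

    def plot_trace(self, ax=None):
        """Best conserved-edge count per iteration."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(range(len(self.objective_trace)), self.objective_trace,
                drawstyle="steps-post")
        ax.set_xlabel("iteration")
        ax.set_ylabel("best conserved edges")
        return ax

    def summary(self, annot1: GOAnnotation | None = None,
                annot2: GOAnnotation | None = None,
                true_map: np.ndarray | None = None) -> str:
        """Human-readable fit report."""
        rep = self.evaluate(annot1=annot1, annot2=annot2, true_map=true_map)
        n1, n2 = self.model.net1, self.model.net2

        def fmt(x):
            return "undefined" if x is None else f"{x:.4f}"

        lines = [
            "Discrete bat network alignment",
            "=" * 46,
            f"{'source network':<28}n={n1.n}, m={n1.m}",
            f"{'target network':<28}n={n2.n}, m={n2.m}",
            f"{'alpha (sequence weight)':<28}{self.model.alpha:g}",
            f"{'population / iterations':<28}"
            f"{self.params.pop_size} / {self.n_iter}",
            f"{'seed':<28}{self.params.seed}",
            "-" * 46,
            f"{'conserved edges':<28}{rep.conserved}",
            f"{'induced target edges':<28}{rep.induced}",
            f"{'EC':<28}{fmt(rep.ec)}",
            f"{'ICS':<28}{fmt(rep.ics)}",
            f"{'S3':<28}{fmt(rep.s3)}",
        ]
        if rep.goc_sum is not None:
            lines.append(f"{'GOC (sum)':<28}{rep.goc_sum:.4f}")
            lines.append(f"{'GOC (mean)':<28}{fmt(rep.goc_mean)}")
        if rep.node_correctness is not None:
            lines.append(f"{'node correctness':<28}"
                         f"{fmt(rep.node_correctness)}")
        lines.append("=" * 46)
        return "\n".join(lines)

    def params_dict(self) -> dict:
        d = asdict(self.params)
        d["alpha"] = self.model.alpha
        return d
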