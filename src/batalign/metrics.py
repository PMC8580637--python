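"""Alignment quality metrics.

Topological scores count conserved edges — source edges whose endpoint
images are adjacent in the target network:

* EC  (edge correctness)            = conserved / |E1|
* ICS (induced conserved structure) = conserved / |E2 induced on f(V1)|
* S3  (symmetric substructure)      = conserved / (|E1| + induced - conserved)

EC only penalizes mapping sparse regions onto dense ones, ICS only the
reverse; S3 penalizes both, so S3 <= min(EC, ICS) wherever all are defined.
Zero denominators leave a score undefined (None).

The biological score GOC sums, over aligned pairs, the Jaccard index of
their GO term-ID sets (no ontology-ancestor expansion). The literal sum is
the primary value; the mean over pairs with a non-empty term union is also
reported for cross-size comparison. For synthetic instances with a known
true mapping, node correctness is the fraction of sources mapped to their
true targets.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .io_formats import Network, GOAnnotation
from .bat_search import conserved_edges, conserved_edge_mask

__all__ = [
    "AlignmentReport",
    "conserved_edge_image",
    "induced_edge_count",
    "ec",
    "ics",
    "s3",
    "goc",
    "node_correctness",
    "evaluate_alignment",
]


@dataclass
class AlignmentReport:
    """All quality scores of one alignment; undefined scores are None."""

    conserved: int
    induced: int
    ec: float | None
    ics: float | None
    s3: float | None
    goc_sum: float | None = None
    goc_mean: float | None = None
    node_correctness: float | None = None

    def as_dict(self) -> dict:
        return asdict(self)


def conserved_edge_image(target_of: np.ndarray, net1: Network,
                         net2: Network) -> set[tuple[int, int]]:
    """The set of target edges that are images of source edges, as
    (min, max) index pairs."""
    mask = conserved_edge_mask(target_of, net1, net2)
    kept = net1.edge_array[mask]
    fu = target_of[kept[:, 0]]
    fv = target_of[kept[:, 1]]
    return {(int(min(a, b)), int(max(a, b))) for a, b in zip(fu, fv)}


def induced_edge_count(target_of: np.ndarray, net2: Network) -> int:
    """Number of target edges with both endpoints in the image f(V1)."""
    if net2.m == 0:
        return 0
    member = np.zeros(net2.n, dtype=bool)
    member[np.asarray(target_of, dtype=np.int64)] = True
    e = net2.edge_array
    return int((member[e[:, 0]] & member[e[:, 1]]).sum())


def ec(target_of: np.ndarray, net1: Network, net2: Network) -> float | None:
    """Edge correctness; None when the source network has no edges."""
    if net1.m == 0:
        return None
    return conserved_edges(target_of, net1, net2) / net1.m


def ics(target_of: np.ndarray, net1: Network, net2: Network) -> float | None:
    """Induced conserved structure; None when the induced subgraph has no
    edges."""
    induced = induced_edge_count(target_of, net2)
    if induced == 0:
        return None
    return conserved_edges(target_of, net1, net2) / induced


def s3(target_of: np.ndarray, net1: Network, net2: Network) -> float | None:
    """Symmetric substructure score; None when both the source edge set and
    the induced target edge set are empty."""
    conserved = conserved_edges(target_of, net1, net2)
    induced = induced_edge_count(target_of, net2)
    denom = net1.m + induced - conserved
    if denom == 0:
        return None
    return conserved / denom


def goc(target_of: np.ndarray, net1: Network, net2: Network,
        annot1: GOAnnotation, annot2: GOAnnotation
        ) -> tuple[float, float | None]:
    """GO consistency: (sum, mean) of per-pair Jaccard indices of term sets.

    Pairs where both term sets are empty contribute 0 to the sum and are
    excluded from the mean's denominator; the mean is None if no pair has
    any terms.
    """
    total = 0.0
    n_scored = 0
    for i, j in enumerate(np.asarray(target_of, dtype=np.int64)):
        gu = annot1[net1.labels[i]]
        gv = annot2[net2.labels[int(j)]]
        union = len(gu | gv)
        if union == 0:
            continue
        total += len(gu & gv) / union
        n_scored += 1
    mean = total / n_scored if n_scored else None
    return total, mean


def node_correctness(target_of: np.ndarray,
                     true_map: np.ndarray) -> float:
    """Fraction of source nodes mapped to their ground-truth targets."""
    target_of = np.asarray(target_of)
    true_map = np.asarray(true_map)
    if target_of.shape != true_map.shape:
        raise ValueError("alignment and truth have different lengths")
    if len(target_of) == 0:
        raise ValueError("empty alignment")
    return float((target_of == true_map).mean())


def evaluate_alignment(target_of: np.ndarray, net1: Network, net2: Network,
                       annot1: GOAnnotation | None = None,
                       annot2: GOAnnotation | None = None,
                       true_map: np.ndarray | None = None
                       ) -> AlignmentReport:
    """Compute every applicable metric for one alignment."""
    conserved = conserved_edges(target_of, net1, net2)
    induced = induced_edge_count(target_of, net2)
    report = AlignmentReport(
        conserved=conserved,
        induced=induced,
        ec=ec(target_of, net1, net2),
        ics=ics(target_of, net1, net2),
        s3=s3(target_of, net1, net2),
    )
    if annot1 is not None and annot2 is not None:
        report.goc_sum, report.goc_mean = goc(target_of, net1, net2,
                                              annot1, annot2)
    if true_map is not None:
        report.node_correctness = node_correctness(target_of, true_map)
    return report
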