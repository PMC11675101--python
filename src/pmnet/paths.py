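"""Shortest-path connectivity ranking on the parieto-premotor graph.

Streamline weights are converted to lengths by the reciprocal transform
(length = 1/weight; absent edges are infinitely long), all-pairs shortest
paths are computed by Dijkstra's algorithm, and the parietal-premotor
distances of one hemisphere are ranked by percentile cutoffs (15/25/50/75
by default): a pair strictly below the 15th percentile is a strongest
link, below the 25th highly linked, and so on.  Shorter distance is read
as stronger connectivity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .group import ThresholdedGraph
from .roi import RoiSet

PERCENTILE_CLASSES = ("p15", "p25", "p50", "p75")
DEFAULT_CUTOFFS = (15.0, 25.0, 50.0, 75.0)


def weights_to_lengths(weights: np.ndarray) -> np.ndarray:
    """Reciprocal weight-to-length conversion; zero weight = no edge."""
    W = np.asarray(weights, dtype=float)
    if np.any(W < 0):
        raise ValueError("weights must be nonnegative")
    with np.errstate(divide="ignore"):
        lengths = np.where(W > 0, 1.0 / W, np.inf)
    np.fill_diagonal(lengths, np.inf)  # no self-edges
    return lengths


def dijkstra_all_pairs(lengths: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances (inf for unreachable pairs)."""
    L = np.asarray(lengths, dtype=float)
    n = L.shape[0]
    finite = np.isfinite(L)
    rows, cols = np.nonzero(finite)
    sparse = csr_matrix((L[rows, cols], (rows, cols)), shape=(n, n))
    D = shortest_path(sparse, method="D", directed=False)
    np.fill_diagonal(D, 0.0)
    return D


def distance_matrix(graph: ThresholdedGraph, interlobar_only: bool = True) -> np.ndarray:
    """Dijkstra distance matrix of a thresholded graph.

    With ``interlobar_only`` (the Tables 2-3 configuration) paths run on the
    parieto-premotor graph: intralobar edges are absent.
    """
    W = graph.weights
    if interlobar_only:
        mask = (graph.mask if graph.mask is not None
                else graph.roiset.interlobar_mask())
        W = np.where(mask, W, 0.0)
    return dijkstra_all_pairs(weights_to_lengths(W))


def classify_edge_percentiles(D: np.ndarray, roiset: RoiSet,
                              cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS
                              ) -> pd.DataFrame:
    """Rank parietal-premotor distances by percentile class.

    Percentiles (linear interpolation) are computed over the finite
    parietal-premotor distances only; a pair is assigned the tightest class
    whose cutoff it falls strictly below, ``none`` otherwise.  Classes are
    nested by construction.
    """
    pairs = roiset.interlobar_pairs()
    dist = np.array([D[i, j] for i, j in pairs])
    finite = dist[np.isfinite(dist)]
    if finite.size < 2:
        raise ValueError("need at least two finite parieto-premotor distances")
    levels = np.percentile(finite, cutoffs)
    classes = []
    for d in dist:
        label = "none"
        if np.isfinite(d):
            for cls, level in zip(PERCENTILE_CLASSES, levels):
                if d < level:
                    label = cls
                    break
        classes.append(label)
    return pd.DataFrame({
        "parietal": [roiset.names[i] for i, _ in pairs],
        "premotor": [roiset.names[j] for _, j in pairs],
        "distance": dist,
        "percentile_class": classes,
    })


def select_analysis_graph(graphs: list[ThresholdedGraph],
                          records=None) -> ThresholdedGraph:
    """The admitted graph of maximal edge density (ties: lowest threshold).

    ``records`` restricts the choice to admitted thresholds; with the
    default sweep this selects the 0.01 graph.
    """
    if records is not None:
        admitted = {r.threshold for r in records if r.admitted}
        graphs = [g for g in graphs if g.threshold in admitted]
    if not graphs:
        raise ValueError("no admitted graphs to select from")
    return max(graphs, key=lambda g: (g.density, -g.threshold))


def distance_frame(D: np.ndarray, roiset: RoiSet) -> pd.DataFrame:
    """Distance matrix as parietal rows x premotor columns (Table 2/3 layout)."""
    p_idx = roiset.parietal_indices
    f_idx = roiset.premotor_indices
    return pd.DataFrame(D[np.ix_(p_idx, f_idx)],
                        index=[roiset.names[i] for i in p_idx],
                        columns=[roiset.names[j] for j in f_idx])
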