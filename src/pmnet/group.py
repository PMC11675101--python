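"""Group aggregation, threshold sweep and graph admission.

Subject connectomes are aggregated into a whole-group weight matrix,
thresholded over a range of cutoffs (default 0.01 to 0.1 in steps of
0.0025, i.e. 37 graphs), and each thresholded graph is screened by three
goodness criteria before entering further analysis:

(a) connectedness — every pair of nodes is linked by a path;
(b) modularity    — maximized Newman Q above 0.3;
(c) small-worldness — S = (C/C_rand) / (L/L_rand) above 1, with C the mean
    binary clustering coefficient, L the characteristic (hop) path length,
    and the null values averaged over degree-preserving Maslov-Sneppen
    rewirings of the same graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .io import NormalizedConnectome
from .modularity import ModularityResult, newman_modularity
from .roi import RoiSet

Q_CUTOFF = 0.3
S_CUTOFF = 1.0


@dataclass
class ThresholdSpec:
    """Weight-threshold sweep; the default yields 37 thresholds."""

    lo: float = 0.01
    hi: float = 0.1
    step: float = 0.0025

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError("threshold lo must be below hi")
        if self.step <= 0:
            raise ValueError("threshold step must be positive")

    def thresholds(self) -> np.ndarray:
        count = int(np.floor((self.hi - self.lo) / self.step + 1e-9)) + 1
        return np.round(self.lo + self.step * np.arange(count), 12)


@dataclass
class GroupGraph:
    """Aggregated weighted-undirected group connectome."""

    weights: np.ndarray
    roiset: RoiSet
    aggregation_tag: str
    mask: np.ndarray | None = None


@dataclass
class ThresholdedGraph:
    threshold: float
    weights: np.ndarray
    roiset: RoiSet
    mask: np.ndarray | None = None

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, k=1)))

    @property
    def density(self) -> float:
        n = self.weights.shape[0]
        return self.n_edges / (n * (n - 1) / 2)


def aggregate_group(subjects: list[NormalizedConnectome],
                    method: str = "mean") -> GroupGraph:
    """Aggregate subject weights edgewise into one group matrix.

    ``mean`` is the default group consensus; ``mean_plus_2sd`` adds twice
    the edgewise sample standard deviation (divisor n-1), the literal
    mean(P_ij) + 2 SD(P_ij) reading.
    """
    if not subjects:
        raise ValueError("need at least one subject")
    roiset = subjects[0].roiset
    for s in subjects[1:]:
        if s.roiset.names != roiset.names:
            raise ValueError("subjects have mismatched RoiSets")
    stack = np.stack([s.weights for s in subjects])
    if method == "mean":
        agg = stack.mean(axis=0)
    elif method == "mean_plus_2sd":
        sd = stack.std(axis=0, ddof=1) if len(subjects) > 1 else np.zeros_like(stack[0])
        agg = stack.mean(axis=0) + 2.0 * sd
    else:
        raise ValueError(f"unknown aggregation method {method!r}")
    mask = subjects[0].mask
    return GroupGraph(weights=agg, roiset=roiset, aggregation_tag=method,
                      mask=None if mask is None else mask.copy())


def threshold_weights(weights: np.ndarray, t: float) -> np.ndarray:
    """Retain edges with weight >= t; strictly-below edges are removed."""
    out = np.where(weights >= t, weights, 0.0)
    np.fill_diagonal(out, 0.0)
    return out


def apply_thresholds(group: GroupGraph,
                     spec: ThresholdSpec | None = None) -> list[ThresholdedGraph]:
    spec = spec or ThresholdSpec()
    return [ThresholdedGraph(float(t), threshold_weights(group.weights, t),
                             group.roiset,
                             None if group.mask is None else group.mask)
            for t in spec.thresholds()]


# ---------------------------------------------------------------------------
# goodness criteria

def _binary_adjacency(weights: np.ndarray) -> np.ndarray:
    A = (np.asarray(weights) > 0).astype(float)
    np.fill_diagonal(A, 0.0)
    return A


def is_connected(weights: np.ndarray) -> bool:
    """True iff a single component spans all nodes (isolated nodes fail)."""
    W = np.asarray(weights)
    if W.size == 0:
        raise ValueError("empty graph")
    n_comp, _ = connected_components(csr_matrix(W != 0), directed=False)
    return n_comp == 1


def clustering_coefficient(weights: np.ndarray) -> tuple[float, np.ndarray]:
    """Binary Watts-Strogatz clustering: C_i = 2 t_i / (k_i (k_i - 1)).

    Nodes with fewer than two neighbors have C_i = 0; C is the mean over
    all nodes.
    """
    A = _binary_adjacency(weights)
    k = A.sum(axis=1)
    triangles = np.diag(A @ A @ A) / 2.0
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        Ci = np.where(denom > 0, 2.0 * triangles / denom, 0.0)
    return float(Ci.mean()), Ci


def characteristic_path_length(weights: np.ndarray) -> float:
    """Mean hop-count distance over all ordered node pairs i != j."""
    A = _binary_adjacency(weights)
    D = shortest_path(csr_matrix(A), method="D", directed=False,
                      unweighted=True)
    off = ~np.eye(A.shape[0], dtype=bool)
    if np.isinf(D[off]).any():
        raise ValueError("graph is disconnected; path length undefined")
    return float(D[off].mean())


def maslov_sneppen_rewire(weights: np.ndarray, rng: np.random.Generator,
                          swap_factor: int = 10) -> np.ndarray:
    """Degree-preserving rewiring of the binarized graph.

    Attempts ``swap_factor * n_edges`` double-edge swaps; a swap is
    rejected if it would create a self-loop or a duplicate edge.  Graphs
    admitting no swap (e.g. complete graphs) are returned unchanged.
    """
    A = _binary_adjacency(weights)
    edges = [tuple(e) for e in np.argwhere(np.triu(A, k=1))]
    m = len(edges)
    if m < 2:
        return A
    adjacency = {i: set(np.flatnonzero(A[i])) for i in range(A.shape[0])}
    for _ in range(swap_factor * m):
        e1, e2 = rng.integers(0, m, size=2)
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a, d) and (c, b)
        if len({a, b, c, d}) < 4:
            continue
        if d in adjacency[a] or b in adjacency[c]:
            continue
        adjacency[a].discard(b); adjacency[b].discard(a)
        adjacency[c].discard(d); adjacency[d].discard(c)
        adjacency[a].add(d); adjacency[d].add(a)
        adjacency[c].add(b); adjacency[b].add(c)
        edges[e1] = (a, d)
        edges[e2] = (c, b)
    out = np.zeros_like(A)
    for i, neigh in adjacency.items():
        for j in neigh:
            out[i, j] = 1.0
    return out


@dataclass
class SmallWorldResult:
    S: float
    C: float
    L: float
    C_rand: float
    L_rand: float


def small_worldness(weights: np.ndarray, n_null: int = 100,
                    seed: int | np.random.SeedSequence = 0,
                    max_retries: int = 20) -> SmallWorldResult:
    """S = (C/C_rand) / (L/L_rand) against degree-preserving nulls.

    C_rand and L_rand are means over ``n_null`` rewired graphs; rewirings
    that disconnect the graph are redrawn (bounded retries), since L is
    undefined on disconnected graphs.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    if not is_connected(weights):
        raise ValueError("small-worldness requires a connected graph")
    C, _ = clustering_coefficient(weights)
    L = characteristic_path_length(weights)
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    c_vals, l_vals = [], []
    for child in ss.spawn(n_null):
        rng = np.random.default_rng(child)
        for attempt in range(max_retries):
            null = maslov_sneppen_rewire(weights, rng)
            if is_connected(null):
                break
        else:
            raise RuntimeError(
                f"rewiring failed to produce a connected null in "
                f"{max_retries} attempts")
        c_k, _ = clustering_coefficient(null)
        c_vals.append(c_k)
        l_vals.append(characteristic_path_length(null))
    C_rand = float(np.mean(c_vals))
    L_rand = float(np.mean(l_vals))
    if C_rand == 0 or L == 0:
        S = 0.0
    else:
        S = (C / C_rand) / (L / L_rand)
    return SmallWorldResult(S=float(S), C=C, L=L, C_rand=C_rand, L_rand=L_rand)


# ---------------------------------------------------------------------------
# admission

@dataclass
class AdmissibilityRecord:
    """Per-threshold goodness-criteria outcome."""

    threshold: float
    connected: bool
    Q: float
    C: float
    L: float
    C_rand: float
    L_rand: float
    S: float
    admitted: bool
    n_modules: int = 0
    modularity: ModularityResult | None = field(default=None, repr=False)


def evaluate_graph(graph: ThresholdedGraph, n_null: int = 100,
                   seed: int | np.random.SeedSequence = 0) -> AdmissibilityRecord:
    """Apply the three goodness criteria to one thresholded graph."""
    connected = is_connected(graph.weights)
    if not connected:
        return AdmissibilityRecord(graph.threshold, False, *(np.nan,) * 6,
                                   admitted=False)
    mod = newman_modularity(graph.weights)
    sw = small_worldness(graph.weights, n_null=n_null, seed=seed)
    admitted = connected and mod.Q > Q_CUTOFF and sw.S > S_CUTOFF
    return AdmissibilityRecord(
        threshold=graph.threshold, connected=True, Q=mod.Q, C=sw.C, L=sw.L,
        C_rand=sw.C_rand, L_rand=sw.L_rand, S=sw.S, admitted=admitted,
        n_modules=mod.n_modules, modularity=mod)


def admissibility_sweep(group: GroupGraph, spec: ThresholdSpec | None = None,
                        n_null: int = 100, seed: int = 0
                        ) -> tuple[list[ThresholdedGraph], list[AdmissibilityRecord]]:
    """Threshold the group graph and screen every level."""
    graphs = apply_thresholds(group, spec)
    ss = np.random.SeedSequence(seed)
    records = [evaluate_graph(g, n_null=n_null, seed=child)
               for g, child in zip(graphs, ss.spawn(len(graphs)))]
    return graphs, records


def admit_graphs(records: list[AdmissibilityRecord]) -> list[AdmissibilityRecord]:
    """Records passing connectedness, Q > 0.3 and S > 1."""
    return [r for r in records if r.admitted]


def records_to_frame(records: list[AdmissibilityRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {"threshold": r.threshold, "connected": r.connected, "Q": r.Q,
         "C": r.C, "L": r.L, "C_rand": r.C_rand, "L_rand": r.L_rand,
         "S": r.S, "admitted": r.admitted}
        for r in records
    ])
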