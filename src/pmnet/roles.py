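"""Node centralities and the two-stage hub characterization.

Stage 1 screens every node across the admitted thresholds: a node whose
participation coefficient exceeds the third quartile of the network at
both the lowest and the highest admitted threshold is a connector hub;
one whose within-module degree z-score does so is a provincial hub;
nodes passing the cutoff only at occasional thresholds stay nonhubs.

Stage 2 subclassifies hubs on the selected analysis graph by strength
and node betweenness centrality relative to the network median (second
quartile): rich central (both above), rich (strength only), poor central
(betweenness only), poor (neither).  Nonhubs with both strength and
betweenness below the first quartile are peripheral; the remaining
nonhubs go unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .paths import weights_to_lengths
from .roi import RoiSet

HUB_TYPES = ("connector", "provincial", "nonhub")
SUBTYPES = ("rich_central", "rich", "poor_central", "poor",
            "peripheral", "unclassified")


def node_strength(weights: np.ndarray) -> np.ndarray:
    """s_i = sum of weights of all edges at node i."""
    W = np.asarray(weights, dtype=float)
    return W.sum(axis=1)


def participation_coefficient(weights: np.ndarray, affiliation: np.ndarray,
                              weighted: bool = True) -> np.ndarray:
    """y_i = 1 - sum_m (k_i(m)/k_i)^2 over the module set M.

    ``weighted`` uses strengths for the per-module link counts (matching
    the weighted-undirected graph); the binary variant counts links.
    Isolated nodes get y_i = 0.
    """
    W = np.asarray(weights, dtype=float)
    if not weighted:
        W = (W > 0).astype(float)
    aff = np.asarray(affiliation)
    k = W.sum(axis=1)
    y = np.zeros(W.shape[0])
    nonzero = k > 0
    for m in np.unique(aff):
        km = W[:, aff == m].sum(axis=1)
        y[nonzero] += (km[nonzero] / k[nonzero]) ** 2
    y[nonzero] = 1.0 - y[nonzero]
    return y


def within_module_degree_z(weights: np.ndarray, affiliation: np.ndarray,
                           weighted: bool = True, ddof: int = 1) -> np.ndarray:
    """z_i = (k_i(m_i) - mean_m) / sd_m of the within-module degree.

    Singleton modules and modules with zero within-degree spread give
    z_i = 0.
    """
    W = np.asarray(weights, dtype=float)
    if not weighted:
        W = (W > 0).astype(float)
    aff = np.asarray(affiliation)
    z = np.zeros(W.shape[0])
    for m in np.unique(aff):
        members = np.flatnonzero(aff == m)
        if members.size < 2:
            continue
        k_within = W[np.ix_(members, members)].sum(axis=1)
        sd = k_within.std(ddof=ddof)
        if sd > 0:
            z[members] = (k_within - k_within.mean()) / sd
    return z


def node_betweenness(weights: np.ndarray) -> np.ndarray:
    """Brandes betweenness on the connection-length (1/weight) matrix.

    Normalized by 1/((n-1)(n-2)) over ordered endpoint pairs, so values
    lie in [0, 1]; path endpoints are not counted as on the path.
    """
    W = np.asarray(weights, dtype=float)
    n = W.shape[0]
    lengths = weights_to_lengths(W)
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if np.isfinite(lengths[i, j]):
                G.add_edge(i, j, length=lengths[i, j])
    bc = nx.betweenness_centrality(G, weight="length", normalized=True)
    return np.array([bc[i] for i in range(n)])


# ---------------------------------------------------------------------------
# two-stage classification

@dataclass
class ThresholdMetrics:
    """Per-node metrics of one admitted thresholded graph."""

    threshold: float
    participation: np.ndarray
    wmdz: np.ndarray
    affiliation: np.ndarray


def _above_q3(values: np.ndarray) -> np.ndarray:
    return values > np.quantile(values, 0.75)


def classify_stage1(metrics: list[ThresholdMetrics]) -> tuple[np.ndarray, np.ndarray]:
    """Hub typing from the endpoint thresholds of the admitted range.

    Returns (hub_type per node, dual-qualification flags).  A node meeting
    both the connector and provincial criteria is assigned connector and
    flagged.  Requires at least two admitted thresholds.
    """
    if len(metrics) < 2:
        raise ValueError("stage-1 classification needs >= 2 admitted thresholds")
    ordered = sorted(metrics, key=lambda m: m.threshold)
    low, high = ordered[0], ordered[-1]
    connector = _above_q3(low.participation) & _above_q3(high.participation)
    provincial = _above_q3(low.wmdz) & _above_q3(high.wmdz)
    dual = connector & provincial
    hub_type = np.where(connector, "connector",
                        np.where(provincial, "provincial", "nonhub"))
    return hub_type, dual


def classify_stage2(hub_type: np.ndarray, strength: np.ndarray,
                    betweenness: np.ndarray) -> np.ndarray:
    """Subtype hubs by strength and betweenness on the analysis graph.

    Quartiles are taken over all nodes; "above" is strict (> Q2), "below"
    inclusive (<= Q2), matching the up/down-arrow convention.
    """
    q2_s = np.quantile(strength, 0.5)
    q2_b = np.quantile(betweenness, 0.5)
    subtype = np.full(len(hub_type), "unclassified", dtype=object)
    is_hub = hub_type != "nonhub"
    rich = strength > q2_s
    central = betweenness > q2_b
    subtype[is_hub & rich & central] = "rich_central"
    subtype[is_hub & rich & ~central] = "rich"
    subtype[is_hub & ~rich & central] = "poor_central"
    subtype[is_hub & ~rich & ~central] = "poor"
    return subtype


def identify_peripheral(hub_type: np.ndarray, strength: np.ndarray,
                        betweenness: np.ndarray) -> np.ndarray:
    """Nonhubs with both strength and betweenness below the first quartile."""
    q1_s = np.quantile(strength, 0.25)
    q1_b = np.quantile(betweenness, 0.25)
    return (hub_type == "nonhub") & (strength < q1_s) & (betweenness < q1_b)


def node_role_table(roiset: RoiSet, metrics: list[ThresholdMetrics],
                    strength: np.ndarray, betweenness: np.ndarray
                    ) -> pd.DataFrame:
    """Full two-stage assignment plus raw metrics per node.

    ``strength`` and ``betweenness`` belong to the selected analysis
    graph; the per-threshold metrics drive stage 1.
    """
    hub_type, dual = classify_stage1(metrics)
    subtype = classify_stage2(hub_type, strength, betweenness)
    peripheral = identify_peripheral(hub_type, strength, betweenness)
    subtype = subtype.copy()
    subtype[peripheral] = "peripheral"
    hemisphere = roiset.table["hemisphere"].to_numpy()
    table = pd.DataFrame({
        "node": roiset.names,
        "hemisphere": hemisphere,
        "hub_type": hub_type,
        "subtype": subtype,
        "dual_qualified": dual,
        "strength": strength,
        "betweenness": betweenness,
    })
    for m in sorted(metrics, key=lambda m: m.threshold):
        tag = f"{m.threshold:g}"
        table[f"pc_t{tag}"] = m.participation
        table[f"wmdz_t{tag}"] = m.wmdz
        table[f"module_t{tag}"] = m.affiliation
    return table
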