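"""Synthetic parieto-premotor cohorts with planted ground truth.

The generator emulates the study conditions the pipeline is built for:
40 subjects x 2 hemispheres x 37 ROIs of directed probabilistic
streamline counts.  Expected normalized weights are block-structured by a
planted module plan (within-module weight 0.05, between-module 0.005 by
default — a 10:1 contrast), scaled by planted hub boosts (connector hubs
triple their cross-module edges, provincial hubs their within-module
edges), damped on planted peripheral nodes, and multiplied by delta on
the left hemisphere for planted lateralized edges.

Counts are drawn as Poisson(waytotal * weight * subject noise), with a
mean-one lognormal subject noise factor per connection and hemisphere,
independently per direction.  A fixed mean-one lognormal per-pair
"anatomical" factor (``edge_sigma``) makes edge weights heterogeneous the
way real tractography counts are; it is part of the planted anatomy, not
noise, and is shared between hemispheres.  Everything is reproducible
from the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .io import SubjectConnectome
from .roi import RoiSet, default_roiset

DEFAULT_MODULE_PLAN = [
    ["hIP1", "hIP2", "hIP3", "PF", "PFm", "PGa", "Area44", "Area45", "PMv"],
    ["PFcm", "PFop", "PFt", "PGp", "IFJ1", "IFJ2", "IFS1", "IFS2"],
    ["hIP4", "hIP5", "hIP6", "hIP7", "hIP8", "hPO1", "IFS3", "IFS4", "PM6d1"],
    ["5Ci", "5L", "5M", "7A", "7M", "7P", "7PC",
     "PM6d2", "PM6d3", "PreSMA", "SMAproper"],
]

DEFAULT_LATERALIZED_EDGES = [
    ("hIP1", "Area44"), ("PGa", "PMv"), ("PFt", "IFJ1"), ("PFm", "IFJ2"),
    ("hIP6", "IFS3"), ("hPO1", "PM6d1"), ("5Ci", "PM6d2"), ("7A", "PreSMA"),
    ("7PC", "SMAproper"), ("5M", "PM6d3"),
]


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic cohort."""

    n_subjects: int = 40
    module_plan: list[list[str]] = field(
        default_factory=lambda: [list(m) for m in DEFAULT_MODULE_PLAN])
    w_within: float = 0.05
    w_between: float = 0.005
    connector_hubs: list[str] = field(default_factory=lambda: ["hIP3", "PM6d1"])
    provincial_hubs: list[str] = field(default_factory=lambda: ["Area45", "5L"])
    hub_boost: float = 3.0
    peripheral_nodes: list[str] = field(default_factory=lambda: ["PFop", "7M"])
    peripheral_factor: float = 0.4
    lateralized_edges: list[tuple[str, str]] = field(
        default_factory=lambda: [tuple(e) for e in DEFAULT_LATERALIZED_EDGES])
    delta: float = 2.0            # left/right expectation ratio
    noise_sigma: float = 0.2      # lognormal subject-noise scale
    edge_sigma: float = 0.5       # fixed per-pair anatomical heterogeneity
    waytotal: float = 100_000.0   # expected streamline budget per seed ROI
    seed: int = 0
    deterministic: bool = False   # replace Poisson by rounded expectation

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lateralized_edges"] = [list(e) for e in self.lateralized_edges]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        if "lateralized_edges" in d:
            d["lateralized_edges"] = [tuple(e) for e in d["lateralized_edges"]]
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Planted structure of a generated cohort."""

    affiliation: np.ndarray            # planted module id per node
    connector_hubs: list[str]
    provincial_hubs: list[str]
    peripheral_nodes: list[str]
    lateralized_edges: list[tuple[str, str]]
    delta: float
    roiset: RoiSet

    def to_dict(self) -> dict:
        return {
            "affiliation": [int(a) for a in self.affiliation],
            "connector_hubs": list(self.connector_hubs),
            "provincial_hubs": list(self.provincial_hubs),
            "peripheral_nodes": list(self.peripheral_nodes),
            "lateralized_edges": [list(e) for e in self.lateralized_edges],
            "delta": self.delta,
            "roi_names": list(self.roiset.names),
        }


def _planted_affiliation(spec: SyntheticSpec, roiset: RoiSet) -> np.ndarray:
    aff = np.full(len(roiset), -1, dtype=int)
    for label, module in enumerate(spec.module_plan):
        for name in module:
            i = roiset.index_of(name)
            if aff[i] != -1:
                raise ValueError(f"ROI {name!r} appears in two modules")
            aff[i] = label
    if np.any(aff == -1):
        missing = [roiset.names[i] for i in np.flatnonzero(aff == -1)]
        raise ValueError(f"module plan does not cover ROIs {missing}")
    return aff


def _mean_one_lognormal(rng: np.random.Generator, sigma: float,
                        size) -> np.ndarray:
    if sigma == 0:
        return np.ones(size)
    return rng.lognormal(mean=-sigma ** 2 / 2.0, sigma=sigma, size=size)


def _symmetric(rng_matrix: np.ndarray) -> np.ndarray:
    upper = np.triu(rng_matrix, k=1)
    return upper + upper.T


def expected_weights(spec: SyntheticSpec, roiset: RoiSet,
                     hemisphere: str,
                     anatomy: np.ndarray | None = None) -> np.ndarray:
    """Planted expected normalized weight per ROI pair for one hemisphere.

    The deterministic block/boost/delta construction is validated to stay
    in [0, 1]; the random anatomical factor (if supplied) is clipped at 1,
    since normalized weights are probabilities.
    """
    aff = _planted_affiliation(spec, roiset)
    n = len(roiset)
    same = aff[:, None] == aff[None, :]
    E = np.where(same, spec.w_within, spec.w_between).astype(float)
    for name in spec.connector_hubs:
        i = roiset.index_of(name)
        E[i, ~same[i]] *= spec.hub_boost
        E[~same[i], i] *= spec.hub_boost
    for name in spec.provincial_hubs:
        i = roiset.index_of(name)
        E[i, same[i]] *= spec.hub_boost
        E[same[i], i] *= spec.hub_boost
    for name in spec.peripheral_nodes:
        i = roiset.index_of(name)
        E[i, :] *= spec.peripheral_factor
        E[:, i] *= spec.peripheral_factor
    if hemisphere == "left":
        for u, v in spec.lateralized_edges:
            i, j = roiset.index_of(u), roiset.index_of(v)
            E[i, j] *= spec.delta
            E[j, i] *= spec.delta
    np.fill_diagonal(E, 0.0)
    if np.any(E > 1):
        i, j = np.argwhere(E > 1)[0]
        raise ValueError(
            f"expected weight exceeds 1 after boosts at "
            f"({roiset.names[i]}, {roiset.names[j]})")
    if anatomy is not None:
        E = np.minimum(E * anatomy, 1.0)
    return E


def generate_cohort(spec: SyntheticSpec
                    ) -> tuple[list[SubjectConnectome],
                               list[SubjectConnectome], SyntheticTruth]:
    """Draw a full cohort (left subjects, right subjects, planted truth)."""
    if spec.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if spec.delta <= 0:
        raise ValueError("delta must be positive")
    roisets = {h: default_roiset(h) for h in ("left", "right")}
    aff = _planted_affiliation(spec, roisets["left"])
    n = len(roisets["left"])

    ss = np.random.SeedSequence(spec.seed)
    anatomy_ss, noise_ss = ss.spawn(2)
    anatomy_rng = np.random.default_rng(anatomy_ss)
    anatomy = _symmetric(_mean_one_lognormal(anatomy_rng, spec.edge_sigma,
                                             (n, n)))
    np.fill_diagonal(anatomy, 0.0)

    expected = {h: expected_weights(spec, roisets[h], h, anatomy=anatomy)
                for h in ("left", "right")}
    waytotal = np.full(n, spec.waytotal)
    noise_rng = np.random.default_rng(noise_ss)

    cohort: dict[str, list[SubjectConnectome]] = {"left": [], "right": []}
    for s in range(spec.n_subjects):
        for h in ("left", "right"):
            lam = spec.waytotal * expected[h]
            if not spec.deterministic:
                factor = _symmetric(_mean_one_lognormal(
                    noise_rng, spec.noise_sigma, (n, n)))
                lam = lam * factor
            if spec.deterministic:
                counts = np.rint(lam)
            else:
                counts = noise_rng.poisson(lam).astype(float)
            # a seed cannot emit more streamlines than its waytotal
            counts = np.minimum(counts, spec.waytotal)
            np.fill_diagonal(counts, 0.0)
            cohort[h].append(SubjectConnectome(
                subject_id=f"sub-{s + 1:02d}", hemisphere=h,
                counts=counts, waytotal=waytotal.copy(),
                roiset=roisets[h]))

    truth = SyntheticTruth(
        affiliation=aff,
        connector_hubs=list(spec.connector_hubs),
        provincial_hubs=list(spec.provincial_hubs),
        peripheral_nodes=list(spec.peripheral_nodes),
        lateralized_edges=[tuple(e) for e in spec.lateralized_edges],
        delta=spec.delta,
        roiset=roisets["left"],
    )
    return cohort["left"], cohort["right"], truth


# ---------------------------------------------------------------------------
# recovery reporting

def _precision_recall(planted: set[str], detected: set[str]
                      ) -> tuple[float | None, float | None]:
    if not planted:
        return None, None
    tp = len(planted & detected)
    precision = tp / len(detected) if detected else None
    recall = tp / len(planted)
    return precision, recall


def truth_recovery_report(truth: SyntheticTruth,
                          affiliation: np.ndarray | None = None,
                          hub_type: np.ndarray | None = None,
                          subtype: np.ndarray | None = None,
                          significant_pairs: list[tuple[str, str]] | None = None,
                          tested_pairs: list[tuple[str, str]] | None = None,
                          ) -> dict:
    """How well pipeline output recovers the planted structure.

    Reports the adjusted Rand index of detected vs planted modules,
    precision/recall of connector, provincial and peripheral node
    recovery (None where nothing was planted), and — given the
    FDR-significant pair list — lateralization sensitivity and the
    realized false-discovery proportion.
    """
    names = truth.roiset.names
    report: dict = {}
    if affiliation is not None:
        report["module_ari"] = float(
            adjusted_rand_score(truth.affiliation, np.asarray(affiliation)))
    if hub_type is not None:
        hub_type = np.asarray(hub_type)
        for role, planted in (("connector", truth.connector_hubs),
                              ("provincial", truth.provincial_hubs)):
            detected = {names[i] for i in np.flatnonzero(hub_type == role)}
            prec, rec = _precision_recall(set(planted), detected)
            report[f"{role}_precision"] = prec
            report[f"{role}_recall"] = rec
    if subtype is not None:
        subtype = np.asarray(subtype)
        detected = {names[i] for i in np.flatnonzero(subtype == "peripheral")}
        prec, rec = _precision_recall(set(truth.peripheral_nodes), detected)
        report["peripheral_precision"] = prec
        report["peripheral_recall"] = rec
    if significant_pairs is not None:
        planted = {frozenset(e) for e in truth.lateralized_edges}
        detected = {frozenset(e) for e in significant_pairs}
        hits = len(planted & detected)
        report["lateralization_sensitivity"] = (
            hits / len(planted) if planted else None)
        report["lateralization_fdp"] = (
            (len(detected) - hits) / len(detected) if detected else 0.0)
        if tested_pairs is not None:
            report["n_tested_pairs"] = len(tested_pairs)
    return report
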