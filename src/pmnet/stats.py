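"""Edge-wise lateralization tests and between-subject variability.

Each of the 322 parietal-premotor connections is compared between
hemispheres with a two-sided paired-sample t test across subjects;
p values are corrected by the Benjamini-Hochberg step-up false discovery
rate at alpha = 0.05.  Between-subject variability per connection is
summarized by the coefficient of variation (sample SD / mean) and grouped
into quartile clusters A (below Q1) through D (at or above Q3).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

CLUSTER_LABELS = ("A", "B", "C", "D")


def paired_t_per_edge(left: np.ndarray, right: np.ndarray) -> pd.DataFrame:
    """Two-sided paired t per edge from subject x edge weight arrays.

    Absent connections enter as weight 0 (a probabilistic count of zero is
    an observation).  Degenerate edges: all differences zero gives t = 0,
    p = 1; a nonzero constant difference (zero variance) gives the smallest
    representable p with ``degenerate`` flagged.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise ValueError("left and right must cover the same subjects and edges")
    n = left.shape[0]
    if n < 3:
        raise ValueError("need at least three subjects for a paired t test")
    diff = left - right
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 1)
    degenerate = sd == 0
    zero = degenerate & (mean == 0)
    const = degenerate & (mean != 0)
    t[zero], p[zero] = 0.0, 1.0
    t[const] = np.sign(mean[const]) * np.inf
    p[const] = np.nextafter(0, 1)
    return pd.DataFrame({"t": t, "p": p, "degenerate": degenerate})


def bh_fdr(p: np.ndarray, alpha: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg step-up adjusted p values and significance flags."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return pd.DataFrame({"p_adj": p_adj, "significant": p_adj <= alpha})


def edge_statistics(left: np.ndarray, right: np.ndarray,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Paired t tests with BH-FDR correction, one row per edge."""
    table = paired_t_per_edge(left, right)
    fdr = bh_fdr(table["p"].to_numpy(), alpha=alpha)
    return pd.concat([table, fdr], axis=1)


def coefficient_of_variation(values: np.ndarray) -> np.ndarray:
    """CV = sample SD / mean per edge; NaN where the mean is zero."""
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least two subjects for a CV")
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / mean, np.nan)
    return cv


def cv_quartile_clusters(cv: np.ndarray) -> np.ndarray:
    """Cluster defined CVs: A < Q1 <= B < Q2 <= C < Q3 <= D.

    Quartiles use linear interpolation over the defined (non-NaN) CVs;
    undefined CVs receive an empty label.
    """
    cv = np.asarray(cv, dtype=float)
    defined = ~np.isnan(cv)
    if defined.sum() < 4:
        raise ValueError("need at least four defined CV values")
    q1, q2, q3 = np.percentile(cv[defined], [25, 50, 75])
    clusters = np.full(cv.shape, "", dtype=object)
    vals = cv[defined]
    labels = np.where(vals < q1, "A",
                      np.where(vals < q2, "B",
                               np.where(vals < q3, "C", "D")))
    clusters[defined] = labels
    return clusters


def variability_table(values: np.ndarray) -> pd.DataFrame:
    """Mean, SD, CV and quartile cluster per edge for one hemisphere."""
    values = np.asarray(values, dtype=float)
    cv = coefficient_of_variation(values)
    return pd.DataFrame({
        "mean": values.mean(axis=0),
        "sd": values.std(axis=0, ddof=1),
        "cv": cv,
        "cluster": cv_quartile_clusters(cv),
    })
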