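"""Reading, validation and normalization of subject connectivity matrices.

The raw input is one directed ROI x ROI matrix of probabilistic streamline
counts per subject and hemisphere (row = seed ROI, column = target ROI),
together with a per-seed "waytotal" — the total number of streamlines
drawn from that seed.  Normalization divides each row by its waytotal so
entries become connection probabilities in [0, 1]; directional averaging
then yields the weighted-undirected connectome P_ij = (d_ij + d_ji) / 2.

Only parietal-premotor ("interlobar") pairs enter the edge-level analyses;
:func:`mask_interlobar` records that restriction as a boolean mask, leaving
masked entries absent (no edge) rather than zero-weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .roi import RoiSet


@dataclass
class SubjectConnectome:
    """Directed streamline counts and waytotals for one subject/hemisphere."""

    subject_id: str
    hemisphere: str
    counts: np.ndarray           # n x n, nonnegative, row = seed
    waytotal: np.ndarray         # per-seed total streamline count
    roiset: RoiSet

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.waytotal = np.asarray(self.waytotal, dtype=float)
        n = len(self.roiset)
        if self.counts.shape != (n, n):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{n} ROIs for subject {self.subject_id!r}")
        if self.waytotal.shape != (n,):
            raise ValueError(
                f"waytotal length {self.waytotal.shape} does not match {n} ROIs")
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at ({self.roiset.names[i]}, "
                f"{self.roiset.names[j]}) for subject {self.subject_id!r}")


@dataclass
class NormalizedConnectome:
    """Symmetric normalized weights P_ij with an optional interlobar mask.

    ``mask`` is None until :func:`mask_interlobar` is applied; afterwards it
    marks the retained parietal-premotor pairs.  Weights on masked-out pairs
    are kept in the array (the full graph is still used for graph admission)
    but are treated as absent edges by the edge-level analyses.
    """

    weights: np.ndarray
    roiset: RoiSet
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.roiset)
        if self.weights.shape != (n, n):
            raise ValueError("weights shape does not match RoiSet")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("weights must be symmetric")

    def interlobar_values(self) -> np.ndarray:
        """Weights of the retained parietal-premotor pairs, in pair order."""
        pairs = self.roiset.interlobar_pairs()
        return np.array([self.weights[i, j] for i, j in pairs])


# ---------------------------------------------------------------------------
# parsing

def _sniff_delimiter(first_line: str) -> str | None:
    if "," in first_line:
        return ","
    if "\t" in first_line:
        return "\t"
    return None  # whitespace


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_connectivity_matrix(
    path: str | Path,
    roiset: RoiSet,
    waytotal: np.ndarray | float | None = None,
    waytotal_path: str | Path | None = None,
    subject_id: str | None = None,
    hemisphere: str = "left",
) -> SubjectConnectome:
    """Read a CSV/TSV/whitespace connectivity matrix aligned to ``roiset``.

    The file may carry ROI labels as header row and first column, or be
    headerless with rows/columns in ``roiset`` order.  Waytotals come from
    ``waytotal_path`` (CSV with columns ``name,waytotal``), an explicit
    array, or a scalar applied to every seed.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty matrix file")
    sep = _sniff_delimiter(lines[0])

    def split(line: str) -> list[str]:
        return [t.strip() for t in (line.split(sep) if sep else line.split())]

    first = split(lines[0])
    headered = not all(_is_number(t) for t in first if t != "")
    n = len(roiset)
    if headered:
        col_labels = [t for t in first if t != ""]
        if len(col_labels) == n + 1:   # corner cell carried a label
            col_labels = col_labels[1:]
        for lab in col_labels:
            if lab not in roiset.names:
                raise ValueError(f"{path}: unknown ROI {lab!r} in header")
        if len(col_labels) != n:
            raise ValueError(
                f"{path}: {len(col_labels)} columns, expected {n}")
        matrix = np.full((n, n), np.nan)
        seen = set()
        for ln in lines[1:]:
            tokens = split(ln)
            row_label, values = tokens[0], tokens[1:]
            if row_label not in roiset.names:
                raise ValueError(f"{path}: unknown ROI {row_label!r}")
            if len(values) != n:
                raise ValueError(
                    f"{path}: row {row_label!r} has {len(values)} values, "
                    f"expected {n}")
            i = roiset.index_of(row_label)
            seen.add(row_label)
            for lab, v in zip(col_labels, values):
                matrix[i, roiset.index_of(lab)] = float(v)
        if len(seen) != n:
            missing = sorted(set(roiset.names) - seen)
            raise ValueError(f"{path}: missing rows for ROIs {missing}")
    else:
        rows = [[float(v) for v in split(ln)] for ln in lines]
        matrix = np.asarray(rows, dtype=float)
        if matrix.shape != (n, n):
            raise ValueError(
                f"{path}: matrix shape {matrix.shape}, expected {(n, n)}")

    if np.any(matrix < 0):
        i, j = np.argwhere(matrix < 0)[0]
        raise ValueError(
            f"{path}: negative entry at ({roiset.names[i]}, {roiset.names[j]})")

    if waytotal_path is not None:
        wt_table = pd.read_csv(waytotal_path)
        wt = np.array([float(wt_table.set_index("name")["waytotal"][name])
                       for name in roiset.names])
    elif waytotal is None:
        wt = np.ones(n)
    elif np.isscalar(waytotal):
        wt = np.full(n, float(waytotal))
    else:
        wt = np.asarray(waytotal, dtype=float)

    return SubjectConnectome(
        subject_id=subject_id or path.stem,
        hemisphere=hemisphere,
        counts=matrix,
        waytotal=wt,
        roiset=roiset,
    )


def write_connectivity_matrix(path: str | Path, matrix: np.ndarray,
                              roiset: RoiSet) -> None:
    """Write a labeled matrix CSV (ROI header row and first column)."""
    frame = pd.DataFrame(np.asarray(matrix, dtype=float),
                         index=roiset.names, columns=roiset.names)
    frame.to_csv(path, float_format="%.17g")


# ---------------------------------------------------------------------------
# normalization and symmetrization

def normalize_by_waytotal(conn: SubjectConnectome, clip: bool = False) -> np.ndarray:
    """Divide each row of counts by its seed waytotal.

    Entries exceeding the waytotal signal a data problem and are warned
    about; they are clipped to 1 only when ``clip=True``.
    """
    if np.any(conn.waytotal <= 0):
        bad = np.flatnonzero(conn.waytotal <= 0)
        names = [conn.roiset.names[i] for i in bad]
        raise ValueError(f"nonpositive waytotal for seed ROIs {names}")
    directed = conn.counts / conn.waytotal[:, None]
    if np.any(directed > 1):
        i, j = np.argwhere(directed > 1)[0]
        warnings.warn(
            f"count exceeds waytotal at ({conn.roiset.names[i]}, "
            f"{conn.roiset.names[j]}) for subject {conn.subject_id!r}")
        if clip:
            directed = np.minimum(directed, 1.0)
    return directed


def symmetrize_average(directed: np.ndarray) -> np.ndarray:
    """P_ij = (d_ij + d_ji) / 2 with a zeroed diagonal."""
    directed = np.asarray(directed, dtype=float)
    if directed.ndim != 2 or directed.shape[0] != directed.shape[1]:
        raise ValueError("directed matrix must be square")
    if np.any(directed < 0):
        raise ValueError("directed matrix must be nonnegative")
    sym = (directed + directed.T) / 2.0
    np.fill_diagonal(sym, 0.0)
    return sym


def normalize_connectome(conn: SubjectConnectome, clip: bool = False,
                         already_normalized: bool = False) -> NormalizedConnectome:
    """Waytotal-normalize and symmetrize one subject's counts."""
    directed = (conn.counts.astype(float) if already_normalized
                else normalize_by_waytotal(conn, clip=clip))
    return NormalizedConnectome(symmetrize_average(directed), conn.roiset)


def mask_interlobar(conn: NormalizedConnectome,
                    roiset: RoiSet | None = None) -> NormalizedConnectome:
    """Restrict the retained pair set to parietal-premotor pairs.

    Idempotent; the retained pair count is n_parietal x n_premotor
    (322 for the default atlas).
    """
    roiset = roiset or conn.roiset
    return replace(conn, mask=roiset.interlobar_mask())
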