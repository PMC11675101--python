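"""ROI metadata for parieto-premotor connectome analysis.

A :class:`RoiSet` is an ordered table of cortical regions of interest with
their lobe (``parietal`` or ``premotor``), a free-form subdomain label
(e.g. ``aIPS``, ``SPL``, ``IFS``), and hemisphere.  All matrices in the
pipeline are aligned to the ROI order of a RoiSet.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

PARIETAL = "parietal"
PREMOTOR = "premotor"
LOBES = (PARIETAL, PREMOTOR)
HEMISPHERES = ("left", "right")

# Julich-Brain style parcellation of the parieto-premotor network:
# 23 parietal + 14 premotor areas per hemisphere.
_DEFAULT_ROIS = [
    # parietal: anterior intraparietal sulcus
    ("hIP1", PARIETAL, "aIPS"),
    ("hIP2", PARIETAL, "aIPS"),
    ("hIP3", PARIETAL, "aIPS"),
    # parietal: inferior parietal lobule
    ("PF", PARIETAL, "IPL"),
    ("PFcm", PARIETAL, "IPL"),
    ("PFm", PARIETAL, "IPL"),
    ("PFop", PARIETAL, "IPL"),
    ("PFt", PARIETAL, "IPL"),
    ("PGa", PARIETAL, "IPL"),
    ("PGp", PARIETAL, "IPL"),
    # parietal: posterior intraparietal sulcus
    ("hIP4", PARIETAL, "pIPS"),
    ("hIP5", PARIETAL, "pIPS"),
    ("hIP6", PARIETAL, "pIPS"),
    ("hIP7", PARIETAL, "pIPS"),
    ("hIP8", PARIETAL, "pIPS"),
    ("hPO1", PARIETAL, "pIPS"),
    # parietal: superior parietal lobule
    ("5Ci", PARIETAL, "SPL"),
    ("5L", PARIETAL, "SPL"),
    ("5M", PARIETAL, "SPL"),
    ("7A", PARIETAL, "SPL"),
    ("7M", PARIETAL, "SPL"),
    ("7P", PARIETAL, "SPL"),
    ("7PC", PARIETAL, "SPL"),
    # premotor: ventrolateral prefrontal cortex
    ("Area44", PREMOTOR, "VLPFC"),
    ("Area45", PREMOTOR, "VLPFC"),
    # premotor: inferior frontal sulcus / junction
    ("IFJ1", PREMOTOR, "IFS"),
    ("IFJ2", PREMOTOR, "IFS"),
    ("IFS1", PREMOTOR, "IFS"),
    ("IFS2", PREMOTOR, "IFS"),
    ("IFS3", PREMOTOR, "IFS"),
    ("IFS4", PREMOTOR, "IFS"),
    # premotor: core premotor cortex
    ("PMv", PREMOTOR, "PMC"),
    ("PM6d1", PREMOTOR, "PMC"),
    ("PM6d2", PREMOTOR, "PMC"),
    ("PM6d3", PREMOTOR, "PMC"),
    # premotor: supplementary motor area
    ("PreSMA", PREMOTOR, "SMA"),
    ("SMAproper", PREMOTOR, "SMA"),
]


class RoiSet:
    """Ordered set of ROIs with lobe, subdomain and hemisphere labels.

    Parameters
    ----------
    table:
        DataFrame with columns ``name``, ``lobe``, ``subdomain``,
        ``hemisphere``.  Names must be unique; lobes must be ``parietal``
        or ``premotor``.
    """

    REQUIRED_COLUMNS = ("name", "lobe", "subdomain", "hemisphere")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"ROI table is missing columns: {missing}")
        table = table.loc[:, list(self.REQUIRED_COLUMNS)].reset_index(drop=True)
        names = table["name"].astype(str)
        if names.duplicated().any():
            dupes = sorted(names[names.duplicated()].unique())
            raise ValueError(f"duplicate ROI names: {dupes}")
        bad_lobes = set(table["lobe"]) - set(LOBES)
        if bad_lobes:
            raise ValueError(f"unknown lobe labels: {sorted(bad_lobes)}")
        self.table = table
        self.names: list[str] = list(names)
        self._index = {n: i for i, n in enumerate(self.names)}

    # -- basic container protocol -------------------------------------
    def __len__(self) -> int:
        return len(self.names)

    def __eq__(self, other) -> bool:
        return isinstance(other, RoiSet) and self.table.equals(other.table)

    def index_of(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown ROI {name!r}") from None

    # -- lobe structure ------------------------------------------------
    @property
    def lobes(self) -> np.ndarray:
        return self.table["lobe"].to_numpy()

    @property
    def parietal_indices(self) -> np.ndarray:
        return np.flatnonzero(self.lobes == PARIETAL)

    @property
    def premotor_indices(self) -> np.ndarray:
        return np.flatnonzero(self.lobes == PREMOTOR)

    @property
    def n_parietal(self) -> int:
        return int(self.parietal_indices.size)

    @property
    def n_premotor(self) -> int:
        return int(self.premotor_indices.size)

    @property
    def n_interlobar_pairs(self) -> int:
        """Number of parietal-premotor pairs (322 for the default atlas)."""
        return self.n_parietal * self.n_premotor

    def interlobar_mask(self) -> np.ndarray:
        """Boolean n x n matrix, True for parietal-premotor pairs."""
        parietal = self.lobes == PARIETAL
        mask = np.logical_xor.outer(parietal, parietal)
        np.fill_diagonal(mask, False)
        return mask

    def interlobar_pairs(self) -> list[tuple[int, int]]:
        """(parietal index, premotor index) pairs in table order."""
        return [(int(i), int(j)) for i in self.parietal_indices
                for j in self.premotor_indices]

    # -- I/O -------------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path) -> "RoiSet":
        return cls(pd.read_csv(path, dtype=str))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def default_roiset(hemisphere: str = "left") -> RoiSet:
    """The 37-ROI (23 parietal + 14 premotor) parieto-premotor atlas."""
    if hemisphere not in HEMISPHERES:
        raise ValueError(f"hemisphere must be one of {HEMISPHERES}")
    table = pd.DataFrame(_DEFAULT_ROIS, columns=["name", "lobe", "subdomain"])
    table["hemisphere"] = hemisphere
    return RoiSet(table)
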