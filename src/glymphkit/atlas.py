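"""Subcortical region atlas conventions shared by the PVS modules.

Regions follow the deep gray-matter structures commonly segmented for
perivascular-space quantification: caudate, putamen, pallidum, amygdala,
thalamus and hippocampus, coded separately per hemisphere.  The basal
ganglia (BG) aggregate is the union of caudate, putamen, pallidum and
amygdala.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["REGION_CODES", "BG_SUBDIVISIONS", "RegionAtlas", "write_region_lookup"]

#: region name -> integer label (left = odd offset 1, right = 2)
REGION_CODES: dict[str, int] = {
    "caudate_left": 11,
    "caudate_right": 12,
    "putamen_left": 21,
    "putamen_right": 22,
    "pallidum_left": 31,
    "pallidum_right": 32,
    "amygdala_left": 41,
    "amygdala_right": 42,
    "thalamus_left": 51,
    "thalamus_right": 52,
    "hippocampus_left": 61,
    "hippocampus_right": 62,
}

#: structures whose union forms the basal-ganglia aggregate
BG_SUBDIVISIONS: tuple[str, ...] = ("caudate", "putamen", "pallidum", "amygdala")

#: all base structure names (hemisphere-less)
STRUCTURES: tuple[str, ...] = (
    "caudate",
    "putamen",
    "pallidum",
    "amygdala",
    "thalamus",
    "hippocampus",
)


@dataclass
class RegionAtlas:
    """Label image of subcortical nuclei plus a GM+WM tissue mask."""

    labels: np.ndarray            # int label volume, 0 = unlabeled
    tissue_mask: np.ndarray       # bool, gray + white matter
    voxel_size: tuple[float, float, float]
    affine: np.ndarray
    codes: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.codes is None:
            self.codes = dict(REGION_CODES)
        self.labels = np.asarray(self.labels)
        self.tissue_mask = np.asarray(self.tissue_mask, dtype=bool)
        if self.labels.shape != self.tissue_mask.shape:
            raise ValueError("labels and tissue_mask must share a grid")

    def mask(self, region: str) -> np.ndarray:
        """Boolean mask for ``region``.

        ``region`` may be a coded name (``putamen_left``), a structure name
        (``putamen`` = both hemispheres), ``bg``/``bg_left``/``bg_right``
        for the basal-ganglia aggregate, or ``tissue``.
        """
        region = region.lower()
        if region == "tissue":
            return self.tissue_mask.copy()
        if region in self.codes:
            return self.labels == self.codes[region]
        if region in STRUCTURES:
            return self.mask(f"{region}_left") | self.mask(f"{region}_right")
        if region == "bg":
            out = np.zeros_like(self.tissue_mask)
            for s in BG_SUBDIVISIONS:
                out |= self.mask(s)
            return out
        if region in ("bg_left", "bg_right"):
            side = region.split("_")[1]
            out = np.zeros_like(self.tissue_mask)
            for s in BG_SUBDIVISIONS:
                out |= self.mask(f"{s}_{side}")
            return out
        raise KeyError(f"unknown region {region!r}")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))


def write_region_lookup(path: str | Path) -> None:
    """Dump the region-name <-> label-code lookup as JSON."""
    Path(path).write_text(json.dumps(REGION_CODES, indent=2, sort_keys=True) + "\n")
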