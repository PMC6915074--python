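"""Probability-level ROI masks.

Anatomical probability atlases assign each voxel to a region in some
percentage of reference subjects; a mask at probability level L contains
the voxels assigned in at least L% of subjects, so masks are nested and
shrink as the level rises. This module represents such hierarchies for the
two regions the pipeline uses (S1, primary and S2, secondary somatosensory
cortex), provides level-encoded NIfTI round-trip, and enforces the
voxel-count inclusion rule used when comparing decoding across levels
(only masks with strictly more than 500 voxels enter the comparison).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

REGIONS = ("S1", "S2")


class MaskLookupError(KeyError):
    """Unknown region or probability level."""


@dataclass
class MaskHierarchy:
    """Nested boolean voxel masks indexed by region and probability level.

    ``masks[region][level]`` is a flat boolean array over the session grid
    (C-order). Higher levels are subsets of lower levels within a region.
    """

    masks: dict[str, dict[int, np.ndarray]]
    voxel_coords: np.ndarray
    grid_shape: tuple[int, int, int]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        n = int(np.prod(self.grid_shape))
        for region, by_level in self.masks.items():
            levels = sorted(by_level)
            for lo, hi in zip(levels, levels[1:]):
                if np.any(by_level[hi] & ~by_level[lo]):
                    raise ValueError(
                        f"{region}: level {hi} mask not nested in level {lo}"
                    )
            for lev, m in by_level.items():
                if m.shape != (n,):
                    raise ValueError(
                        f"{region}@{lev}: mask not on the session grid"
                    )
                if not m.any():
                    warnings.warn(
                        f"{region}: empty mask at level {lev}", stacklevel=2
                    )

    @property
    def regions(self) -> list[str]:
        return list(self.masks)

    def levels(self, region: str) -> list[int]:
        self._check_region(region)
        return sorted(self.masks[region])

    def _check_region(self, region: str) -> None:
        if region not in self.masks:
            raise MaskLookupError(f"unknown region {region!r}")

    def voxel_count(self, region: str, level: int) -> int:
        return int(self.select({region}, level).sum())

    def select(self, regions, level: int) -> np.ndarray:
        """Boolean union of the requested regions' masks at one level.

        The most inclusive selectable mask is the union of all regions at
        the lowest level. An empty region set selects nothing.
        """
        n = int(np.prod(self.grid_shape))
        out = np.zeros(n, dtype=bool)
        for region in regions:
            self._check_region(region)
            if level not in self.masks[region]:
                raise MaskLookupError(f"{region}: no level {level}")
            out |= self.masks[region][level]
        return out

    def select_indices(self, regions, level: int) -> np.ndarray:
        return np.flatnonzero(self.select(regions, level))

    def usable_levels(self, region: str, min_voxels: int = 500) -> list[int]:
        """Levels whose mask has strictly more than ``min_voxels`` voxels."""
        self._check_region(region)
        return [
            lev
            for lev in self.levels(region)
            if int(self.masks[region][lev].sum()) > min_voxels
        ]

    # -- level-encoded NIfTI: voxel value = highest level containing it --

    def to_nifti(self, region: str) -> nib.Nifti1Image:
        self._check_region(region)
        encoded = np.zeros(int(np.prod(self.grid_shape)), dtype=np.int16)
        for lev in self.levels(region):  # ascending: later writes win
            encoded[self.masks[region][lev]] = lev
        return nib.Nifti1Image(
            encoded.reshape(self.grid_shape), self.affine
        )

    @classmethod
    def from_niftis(cls, images: dict[str, nib.Nifti1Image]) -> "MaskHierarchy":
        """Rebuild a hierarchy from level-encoded region images."""
        first = next(iter(images.values()))
        shape = tuple(first.shape[:3])
        affine = np.asarray(first.affine)
        from .data_io import grid_world_coords

        masks: dict[str, dict[int, np.ndarray]] = {}
        for region, img in images.items():
            enc = np.asarray(img.get_fdata()).reshape(-1).astype(int)
            levels = sorted(set(enc[enc > 0]))
            masks[region] = {lev: enc >= lev for lev in levels}
        return cls(
            masks=masks,
            voxel_coords=grid_world_coords(shape, affine),
            grid_shape=shape,
            affine=affine,
        )


def select_mask(h: MaskHierarchy, regions, level: int) -> np.ndarray:
    """Functional alias for :meth:`MaskHierarchy.select_indices`."""
    return h.select_indices(regions, level)


def usable_levels(h: MaskHierarchy, region: str, min_voxels: int = 500) -> list[int]:
    """Functional alias for :meth:`MaskHierarchy.usable_levels`."""
    return h.usable_levels(region, min_voxels)
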