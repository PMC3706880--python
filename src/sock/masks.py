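"""Fallback edge / CSF mask derivation from a brain mask.

The classifier normally consumes segmentation-derived masks supplied by the
user.  When none are available, the edge band can be approximated
morphologically from a brain mask, and a ventricle region can be declared
geometrically (boxes or ellipsoids in voxel coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from sock.ica_io import SockInputError

# 6-connected structuring element: one step along each axis per iteration,
# isotropic in index space.
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class Ellipsoid:
    """Axis-aligned ellipsoid in voxel coordinates: center and semi-axes."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def rasterize(self, grid_shape) -> np.ndarray:
        coords = np.indices(grid_shape, dtype=float)
        d2 = sum(
            ((coords[i] - self.center[i]) / self.semi_axes[i]) ** 2 for i in range(3)
        )
        return d2 <= 1.0


@dataclass
class Box:
    """Axis-aligned box in voxel coordinates: inclusive lower/upper corners."""

    lower: tuple[int, int, int]
    upper: tuple[int, int, int]

    def rasterize(self, grid_shape) -> np.ndarray:
        mask = np.zeros(grid_shape, dtype=bool)
        sl = tuple(
            slice(max(lo, 0), min(hi + 1, n))
            for lo, hi, n in zip(self.lower, self.upper, grid_shape)
        )
        mask[sl] = True
        return mask


@dataclass
class MaskConfig:
    """Configuration for fallback mask derivation."""

    edge_thickness_voxels: int = 1
    csf_regions: list = field(default_factory=list)  # Ellipsoid | Box

    def __post_init__(self) -> None:
        if self.edge_thickness_voxels < 1:
            raise SockInputError(
                f"edge_thickness_voxels must be >= 1, got {self.edge_thickness_voxels}"
            )


def derive_edge_mask(brain: np.ndarray, thickness: int = 1) -> np.ndarray:
    """Symmetric boundary band of a brain mask.

    Returns (brain dilated ``thickness`` times) minus (brain eroded
    ``thickness`` times), 6-connected per iteration.  The band straddles
    the topological boundary symmetrically; inner and outer sides get the
    same thickness.
    """
    brain = np.asarray(brain).astype(bool)
    if not brain.any():
        raise SockInputError("cannot derive an edge mask from an empty brain mask")
    if thickness < 1:
        raise SockInputError(f"edge thickness must be >= 1, got {thickness}")
    dilated = ndimage.binary_dilation(brain, structure=_STRUCT6, iterations=thickness)
    eroded = ndimage.binary_erosion(brain, structure=_STRUCT6, iterations=thickness)
    return dilated & ~eroded


def derive_csf_mask(brain: np.ndarray, config: MaskConfig) -> np.ndarray:
    """Union of the configured ventricle regions, clipped to the brain."""
    brain = np.asarray(brain).astype(bool)
    if not config.csf_regions:
        raise SockInputError("MaskConfig defines no CSF regions")
    mask = np.zeros(brain.shape, dtype=bool)
    for region in config.csf_regions:
        mask |= region.rasterize(brain.shape)
    mask &= brain
    if not mask.any():
        raise SockInputError(
            "configured CSF regions do not intersect the brain mask; "
            f"brain volume {int(brain.sum())}, regions {config.csf_regions}"
        )
    return mask
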