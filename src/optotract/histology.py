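"""3D reconstruction and quantification of serial-section fluorescence.

Segmented coronal sections are stacked into an anisotropic voxel block
(in-plane resolution × inter-slice spacing; 0.32 mm default spacing, i.e.
every 8th 40-µm section), per-region fluorescent volume statistics are
computed by voxel counting, and the fluorescence is projected onto the
cortical surface as the histological reference map against which
tractography is optimized.  Inter-slice gaps are not interpolated:
statistics are computed on the sampled slabs, which is unbiased for volume
fractions.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Literal, Mapping, Sequence

import numpy as np
from skimage.filters import threshold_otsu

from .surface import LabeledSurface
from .tracts import SurfaceMap

log = logging.getLogger("optotract")

UNASSIGNED = 0  # region code for fluorescence outside every mask


class EmptyFluorescenceError(ValueError):
    """No fluorescent voxels: the distribution over regions is undefined."""


@dataclasses.dataclass
class HistologyBlock:
    """Ordered stack of segmented sections registered into world space.

    ``slices`` is a 3D array whose first axis is the slicing axis when
    ``axis == 0`` (the array is stored with the slice axis first and the
    block's world orientation given by ``axis``); ``origin_mm`` is the
    world position of the block corner, voxel size is
    (slice_spacing, in_plane_res, in_plane_res) along (slice, row, col).
    """

    slices: np.ndarray
    in_plane_res_mm: float
    slice_spacing_mm: float = 0.32
    axis: int = 0
    origin_mm: np.ndarray = dataclasses.field(
        default_factory=lambda: np.zeros(3)
    )

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=float)
        if self.slices.ndim != 3:
            raise ValueError("slices must stack to a 3D array")
        if self.in_plane_res_mm <= 0 or self.slice_spacing_mm <= 0:
            raise ValueError("voxel dimensions must be > 0")
        if self.axis not in (0, 1, 2):
            raise ValueError("axis must be 0, 1 or 2")
        self.origin_mm = np.asarray(self.origin_mm, dtype=float).reshape(3)

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    @property
    def voxel_volume_mm3(self) -> float:
        return self.slice_spacing_mm * self.in_plane_res_mm**2

    @property
    def fluorescent_mask(self) -> np.ndarray:
        return self.slices > 0

    @property
    def fluorescent_volume_mm3(self) -> float:
        return float(self.fluorescent_mask.sum()) * self.voxel_volume_mm3

    def voxel_centers(self, mask: np.ndarray | None = None) -> np.ndarray:
        """World coordinates of voxel centers (all voxels or ``mask``)."""
        if mask is None:
            mask = np.ones(self.slices.shape, dtype=bool)
        idx = np.argwhere(mask).astype(float) + 0.5
        sizes = np.array(
            [self.slice_spacing_mm, self.in_plane_res_mm, self.in_plane_res_mm]
        )
        local = idx * sizes  # (slice, row, col) in block frame
        world = np.empty_like(local)
        order = [self.axis] + [a for a in range(3) if a != self.axis]
        world[:, order] = local
        return world + self.origin_mm

    def extent_along_axis_mm(self) -> float:
        """Distance between first and last slice centers."""
        return (self.n_slices - 1) * self.slice_spacing_mm


@dataclasses.dataclass
class RegionFluorescence:
    region: int
    share_of_total_pct: float
    fraction_of_region_pct: float

    def __post_init__(self) -> None:
        for v in (self.share_of_total_pct, self.fraction_of_region_pct):
            if not 0 <= v <= 100 + 1e-9:
                raise ValueError("percentages must lie in [0, 100]")


def segment_slices(
    raw_slices: Sequence[np.ndarray] | np.ndarray,
    method: Literal["otsu"] | tuple[Literal["fixed"], float] = "otsu",
) -> np.ndarray:
    """Binary fluorescence masks from raw intensity sections.

    ``method="otsu"`` thresholds each slice independently (robust to
    per-section staining variation); ``("fixed", th)`` applies one global
    threshold.  A constant-intensity slice defeats Otsu and falls back to
    all-background with a warning.
    """
    stack = np.asarray(raw_slices, dtype=float)
    if not np.isfinite(stack).all() or np.any(stack < 0):
        raise ValueError("intensities must be finite and non-negative")
    masks = np.zeros(stack.shape, dtype=bool)
    if method == "otsu":
        for i, sl in enumerate(stack):
            if np.ptp(sl) == 0:
                log.warning("slice %d is constant; otsu falls back to background", i)
                continue
            masks[i] = sl > threshold_otsu(sl)
    else:
        name, th = method
        if name != "fixed":
            raise ValueError("method must be 'otsu' or ('fixed', threshold)")
        masks = stack > th
    return masks


def reconstruct_block(
    masks: Sequence[np.ndarray] | np.ndarray,
    in_plane_res_mm: float,
    slice_spacing_mm: float = 0.32,
    origin_mm: np.ndarray | None = None,
    axis: int = 0,
) -> HistologyBlock:
    """Stack segmented sections into a world-registered block."""
    masks = list(np.asarray(m) for m in masks)
    if len(masks) < 1:
        raise ValueError("need at least one slice")
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise ValueError(f"mixed slice shapes: {sorted(shapes)}")
    stack = np.stack([m.astype(float) for m in masks])
    return HistologyBlock(
        slices=stack,
        in_plane_res_mm=in_plane_res_mm,
        slice_spacing_mm=slice_spacing_mm,
        axis=axis,
        origin_mm=np.zeros(3) if origin_mm is None else origin_mm,
    )


def region_stats(
    block: HistologyBlock,
    region_volumes: Mapping[int, np.ndarray],
) -> list[RegionFluorescence]:
    """Per-region fluorescent share and volume fraction by voxel counting.

    ``region_volumes`` maps region labels to boolean masks in block voxel
    space (disjoint).  ``share_of_total_pct`` distributes all fluorescent
    voxels over regions (an ``UNASSIGNED`` row collects voxels outside
    every mask, so shares sum to 100); ``fraction_of_region_pct`` is the
    fluorescent proportion of each region's own volume.
    """
    fluo = block.fluorescent_mask
    total = int(fluo.sum())
    if total == 0:
        raise EmptyFluorescenceError("block contains no fluorescence")
    covered = np.zeros(fluo.shape, dtype=bool)
    out = []
    for region, mask in sorted(region_volumes.items()):
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != fluo.shape:
            raise ValueError(f"region {region} mask shape mismatch")
        if np.any(mask & covered):
            raise ValueError("region masks must be disjoint")
        covered |= mask
        inter = int((fluo & mask).sum())
        region_vox = int(mask.sum())
        out.append(
            RegionFluorescence(
                region=region,
                share_of_total_pct=100.0 * inter / total,
                fraction_of_region_pct=(
                    100.0 * inter / region_vox if region_vox else 0.0
                ),
            )
        )
    unassigned = int((fluo & ~covered).sum())
    out.append(
        RegionFluorescence(
            region=UNASSIGNED,
            share_of_total_pct=100.0 * unassigned / total,
            fraction_of_region_pct=0.0,
        )
    )
    return out


def fluorescence_to_surface(
    block: HistologyBlock,
    surface: LabeledSurface,
    max_assign_dist_mm: float = 3.0,
) -> SurfaceMap:
    """Project fluorescent voxel volume onto nearest surface vertices.

    Every fluorescent voxel contributes its volume to its nearest vertex
    when that vertex lies within ``max_assign_dist_mm``; farther voxels are
    left unassigned (logged).  Total map mass therefore equals the assigned
    fluorescent volume exactly.
    """
    values = np.zeros(surface.n_vertices)
    centers = block.voxel_centers(block.fluorescent_mask)
    if len(centers) == 0:
        return SurfaceMap(values=values, kind="fluorescence")
    dist, nn = surface.kdtree.query(centers)
    ok = dist <= max_assign_dist_mm
    np.add.at(values, nn[ok], block.voxel_volume_mm3)
    n_out = int((~ok).sum())
    if n_out:
        log.info(
            "fluorescence_to_surface: %d voxels (%.3g mm^3) beyond %g mm left "
            "unassigned", n_out, n_out * block.voxel_volume_mm3,
            max_assign_dist_mm,
        )
    return SurfaceMap(values=values, kind="fluorescence")
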