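"""Volume/mask data model, NIfTI I/O, and mask geometry utilities.

The package operates on 3D proton-density MRI-like volumes with aligned
multi-label lesion masks.  Label semantics are fixed throughout:

    0 = background, 1 = EC (enchondroma), 2 = ACT (atypical cartilaginous tumor)

Voxel indices are 0-based; physical position of a voxel center is
``index * spacing`` (the orientation/affine matrix is applied only at the
I/O boundary).  No resampling happens anywhere: masks must match their
volume grid exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay, QhullError

logger = logging.getLogger(__name__)

BACKGROUND, EC, ACT = 0, 1, 2
VALID_LABELS = frozenset({BACKGROUND, EC, ACT})
LABEL_NAMES = {EC: "EC", ACT: "ACT"}

#: case-level classes
CLASSES = ("NT", "EC", "ACT")


class LoadError(ValueError):
    """Raised when a file cannot be interpreted as a valid volume or mask."""


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D scalar intensity lattice with physical voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise LoadError(f"expected 3 dimensions, got {data.ndim}")
        if not np.all(np.isfinite(data)):
            raise LoadError("volume contains non-finite voxels (NaN/Inf)")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise LoadError(f"spacing must be 3 positive values, got {self.spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)
        if self.affine is None:
            object.__setattr__(self, "affine", _affine_from_spacing(spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class MultiLabelMask:
    """A 3D integer label lattice aligned to a :class:`VolumeGrid`.

    Labels: 0=background, 1=EC, 2=ACT.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise LoadError(f"expected 3 dimensions, got {labels.ndim}")
        if not np.issubdtype(labels.dtype, np.integer):
            rounded = np.rint(labels)
            if not np.allclose(labels, rounded, atol=1e-6, equal_nan=False):
                raise LoadError("mask contains non-integer values")
            labels = rounded.astype(np.uint8)
        offending = set(np.unique(labels)) - VALID_LABELS
        if offending:
            raise LoadError(f"mask contains labels outside {{0,1,2}}: {sorted(offending)}")
        spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in spacing):
            raise LoadError(f"spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "labels", labels.astype(np.uint8))
        object.__setattr__(self, "spacing", spacing)
        if self.affine is None:
            object.__setattr__(self, "affine", _affine_from_spacing(spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def foreground_count(self) -> int:
        return int(np.count_nonzero(self.labels))

    def count(self, label: int) -> int:
        return int(np.count_nonzero(self.labels == label))

    def is_empty(self) -> bool:
        return self.foreground_count() == 0


@dataclass(frozen=True)
class ComponentInfo:
    """One connected foreground component of a multi-label mask."""

    component_id: int
    label: int
    voxel_count: int
    bbox: tuple[slice, slice, slice]


@dataclass
class CaseRecord:
    """One patient: volume, ground-truth mask, case-level class, inventory."""

    case_id: str
    volume: VolumeGrid
    gt_mask: MultiLabelMask | None
    case_class: str
    lesion_inventory: list[ComponentInfo] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.case_class not in CLASSES:
            raise ValueError(f"unknown case class {self.case_class!r}")
        if self.gt_mask is not None:
            if (self.case_class == "NT") != self.gt_mask.is_empty():
                raise ValueError(
                    "case_class NT requires an empty ground-truth mask and vice versa"
                )


def derive_case_class(mask: MultiLabelMask) -> str:
    """Case-level class from a mask: NT if empty, else the class of the
    largest connected lesion (when both tumor classes are present, the
    larger tumor defines the target class)."""
    comps = connected_components(mask)
    if not comps:
        return "NT"
    largest = max(comps, key=lambda c: c.voxel_count)
    return LABEL_NAMES[largest.label]


# --------------------------------------------------------------------------
# NIfTI I/O
# --------------------------------------------------------------------------

def _affine_from_spacing(spacing: Sequence[float]) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    return aff


def read_volume(path: str | Path) -> VolumeGrid:
    """Load a 3D NIfTI volume.

    Spacing comes from the header; intensities are unchanged apart from the
    header scl slope/intercept applied by nibabel.
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"file not found: {path}")
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise LoadError(f"expected 3 dimensions, got {len(img.shape)} in {path}")
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise LoadError(f"non-finite voxels in {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeGrid(data=data, spacing=spacing, affine=np.asarray(img.affine))


def write_volume(volume: VolumeGrid, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float64), volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path, reference: VolumeGrid) -> MultiLabelMask:
    """Load a multi-label mask and check it against its reference grid.

    A shape or spacing mismatch is an error — never a silent resampling.
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"file not found: {path}")
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise LoadError(f"expected 3 dimensions, got {len(img.shape)} in {path}")
    if tuple(img.shape) != reference.shape:
        raise LoadError(
            f"mask grid {tuple(img.shape)} does not match volume grid "
            f"{reference.shape} for {path}"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if not np.allclose(spacing, reference.spacing, rtol=1e-3):
        raise LoadError(
            f"mask spacing {spacing} does not match volume spacing "
            f"{reference.spacing} for {path}"
        )
    data = np.asarray(img.get_fdata())
    return MultiLabelMask(labels=data, spacing=reference.spacing,
                          affine=np.asarray(img.affine))


def write_mask(mask: MultiLabelMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.labels.astype(np.uint8), mask.affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


# --------------------------------------------------------------------------
# Geometry utilities
# --------------------------------------------------------------------------

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def connected_components(
    mask: MultiLabelMask,
    class_filter: int | None = None,
    connectivity: int = 26,
) -> list[ComponentInfo]:
    """Per-class connected components, ordered by first voxel in raster order.

    Default 26-connectivity (the most permissive 3D neighborhood).
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    structure = _STRUCTURES[connectivity]
    labels_to_scan = [class_filter] if class_filter is not None else [EC, ACT]
    comps: list[ComponentInfo] = []
    entries = []
    for lab in labels_to_scan:
        binary = mask.labels == lab
        if not binary.any():
            continue
        lbl, n = ndimage.label(binary, structure=structure)
        slices = ndimage.find_objects(lbl)
        for k in range(1, n + 1):
            sl = slices[k - 1]
            count = int(np.count_nonzero(lbl[sl] == k))
            # raster position of the component's first voxel, for a stable order
            first = np.argwhere(lbl == k)[0]
            raster = int(np.ravel_multi_index(tuple(first), mask.shape))
            entries.append((raster, lab, count, sl))
    entries.sort(key=lambda e: e[0])
    for cid, (_, lab, count, sl) in enumerate(entries):
        comps.append(ComponentInfo(component_id=cid, label=lab,
                                   voxel_count=count, bbox=sl))
    return comps


def _component_maps(mask: MultiLabelMask, connectivity: int = 26):
    """Yield (label, boolean map) per component in raster order."""
    structure = _STRUCTURES[connectivity]
    entries = []
    for lab in (EC, ACT):
        binary = mask.labels == lab
        if not binary.any():
            continue
        lbl, n = ndimage.label(binary, structure=structure)
        for k in range(1, n + 1):
            where = lbl == k
            first = np.argwhere(where)[0]
            raster = int(np.ravel_multi_index(tuple(first), mask.shape))
            entries.append((raster, lab, where))
    entries.sort(key=lambda e: e[0])
    return [(lab, where) for _, lab, where in entries]


def _hull_fill_component(where: np.ndarray) -> np.ndarray | None:
    """Boolean map of all voxel centers inside the convex hull of a component.

    Returns None when the hull is degenerate (< 4 non-coplanar voxels).
    """
    pts = np.argwhere(where).astype(np.float64)
    if len(pts) < 4:
        return None
    try:
        tri = Delaunay(pts)
    except QhullError:
        return None  # coplanar / collinear component
    lo = pts.min(axis=0).astype(int)
    hi = pts.max(axis=0).astype(int)
    grid = np.stack(
        np.meshgrid(*[np.arange(lo[d], hi[d] + 1) for d in range(3)], indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    inside = tri.find_simplex(grid.astype(np.float64)) >= 0
    out = np.zeros(where.shape, dtype=bool)
    coords = grid[inside]
    out[coords[:, 0], coords[:, 1], coords[:, 2]] = True
    return out


def fill_holes_convex(mask: MultiLabelMask, connectivity: int = 26) -> MultiLabelMask:
    """Fill each foreground component to its 3D convex hull (per class).

    Every voxel whose center lies inside the convex hull of a component's
    voxel centers receives that component's label.  Filling is iterated to a
    fixed point so the operation is idempotent even when filled components
    merge.  Original foreground labels are never overwritten; when the hulls
    of two components compete for a background voxel, the component earlier
    in raster order wins (logged).
    """
    current = mask.labels.copy()
    for _ in range(10):  # fixed-point iteration; converges in 1-2 passes
        m = MultiLabelMask(labels=current, spacing=mask.spacing, affine=mask.affine)
        new = current.copy()
        claimed = current > 0
        conflict = False
        for lab, where in _component_maps(m, connectivity):
            filled = _hull_fill_component(where)
            if filled is None:
                logger.debug("degenerate hull (<4 non-coplanar voxels); left unchanged")
                continue
            add = filled & ~claimed
            if (filled & claimed & ~where & (current != lab)).any():
                conflict = True
            new[add] = lab
            claimed |= filled
        if conflict:
            logger.warning("overlapping hulls of distinct components; "
                           "earlier component (raster order) wins")
        if np.array_equal(new, current):
            break
        current = new
    return MultiLabelMask(labels=current, spacing=mask.spacing, affine=mask.affine)


def binarize(mask: MultiLabelMask) -> np.ndarray:
    """Aggregate tumor labels into a binary tumor-vs-background mask."""
    return (mask.labels > 0)


def surface_voxels(binary: np.ndarray) -> np.ndarray:
    """(N, 3) indices of boundary voxels of a binary mask.

    A foreground voxel is boundary iff at least one of its 6-neighbors is
    background or out of bounds.
    """
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        return np.empty((0, 3), dtype=np.intp)
    interior = ndimage.binary_erosion(
        binary, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    return np.argwhere(binary & ~interior)
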