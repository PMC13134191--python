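"""Mask providers: externally produced segmentations or a built-in toy segmenter.

The real study pipeline consumes voxel-wise multi-label lesion segmentations
from trained deep networks.  This module decouples the classification stages
from any particular segmenter: a :class:`MaskProvider` resolves a case id to
a predicted :class:`~chondropipe.imaging_core.MultiLabelMask`, either loaded
from a prediction directory (``<case_id>_pred.nii.gz``) or computed by a
deterministic rule-based toy segmenter good enough to exercise the full
two-stage pipeline on phantom cohorts.

The toy segmenter is intensity-affine invariant: it z-score normalizes the
volume, smooths in-plane, thresholds hyperintensities, filters components by
physical volume, and assigns EC/ACT per component from a high-frequency
energy score (variance of the high-pass residual inside the component).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .imaging_core import (
    ACT,
    EC,
    MultiLabelMask,
    VolumeGrid,
    read_mask,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ToySegmenterConfig:
    """Thresholds calibrated once on the default phantom cohort."""

    z_threshold: float = 4.8          # hyperintensity cut on the z-scored volume
    smooth_mm: float = 1.0            # in-plane Gaussian smoothing
    min_component_mm3: float = 60.0   # drop smaller components
    hf_threshold: float = 0.020       # HF energy score >= threshold -> ACT
    hf_smooth_mm: float = 0.9         # low-pass scale defining the HF residual
    score_erosion: int = 4            # in-plane core erosion before HF scoring
    boundary_erosion: int = 0         # optional shrink of predicted components

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ToySegmenterConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        from dataclasses import asdict
        Path(path).write_text(yaml.safe_dump(asdict(self)))


class MaskProvider:
    """Resolves case ids to predicted multi-label masks."""

    def __init__(self, mode: str, lookup=None, segmenter=None, volumes=None):
        self.mode = mode
        self._lookup = lookup or {}
        self._segmenter = segmenter
        self._volumes = volumes or {}
        self._cache: dict[str, MultiLabelMask] = {}

    def get(self, case_id: str) -> MultiLabelMask:
        if case_id in self._cache:
            return self._cache[case_id]
        if self.mode == "from_files":
            if case_id not in self._lookup:
                raise KeyError(f"no predicted mask for case {case_id!r}")
            mask = self._lookup[case_id]()
        else:
            if case_id not in self._volumes:
                raise KeyError(f"no volume registered for case {case_id!r}")
            mask = self._segmenter(self._volumes[case_id])
        self._cache[case_id] = mask
        return mask

    def case_ids(self):
        return list(self._lookup or self._volumes)


def load_predictions(directory: str | Path, manifest) -> MaskProvider:
    """Grid-checked predicted masks from ``<case_id>_pred.nii.gz`` files.

    ``manifest`` must provide case ids and reference volumes: either a
    :class:`~chondropipe.phantom.CohortManifest` (volumes read from disk) or a
    mapping case_id -> VolumeGrid.  Missing files raise; extra files are
    ignored with a warning.
    """
    from .imaging_core import read_volume

    directory = Path(directory)
    if hasattr(manifest, "entries"):
        refs = {e["case_id"]: e["volume_path"] for e in manifest.entries}
        get_ref = lambda cid: read_volume(refs[cid])
    else:
        refs = dict(manifest)
        get_ref = lambda cid: refs[cid]
    missing = [cid for cid in refs if not (directory / f"{cid}_pred.nii.gz").exists()]
    if missing:
        raise FileNotFoundError(f"missing predicted masks for cases: {missing}")
    known = {f"{cid}_pred.nii.gz" for cid in refs}
    extra = [p.name for p in directory.glob("*_pred.nii.gz") if p.name not in known]
    if extra:
        logger.warning("ignoring %d extra prediction files: %s", len(extra), extra[:5])
    lookup = {
        cid: (lambda cid=cid: read_mask(directory / f"{cid}_pred.nii.gz", get_ref(cid)))
        for cid in refs
    }
    return MaskProvider(mode="from_files", lookup=lookup)


# --------------------------------------------------------------------------
# Toy segmenter
# --------------------------------------------------------------------------

def toy_segment(volume: VolumeGrid, cfg: ToySegmenterConfig | None = None) -> MultiLabelMask:
    """Deterministic rule-based multi-label segmentation of a phantom volume.

    Pipeline: z-score normalization -> Gaussian smoothing -> threshold ->
    component volume filter -> per-component EC/ACT assignment by the
    high-frequency energy score.  No surviving component yields an empty mask.
    """
    cfg = cfg or ToySegmenterConfig()
    data = volume.data.astype(float)
    sd = data.std()
    z = (data - data.mean()) / sd if sd > 0 else np.zeros_like(data)
    sigma_vox = np.asarray([cfg.smooth_mm, cfg.smooth_mm, 0.0]) / np.asarray(volume.spacing)
    smooth = ndimage.gaussian_filter(z, sigma=sigma_vox)
    fore = smooth >= cfg.z_threshold
    labels = np.zeros(volume.shape, dtype=np.uint8)
    if fore.any():
        structure = ndimage.generate_binary_structure(3, 3)
        lbl, n = ndimage.label(fore, structure=structure)
        vox_vol = volume.voxel_volume
        # high-pass residual for class scoring, on the normalized volume
        hf_sigma = np.asarray([cfg.hf_smooth_mm, cfg.hf_smooth_mm, 0.0]) \
            / np.asarray(volume.spacing)
        residual = z - ndimage.gaussian_filter(z, sigma=hf_sigma)
        for k in range(1, n + 1):
            comp = lbl == k
            if comp.sum() * vox_vol < cfg.min_component_mm3:
                continue
            if cfg.boundary_erosion > 0:
                comp_er = ndimage.binary_erosion(
                    comp, structure=ndimage.generate_binary_structure(3, 1),
                    iterations=cfg.boundary_erosion)
                if comp_er.sum() * vox_vol >= cfg.min_component_mm3:
                    comp = comp_er
            # score the component core: the bright lesion edge is itself a
            # high-frequency structure and would swamp the interior texture.
            # Erode in-plane step by step, keeping the deepest non-empty core.
            in_plane = np.zeros((3, 3, 3), dtype=bool)
            in_plane[:, :, 1] = True
            core = comp
            for _ in range(cfg.score_erosion):
                nxt = ndimage.binary_erosion(core, structure=in_plane)
                if not nxt.any():
                    break
                core = nxt
            score = float(residual[core].var())
            labels[comp] = ACT if score >= cfg.hf_threshold else EC
    return MultiLabelMask(labels=labels, spacing=volume.spacing, affine=volume.affine)


def toy_provider(volumes: dict[str, VolumeGrid],
                 cfg: ToySegmenterConfig | None = None) -> MaskProvider:
    cfg = cfg or ToySegmenterConfig()
    return MaskProvider(mode="toy_segmenter",
                        segmenter=lambda v: toy_segment(v, cfg),
                        volumes=volumes)


def scout_specialist_pair(
    volumes: dict[str, VolumeGrid],
    cfg: ToySegmenterConfig | None = None,
) -> tuple[MaskProvider, MaskProvider]:
    """Two toy providers mirroring the study's role asymmetry.

    The scout is tuned conservative (higher threshold, larger minimum
    component: fewer false foregrounds on tumor-free volumes); the specialist
    is tuned sensitive (lower threshold: better boundary recall on tumor
    cases).
    """
    cfg = cfg or ToySegmenterConfig()
    scout_cfg = replace(cfg, z_threshold=cfg.z_threshold + 0.3,
                        min_component_mm3=cfg.min_component_mm3 * 1.5)
    specialist_cfg = replace(cfg, z_threshold=cfg.z_threshold - 0.4)
    return toy_provider(volumes, scout_cfg), toy_provider(volumes, specialist_cfg)
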