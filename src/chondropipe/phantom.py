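"""Synthetic MRI-like phantom cohorts with NT/EC/ACT lesions.

The generator emulates the geometry of a proton-density fat-suppressed MRI
cohort of knee/shoulder cartilaginous tumors — voxel spacing around
(0.6, 0.6, 4.5) mm, lesions occupying a small fraction of the volume, EC
(enchondroma) diameters around 14 ± 12 mm (lognormal), ACT (atypical
cartilaginous tumor) diameters around 54 ± 20 mm (truncated normal) — and
the texture phenotypes that separate the two tumor classes:

* ACT carries fine-scale voxelwise noise (elevated high-frequency wavelet
  energy) superimposed on several large homogeneous bright plateaus
  (elevated GLSZM large-area emphasis and zone variance), with overall
  higher intensity energy.
* EC is a smooth, regular, hyperintense lesion (high NGTDM strength) whose
  first two principal axes are nearly equal (higher shape Elongation =
  sqrt(λ2/λ1)), while ACT expands anisotropically in-plane.

Everything is a pure function of (params, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import mannwhitneyu

from .imaging_core import (
    ACT,
    EC,
    CaseRecord,
    MultiLabelMask,
    VolumeGrid,
    connected_components,
    derive_case_class,
    write_mask,
    write_volume,
)
from .stats import mann_whitney_r

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhantomParams:
    """Generation parameters.  Defaults are the study conditions at desk scale."""

    grid_shape: tuple[int, int, int] = (128, 128, 24)
    spacing_mm: tuple[float, float, float] = (0.6, 0.6, 4.5)
    # size laws (mm): EC lognormal matched to mean 14, sd 12; ACT normal(54, 20) > 10
    ec_diameter_mean_mm: float = 14.0
    ec_diameter_sd_mm: float = 12.0
    act_diameter_mean_mm: float = 54.0
    act_diameter_sd_mm: float = 20.0
    act_diameter_min_mm: float = 10.0
    # axis ratios (second/third semi-axis relative to the longest)
    ec_elongation_target: float = 0.90   # EC: near-isotropic leading plane
    act_elongation_target: float = 0.55  # ACT: anisotropic in-plane expansion
    ec_z_ratio: float = 0.35
    act_z_ratio: float = 0.30
    # texture amplitudes (intensity units on a [0, 1000] scale)
    background_mean: float = 300.0
    background_texture_sd: float = 40.0
    background_smooth_mm: float = 6.0
    bone_intensity: float = 130.0
    ec_base_intensity: float = 760.0
    act_base_intensity: float = 800.0
    ec_pattern_amplitude: float = 60.0
    ec_pattern_scale_mm: float = 8.0
    ec_high_freq_noise_sd: float = 3.0
    act_high_freq_noise_sd: float = 18.0
    act_blotch_zone_scale_mm: float = 9.0
    act_blotch_amplitude: float = 90.0
    act_blotch_levels: int = 4
    edge_softness: float = 0.25  # fraction of the ellipsoid radius that tapers
    intensity_range: tuple[float, float] = (0.0, 1000.0)
    # lesion voxel budget as a fraction of the grid (diameters resampled to fit)
    lesion_fraction_bounds: tuple[float, float] = (1e-4, 5e-2)
    margin_voxels: int = 2

    def __post_init__(self):
        if not (0 < self.act_elongation_target < self.ec_elongation_target <= 1):
            raise ValueError("need 0 < act_elongation_target < ec_elongation_target <= 1")
        for name in ("ec_diameter_mean_mm", "act_diameter_mean_mm",
                     "ec_pattern_scale_mm", "act_blotch_zone_scale_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CohortManifest:
    """Index of a generated cohort: per-case class, seed and file paths."""

    entries: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.entries, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortManifest":
        return cls(entries=json.loads(Path(path).read_text()))

    def case_ids(self) -> list[str]:
        return [e["case_id"] for e in self.entries]

    def classes(self) -> dict[str, str]:
        return {e["case_id"]: e["case_class"] for e in self.entries}


# --------------------------------------------------------------------------
# Size laws
# --------------------------------------------------------------------------

def sample_diameter(case_class: str, params: PhantomParams,
                    rng: np.random.Generator) -> float:
    """One diameter draw from the class size law (no grid constraint applied).

    EC ~ lognormal matched to mean/sd by moments; ACT ~ normal truncated at
    the stated minimum.
    """
    if case_class == "EC":
        m, s = params.ec_diameter_mean_mm, params.ec_diameter_sd_mm
        sigma2 = np.log(1.0 + (s / m) ** 2)
        mu = np.log(m) - sigma2 / 2.0
        return float(rng.lognormal(mu, np.sqrt(sigma2)))
    if case_class == "ACT":
        while True:
            d = rng.normal(params.act_diameter_mean_mm, params.act_diameter_sd_mm)
            if d > params.act_diameter_min_mm:
                return float(d)
    raise ValueError(f"no size law for class {case_class!r}")


def _semi_axes_mm(case_class: str, d: float, params: PhantomParams,
                  rng: np.random.Generator) -> np.ndarray:
    """Physical semi-axes (x, y, z) in mm for a lesion of diameter d."""
    sz = params.spacing_mm[2]
    if case_class == "EC":
        ax = d / 2.0
        ay = params.ec_elongation_target * ax
        az = params.ec_z_ratio * ax
    else:
        ax = d / 2.0
        ay = params.act_elongation_target * ax
        az = params.act_z_ratio * ax
    # lesions thinner than the slice spacing collapse to a single slice so the
    # through-plane axis cannot dominate the covariance of small lesions
    az = 0.45 * sz if az < sz else az
    return np.array([ax, ay, az])


# --------------------------------------------------------------------------
# Field helpers
# --------------------------------------------------------------------------

def _smooth_field(shape, spacing, scale_mm, rng) -> np.ndarray:
    """Unit-variance Gaussian random field with physical correlation length."""
    sigma_vox = np.asarray(scale_mm) / np.asarray(spacing)
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox)
    sd = f.std()
    return f / sd if sd > 0 else f


def _background(params: PhantomParams, rng: np.random.Generator) -> np.ndarray:
    shape, spacing = params.grid_shape, params.spacing_mm
    bg = params.background_mean + params.background_texture_sd * _smooth_field(
        shape, spacing, params.background_smooth_mm, rng
    )
    # bone-like bright ellipsoid along x through the volume, for segmenter context
    sp = np.asarray(spacing)
    coords = [np.arange(n) * s for n, s in zip(shape, sp)]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    cx = np.array([shape[0] * sp[0] / 2, shape[1] * sp[1] * 0.5, shape[2] * sp[2] * 0.5])
    axes = np.array([shape[0] * sp[0] * 0.6, shape[1] * sp[1] * 0.12,
                     shape[2] * sp[2] * 0.5])
    u = (((X - cx[0]) / axes[0]) ** 2 + ((Y - cx[1]) / axes[1]) ** 2
         + ((Z - cx[2]) / axes[2]) ** 2)
    profile = np.clip((1.0 - u) / 0.4, 0.0, 1.0)
    return bg + params.bone_intensity * profile


def _ellipsoid_field(shape, spacing, center_mm, axes_mm, angle_rad) -> np.ndarray:
    """Quadratic-form field u; the lesion is u <= 1 (in-plane rotated)."""
    sp = np.asarray(spacing)
    coords = [np.arange(n) * s for n, s in zip(shape, sp)]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    dx, dy, dz = X - center_mm[0], Y - center_mm[1], Z - center_mm[2]
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    rx = c * dx + s * dy
    ry = -s * dx + c * dy
    return (rx / axes_mm[0]) ** 2 + (ry / axes_mm[1]) ** 2 + (dz / axes_mm[2]) ** 2


def _lesion_texture(case_class: str, shape, params: PhantomParams,
                    rng: np.random.Generator) -> np.ndarray:
    """Interior intensity field of a lesion (full-grid array; masked later)."""
    spacing = params.spacing_mm
    if case_class == "EC":
        pattern = _smooth_field(shape, spacing, params.ec_pattern_scale_mm, rng)
        noise = rng.normal(0.0, params.ec_high_freq_noise_sd, shape)
        return params.ec_base_intensity + params.ec_pattern_amplitude * pattern + noise
    # ACT: quantized large plateaus + fine voxelwise noise
    blotch = _smooth_field(shape, spacing, params.act_blotch_zone_scale_mm, rng)
    qs = np.quantile(blotch, np.linspace(0, 1, params.act_blotch_levels + 1)[1:-1])
    level = np.digitize(blotch, qs).astype(float)
    noise = rng.normal(0.0, params.act_high_freq_noise_sd, shape)
    return (params.act_base_intensity
            + params.act_blotch_amplitude * (level - (params.act_blotch_levels - 1) / 2)
            + noise)


# --------------------------------------------------------------------------
# Case generation
# --------------------------------------------------------------------------

def _place_lesion(case_class: str, params: PhantomParams,
                  rng: np.random.Generator):
    """Draw a diameter and placement satisfying the grid and voxel-fraction
    constraints; up to 10 redraws, then an error."""
    shape = np.asarray(params.grid_shape)
    sp = np.asarray(params.spacing_mm)
    extent = shape * sp
    total_vox = int(np.prod(shape))
    lo_frac, hi_frac = params.lesion_fraction_bounds
    vox_vol = float(np.prod(sp))
    margin = params.margin_voxels * sp
    for _ in range(10):
        d = sample_diameter(case_class, params, rng)
        axes = _semi_axes_mm(case_class, d, params, rng)
        approx_vox = 4.0 / 3.0 * np.pi * np.prod(axes) / vox_vol
        frac = approx_vox / total_vox
        if not (lo_frac <= frac <= hi_frac):
            logger.debug("%s diameter %.1f mm -> fraction %.2g outside bounds; redrawn",
                         case_class, d, frac)
            continue
        half = axes + margin
        lo = half
        hi = extent - half
        if np.any(hi <= lo):
            logger.debug("%s diameter %.1f mm does not fit the grid; redrawn",
                         case_class, d)
            continue
        center = lo + rng.random(3) * (hi - lo)
        # snap the through-plane center to a slice so thin lesions always
        # intersect at least one voxel plane
        center[2] = np.round(center[2] / sp[2]) * sp[2]
        angle = rng.uniform(-np.pi / 6, np.pi / 6)
        return d, axes, center, angle
    raise ValueError(
        f"could not place a {case_class} lesion after 10 diameter redraws"
    )


def generate_case(case_class: str, params: PhantomParams | None = None,
                  seed: int = 0, case_id: str | None = None,
                  n_lesions: int = 1) -> CaseRecord:
    """Generate one phantom case; deterministic given (class, params, seed).

    NT cases carry an empty mask.  The optional two-lesion mode places a
    second, smaller lesion of the other class (used to exercise the
    larger-lesion-defines-class rule)."""
    params = params or PhantomParams()
    if case_class not in ("NT", "EC", "ACT"):
        raise ValueError(f"unknown case class {case_class!r}")
    rng = np.random.default_rng(seed)
    shape = params.grid_shape
    vol = _background(params, rng)
    labels = np.zeros(shape, dtype=np.uint8)

    if case_class != "NT":
        classes = [case_class]
        if n_lesions == 2:
            classes.append("EC" if case_class == "ACT" else "ACT")
        primary_count = None
        for k, cls in enumerate(classes):
            sub_params = params
            if k > 0:
                # secondary lesion: shrink the size law so the primary stays larger
                sub_params = PhantomParams(**{
                    **asdict(params),
                    "ec_diameter_mean_mm": 8.0, "ec_diameter_sd_mm": 2.0,
                    "act_diameter_mean_mm": 12.0, "act_diameter_sd_mm": 2.0,
                    "act_diameter_min_mm": 8.0,
                })
            d, axes, center, angle = _place_lesion(cls, sub_params, rng)
            u = _ellipsoid_field(shape, params.spacing_mm, center, axes, angle)
            inside = u <= 1.0
            if k > 0 and primary_count is not None:
                if inside.sum() >= primary_count:
                    continue  # secondary must stay smaller; skip rather than flip class
                inside &= labels == 0
            texture = _lesion_texture(cls, shape, params, rng)
            w = np.clip((1.0 - u) / params.edge_softness, 0.0, 1.0)
            vol = vol * (1 - w) + texture * w
            labels[inside] = EC if cls == "EC" else ACT
            if k == 0:
                primary_count = int(inside.sum())

    lo, hi = params.intensity_range
    vol = np.clip(vol, lo, hi)
    volume = VolumeGrid(data=vol, spacing=params.spacing_mm)
    mask = MultiLabelMask(labels=labels, spacing=params.spacing_mm)
    derived = derive_case_class(mask)
    if derived != case_class:
        raise RuntimeError(f"generated case derives class {derived}, requested {case_class}")
    return CaseRecord(
        case_id=case_id or f"{case_class}_{seed}",
        volume=volume,
        gt_mask=mask,
        case_class=case_class,
        lesion_inventory=connected_components(mask),
        meta={"seed": seed},
    )


def case_seed(master_seed: int, index: int) -> int:
    """Per-case seed: a stated, collision-free split of the master seed."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0]
               & 0x7FFFFFFF)


def generate_cohort_records(n_nt: int, n_ec: int, n_act: int,
                            params: PhantomParams | None = None,
                            master_seed: int = 0) -> list[CaseRecord]:
    """In-memory cohort with exact class counts and derived per-case seeds."""
    if min(n_nt, n_ec, n_act) < 0:
        raise ValueError("case counts must be nonnegative")
    if n_nt + n_ec + n_act == 0:
        raise ValueError("cohort must contain at least one case")
    params = params or PhantomParams()
    cases = []
    plan = [("NT", i) for i in range(n_nt)] + [("EC", i) for i in range(n_ec)] \
        + [("ACT", i) for i in range(n_act)]
    for idx, (cls, k) in enumerate(plan):
        seed = case_seed(master_seed, idx)
        cases.append(generate_case(cls, params, seed=seed,
                                   case_id=f"{cls.lower()}_{k:03d}"))
    return cases


def generate_cohort(n_nt: int, n_ec: int, n_act: int, out_dir: str | Path,
                    params: PhantomParams | None = None,
                    master_seed: int = 0) -> CohortManifest:
    """Write a cohort of NIfTI volume+mask pairs plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cases = generate_cohort_records(n_nt, n_ec, n_act, params, master_seed)
    manifest = CohortManifest()
    for case in cases:
        vol_path = out_dir / f"{case.case_id}.nii.gz"
        mask_path = out_dir / f"{case.case_id}_mask.nii.gz"
        write_volume(case.volume, vol_path)
        write_mask(case.gt_mask, mask_path)
        manifest.entries.append({
            "case_id": case.case_id,
            "case_class": case.case_class,
            "seed": case.meta["seed"],
            "volume_path": str(vol_path),
            "mask_path": str(mask_path),
        })
    manifest.to_json(out_dir / "manifest.json")
    return manifest


# --------------------------------------------------------------------------
# Separability report
# --------------------------------------------------------------------------

#: the six discriminative feature families and their expected direction
#: (class with the higher median)
SEPARABILITY_CHECKS = (
    ("wavelet-HHH_firstorder_TotalEnergy", "ACT"),
    ("original_glszm_LargeAreaEmphasis", "ACT"),
    ("logarithm_firstorder_TotalEnergy", "ACT"),
    ("original_glszm_ZoneVariance", "ACT"),
    ("original_ngtdm_Strength", "EC"),
    ("original_shape_Elongation", "EC"),
)


def separability_report(cases: list[CaseRecord],
                        feature_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Group medians, Mann-Whitney effect size r, and direction checks for the
    six discriminative feature families, over the tumor cases of a cohort.

    ``feature_table`` (cases x features, indexed by case_id) may be passed to
    reuse an existing extraction; otherwise features are extracted here.
    """
    from .radiomics import extract_all  # local import: avoid cycle at module load

    tumor = [c for c in cases if c.case_class in ("EC", "ACT")]
    n_ec = sum(c.case_class == "EC" for c in tumor)
    n_act = sum(c.case_class == "ACT" for c in tumor)
    if n_ec < 5 or n_act < 5:
        raise ValueError(f"need >= 5 cases per tumor class, got EC={n_ec}, ACT={n_act}")
    if feature_table is None:
        rows = {c.case_id: extract_all(c.volume, c.gt_mask) for c in tumor}
        feature_table = pd.DataFrame.from_dict(rows, orient="index")
    classes = pd.Series({c.case_id: c.case_class for c in tumor})
    classes = classes.loc[feature_table.index]
    records = []
    for feat, higher_in in SEPARABILITY_CHECKS:
        x_act = feature_table.loc[classes == "ACT", feat].to_numpy()
        x_ec = feature_table.loc[classes == "EC", feat].to_numpy()
        u, p = mannwhitneyu(x_act, x_ec, alternative="two-sided")
        n = len(x_act) + len(x_ec)
        r = mann_whitney_r(x_act, x_ec)
        med_act, med_ec = float(np.median(x_act)), float(np.median(x_ec))
        observed = "ACT" if med_act > med_ec else "EC"
        records.append({
            "feature": feat,
            "median_EC": med_ec,
            "median_ACT": med_act,
            "effect_size_r": r,
            "p_value": float(p),
            "expected_higher_in": higher_in,
            "observed_higher_in": observed,
            "direction_ok": observed == higher_in,
        })
    return pd.DataFrame.from_records(records)
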