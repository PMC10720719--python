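"""Synthetic multi-subject, multi-timepoint MEMRI cohort generator.

The phantom emulates the structure of a longitudinal Mn(II) tract-tracing
study in mouse: each subject is imaged at four sessions (pre-injection,
30 min, 6 h, 24 h) at nominally 0.1 mm isotropic resolution.  A brain-shaped
template (nested ellipsoidal compartments with a smooth deterministic
texture) is warped by a per-subject rigid misalignment plus a mild smooth
deformation, modulated by a multiplicative bias field and a global intensity
scale, and degraded by additive Gaussian noise.  The manganese injection is
biphasic: a hypo-intense core (high local Mn(II) concentration darkens the
T1-weighted signal) surrounded by a hyper-intense halo, both fading over the
6 h and 24 h sessions.  Distal tract transport is emulated by planting
per-segment multiplicative intensity enhancements on a group-specific
schedule.  Every random choice derives from the spec seed, and the generator
returns the complete ground truth (transforms, injection centroids, applied
schedule) so downstream stages can be scored against it.

Axis convention: RAS+ world mm; x is medio-lateral (positive right of the
midline), y antero-posterior (positive anterior), z dorso-ventral (positive
dorsal).  Bregma is not an image feature and is carried as atlas metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .atlas import AtlasBundle, LabelInfo
from .image import VolumeImage, save_volume
from .transforms import ComposedTransform, RigidTransform, Transform, WarpTransform, resample

__all__ = [
    "TIMEPOINTS",
    "InjectionPlan",
    "GroupPlan",
    "PhantomSpec",
    "SubjectSession",
    "SubjectTruth",
    "PhantomTruth",
    "make_phantom_atlas",
    "simulate_subject",
    "simulate_cohorts",
]

TIMEPOINTS = ("pre", "30min", "6h", "24h")

# Reference brain semi-axes (mm) at which the segment geometry below is laid
# out; other brain sizes scale the whole geometry proportionally.
_REF_SEMI = np.array([3.0, 2.4, 1.7])

# Segment geometry at reference scale: (abbrev, name, center mm, semi-axes mm,
# bilateral?, is_tract?).  Bilateral entries are mirrored about the midline
# x = 0 and painted with identical ordering so voxel counts match exactly.
# Placement keeps every segment of one group's target set >= ~0.45 mm clear
# of the other group's targets so smoothing/registration bleed from a planted
# enhancement cannot spill into a segment planted for the other cohort.
_SEGMENT_TABLE = [
    ("ACA", "anterior cingulate-like area", (0.50, 0.74, 0.78), (0.45, 0.45, 0.55), True, False),
    ("ILPL", "infralimbic/prelimbic-like area", (0.50, 1.62, -0.15), (0.45, 0.30, 0.45), True, False),
    ("DS", "dorsal striatum", (1.60, 0.90, 0.15), (0.45, 0.55, 0.45), True, False),
    ("RTN", "reticular nucleus of thalamus", (1.10, -0.40, 0.10), (0.38, 0.42, 0.38), True, False),
    ("SNr", "substantia nigra reticulata", (0.90, -1.50, -0.35), (0.42, 0.42, 0.37), True, False),
    ("BLA", "basolateral amygdala", (2.10, 0.0, -0.72), (0.36, 0.40, 0.32), True, False),
    ("LC", "locus coeruleus", (0.60, -2.00, 0.05), (0.33, 0.36, 0.32), True, False),
    ("PAG", "periaqueductal gray", (0.0, -1.70, 0.55), (0.45, 0.50, 0.40), False, False),
    ("CC", "corpus callosum (fiber tract)", (0.0, 0.60, 1.20), (1.20, 0.50, 0.10), False, True),
    ("AHN", "anterior hypothalamic nucleus", (0.40, 0.85, -0.90), (0.38, 0.34, 0.34), True, False),
    ("DMH", "dorsomedial hypothalamic nucleus", (0.40, -0.55, -0.85), (0.38, 0.30, 0.34), True, False),
    ("MBO", "mammillary body", (0.35, -1.15, -1.00), (0.35, 0.34, 0.32), True, False),
    ("LHA", "lateral hypothalamic area", (0.85, 0.42, -0.98), (0.36, 0.32, 0.30), True, False),
    ("HYP", "hypothalamus (parent, unassigned)", (0.0, -0.10, -0.95), (1.55, 1.75, 0.68), False, False),
]
_HYP_SUBSEGMENTS = ("AHN", "DMH", "MBO", "LHA")
_HYP_PARENT = "HYP"
# unassigned parent voxels keep a moat around every named segment so planted
# effects (after 0.3 mm smoothing and residual registration error) cannot
# bleed into the parent
_PARENT_MOAT_MM = 0.5

# Tissue model: a dominant white-matter-like plateau at 100 provides the
# sharp histogram mode used for modal scaling and noise calibration; a thin
# brighter cortical shell (118) and deep gray (108) add moderate contrast
# that survives polynomial bias correction without smearing the mode.  The
# hypo-intense injection core (core_factor ~0.3) is far darker than any
# tissue, as for high local Mn(II) concentrations in vivo.
_WM_VALUE = 100.0
_DEEPGRAY_VALUE = 108.0
_CORTEX_VALUE = 118.0
_TISSUE_MODE = 100.0
_TEXTURE_AMPLITUDE = 9.0
_BREGMA_Y_REF = 0.40


@dataclass
class InjectionPlan:
    """Stereotaxic placement and biphasic bolus shape of one group's injection.

    Coordinates follow the stereotaxic convention: ``ml_mm`` right of the
    midline, ``ap_mm`` anterior of bregma, ``dv_mm`` below the *brain surface*
    (negative down).  ``core_factor`` (< 1) darkens the hypo-intense core;
    ``halo_factor`` (> 1) brightens the halo, with a Gaussian falloff from the
    core boundary out to ``halo_radius_mm``.  ``decay_per_timepoint`` fades
    both effects toward 1 at the later sessions.
    """

    ml_mm: float = 0.5
    ap_mm: float = 0.34
    dv_mm: float = -0.81
    core_radius_mm: float = 0.3
    halo_radius_mm: float = 0.8
    core_factor: float = 0.3
    halo_factor: float = 1.25
    decay_per_timepoint: dict = field(default_factory=lambda: {"6h": 0.5, "24h": 0.01})
    site_jitter_mm: float = 0.15  # per-subject isotropic placement scatter

    def validate(self) -> None:
        if not self.core_radius_mm < self.halo_radius_mm:
            raise ValueError("core_radius_mm must be smaller than halo_radius_mm")
        if not (0.0 < self.core_factor < 1.0 < self.halo_factor):
            raise ValueError("require 0 < core_factor < 1 < halo_factor")
        if self.dv_mm > 0:
            raise ValueError("dv_mm is measured below the brain surface and must be <= 0")
        if self.site_jitter_mm < 0:
            raise ValueError("site_jitter_mm must be >= 0")
        for tp, d in self.decay_per_timepoint.items():
            if tp not in TIMEPOINTS:
                raise ValueError(f"unknown timepoint {tp!r} in decay schedule")
            if d < 0:
                raise ValueError("decay factors must be >= 0")

    def factors_at(self, timepoint: str) -> tuple[float, float]:
        """(core, halo) multiplicative factors at a post-injection timepoint."""
        decay = 1.0 if timepoint == "30min" else self.decay_per_timepoint.get(timepoint, 0.0)
        return (
            1.0 + (self.core_factor - 1.0) * decay,
            1.0 + (self.halo_factor - 1.0) * decay,
        )


@dataclass
class GroupPlan:
    """Injection plan plus planted distal-enhancement schedule for one group.

    ``schedule`` entries are ``(segment, timepoint, fractional_enhancement)``
    where segment is a label id, abbreviation, or bilateral base (applied to
    both hemispheres) and fractional enhancement is multiplicative
    (+0.10 -> intensities x1.10 at that timepoint).
    """

    injection: InjectionPlan | None = None
    schedule: list = field(default_factory=list)

    def validate(self) -> None:
        if self.injection is not None:
            self.injection.validate()
        for seg, tp, f in self.schedule:
            if tp not in TIMEPOINTS:
                raise ValueError(f"unknown timepoint {tp!r} in schedule entry for {seg!r}")
            if f <= -1.0:
                raise ValueError("fractional_enhancement must be > -1")


def default_group_defs() -> dict[str, GroupPlan]:
    """The two study-like cohorts: anterior (ACA-like) and posterior-shifted
    ventral (ILPL-like) medial prefrontal injections, 0.84 mm apart in AP,
    each with a disjoint set of distal targets on a 6 h / 24 h schedule."""
    aca = GroupPlan(
        injection=InjectionPlan(ml_mm=0.5, ap_mm=0.34, dv_mm=-0.81),
        schedule=[
            ("ACA", "24h", 0.15),
            ("DS", "6h", 0.10),
            ("DS", "24h", 0.12),
            ("RTN", "6h", 0.10),
            ("RTN", "24h", 0.05),
            ("SNr", "24h", 0.08),
            ("PAG", "24h", 0.08),
            ("LC", "6h", 0.06),
            ("LC", "24h", 0.05),
            ("DMH", "24h", 0.06),
            ("MBO", "24h", 0.07),
        ],
    )
    ilpl = GroupPlan(
        injection=InjectionPlan(ml_mm=0.5, ap_mm=1.18, dv_mm=-1.30),
        schedule=[
            ("ILPL", "24h", 0.15),
            ("BLA", "24h", 0.10),
            ("AHN", "6h", 0.08),
            ("AHN", "24h", 0.10),
            ("LHA", "24h", 0.08),
        ],
    )
    return {"ACA": aca, "ILPL": ilpl}


@dataclass
class PhantomSpec:
    """Study-condition parameters of the synthetic cohort generator."""

    grid_shape: tuple[int, int, int] = (80, 64, 48)
    voxel_mm: tuple[float, float, float] = (0.1, 0.1, 0.1)
    brain_semi_mm: tuple[float, float, float] = (3.0, 2.4, 1.7)
    n_subjects_per_group: int = 10
    group_defs: dict[str, GroupPlan] = field(default_factory=default_group_defs)
    rigid_jitter_mm: float = 0.3
    rigid_jitter_deg: float = 3.0
    warp_jitter_mm: float = 0.2
    bias_amplitude: float = 0.2
    scale_range: tuple[float, float] = (0.8, 1.25)
    noise_sigma: float = 0.04
    seed: int = 0

    def validate(self) -> None:
        if any(n < 8 for n in self.grid_shape):
            raise ValueError("grid_shape axes must be >= 8 voxels")
        if any(v <= 0 for v in self.voxel_mm):
            raise ValueError("voxel_mm must be positive")
        for name in ("rigid_jitter_mm", "rigid_jitter_deg", "warp_jitter_mm", "bias_amplitude", "noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.scale_range[0] <= self.scale_range[1]:
            raise ValueError("scale_range must be a positive increasing interval")
        if self.n_subjects_per_group < 1:
            raise ValueError("n_subjects_per_group must be >= 1")
        half_extent = np.asarray(self.grid_shape) * np.asarray(self.voxel_mm) / 2.0
        margin = self.rigid_jitter_mm + self.warp_jitter_mm + 2.0 * max(self.voxel_mm)
        if np.any(np.asarray(self.brain_semi_mm) + margin > half_extent):
            raise ValueError(
                "grid too small: the brain ellipsoid with semi-axes "
                f"{tuple(self.brain_semi_mm)} mm plus a {margin:.2f} mm jitter margin does "
                f"not fit inside the {tuple(half_extent)} mm half-extents; enlarge "
                "grid_shape or shrink brain_semi_mm"
            )
        for plan in self.group_defs.values():
            plan.validate()

    def grid_affine(self) -> np.ndarray:
        """Affine centring the grid on world (0,0,0), midline at x = 0."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_mm)
        aff[:3, 3] = -(np.asarray(self.grid_shape) - 1.0) / 2.0 * np.asarray(self.voxel_mm)
        return aff

    @property
    def scale_factors(self) -> np.ndarray:
        """Per-axis geometry scale relative to the reference brain."""
        return np.asarray(self.brain_semi_mm) / _REF_SEMI


@dataclass
class SubjectSession:
    subject_id: str
    group: str
    timepoint: str
    image: VolumeImage


@dataclass
class SubjectTruth:
    """Planted ground truth for one subject."""

    subject_id: str
    group: str
    rigid: RigidTransform  # subject world -> atlas world (applied after warp)
    warp: WarpTransform | None  # subject-frame displacement
    transform: Transform  # full subject -> atlas map (rigid ∘ (x + u))
    injection_centroid_world: np.ndarray | None  # subject frame, mm
    injection_site_atlas: np.ndarray | None  # atlas frame, mm
    bias_field: np.ndarray | None = None
    global_scale: float = 1.0

    def to_jsonable(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "group": self.group,
            "rigid": self.rigid.to_dict(),
            "max_warp_mm": None if self.warp is None else self.warp.max_displacement(),
            "injection_centroid_world_mm": None
            if self.injection_centroid_world is None
            else list(self.injection_centroid_world),
            "injection_site_atlas_mm": None
            if self.injection_site_atlas is None
            else list(self.injection_site_atlas),
            "global_scale": self.global_scale,
        }


@dataclass
class PhantomTruth:
    """Everything needed to score the pipeline against the generator."""

    atlas: AtlasBundle
    subjects: dict[str, SubjectTruth]
    schedule_by_group: dict[str, list]
    spec: PhantomSpec

    def enhanced_segments(self, group: str, timepoint: str) -> dict[int, float]:
        """Label id -> fractional enhancement applied at ``timepoint``."""
        out: dict[int, float] = {}
        for seg, tp, f in self.schedule_by_group[group]:
            if tp != timepoint:
                continue
            for i in self.atlas.ids_for(seg):
                out[i] = out.get(i, 0.0) + f
        return out

    def brain_support(self) -> np.ndarray:
        """True (atlas-frame) brain support mask."""
        return np.asarray(self.atlas.meta["brain_support"], dtype=bool)

    def planned_site_atlas(self, group: str) -> np.ndarray:
        """The group's *plan* injection site (atlas frame, before per-subject
        placement jitter)."""
        plan = self.spec.group_defs[group].injection
        if plan is None:
            raise ValueError(f"group {group!r} has no injection plan")
        return _injection_site_atlas(self.atlas, plan, self.brain_support())

    def manifest(self) -> dict:
        return {
            "seed": self.spec.seed,
            "grid_shape": list(self.spec.grid_shape),
            "voxel_mm": list(self.spec.voxel_mm),
            "groups": {
                g: [[str(s), tp, float(f)] for s, tp, f in sched]
                for g, sched in self.schedule_by_group.items()
            },
            "subjects": {sid: t.to_jsonable() for sid, t in self.subjects.items()},
        }


# ---------------------------------------------------------------------------
# Atlas construction
# ---------------------------------------------------------------------------

def _ellipsoid_mask(world: np.ndarray, center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    d = (world - center) / semi
    return np.einsum("...d,...d->...", d, d) <= 1.0


def make_phantom_atlas(spec: PhantomSpec) -> AtlasBundle:
    """Build the brain-shaped template, label volume, lookup table, and
    stereotaxic metadata for a phantom study.

    The template nests cortex / white matter / deep gray / ventricle
    compartments inside a brain ellipsoid and adds a smooth deterministic
    intensity texture so registration has structure to lock onto.  Labels
    comprise bilateral pairs (mirror-symmetric about the midline plane) plus
    midline structures, including a hypothalamus parent subdivided into
    sub-segments; one fiber-tract label is flagged for exclusion from
    fractional-volume tables.
    """
    spec.validate()
    affine = spec.grid_affine()
    template = VolumeImage(np.zeros(spec.grid_shape, dtype=np.float32), affine)
    world = template.world_grid()
    semi = np.asarray(spec.brain_semi_mm, dtype=float)
    scale = spec.scale_factors

    rnorm = np.sqrt(np.einsum("...d,...d->...", world / semi, world / semi))
    brain = rnorm <= 1.0

    gray = np.zeros(spec.grid_shape, dtype=np.float32)
    deep = brain & (rnorm <= 0.55)
    wm = brain & (rnorm > 0.55) & (rnorm <= 0.88)
    cortex = brain & (rnorm > 0.88)
    gray[deep] = _DEEPGRAY_VALUE
    gray[wm] = _WM_VALUE
    gray[cortex] = _CORTEX_VALUE

    # Deterministic smooth texture at two scales (periods ~2 mm and ~1 mm):
    # anatomy-like structure that survives smoothing and gives NCC/SSD
    # registration a sharp optimum.  Two products with different periods and
    # phases keep the intensity gradient nonzero almost everywhere (a single
    # separable product has nodal planes where displacement along the plane
    # would be unconstrained), and the phase offsets break the 180-degree
    # rotational symmetry of the ellipsoidal compartments, which would
    # otherwise create a spurious registration optimum at half a turn.
    tex = (
        np.sin(2 * np.pi * world[..., 0] / (2.5 * scale[0]) + 0.9)
        * np.sin(2 * np.pi * world[..., 1] / (2.1 * scale[1]) + 0.5)
        * np.sin(2 * np.pi * world[..., 2] / (1.7 * scale[2]) + 0.3)
    )
    tex2 = (
        np.sin(2 * np.pi * world[..., 0] / (1.3 * scale[0]) + 0.2)
        * np.sin(2 * np.pi * world[..., 1] / (1.1 * scale[1]) + 1.1)
        * np.sin(2 * np.pi * world[..., 2] / (0.9 * scale[2]) + 0.7)
    )
    gray[brain] += (
        _TEXTURE_AMPLITUDE * tex[brain] + 0.7 * _TEXTURE_AMPLITUDE * tex2[brain]
    ).astype(np.float32)

    # band-limit the template (scanner PSF): sharp compartment steps would
    # alias under resampling, putting a hard ceiling on attainable pairwise
    # similarity between differently-posed subjects
    gray = ndimage.gaussian_filter(gray, sigma=1.2).astype(np.float32)

    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    lut: dict[int, LabelInfo] = {}
    rng_color = np.random.default_rng(12345)  # palette only; not study randomness
    next_id = 1
    for abbrev, name, center, seg_semi, bilateral, is_tract in _SEGMENT_TABLE:
        center = np.asarray(center) * scale
        seg_semi = np.asarray(seg_semi) * scale
        sides = [("-R", center), ("-L", center * np.array([-1.0, 1.0, 1.0]))] if bilateral else [("", center)]
        for suffix, c in sides:
            mask = _ellipsoid_mask(world, c, seg_semi) & brain & (labels == 0)
            if abbrev == _HYP_PARENT:
                # unassigned parent tissue keeps a moat around every named
                # segment (its own sub-segments included)
                dist = ndimage.distance_transform_edt(labels == 0, sampling=spec.voxel_mm)
                mask &= dist > _PARENT_MOAT_MM * min(1.0, float(scale.min()))
            rgb = tuple(np.round(rng_color.uniform(0.15, 0.95, 3), 4))
            lut[next_id] = LabelInfo(
                id=next_id,
                abbrev=abbrev + suffix,
                name=name + {"-L": " (left)", "-R": " (right)", "": ""}[suffix],
                rgb=rgb,  # type: ignore[arg-type]
                is_tract=is_tract,
            )
            labels[mask] = next_id
            next_id += 1

    bregma = np.array([0.0, _BREGMA_Y_REF * scale[1], 0.0])
    bregma[2] = semi[2] * np.sqrt(max(0.0, 1.0 - (bregma[1] / semi[1]) ** 2))
    return AtlasBundle(
        gray=VolumeImage(gray, affine),
        labels=labels,
        lut=lut,
        bregma_world=bregma,
        midline_x=0.0,
        meta={
            "brain_support": brain,
            "brain_semi_mm": semi.tolist(),
            "hyp_parent": "HYP",
            "hyp_subsegments": list(_HYP_SUBSEGMENTS),
        },
    )


# ---------------------------------------------------------------------------
# Subject simulation
# ---------------------------------------------------------------------------

def _subject_rng(spec: PhantomSpec, group: str, subject_index: int) -> np.random.Generator:
    gi = sorted(spec.group_defs).index(group)
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed), 7919, gi, int(subject_index)]))


def _smooth_displacement(
    rng: np.random.Generator, spec: PhantomSpec, affine: np.ndarray
) -> WarpTransform | None:
    """Coarse random displacement grid (8-voxel spacing) upsampled by cubic
    interpolation and amplitude-clamped to ``warp_jitter_mm``."""
    if spec.warp_jitter_mm <= 0:
        return None
    shape = np.asarray(spec.grid_shape)
    coarse = np.maximum(shape // 8 + 1, 4)  # ~8-voxel control spacing
    grid = rng.normal(0.0, 1.0, size=(*coarse, 3))
    zoom = shape / coarse
    dense = np.stack(
        [ndimage.zoom(grid[..., d], zoom, order=3, mode="nearest", grid_mode=True) for d in range(3)],
        axis=-1,
    )
    peak = np.abs(dense).max()
    if peak > 0:
        dense *= spec.warp_jitter_mm / peak
    return WarpTransform(displacement_mm=dense, affine=affine)


def _bias_field(rng: np.random.Generator, spec: PhantomSpec, world: np.ndarray) -> np.ndarray:
    """exp(p) for a random degree-2 polynomial p scaled to max|p| = amplitude."""
    if spec.bias_amplitude <= 0:
        return np.ones(world.shape[:3], dtype=np.float32)
    semi = np.asarray(spec.brain_semi_mm)
    u = world / semi  # normalised coords, O(1) over the brain
    terms = [
        u[..., 0], u[..., 1], u[..., 2],
        u[..., 0] * u[..., 1], u[..., 0] * u[..., 2], u[..., 1] * u[..., 2],
        u[..., 0] ** 2, u[..., 1] ** 2, u[..., 2] ** 2,
    ]
    coefs = rng.uniform(-1.0, 1.0, len(terms))
    p = sum(c * t for c, t in zip(coefs, terms))
    peak = np.abs(p).max()
    if peak > 0:
        p *= spec.bias_amplitude / peak
    return np.exp(p).astype(np.float32)


def _apply_schedule(atlas: AtlasBundle, plan: GroupPlan, timepoint: str) -> np.ndarray:
    """Template with the group's planted multiplicative enhancements at one
    timepoint (atlas space; applied before warping/bias/scale/noise)."""
    img = atlas.gray.voxels.astype(np.float32).copy()
    factors: dict[int, float] = {}
    for seg, tp, f in plan.schedule:
        if tp != timepoint:
            continue
        for i in atlas.ids_for(seg):
            factors[i] = factors.get(i, 1.0) * (1.0 + f)
    for i, fac in factors.items():
        img[atlas.labels == i] *= fac
    return img


def _injection_site_atlas(atlas: AtlasBundle, plan: InjectionPlan, brain: np.ndarray) -> np.ndarray:
    """World coordinate of the planted bolus centre in atlas space: ML right
    of midline, AP anterior of bregma, DV below the brain surface in that
    (x, y) column."""
    x = atlas.midline_x + plan.ml_mm
    y = atlas.bregma_world[1] + plan.ap_mm
    # top of the brain support in this column
    grid = atlas.gray
    idx = grid.world_to_index(np.array([x, y, 0.0]))
    i, j = int(round(idx[0])), int(round(idx[1]))
    if not (0 <= i < brain.shape[0] and 0 <= j < brain.shape[1]) or not brain[i, j, :].any():
        raise ValueError("injection column lies outside the brain mask")
    k_top = int(np.max(np.nonzero(brain[i, j, :])[0]))
    z_surface = grid.index_to_world(np.array([i, j, k_top]))[2]
    site = np.array([x, y, z_surface + plan.dv_mm])
    site_idx = np.rint(grid.world_to_index(site)).astype(int)
    if not brain[tuple(site_idx)]:
        raise ValueError("injection site falls outside the brain mask; check ml/ap/dv")
    return site


def _bolus_field(
    image: VolumeImage, site: np.ndarray, plan: InjectionPlan, timepoint: str
) -> np.ndarray | None:
    """Multiplicative biphasic bolus field in the image's own frame."""
    if timepoint == "pre":
        return None
    core_f, halo_f = plan.factors_at(timepoint)
    world = image.world_grid()
    d = np.linalg.norm(world - site, axis=-1)
    f = np.ones(image.shape, dtype=np.float32)
    ring = (d > plan.core_radius_mm) & (d <= plan.halo_radius_mm)
    sigma = (plan.halo_radius_mm - plan.core_radius_mm) / 2.5
    f[ring] = 1.0 + (halo_f - 1.0) * np.exp(-(((d[ring] - plan.core_radius_mm) / sigma) ** 2)).astype(np.float32)
    f[d <= plan.core_radius_mm] = core_f
    return f


def _invert_subject_map(
    rigid: RigidTransform, warp: WarpTransform | None, atlas_point: np.ndarray
) -> np.ndarray:
    """Solve T(x) = rigid(x + u(x)) = p for x by fixed-point iteration."""
    y = rigid.inverse().map_points(atlas_point[None, :])[0]
    if warp is None:
        return y
    x = y.copy()
    for _ in range(25):
        u = warp.map_points(x[None, :])[0] - x
        x_new = y - u
        if np.linalg.norm(x_new - x) < 1e-9:
            x = x_new
            break
        x = x_new
    return x


def simulate_subject(
    spec: PhantomSpec,
    group: str,
    subject_index: int,
    atlas: AtlasBundle | None = None,
) -> tuple[list[SubjectSession], SubjectTruth]:
    """Simulate the four imaging sessions of one subject.

    The subject's image at world point x samples the (schedule-enhanced)
    template at ``rigid(x + u(x))``; the biphasic bolus is evaluated
    analytically in the subject frame at the mapped planted site; bias field
    and global scale multiply the result, and Gaussian noise (sigma expressed
    as a fraction of the tissue-mode intensity) is added last.  Deterministic
    given (seed, group, subject_index).
    """
    spec.validate()
    if group not in spec.group_defs:
        raise KeyError(f"group {group!r} not in spec.group_defs")
    if atlas is None:
        atlas = make_phantom_atlas(spec)
    plan = spec.group_defs[group]
    rng = _subject_rng(spec, group, subject_index)
    affine = atlas.gray.affine
    brain = np.asarray(atlas.meta["brain_support"], dtype=bool)

    # -- per-subject nuisance draws (order fixed: geometry, bias, scale) ----
    angles = rng.uniform(-spec.rigid_jitter_deg, spec.rigid_jitter_deg, 3)
    trans = rng.uniform(-spec.rigid_jitter_mm, spec.rigid_jitter_mm, 3)
    rigid = RigidTransform(angles, trans, center=atlas.gray.center_world())
    warp = _smooth_displacement(rng, spec, affine)
    target_grid = VolumeImage(np.zeros(spec.grid_shape, dtype=np.float32), affine)
    world = target_grid.world_grid()
    bias = _bias_field(rng, spec, world)
    gscale = float(rng.uniform(*spec.scale_range))

    if warp is None:
        subj_to_atlas: Transform = rigid
    else:
        subj_to_atlas = ComposedTransform([rigid, warp])

    site_atlas = centroid_subject = None
    if plan.injection is not None:
        site_atlas = _injection_site_atlas(atlas, plan.injection, brain)
        if plan.injection.site_jitter_mm > 0:
            site_atlas = site_atlas + rng.normal(0.0, plan.injection.site_jitter_mm, 3)
            jidx = np.rint(atlas.gray.world_to_index(site_atlas)).astype(int)
            if not (np.all(jidx >= 0) and np.all(jidx < np.asarray(brain.shape)) and brain[tuple(jidx)]):
                raise ValueError("jittered injection site fell outside the brain mask")
        centroid_subject = _invert_subject_map(rigid, warp, site_atlas)

    mode_ref = float(_TISSUE_MODE)  # tissue-mode intensity of the template
    sessions = []
    identity_geometry = (
        spec.rigid_jitter_deg == 0 and spec.rigid_jitter_mm == 0 and warp is None
    )
    for tp in TIMEPOINTS:
        enhanced = _apply_schedule(atlas, plan, tp)
        if identity_geometry:
            vox = enhanced.copy()  # exact: no interpolation when no jitter
        else:
            # cubic interpolation: the generator should not inject linear-
            # interpolation artifacts that downstream registration would see
            # as an irreducible similarity floor
            vox = resample(
                VolumeImage(enhanced, affine), subj_to_atlas, target_grid, interp="cubic"
            ).voxels
        if plan.injection is not None and tp != "pre":
            f = _bolus_field(target_grid, centroid_subject, plan.injection, tp)
            vox = vox * f
        vox = vox * bias * gscale
        if spec.noise_sigma > 0:
            vox = vox + rng.normal(0.0, spec.noise_sigma * mode_ref, size=vox.shape)
        sessions.append(
            SubjectSession(
                subject_id=f"{group}_{subject_index:02d}",
                group=group,
                timepoint=tp,
                image=VolumeImage(vox.astype(np.float32), affine.copy()),
            )
        )

    truth = SubjectTruth(
        subject_id=f"{group}_{subject_index:02d}",
        group=group,
        rigid=rigid,
        warp=warp,
        transform=subj_to_atlas,
        injection_centroid_world=centroid_subject,
        injection_site_atlas=site_atlas,
        bias_field=bias,
        global_scale=gscale,
    )
    return sessions, truth


def simulate_cohorts(
    spec: PhantomSpec, out_dir: str | Path | None = None
) -> tuple[dict[str, dict[str, dict[str, VolumeImage]]], PhantomTruth]:
    """Simulate the full two-cohort study.

    Returns ``cohorts[group][subject_id][timepoint] -> VolumeImage`` plus the
    :class:`PhantomTruth`.  When ``out_dir`` is given, one NIfTI per
    subject-timepoint, the atlas bundle, and a JSON truth manifest are
    written there.
    """
    spec.validate()
    if len(spec.group_defs) != 2:
        raise ValueError("simulate_cohorts expects exactly two group definitions")
    atlas = make_phantom_atlas(spec)
    cohorts: dict[str, dict[str, dict[str, VolumeImage]]] = {}
    subjects: dict[str, SubjectTruth] = {}
    for group in sorted(spec.group_defs):
        cohorts[group] = {}
        for si in range(spec.n_subjects_per_group):
            sessions, truth = simulate_subject(spec, group, si, atlas=atlas)
            sid = truth.subject_id
            if sid in subjects:
                raise ValueError(f"duplicate subject id {sid!r}")
            subjects[sid] = truth
            cohorts[group][sid] = {s.timepoint: s.image for s in sessions}
    truth_all = PhantomTruth(
        atlas=atlas,
        subjects=subjects,
        schedule_by_group={g: list(p.schedule) for g, p in spec.group_defs.items()},
        spec=spec,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        atlas.save(out_dir / "atlas")
        for group, subj in cohorts.items():
            for sid, tps in subj.items():
                for tp, img in tps.items():
                    save_volume(img, out_dir / "images" / f"{sid}_{tp}.nii.gz")
        (out_dir / "truth.json").write_text(json.dumps(truth_all.manifest(), indent=2))
    return cohorts, truth_all
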