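"""Atlas-based quantification: affine atlas alignment, fractional
accumulation volumes, segment-dynamics classification, injection-site
localization and stereotaxic summaries, and ROI time-course statistics.

The projection-strength metric is the *fractional accumulation volume*: per
atlas segment, the ratio of statistically enhanced voxels (from an FDR-
thresholded t-map) to total segment voxels, counted bilaterally.  Injection
sites are localized from the biphasic Mn(II) signal: the high-concentration
epicenter is hypo-intense at 30 min, so the core is the largest connected
component below a robust intensity threshold, and its deficit-weighted
centroid is converted to stereotaxic ML/AP/DV coordinates (midline, bregma,
brain surface).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

from .atlas import AtlasBundle
from .image import BrainMask, VolumeImage
from .preprocess import _level_affine, _pyramid_level, histogram_mode, ncc
from .statmap import ThresholdedMap, bh_reject
from .transforms import AffineTransform, resample

__all__ = [
    "FractionalVolumeRow",
    "InjectionSite",
    "ROISpec",
    "ROITimecourse",
    "DynamicsRow",
    "align_atlas",
    "register_affine",
    "segment_voxel_counts",
    "fractional_accumulation",
    "fractional_table",
    "classify_dynamics",
    "locate_injection_site",
    "site_to_stereotaxic",
    "cohort_site_summary",
    "extract_roi_timecourse",
    "roi_group_stats",
]


# ---------------------------------------------------------------------------
# Atlas alignment (12-parameter affine, inverse-matrix label mapping)
# ---------------------------------------------------------------------------

def _affine_from_params(p: np.ndarray, center: np.ndarray) -> AffineTransform:
    """12 parameters: 3 Euler rotations (deg), 3 translations (mm),
    3 log-scales, 3 shears; linear part R @ diag(exp(s)) @ Shear."""
    from scipy.spatial.transform import Rotation

    R = Rotation.from_euler("xyz", p[:3], degrees=True).as_matrix()
    S = np.diag(np.exp(p[6:9]))
    H = np.eye(3)
    H[0, 1], H[0, 2], H[1, 2] = p[9], p[10], p[11]
    L = R @ S @ H
    M = np.eye(4)
    M[:3, :3] = L
    M[:3, 3] = center + p[3:6] - L @ center
    return AffineTransform(M)


def register_affine(
    moving: VolumeImage,
    fixed: VolumeImage,
    fixed_mask: np.ndarray | None = None,
    levels: tuple[int, ...] = (4, 2, 1),
    max_points: int = 40000,
) -> AffineTransform:
    """12-parameter affine maximizing masked NCC, multi-resolution Powell.

    Returns the pull-back map (fixed world -> moving world), i.e. the
    "fixed to moving" affine; apply its inverse to carry moving-frame
    metadata into the fixed frame.
    """
    center = fixed.center_world()
    p = np.zeros(12)
    for level in levels:
        fvox, fmask = _pyramid_level(np.asarray(fixed.voxels), fixed_mask, level)
        mvox, _ = _pyramid_level(np.asarray(moving.voxels), None, level)
        laff = _level_affine(fixed.affine, level)
        minv = np.linalg.inv(_level_affine(moving.affine, level))
        sel = np.ones(fvox.shape, dtype=bool) if fmask is None else fmask.astype(bool)
        idx = np.argwhere(sel)
        if idx.shape[0] > max_points:
            idx = idx[:: int(np.ceil(idx.shape[0] / max_points))]
        pts = idx @ laff[:3, :3].T + laff[:3, 3]
        fvals = fvox[tuple(idx.T)].astype(np.float64)
        fvals = fvals - fvals.mean()
        fnorm = np.sqrt(fvals @ fvals)

        scales = np.array([20.0] * 3 + [3.0] * 3 + [0.3] * 3 + [0.3] * 3)

        def neg_ncc(q: np.ndarray) -> float:
            excess = np.maximum(np.abs(q) - scales, 0.0) / scales
            wall = 10.0 * float(excess @ excess)
            T = _affine_from_params(q, center)
            src = T.map_points(pts)
            midx = src @ minv[:3, :3].T + minv[:3, 3]
            mv = ndimage.map_coordinates(mvox, midx.T, order=1, mode="constant", cval=0.0)
            mv = mv - mv.mean()
            denom = fnorm * np.sqrt(mv @ mv)
            return wall if denom == 0 else wall - float((fvals @ mv) / denom)

        res = optimize.minimize(
            neg_ncc,
            p,
            method="Powell",
            options={"xtol": 1e-4 if level == 1 else 1e-3, "ftol": 1e-10, "maxfev": 1500},
        )
        p = np.asarray(res.x)
    return _affine_from_params(p, center)


def align_atlas(atlas: AtlasBundle, mdt: VolumeImage, mdt_mask: np.ndarray | None = None) -> AtlasBundle:
    """Carry an atlas bundle into study (MDT) space.

    A 12-parameter affine from the MDT to the atlas gray template is
    estimated by NCC; that map is exactly the pull-back used to resample the
    gray atlas (linear) and label volume (nearest-neighbour, which never
    invents label values) onto the MDT grid, and its inverse carries the
    bregma/midline metadata into study space.
    """
    # the study-space MDT averages bias-corrected images, whose smooth anatomy
    # trend the log-polynomial correction has flattened; flatten the atlas
    # gray identically before NCC registration so both images share a
    # modality, then apply the recovered affine to the *original* bundle
    from .preprocess import compute_brain_mask, correct_bias, erode_mask

    try:
        amask = erode_mask(compute_brain_mask(atlas.gray), 0.25)
        atlas_flat = correct_bias(atlas.gray, amask)
    except ValueError:
        atlas_flat = atlas.gray
    pull = register_affine(atlas_flat, mdt, fixed_mask=mdt_mask)  # mdt -> atlas world
    inv = pull.inverse()
    gray = resample(atlas.gray, pull, mdt, interp="linear")
    labels = resample(atlas.label_image(), pull, mdt, interp="nearest")
    bregma = inv.map_points(atlas.bregma_world[None, :])[0]
    midline_pt = inv.map_points(np.array([[atlas.midline_x, 0.0, 0.0]]))[0]
    meta = {k: v for k, v in atlas.meta.items() if not isinstance(v, np.ndarray)}
    meta["mdt_to_atlas_affine"] = pull.matrix.tolist()
    return AtlasBundle(
        gray=gray,
        labels=np.rint(labels.voxels).astype(np.int16),
        lut={i: e for i, e in atlas.lut.items()},
        bregma_world=bregma,
        midline_x=float(midline_pt[0]),
        meta=meta,
    )


# ---------------------------------------------------------------------------
# Fractional accumulation volumes
# ---------------------------------------------------------------------------

@dataclass
class FractionalVolumeRow:
    """Per-segment enhanced/total voxel ratio (bilateral by default)."""

    segment_ids: tuple[int, ...]
    abbrev: str
    total_voxels: int
    enhanced_voxels: int

    def __post_init__(self) -> None:
        if self.enhanced_voxels > self.total_voxels:
            raise ValueError("enhanced voxel count exceeds segment size")

    @property
    def fraction(self) -> float:
        return self.enhanced_voxels / self.total_voxels if self.total_voxels else 0.0


def segment_voxel_counts(labels: np.ndarray) -> dict[int, int]:
    """Exact voxel count per nonzero label id."""
    labels = np.asarray(labels)
    counts = np.bincount(labels.ravel().astype(np.int64))
    return {int(i): int(c) for i, c in enumerate(counts) if i != 0 and c > 0}


def fractional_accumulation(
    thresholded: ThresholdedMap,
    atlas: AtlasBundle,
    bilateral: bool = True,
    include_tracts: bool = False,
) -> list[FractionalVolumeRow]:
    """Fraction of statistically enhanced voxels per atlas segment.

    Counts are bilateral (left+right merged through the lookup table's
    lateral pairing) unless ``bilateral=False``; fiber-tract labels are
    omitted unless ``include_tracts``.  Rows follow the lookup table's
    anatomical ordering.
    """
    labels = atlas.labels
    if thresholded.binary.shape != labels.shape:
        raise ValueError("thresholded map and label volume must share a grid")
    totals = segment_voxel_counts(labels)
    enhanced = segment_voxel_counts(np.where(thresholded.binary, labels, 0))
    rows: list[FractionalVolumeRow] = []
    if bilateral:
        for base, ids in atlas.bilateral_groups(include_tracts=include_tracts).items():
            ids = [i for i in ids if i in totals]
            if not ids:
                continue
            rows.append(
                FractionalVolumeRow(
                    segment_ids=tuple(ids),
                    abbrev=base,
                    total_voxels=sum(totals[i] for i in ids),
                    enhanced_voxels=sum(enhanced.get(i, 0) for i in ids),
                )
            )
        rows.sort(key=lambda r: r.segment_ids[0])
    else:
        for i in sorted(totals):
            entry = atlas.lut[i]
            if entry.is_tract and not include_tracts:
                continue
            rows.append(
                FractionalVolumeRow(
                    segment_ids=(i,),
                    abbrev=entry.abbrev,
                    total_voxels=totals[i],
                    enhanced_voxels=enhanced.get(i, 0),
                )
            )
    return rows


def fractional_table(rows_by_contrast: dict[str, list[FractionalVolumeRow]]) -> pd.DataFrame:
    """Column-graph-ready long table: one row per (contrast, segment)."""
    records = []
    for contrast, rows in rows_by_contrast.items():
        for r in rows:
            records.append(
                {
                    "contrast": contrast,
                    "segment": r.abbrev,
                    "segment_ids": ",".join(str(i) for i in r.segment_ids),
                    "total_voxels": r.total_voxels,
                    "enhanced_voxels": r.enhanced_voxels,
                    "fraction": r.fraction,
                }
            )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Dynamics classification
# ---------------------------------------------------------------------------

@dataclass
class DynamicsRow:
    segment: str
    category: str  # greater_at_6h | greater_at_24h | similar | accumulating_6_24
    frac_6h: float
    frac_24h: float
    frac_24v6: float


def classify_dynamics(
    frac_6h: dict[str, float],
    frac_24h: dict[str, float],
    frac_24v6: dict[str, float],
    delta: float = 0.05,
) -> list[DynamicsRow]:
    """Classify per-segment accumulation dynamics from fractional volumes.

    ``greater_at_6h`` if frac6 - frac24 > delta; ``greater_at_24h`` if
    frac24 - frac6 > delta; ``accumulating_6_24`` when the 24h>6h contrast
    itself occupies more than delta of the segment (overriding "similar");
    otherwise ``similar``.  Segments below delta at both timepoints are
    omitted.  The threshold delta is a declared convention (fraction of
    segment volume), configurable and reported with the table.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    keys = set(frac_6h) | set(frac_24h)
    rows: list[DynamicsRow] = []
    for seg in sorted(keys):
        f6 = frac_6h.get(seg, 0.0)
        f24 = frac_24h.get(seg, 0.0)
        f246 = frac_24v6.get(seg, 0.0)
        if f6 < delta and f24 < delta:
            continue
        if f6 - f24 > delta:
            cat = "greater_at_6h"
        elif f24 - f6 > delta:
            cat = "greater_at_24h"
        elif f246 > delta:
            cat = "accumulating_6_24"
        else:
            cat = "similar"
        rows.append(DynamicsRow(seg, cat, f6, f24, f246))
    return rows


# ---------------------------------------------------------------------------
# Injection-site localization
# ---------------------------------------------------------------------------

@dataclass
class InjectionSite:
    """Localized injection epicenter with stereotaxic coordinates."""

    subject_id: str
    centroid_world: np.ndarray
    ml_mm: float | None = None
    ap_mm: float | None = None
    dv_mm: float | None = None
    n_core_voxels: int = 0


def _default_search_region(mask: np.ndarray, img: VolumeImage) -> np.ndarray:
    """Dorsal anterior quadrant of the mask (y and z above the mask centroid)."""
    idx = np.argwhere(mask)
    cy, cz = idx[:, 1].mean(), idx[:, 2].mean()
    jj, kk = np.meshgrid(np.arange(mask.shape[1]), np.arange(mask.shape[2]), indexing="ij")
    region = np.zeros_like(mask)
    region[:, :, :] = (jj >= cy)[None, :, :] & (kk >= cz)[None, :, :]
    return region & mask


def locate_injection_site(
    img_30min: VolumeImage,
    mask: BrainMask | np.ndarray,
    search_region: np.ndarray | None = None,
    k_mad: float = 3.0,
    subject_id: str = "",
) -> InjectionSite:
    """Find the hypo-intense injection core in a 30 min image.

    High Mn(II) concentrations darken the T1-weighted signal, so the core is
    the largest 6-connected component of voxels below ``mode - k_mad * MAD``
    (scaled median absolute deviation) within the search region (default:
    the dorsal anterior quadrant of the mask).  The centroid is weighted by
    the intensity deficit below the threshold.
    """
    m = mask.data if isinstance(mask, BrainMask) else np.asarray(mask, dtype=bool)
    # trim the partial-volume rim so brain-edge voxels cannot mimic a core
    voxel_mm = np.linalg.norm(img_30min.affine[:3, :3], axis=0)
    m = ndimage.distance_transform_edt(m, sampling=voxel_mm) > 0.25
    region = _default_search_region(m, img_30min) if search_region is None else (search_region & m)
    if not region.any():
        raise ValueError("empty search region")
    vox = np.asarray(img_30min.voxels, dtype=np.float64)
    mode = histogram_mode(img_30min, BrainMask(region, img_30min.affine))
    vals = vox[region]
    mad = 1.4826 * float(np.median(np.abs(vals - np.median(vals))))
    thr = mode - k_mad * mad
    hypo = region & (vox < thr)
    if not hypo.any():
        raise ValueError("no injection core detected (no hypo-intense voxels)")
    six = ndimage.generate_binary_structure(3, 1)
    comp, n = ndimage.label(hypo, structure=six)
    sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
    core = comp == (1 + int(np.argmax(sizes)))
    if core.sum() < 5:
        raise ValueError("no injection core detected (largest hypo-intense component too small)")
    w = (thr - vox)[core]
    idx = np.argwhere(core).astype(np.float64)
    centroid_idx = (idx * w[:, None]).sum(axis=0) / w.sum()
    centroid = img_30min.index_to_world(centroid_idx)
    return InjectionSite(
        subject_id=subject_id,
        centroid_world=centroid,
        n_core_voxels=int(core.sum()),
    )


def site_to_stereotaxic(
    centroid_world: np.ndarray,
    atlas: AtlasBundle,
    mask: BrainMask | np.ndarray,
) -> tuple[float, float, float]:
    """Convert a world-mm centroid to stereotaxic (ML, AP, DV) mm.

    ML is distance right of the midline plane; AP is distance anterior of
    bregma; DV is depth below the *brain surface*, defined as the topmost
    in-mask voxel of the centroid's (x, y) column (so DV <= 0 below the
    surface, matching measurement from the brain rather than the skull).
    """
    m = mask.data if isinstance(mask, BrainMask) else np.asarray(mask, dtype=bool)
    centroid_world = np.asarray(centroid_world, dtype=float)
    ml = float(centroid_world[0] - atlas.midline_x)
    ap = float(centroid_world[1] - atlas.bregma_world[1])
    idx = atlas.gray.world_to_index(centroid_world)
    i, j = int(round(idx[0])), int(round(idx[1]))
    if not (0 <= i < m.shape[0] and 0 <= j < m.shape[1]) or not m[i, j, :].any():
        raise ValueError("centroid (x, y) column lies outside the brain mask")
    k_top = int(np.max(np.nonzero(m[i, j, :])[0]))
    surface_z = atlas.gray.index_to_world(np.array([i, j, k_top]))[2]
    dv = float(centroid_world[2] - surface_z)
    return ml, ap, dv


def cohort_site_summary(sites: list[InjectionSite]) -> dict:
    """Per-axis mean +/- sample SD of ML/AP/DV plus the largest Euclidean
    distance of any site from the cohort centroid."""
    if len(sites) < 2:
        raise ValueError("cohort summary needs at least 2 sites")
    coords = np.array([[s.ml_mm, s.ap_mm, s.dv_mm] for s in sites], dtype=float)
    if np.any(np.isnan(coords)):
        raise ValueError("sites must carry stereotaxic coordinates")
    mean = coords.mean(axis=0)
    sd = coords.std(axis=0, ddof=1)
    dist = np.linalg.norm(coords - mean, axis=1)
    return {
        "n": len(sites),
        "ml_mean": float(mean[0]), "ml_sd": float(sd[0]),
        "ap_mean": float(mean[1]), "ap_sd": float(sd[1]),
        "dv_mean": float(mean[2]), "dv_sd": float(sd[2]),
        "max_distance_from_centroid": float(dist.max()),
    }


# ---------------------------------------------------------------------------
# ROI time courses
# ---------------------------------------------------------------------------

@dataclass
class ROISpec:
    """A 3x3x3-voxel cubic region of interest."""

    name: str
    hemisphere: str
    center_index: tuple[int, int, int]
    edge: int = 3


@dataclass
class ROITimecourse:
    roi: ROISpec
    subject_id: str
    group: str
    means: dict[str, float]  # timepoint -> mean intensity over the cube

    @property
    def ratio_6h(self) -> float:
        return self.means["6h"] / self.means["30min"]

    @property
    def ratio_24h(self) -> float:
        return self.means["24h"] / self.means["30min"]


def extract_roi_timecourse(
    sessions: dict[str, VolumeImage],
    roi: ROISpec,
    mask: BrainMask | np.ndarray | None = None,
    subject_id: str = "",
    group: str = "",
) -> ROITimecourse:
    """Mean intensity over the ROI cube per timepoint, plus ratios to 30 min.

    Runs on *unsmoothed* aligned images; the cube must lie inside the grid
    (and the mask, when given).
    """
    half = roi.edge // 2
    c = np.asarray(roi.center_index, dtype=int)
    means: dict[str, float] = {}
    for tp, img in sessions.items():
        lo = c - half
        hi = c + half + 1
        if np.any(lo < 0) or np.any(hi > np.asarray(img.shape)):
            raise ValueError(f"ROI {roi.name} cube exits the image grid")
        if mask is not None:
            m = mask.data if isinstance(mask, BrainMask) else np.asarray(mask, dtype=bool)
            if not m[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].all():
                raise ValueError(f"ROI {roi.name} cube exits the brain mask")
        cube = np.asarray(img.voxels)[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        means[tp] = float(cube.mean())
    return ROITimecourse(roi=roi, subject_id=subject_id, group=group, means=means)


def roi_group_stats(timecourses: list[ROITimecourse], q: float = 0.05) -> pd.DataFrame:
    """ROI-level inference on log-ratios with BH-FDR across ROIs.

    Within each group: paired t-test of log(ratio 24h) vs log(ratio 6h)
    across subjects.  Between groups: Welch two-sample t-test on subject
    log(ratio 24h).  The subject is the experimental unit throughout; BH is
    applied across ROIs separately within each comparison family.
    """
    df = pd.DataFrame(
        [
            {
                "roi": tc.roi.name,
                "hemisphere": tc.roi.hemisphere,
                "subject_id": tc.subject_id,
                "group": tc.group,
                "log_ratio_6h": np.log(tc.ratio_6h) if "6h" in tc.means else np.nan,
                "log_ratio_24h": np.log(tc.ratio_24h),
            }
            for tc in timecourses
        ]
    )
    groups = sorted(df["group"].unique())
    records = []
    # within-group 6 h vs 24 h (paired over subjects)
    for g in groups:
        sub = df[df["group"] == g]
        for (roi, hemi), block in sub.groupby(["roi", "hemisphere"]):
            block = block.dropna(subset=["log_ratio_6h"])
            if len(block) < 3:
                raise ValueError(f"ROI {roi} ({hemi}) in group {g} has < 3 complete subjects")
            d = block["log_ratio_24h"].to_numpy() - block["log_ratio_6h"].to_numpy()
            t, p = stats.ttest_rel(block["log_ratio_24h"], block["log_ratio_6h"])
            se = d.std(ddof=1) / np.sqrt(len(d))
            ci = stats.t.interval(0.95, len(d) - 1, loc=d.mean(), scale=max(se, 1e-300))
            records.append(
                {
                    "family": f"within:{g}:24h_vs_6h",
                    "roi": roi, "hemisphere": hemi, "group": g,
                    "estimate": float(d.mean()),
                    "ci_low": float(ci[0]), "ci_high": float(ci[1]),
                    "t": float(t), "p": float(p), "n": len(d),
                }
            )
    # between-group 24 h ratio (Welch)
    if len(groups) == 2:
        ga, gb = groups
        for (roi, hemi), block in df.groupby(["roi", "hemisphere"]):
            a = block[block["group"] == ga]["log_ratio_24h"].to_numpy()
            b = block[block["group"] == gb]["log_ratio_24h"].to_numpy()
            if len(a) < 3 or len(b) < 3:
                raise ValueError(f"ROI {roi} ({hemi}) has < 3 subjects in a group")
            t, p = stats.ttest_ind(a, b, equal_var=False)
            est = float(a.mean() - b.mean())
            se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
            dof = se**4 / (
                (a.var(ddof=1) / len(a)) ** 2 / (len(a) - 1)
                + (b.var(ddof=1) / len(b)) ** 2 / (len(b) - 1)
            )
            ci = stats.t.interval(0.95, dof, loc=est, scale=max(se, 1e-300))
            records.append(
                {
                    "family": f"between:{ga}_vs_{gb}:24h",
                    "roi": roi, "hemisphere": hemi, "group": f"{ga}-{gb}",
                    "estimate": est,
                    "ci_low": float(ci[0]), "ci_high": float(ci[1]),
                    "t": float(t), "p": float(p), "n": len(a) + len(b),
                }
            )
    out = pd.DataFrame.from_records(records)
    out["p_adj"] = np.nan
    for fam, idx in out.groupby("family").groups.items():
        p = out.loc[idx, "p"].to_numpy()
        # BH adjusted p-values from the same step-up rule used voxel-wise
        order = np.argsort(p, kind="stable")
        m = len(p)
        adj = np.empty(m)
        prev = 1.0
        for rank in range(m - 1, -1, -1):
            val = min(prev, p[order[rank]] * m / (rank + 1))
            adj[order[rank]] = val
            prev = val
        out.loc[idx, "p_adj"] = adj
    out["significant"] = out["p_adj"] <= q
    return out
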