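"""End-to-end orchestration: phantom/files -> preprocess -> statistics ->
quantification, with provenance.

The in-memory entry points (`preprocess_cohorts`, `analyze_study`) are what
tests and scripts drive; :func:`run_pipeline` wraps them with config
validation, file output, and a JSON run report whose tables are
byte-reproducible for a fixed master seed.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import AtlasBundle
from .config import Finding, RunConfig, child_seed, validate_config
from .image import BrainMask, VolumeImage, load_volume, save_volume
from .phantom import TIMEPOINTS, PhantomTruth, simulate_cohorts
from .preprocess import (
    RigidConfig,
    WarpConfig,
    apply_bias_field,
    build_mdt,
    compute_brain_mask,
    correct_bias,
    erode_mask,
    estimate_bias_field,
    estimate_warp,
    histogram_mode,
    modal_scale,
    propagate_to_timepoints,
    register_rigid,
    smooth_gaussian,
)
from .transforms import resample
from .quantify import (
    ROISpec,
    align_atlas,
    classify_dynamics,
    cohort_site_summary,
    extract_roi_timecourse,
    fractional_accumulation,
    fractional_table,
    locate_injection_site,
    roi_group_stats,
    site_to_stereotaxic,
)
from .statmap import contrast_suite
from .transforms import ComposedTransform

__all__ = [
    "PreprocessResult",
    "StudyResult",
    "preprocess_cohorts",
    "analyze_study",
    "run_pipeline",
    "load_file_cohorts",
]

Cohorts = dict[str, dict[str, dict[str, VolumeImage]]]


@dataclass
class PreprocessResult:
    aligned: Cohorts  # per group/subject/timepoint, on the MDT grid
    mdt: VolumeImage
    analysis_mask: np.ndarray
    mdt_diagnostics: dict
    reference_mode: float
    subject_chains: dict  # subject_id -> transform chain (pre -> MDT)
    scale_factors: dict  # subject_id -> {timepoint: modal factor}


@dataclass
class StudyResult:
    preprocess: PreprocessResult
    maps: dict  # contrast -> ThresholdedMap
    atlas_study: AtlasBundle
    fractions: dict  # contrast -> list[FractionalVolumeRow]
    dynamics: dict  # group -> list[DynamicsRow]
    sites: dict  # group -> list[InjectionSite]
    site_summaries: dict  # group -> summary dict
    roi_stats: pd.DataFrame | None
    roi_timecourses: list = field(default_factory=list)
    report: dict = field(default_factory=dict)


def load_file_cohorts(input_dir: str | Path) -> Cohorts:
    """Load sessions listed in ``manifest.csv`` (subject_id, group,
    timepoint, path) from a directory of NIfTI files."""
    input_dir = Path(input_dir)
    cohorts: Cohorts = {}
    with open(input_dir / "manifest.csv") as fh:
        for row in csv.DictReader(fh):
            img = load_volume(input_dir / row["path"])
            cohorts.setdefault(row["group"], {}).setdefault(row["subject_id"], {})[
                row["timepoint"]
            ] = img
    return cohorts


def preprocess_cohorts(
    cohorts: Cohorts,
    seed: int,
    rigid_config: RigidConfig | None = None,
    warp_config: WarpConfig | None = None,
    mdt_warp_config: WarpConfig | None = None,
    with_warp: bool = True,
    bias_order: int = 3,
) -> PreprocessResult:
    """Full normalization + alignment of raw cohorts.

    Per subject: brain mask from the pre-injection image, per-session bias
    correction, modal scaling to a seeded-randomly chosen reference pre
    image; then a two-pass MDT from all pre images; then one rigid + B-spline
    warp chain per subject estimated on its pre image against the MDT and
    applied unchanged to every session (two-step propagation, one resampling
    per image).
    """
    rng = np.random.default_rng(seed)
    order = [(g, sid) for g in sorted(cohorts) for sid in sorted(cohorts[g])]
    # -- mask / bias / modal scale -----------------------------------------
    masks: dict[str, BrainMask] = {}
    corrected: Cohorts = {g: {} for g in cohorts}
    for g, sid in order:
        sessions = cohorts[g][sid]
        if "pre" not in sessions:
            raise ValueError(f"subject {sid} lacks a pre-injection image")
        mask = compute_brain_mask(sessions["pre"])
        # intensity models (bias fit, histogram mode) use a rim-eroded mask so
        # partial-volume edge voxels cannot corrupt them; the bias field is
        # estimated on the pre-injection image only and applied unchanged to
        # every session (two-step principle, as for the geometric chain)
        fit_mask = erode_mask(mask, 0.25)
        masks[sid] = fit_mask
        field = estimate_bias_field(sessions["pre"], fit_mask, order=bias_order)
        corrected[g][sid] = {
            tp: apply_bias_field(img, field) for tp, img in sessions.items()
        }
    ref_g, ref_sid = order[int(rng.integers(len(order)))]
    reference_mode = histogram_mode(corrected[ref_g][ref_sid]["pre"], masks[ref_sid])
    scale_factors: dict[str, dict[str, float]] = {}
    scaled: Cohorts = {g: {} for g in cohorts}
    for g, sid in order:
        scaled[g][sid] = {}
        scale_factors[sid] = {}
        for tp, img in corrected[g][sid].items():
            out, f = modal_scale(img, masks[sid], reference_mode)
            scaled[g][sid][tp] = out
            scale_factors[sid][tp] = f
    # -- MDT from pre-injection images -------------------------------------
    pre_images = [scaled[g][sid]["pre"] for g, sid in order]
    if mdt_warp_config is None:
        mdt_warp_config = warp_config
    mdt_result = build_mdt(
        pre_images,
        seed=int(rng.integers(2**31)),
        rigid_config=rigid_config,
        warp_config=mdt_warp_config,
        with_warp=with_warp,
    )
    mdt = mdt_result.mdt
    mdt_mask = compute_brain_mask(mdt)
    # -- per-subject chain to the final MDT, propagated to all sessions ----
    aligned: Cohorts = {g: {} for g in cohorts}
    chains = {}
    for (g, sid) in order:
        pre = scaled[g][sid]["pre"]
        rigid = register_rigid(pre, mdt, fixed_mask=mdt_mask.data, config=rigid_config)
        if with_warp:
            moved = resample(pre, rigid, mdt)
            warp = estimate_warp(moved, mdt, mask=mdt_mask.data, config=warp_config)
            chain = ComposedTransform([rigid, warp])
        else:
            chain = rigid
        chains[sid] = chain
        tps = [tp for tp in TIMEPOINTS if tp in scaled[g][sid]]
        moved_all = propagate_to_timepoints(chain, [scaled[g][sid][tp] for tp in tps], mdt)
        aligned[g][sid] = dict(zip(tps, moved_all))
    return PreprocessResult(
        aligned=aligned,
        mdt=mdt,
        analysis_mask=mdt_mask.data,
        mdt_diagnostics=dict(mdt_result.diagnostics),
        reference_mode=float(reference_mode),
        subject_chains=chains,
        scale_factors=scale_factors,
    )


def _roi_specs(atlas_study: AtlasBundle, segment_bases: list[str]) -> list[ROISpec]:
    specs = []
    for base in segment_bases:
        for i in atlas_study.ids_for(base):
            entry = atlas_study.lut[i]
            idx = np.argwhere(atlas_study.labels == i)
            if idx.size == 0:
                continue
            center = tuple(int(round(v)) for v in idx.mean(axis=0))
            specs.append(ROISpec(name=entry.lateral_base, hemisphere=entry.hemisphere, center_index=center))
    return specs


def analyze_study(
    pre: PreprocessResult,
    atlas: AtlasBundle,
    q_within: float = 0.05,
    q_between: float = 0.01,
    fwhm_mm: float = 0.3,
    dynamics_delta: float = 0.05,
    roi_segments: list[str] | None = None,
    injection_groups: list[str] | None = None,
) -> StudyResult:
    """Statistics + quantification over a preprocessed study.

    Voxel-wise maps run on images smoothed at ``fwhm_mm``; ROI time courses
    and injection-site localization use the unsmoothed aligned images.
    """
    mask = BrainMask(pre.analysis_mask, pre.mdt.affine)
    smoothed: Cohorts = {
        g: {
            sid: {tp: smooth_gaussian(img, fwhm_mm, mask=mask) for tp, img in tps.items()}
            for sid, tps in subj.items()
        }
        for g, subj in pre.aligned.items()
    }
    maps = contrast_suite(smoothed, mask.data, q_within=q_within, q_between=q_between)
    atlas_study = align_atlas(atlas, pre.mdt, mdt_mask=mask.data)

    fractions = {name: fractional_accumulation(tm, atlas_study) for name, tm in maps.items()}
    dynamics = {}
    for g in sorted(pre.aligned):
        def frac_of(contrast: str) -> dict[str, float]:
            return {r.abbrev: r.fraction for r in fractions.get(f"{g}:{contrast}", [])}

        dynamics[g] = classify_dynamics(
            frac_of("6hgt30min"), frac_of("24hgt30min"), frac_of("24hgt6h"), delta=dynamics_delta
        )

    # injection sites from aligned, unsmoothed 30 min images; the search
    # region is the anterior half of the analysis mask, which covers both
    # dorsal (ACA-like) and deeper (IL/PL-like) medial prefrontal placements
    idx = np.argwhere(mask.data)
    cy = idx[:, 1].mean()
    anterior = np.zeros_like(mask.data)
    anterior[:, int(np.ceil(cy)):, :] = True
    anterior &= mask.data
    sites, summaries = {}, {}
    for g in injection_groups if injection_groups is not None else sorted(pre.aligned):
        glist = []
        for sid in sorted(pre.aligned[g]):
            if "30min" not in pre.aligned[g][sid]:
                continue
            site = locate_injection_site(
                pre.aligned[g][sid]["30min"], mask, search_region=anterior, subject_id=sid
            )
            site.ml_mm, site.ap_mm, site.dv_mm = site_to_stereotaxic(
                site.centroid_world, atlas_study, mask
            )
            glist.append(site)
        if glist:
            sites[g] = glist
            if len(glist) >= 2:
                summaries[g] = cohort_site_summary(glist)

    roi_stats = None
    roi_tcs = []
    if roi_segments:
        specs = _roi_specs(atlas_study, roi_segments)
        for g, subj in pre.aligned.items():
            for sid, tps in subj.items():
                for spec_ in specs:
                    roi_tcs.append(
                        extract_roi_timecourse(tps, spec_, mask=mask, subject_id=sid, group=g)
                    )
        if roi_tcs and all(len(s) >= 3 for s in (list(pre.aligned[g]) for g in pre.aligned)):
            roi_stats = roi_group_stats(roi_tcs)

    report = {
        "contrasts": {
            name: {
                "q": tm.q,
                "df": tm.parent.df if tm.parent else None,
                "critical_t": tm.critical_t,
                "n_suprathreshold": tm.n_suprathreshold,
            }
            for name, tm in maps.items()
        },
        "mdt_diagnostics": pre.mdt_diagnostics,
        "reference_mode": pre.reference_mode,
    }
    return StudyResult(
        preprocess=pre,
        maps=maps,
        atlas_study=atlas_study,
        fractions=fractions,
        dynamics=dynamics,
        sites=sites,
        site_summaries=summaries,
        roi_stats=roi_stats,
        roi_timecourses=roi_tcs,
        report=report,
    )


# ---------------------------------------------------------------------------
# File-level runner
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, through: str = "all") -> dict:
    """Execute the configured pipeline and write all outputs + a run report.

    ``through`` stops early after "simulate", "preprocess", or "stats".
    Raises ``ValueError`` on config validation errors; stage failures
    propagate with the stage name attached.
    """
    findings = validate_config(config)
    errors = [f for f in findings if f.severity == "error"]
    if errors:
        raise ValueError("config validation failed: " + "; ".join(f.message for f in errors))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": config.to_dict(),
        "findings": [str(f) for f in findings],
        "stages": [],
        "outputs": {},
        "seeds": {},
    }

    def _stage(name):
        report["stages"].append(name)

    def _write_csv(df: pd.DataFrame, rel: str) -> None:
        p = out / rel
        p.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(p, index=False, float_format="%.10g")
        report["outputs"][rel] = _sha256(p)

    try:
        _stage("simulate")
        truth: PhantomTruth | None = None
        if config.mode == "phantom":
            spec = config.phantom_spec()
            report["seeds"]["phantom"] = spec.seed
            cohorts, truth = simulate_cohorts(
                spec, out_dir=(out / "phantom") if config.write_intermediates else None
            )
            atlas = truth.atlas
        else:
            cohorts = load_file_cohorts(config.input_dir)
            atlas = AtlasBundle.load(config.atlas_dir)
        if through == "simulate":
            (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
            return report

        _stage("preprocess")
        reg = config.registration
        rigid_cfg = RigidConfig(**reg["rigid"]) if "rigid" in reg else None
        warp_cfg = WarpConfig(**reg["warp"]) if "warp" in reg else None
        pp_seed = child_seed(config.seed, "preprocess")
        report["seeds"]["preprocess"] = pp_seed
        pre = preprocess_cohorts(
            cohorts,
            seed=pp_seed,
            rigid_config=rigid_cfg,
            warp_config=warp_cfg,
            with_warp=reg.get("with_warp", True),
        )
        report["mdt_diagnostics"] = pre.mdt_diagnostics
        report["reference_mode"] = pre.reference_mode
        if config.write_intermediates:
            save_volume(pre.mdt, out / "mdt.nii.gz")
            report["outputs"]["mdt.nii.gz"] = _sha256(out / "mdt.nii.gz")
            for g, subj in pre.aligned.items():
                for sid, tps in subj.items():
                    for tp, img in tps.items():
                        rel = f"aligned/{sid}_{tp}.nii.gz"
                        save_volume(img, out / rel)
                        report["outputs"][rel] = _sha256(out / rel)
        if through == "preprocess":
            (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
            return report

        _stage("stats")
        study = analyze_study(
            pre,
            atlas,
            q_within=config.q_within,
            q_between=config.q_between,
            fwhm_mm=config.fwhm_mm,
            dynamics_delta=config.dynamics_delta,
            roi_segments=config.roi_segments if through != "stats" else None,
        )
        report.update(study.report)
        for name, tm in study.maps.items():
            safe = name.replace(":", "_").replace(">", "gt")
            save_volume(
                VolumeImage(tm.parent.t.astype(np.float32), pre.mdt.affine),
                out / f"maps/{safe}_t.nii.gz",
            )
            save_volume(
                VolumeImage(tm.binary.astype(np.uint8), pre.mdt.affine),
                out / f"maps/{safe}_thresh.nii.gz",
                dtype=np.uint8,
            )
            sidecar = {
                "contrast": name,
                "df": tm.parent.df,
                "tail": tm.parent.tail,
                "q": tm.q,
                "correction": tm.correction,
                "critical_t": tm.critical_t,
                "n_suprathreshold": tm.n_suprathreshold,
            }
            (out / f"maps/{safe}.json").write_text(json.dumps(sidecar, indent=2))
            for rel in (f"maps/{safe}_t.nii.gz", f"maps/{safe}_thresh.nii.gz", f"maps/{safe}.json"):
                report["outputs"][rel] = _sha256(out / rel)
        if through == "stats":
            (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
            return report

        _stage("quantify")
        _write_csv(fractional_table(study.fractions), "tables/fractional_volumes.csv")
        dyn_records = [
            {"group": g, "segment": r.segment, "category": r.category,
             "frac_6h": r.frac_6h, "frac_24h": r.frac_24h, "frac_24v6": r.frac_24v6}
            for g, rows in study.dynamics.items() for r in rows
        ]
        _write_csv(pd.DataFrame.from_records(dyn_records), "tables/dynamics.csv")
        site_records = [
            {"group": g, "subject_id": s.subject_id, "ml_mm": s.ml_mm, "ap_mm": s.ap_mm,
             "dv_mm": s.dv_mm, "n_core_voxels": s.n_core_voxels}
            for g, ss in study.sites.items() for s in ss
        ]
        _write_csv(pd.DataFrame.from_records(site_records), "tables/injection_sites.csv")
        (out / "tables/site_summaries.json").write_text(
            json.dumps(study.site_summaries, indent=2)
        )
        report["outputs"]["tables/site_summaries.json"] = _sha256(out / "tables/site_summaries.json")
        if study.roi_stats is not None:
            _write_csv(study.roi_stats, "tables/roi_stats.csv")
            roi_tc = pd.DataFrame(
                [
                    {"roi": tc.roi.name, "hemisphere": tc.roi.hemisphere, "subject_id": tc.subject_id,
                     "group": tc.group, **{f"mean_{tp}": v for tp, v in tc.means.items()},
                     "ratio_6h": tc.ratio_6h, "ratio_24h": tc.ratio_24h}
                    for tc in study.roi_timecourses
                ]
            )
            _write_csv(roi_tc, "tables/roi_timecourses.csv")
        report["site_summaries"] = study.site_summaries
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
        return report
    except ValueError:
        raise
    except Exception as e:
        stage = report["stages"][-1] if report["stages"] else "setup"
        raise RuntimeError(f"pipeline failed during stage {stage!r}: {e}") from e
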