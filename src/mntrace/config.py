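"""Run configuration: a single YAML/JSON document drives the whole pipeline.

A config either embeds a phantom spec (simulation mode) or points at a
directory of NIfTI sessions with a manifest plus an atlas bundle (file
mode).  ``validate_config`` returns findings without mutating state; the
pipeline refuses to run on any error-level finding.  One master seed fans
out to stage-specific child seeds through ``numpy``'s SeedSequence spawning
so each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .phantom import TIMEPOINTS, GroupPlan, InjectionPlan, PhantomSpec, _SEGMENT_TABLE

__all__ = ["RunConfig", "Finding", "load_config", "validate_config", "child_seed"]

_KNOWN_SEGMENT_BASES = {row[0] for row in _SEGMENT_TABLE}


@dataclass
class Finding:
    severity: str  # "error" | "warning"
    message: str

    def __str__(self) -> str:  # pragma: no cover
        return f"[{self.severity}] {self.message}"


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    mode: str = "phantom"  # "phantom" | "files"
    phantom: dict = field(default_factory=dict)  # PhantomSpec field overrides
    input_dir: str | None = None  # files mode: manifest.csv + NIfTI sessions
    atlas_dir: str | None = None  # files mode: AtlasBundle directory
    q_within: float = 0.05
    q_between: float = 0.01
    fwhm_mm: float = 0.3
    dynamics_delta: float = 0.05
    roi_segments: list = field(default_factory=lambda: ["DS", "RTN", "SNr", "BLA"])
    registration: dict = field(default_factory=dict)
    output_dir: str = "mntrace_out"
    seed: int = 0
    write_intermediates: bool = True

    def phantom_spec(self) -> PhantomSpec:
        """Materialize the phantom spec with config overrides applied."""
        overrides = dict(self.phantom)
        group_defs = overrides.pop("group_defs", None)
        spec = PhantomSpec(seed=child_seed(self.seed, "phantom"))
        for k, v in overrides.items():
            if not hasattr(spec, k):
                raise KeyError(f"unknown phantom parameter {k!r}")
            setattr(spec, k, tuple(v) if isinstance(getattr(spec, k), tuple) else v)
        if group_defs is not None:
            spec.group_defs = {
                name: GroupPlan(
                    injection=None if g.get("injection") is None else InjectionPlan(**g["injection"]),
                    schedule=[tuple(e) for e in g.get("schedule", [])],
                )
                for name, g in group_defs.items()
            }
        return spec

    def to_dict(self) -> dict:
        return asdict(self)


def child_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed derived from the master seed."""
    h = np.random.SeedSequence([int(master_seed), abs(hash_stable(stage)) % (2**31)])
    return int(h.generate_state(1)[0] % (2**31))


def hash_stable(text: str) -> int:
    """Stable (process-independent) string hash."""
    h = 2166136261
    for ch in text.encode():
        h = ((h ^ ch) * 16777619) % (2**32)
    return h


def load_config(path: str | Path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**doc)


def validate_config(config: RunConfig) -> list[Finding]:
    """Check a config; returns findings (never raises, never mutates)."""
    findings: list[Finding] = []
    err = lambda m: findings.append(Finding("error", m))  # noqa: E731
    warn = lambda m: findings.append(Finding("warning", m))  # noqa: E731

    if config.mode not in ("phantom", "files"):
        err(f"mode must be 'phantom' or 'files', got {config.mode!r}")
    for name, q in (("q_within", config.q_within), ("q_between", config.q_between)):
        if not 0.0 < q < 1.0:
            err(f"{name} must lie in (0, 1), got {q}")
    if config.fwhm_mm < 0:
        err(f"fwhm_mm must be >= 0, got {config.fwhm_mm}")
    if config.dynamics_delta <= 0:
        err(f"dynamics_delta must be > 0, got {config.dynamics_delta}")

    if config.mode == "phantom":
        try:
            spec = config.phantom_spec()
            spec.validate()
        except Exception as e:  # surfaced as a finding, not an exception
            err(f"phantom spec invalid: {e}")
        else:
            if spec.n_subjects_per_group < 3:
                warn("fewer than 3 subjects per group: paired t-maps will fail")
            for gname, plan in spec.group_defs.items():
                for seg, tp, f in plan.schedule:
                    if isinstance(seg, str) and seg.removesuffix("-L").removesuffix("-R") not in _KNOWN_SEGMENT_BASES:
                        err(f"group {gname!r}: unknown segment id {seg!r} in enhancement schedule")
                    if tp not in TIMEPOINTS:
                        err(f"group {gname!r}: unknown timepoint {tp!r} in schedule")
    else:
        if config.input_dir is None:
            err("files mode requires input_dir")
        elif not Path(config.input_dir).is_dir():
            err(f"input_dir does not exist: {config.input_dir}")
        else:
            manifest = Path(config.input_dir) / "manifest.csv"
            if not manifest.is_file():
                err(f"missing manifest: {manifest}")
            else:
                import csv

                with open(manifest) as fh:
                    for row in csv.DictReader(fh):
                        p = Path(config.input_dir) / row["path"]
                        if not p.is_file():
                            err(f"manifest references a missing file: {p}")
                        if row.get("timepoint") not in TIMEPOINTS:
                            err(f"manifest row with unknown timepoint {row.get('timepoint')!r}")
        if config.atlas_dir is None:
            err("files mode requires atlas_dir")
        elif not Path(config.atlas_dir).is_dir():
            err(f"atlas_dir does not exist: {config.atlas_dir}")

    for seg in config.roi_segments:
        if config.mode == "phantom" and seg.removesuffix("-L").removesuffix("-R") not in _KNOWN_SEGMENT_BASES:
            err(f"unknown ROI segment {seg!r}")
    return findings
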