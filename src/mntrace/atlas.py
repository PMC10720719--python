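"""Atlas bundle: grayscale template, integer label volume, lookup table.

The bundle mirrors how small-animal MRI atlases are distributed: a grayscale
template, a label image on the same grid, and a text lookup table naming each
label.  Two pieces of stereotaxic metadata that cannot be imaged by MR are
carried alongside: the world coordinate of bregma and the x position of the
mid-sagittal plane.  Lookup tables are read and written in the FSLeyes ``.lut``
convention (one line per label: id, three 0-1 RGB floats, display name); the
display name starts with the abbreviation, and bundle-level metadata
(bregma, midline, fiber-tract flags) lives in a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .image import VolumeImage, load_volume, save_volume

__all__ = ["LabelInfo", "AtlasBundle", "read_lut", "write_lut"]


@dataclass
class LabelInfo:
    """One lookup-table entry."""

    id: int
    abbrev: str
    name: str
    rgb: tuple[float, float, float]
    is_tract: bool = False

    @property
    def lateral_base(self) -> str:
        """Pair-merging key: 'DS-L' and 'DS-R' both map to 'DS'."""
        if self.abbrev.endswith(("-L", "-R")):
            return self.abbrev[:-2]
        return self.abbrev

    @property
    def hemisphere(self) -> str:
        if self.abbrev.endswith("-L"):
            return "left"
        if self.abbrev.endswith("-R"):
            return "right"
        return "midline"


@dataclass
class AtlasBundle:
    """Template + labels + lookup table + stereotaxic metadata."""

    gray: VolumeImage
    labels: np.ndarray  # integer volume on gray's grid
    lut: dict[int, LabelInfo]
    bregma_world: np.ndarray  # (3,) mm
    midline_x: float  # world x of the mid-sagittal plane
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.gray.shape:
            raise ValueError("gray template and label volume must share a grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label volume must be integer-typed")
        self.bregma_world = np.asarray(self.bregma_world, dtype=float).reshape(3)
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.lut)
        if missing:
            raise ValueError(f"label ids without lookup-table entries: {sorted(missing)}")

    @property
    def affine(self) -> np.ndarray:
        return self.gray.affine

    def label_image(self) -> VolumeImage:
        return VolumeImage(self.labels.astype(np.float32), self.gray.affine.copy())

    def ids_for(self, key: str | int) -> list[int]:
        """Resolve a label id, abbreviation, or bilateral base to label ids."""
        if isinstance(key, (int, np.integer)):
            if int(key) not in self.lut:
                raise KeyError(f"unknown label id {key}")
            return [int(key)]
        ids = [i for i, e in self.lut.items() if e.abbrev == key or e.lateral_base == key]
        if not ids:
            raise KeyError(f"unknown segment {key!r}")
        return sorted(ids)

    def bilateral_groups(self, include_tracts: bool = True) -> dict[str, list[int]]:
        """Map bilateral base abbreviation -> sorted label ids (L, R or midline)."""
        groups: dict[str, list[int]] = {}
        for i, entry in sorted(self.lut.items()):
            if not include_tracts and entry.is_tract:
                continue
            groups.setdefault(entry.lateral_base, []).append(i)
        return groups

    def mask_for(self, key: str | int) -> np.ndarray:
        return np.isin(self.labels, self.ids_for(key))

    # -- persistence --------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        save_volume(self.gray, directory / "template.nii.gz")
        save_volume(
            VolumeImage(self.labels.astype(np.int16), self.gray.affine),
            directory / "labels.nii.gz",
            dtype=np.int16,
        )
        write_lut(self.lut, directory / "labels.lut")
        meta = {}
        for k, v in self.meta.items():
            if isinstance(v, np.ndarray):
                save_volume(
                    VolumeImage(v.astype(np.uint8 if v.dtype == bool else np.float32), self.gray.affine),
                    directory / f"meta_{k}.nii.gz",
                    dtype=np.uint8 if v.dtype == bool else np.float32,
                )
                meta[k] = {"__volume__": f"meta_{k}.nii.gz", "bool": bool(v.dtype == bool)}
            else:
                meta[k] = v
        meta.update(
            {
                "bregma_world_mm": self.bregma_world.tolist(),
                "midline_x_mm": self.midline_x,
                "tract_ids": sorted(i for i, e in self.lut.items() if e.is_tract),
            }
        )
        (directory / "atlas.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "AtlasBundle":
        directory = Path(directory)
        gray = load_volume(directory / "template.nii.gz")
        labels = np.rint(load_volume(directory / "labels.nii.gz").voxels).astype(np.int16)
        lut = read_lut(directory / "labels.lut")
        meta = json.loads((directory / "atlas.json").read_text())
        for k, v in list(meta.items()):
            if isinstance(v, dict) and "__volume__" in v:
                arr = load_volume(directory / v["__volume__"]).voxels
                meta[k] = arr.astype(bool) if v.get("bool") else arr
        for tid in meta.get("tract_ids", []):
            if tid in lut:
                lut[tid].is_tract = True
        return cls(
            gray=gray,
            labels=labels,
            lut=lut,
            bregma_world=np.asarray(meta["bregma_world_mm"]),
            midline_x=float(meta["midline_x_mm"]),
            meta={k: v for k, v in meta.items() if k not in ("bregma_world_mm", "midline_x_mm", "tract_ids")},
        )


def write_lut(lut: dict[int, LabelInfo], path: str | Path) -> None:
    """Write an FSLeyes-style .lut: ``id  r g b  ABBREV full name``."""
    lines = []
    for i, e in sorted(lut.items()):
        r, g, b = e.rgb
        lines.append(f"{i} {r:.4f} {g:.4f} {b:.4f} {e.abbrev} {e.name}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_lut(path: str | Path) -> dict[int, LabelInfo]:
    lut: dict[int, LabelInfo] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 5:
            raise ValueError(f"malformed .lut line: {line!r}")
        i = int(parts[0])
        rgb = tuple(float(v) for v in parts[1:4])
        abbrev = parts[4]
        name = " ".join(parts[5:]) if len(parts) > 5 else abbrev
        lut[i] = LabelInfo(id=i, abbrev=abbrev, name=name, rgb=rgb)  # type: ignore[arg-type]
    return lut
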