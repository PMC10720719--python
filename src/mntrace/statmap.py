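"""Voxel-wise t-maps with Benjamini-Hochberg FDR thresholding.

Within-group contrasts are paired t-tests across timepoints of the same
subjects; the between-group contrast is a pooled-variance two-sample t-test
at matched timepoints.  All directional contrasts ("A > B") are one-sided,
matching statistical-parametric-mapping contrast semantics, and FDR is
computed per contrast over in-mask voxels only.  The realized critical t of
each thresholded map (the smallest t among rejected voxels) is reported; it
is data-dependent by construction and never hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .image import BrainMask, VolumeImage

__all__ = [
    "TMap",
    "ThresholdedMap",
    "paired_tmap",
    "two_sample_tmap",
    "p_from_t",
    "bh_fdr_threshold",
    "contrast_suite",
    "WITHIN_GROUP_CONTRASTS",
]

#: the study's within-group contrast family (one-sided, later > earlier)
WITHIN_GROUP_CONTRASTS = (
    ("30min", "pre"),
    ("6h", "30min"),
    ("24h", "30min"),
    ("24h", "6h"),
)


@dataclass
class TMap:
    """Voxel-wise t statistic volume with its degrees of freedom and contrast."""

    t: np.ndarray
    df: int
    contrast: str
    mask: np.ndarray
    paired: bool
    tail: str = "greater"  # one-sided by default; "two-sided" supported
    degenerate: np.ndarray | None = None  # sd == 0 with nonzero mean; excluded from FDR

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.t.shape != self.mask.shape:
            raise ValueError("t volume and mask must share a shape")
        if self.degenerate is None:
            self.degenerate = np.zeros(self.t.shape, dtype=bool)

    @property
    def valid(self) -> np.ndarray:
        """Voxels entering the p-value pool."""
        return self.mask & ~self.degenerate

    def p_values(self) -> np.ndarray:
        """P-value volume (NaN outside the valid pool)."""
        p = np.full(self.t.shape, np.nan)
        v = self.valid
        p[v] = p_from_t(self.t[v], self.df, tail=self.tail)
        return p


@dataclass
class ThresholdedMap:
    """Binary suprathreshold map from FDR (or uncorrected) thresholding."""

    binary: np.ndarray
    q: float
    correction: str  # "BH-FDR" or "none"
    critical_t: float
    n_suprathreshold: int
    contrast: str
    parent: TMap | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.binary = np.asarray(self.binary, dtype=bool)
        if self.n_suprathreshold != int(self.binary.sum()):
            raise ValueError("n_suprathreshold inconsistent with the binary map")


def _stack(images: list[VolumeImage | np.ndarray]) -> np.ndarray:
    arrs = [np.asarray(v.voxels if isinstance(v, VolumeImage) else v, dtype=np.float64) for v in images]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("all volumes must share a shape")
    return np.stack(arrs, axis=0)


def _as_mask(mask, shape) -> np.ndarray:
    m = mask.data if isinstance(mask, BrainMask) else np.asarray(mask)
    m = m.astype(bool)
    if m.shape != shape:
        raise ValueError("mask shape mismatch")
    return m


def paired_tmap(
    images_a: list, images_b: list, mask, contrast: str = "A>B", tail: str = "greater"
) -> TMap:
    """Paired t-map of matched per-subject volumes (same subjects, same order).

    Per voxel, d_i = A_i - B_i, t = mean(d) / (sd(d)/sqrt(n)), df = n-1.
    Voxels with sd = 0 and zero mean get t = 0; sd = 0 with nonzero mean is
    degenerate (constant nonzero difference) and is excluded from FDR.
    """
    if len(images_a) != len(images_b):
        raise ValueError("paired test needs matched subject lists of equal length")
    n = len(images_a)
    if n < 3:
        raise ValueError(f"paired t-test needs n >= 3 subjects, got {n}")
    d = _stack(images_a) - _stack(images_b)
    m = _as_mask(mask, d.shape[1:])
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    t = np.zeros(mean.shape)
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    degenerate = (~ok) & (mean != 0)
    return TMap(t=t, df=n - 1, contrast=contrast, mask=m, paired=True, tail=tail, degenerate=degenerate)


def two_sample_tmap(
    group_a: list, group_b: list, mask, contrast: str = "A>B", tail: str = "greater"
) -> TMap:
    """Pooled-variance two-sample t-map, df = n_a + n_b - 2.

    The one-sided tail tests mean(A) > mean(B); run the reversed argument
    order for the opposite direction (the map negates exactly).
    """
    na, nb = len(group_a), len(group_b)
    if na < 2 or nb < 2:
        raise ValueError("two-sample t-test needs n >= 2 per group")
    a = _stack(group_a)
    b = _stack(group_b)
    m = _as_mask(mask, a.shape[1:])
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    ss_a = ((a - mean_a) ** 2).sum(axis=0)
    ss_b = ((b - mean_b) ** 2).sum(axis=0)
    df = na + nb - 2
    pooled = (ss_a + ss_b) / df
    se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    t = np.zeros(mean_a.shape)
    ok = se > 0
    t[ok] = (mean_a - mean_b)[ok] / se[ok]
    degenerate = (~ok) & ((mean_a - mean_b) != 0)
    return TMap(t=t, df=df, contrast=contrast, mask=m, paired=False, tail=tail, degenerate=degenerate)


def p_from_t(t, df: int, tail: str = "greater"):
    """Student-t p-values: one-sided upper tail or two-sided."""
    if df < 1:
        raise ValueError("df must be >= 1")
    t = np.asarray(t, dtype=np.float64)
    if tail == "greater":
        p = stats.t.sf(t, df)
    elif tail == "two-sided":
        p = 2.0 * stats.t.sf(np.abs(t), df)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return p if p.shape else float(p)


def bh_reject(p: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up over a flat p-value vector.

    Rejects p <= p_(k) for the largest k with p_(k) <= k q / m; returns a
    boolean vector aligned with the input.
    """
    p = np.asarray(p, dtype=np.float64)
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    crit = (np.arange(1, m + 1) * q) / m
    passing = np.nonzero(sorted_p <= crit)[0]
    if passing.size == 0:
        return np.zeros(m, dtype=bool)
    k = passing[-1]
    return p <= sorted_p[k]


def bh_fdr_threshold(tmap: TMap, q: float) -> ThresholdedMap:
    """Threshold a t-map by Benjamini-Hochberg FDR over in-mask voxels.

    Degenerate voxels are excluded from the p-value pool (m excludes them).
    ``critical_t`` is the minimum t among rejected voxels (+inf when the map
    is empty).
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    valid = tmap.valid
    if not valid.any():
        raise ValueError("no valid in-mask voxels to threshold")
    p = p_from_t(tmap.t[valid], tmap.df, tail=tmap.tail)
    rej = bh_reject(p, q)
    binary = np.zeros(tmap.t.shape, dtype=bool)
    binary[valid] = rej
    critical_t = float(tmap.t[binary].min()) if binary.any() else float("inf")
    return ThresholdedMap(
        binary=binary,
        q=q,
        correction="BH-FDR",
        critical_t=critical_t,
        n_suprathreshold=int(binary.sum()),
        contrast=tmap.contrast,
        parent=tmap,
    )


def contrast_suite(
    cohorts: dict[str, dict[str, dict[str, VolumeImage]]],
    mask,
    q_within: float = 0.05,
    q_between: float = 0.01,
    between_timepoint: str = "24h",
) -> dict[str, ThresholdedMap]:
    """Run the study's contrast family over fully preprocessed, smoothed cohorts.

    Within each group: {30min>pre, 6h>30min, 24h>30min, 24h>6h} paired maps
    at ``q_within``; between the two groups at ``between_timepoint``: both
    directions at ``q_between``.  Keys are "<group>:<A>gt<B>" and
    "between:<A>gt<B>".
    """
    out: dict[str, ThresholdedMap] = {}
    for group, subjects in cohorts.items():
        sids = sorted(subjects)
        for later, earlier in WITHIN_GROUP_CONTRASTS:
            for sid in sids:
                for tp in (later, earlier):
                    if tp not in subjects[sid]:
                        raise ValueError(f"subject {sid} is missing timepoint {tp!r}")
            tm = paired_tmap(
                [subjects[s][later] for s in sids],
                [subjects[s][earlier] for s in sids],
                mask,
                contrast=f"{group}:{later}gt{earlier}",
            )
            out[tm.contrast] = bh_fdr_threshold(tm, q_within)
    groups = sorted(cohorts)
    if len(groups) == 2:
        ga, gb = groups
        vols = {
            g: [cohorts[g][s][between_timepoint] for s in sorted(cohorts[g])] for g in groups
        }
        for first, second in ((ga, gb), (gb, ga)):
            tm = two_sample_tmap(
                vols[first], vols[second], mask, contrast=f"between:{first}gt{second}"
            )
            out[tm.contrast] = bh_fdr_threshold(tm, q_between)
    return out
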