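"""Point-count stereology on ovarian sections.

Implements the classical area-fraction estimator: segment the tissue by gray
threshold, overlay a systematic uniform random grid of 500-600 points, assign
one structure to each point, and report each germ structure's share of
germ-cell points as a surface percentage (%GCS).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import remove_small_holes

from .stages import ATRESIA_LABELS, GERM_STAGES, GROUPS, canonical_label
from .synthetic import LabelImage

__all__ = [
    "TissueMask",
    "PointGrid",
    "PointAnnotation",
    "CompositionEstimate",
    "segment_tissue",
    "make_grid",
    "annotate_points",
    "estimate_composition",
    "replicate_composition",
]


@dataclass
class TissueMask:
    mask: np.ndarray
    threshold_used: float
    method: str

    @property
    def area(self) -> int:
        return int(np.count_nonzero(self.mask))


@dataclass
class PointGrid:
    """A square point lattice with systematic uniform random offset."""

    spacing: float
    offset: tuple[float, float]          # (dx, dy), each in [0, spacing)
    points: np.ndarray                   # (n, 2) float (x, y), in-mask only
    pixels: np.ndarray                   # (n, 2) int (x, y) sampled pixels
    seed: Optional[int] = None
    n_target: Optional[int] = None

    def __len__(self) -> int:
        return int(self.points.shape[0])


@dataclass(frozen=True)
class PointAnnotation:
    point_id: int
    x: float
    y: float
    structure: str


@dataclass
class CompositionEstimate:
    """Per-structure point counts and germ-cell surface percentages.

    ``gcs`` values are exact rationals (so they sum to exactly 100 over germ
    structures); cast to float for display.
    """

    counts: dict[str, int]
    n_germ: int
    gcs: dict[str, Fraction] = field(default_factory=dict)
    groups: dict[str, Fraction] = field(default_factory=dict)

    @property
    def n_points(self) -> int:
        return sum(self.counts.values())

    @property
    def pca(self) -> Fraction:
        return self.groups["pca"]

    @property
    def vit(self) -> Fraction:
        return self.groups["vit"]

    @classmethod
    def from_counts(cls, counts: dict[str, int]) -> "CompositionEstimate":
        return estimate_counts(counts)


def segment_tissue(
    gray: np.ndarray,
    method: str = "otsu",
    fixed_threshold: Optional[float] = None,
    max_hole: Optional[int] = None,
) -> TissueMask:
    """Threshold a grayscale image and keep the largest tissue component.

    Tissue is the set of pixels strictly darker than the threshold. Enclosed
    holes are filled (all of them when ``max_hole`` is None, else only holes
    of at most ``max_hole`` pixels). Raises ``ValueError`` when nothing is
    segmented.
    """
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("segment_tissue expects a 2-D grayscale image")
    if method == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed method requires fixed_threshold")
        thr = float(fixed_threshold)
    elif method == "otsu":
        if np.ptp(gray) == 0:
            raise ValueError("no tissue found: image is uniform")
        thr = float(threshold_otsu(gray))
    else:
        raise ValueError(f"unknown segmentation method: {method!r}")

    mask = gray <= thr  # tissue = dark side; otsu reports the last dark level
    if not mask.any():
        raise ValueError("no tissue found below the threshold")
    comps = cc_label(mask, connectivity=2)
    sizes = np.bincount(comps.ravel())
    sizes[0] = 0
    mask = comps == int(np.argmax(sizes))
    if max_hole is None:
        mask = ndimage.binary_fill_holes(mask)
    elif max_hole > 0:
        mask = remove_small_holes(mask, area_threshold=int(max_hole))
    return TissueMask(mask=mask, threshold_used=thr, method=method)


def _lattice_points(
    shape: tuple[int, int], spacing: float, offset: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """All lattice points (x, y) inside the image, and their sample pixels."""
    h, w = shape
    xs = np.arange(offset[0], w, spacing)
    ys = np.arange(offset[1], h, spacing)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    pix = np.round(pts).astype(int)
    ok = (pix[:, 0] < w) & (pix[:, 1] < h)
    return pts[ok], pix[ok]


def _count_in_mask(
    mask: np.ndarray, spacing: float, frac_offset: tuple[float, float]
) -> tuple[int, np.ndarray, np.ndarray, tuple[float, float]]:
    offset = (frac_offset[0] * spacing, frac_offset[1] * spacing)
    pts, pix = _lattice_points(mask.shape, spacing, offset)
    inside = mask[pix[:, 1], pix[:, 0]]
    return int(inside.sum()), pts[inside], pix[inside], offset


def make_grid(
    mask: TissueMask | np.ndarray,
    n_target: int = 550,
    seed: Optional[int] = None,
    n_min: int = 500,
    n_max: int = 600,
    spacing: Optional[float] = None,
    offset: Optional[tuple[float, float]] = None,
    max_iter: int = 200,
) -> PointGrid:
    """Lay a systematic uniform random point grid over the tissue mask.

    The lattice spacing starts at sqrt(area / n_target) and the offset is
    uniform in [0, spacing)^2. If the in-mask point count falls outside
    [n_min, n_max], the spacing is adjusted by bisection (the offset keeps
    the same fractional position within a cell) until it does.

    Passing explicit ``spacing``/``offset`` bypasses target-count adjustment
    (used e.g. for the exhaustive spacing-1 oracle).
    """
    m = mask.mask if isinstance(mask, TissueMask) else np.asarray(mask, dtype=bool)
    area = int(np.count_nonzero(m))
    if area == 0:
        raise ValueError("empty tissue mask")

    rng = np.random.default_rng(seed)
    if spacing is not None:
        if spacing <= 0:
            raise ValueError("spacing must be > 0")
        off = (0.0, 0.0) if offset is None else offset
        frac = (off[0] / spacing % 1.0, off[1] / spacing % 1.0) if spacing > 0 else (0.0, 0.0)
        n, pts, pix, off = _count_in_mask(m, spacing, frac)
        return PointGrid(spacing=spacing, offset=off, points=pts, pixels=pix,
                         seed=seed, n_target=n_target)

    if area < n_min:
        raise ValueError(
            f"mask too small ({area} px) to hold {n_min} points at >= 1 px spacing"
        )
    frac = (float(rng.uniform()), float(rng.uniform()))
    s = math.sqrt(area / n_target)

    n, pts, pix, off = _count_in_mask(m, s, frac)
    if n_min <= n <= n_max:
        return PointGrid(spacing=s, offset=off, points=pts, pixels=pix,
                         seed=seed, n_target=n_target)

    # Bracket: count decreases with spacing. lo -> too many points, hi -> too few.
    lo = hi = s
    it = 0
    if n > n_max:
        while it < max_iter:
            it += 1
            hi = hi * 1.25
            n_hi, *_ = _count_in_mask(m, hi, frac)
            if n_hi <= n_max:
                break
        else:
            raise ValueError("could not bracket grid spacing from above")
    else:
        while it < max_iter and lo > 1.0:
            it += 1
            lo = max(1.0, lo / 1.25)
            n_lo, *_ = _count_in_mask(m, lo, frac)
            if n_lo >= n_min:
                break
        n_lo, *_ = _count_in_mask(m, lo, frac)
        if n_lo < n_min:
            raise ValueError(
                f"mask too small: only {n_lo} in-mask points at 1 px spacing"
            )

    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        n, pts, pix, off = _count_in_mask(m, mid, frac)
        if n_min <= n <= n_max:
            return PointGrid(spacing=mid, offset=off, points=pts, pixels=pix,
                             seed=seed, n_target=n_target)
        if n > n_max:
            lo = mid
        else:
            hi = mid
    raise ValueError(
        f"grid adjustment failed: could not reach {n_min}-{n_max} in-mask points"
    )


def annotate_points(
    grid: PointGrid,
    labels: LabelImage,
    zp_to_owner: bool = True,
) -> list[PointAnnotation]:
    """Assign each grid point the structure of the pixel it falls on.

    Zona pellucida pixels are attributed to their owner oocyte's stage when
    ``zp_to_owner`` (the default; the estimator counts whole-follicle
    surfaces). Background pixels map to ``unknown``.
    """
    h, w = labels.labels.shape
    out: list[PointAnnotation] = []
    for pid, ((x, y), (px, py)) in enumerate(zip(grid.points, grid.pixels)):
        if not (0 <= px < w and 0 <= py < h):
            raise ValueError(f"point {pid} at ({px}, {py}) is out of bounds")
        name = labels.structure_at(int(px), int(py), zp_to_owner=zp_to_owner)
        if name == "background":
            name = "unknown"
        out.append(PointAnnotation(point_id=pid, x=float(x), y=float(y), structure=name))
    return out


def estimate_counts(counts: dict[str, int]) -> CompositionEstimate:
    """Build a CompositionEstimate from per-structure point counts."""
    n_germ = sum(counts.get(s, 0) for s in GERM_STAGES)
    if n_germ == 0:
        raise ValueError("no germ-cell points: composition undefined")
    gcs = {s: Fraction(100 * counts.get(s, 0), n_germ) for s in GERM_STAGES}
    groups = {
        g: sum((gcs[s] for s in members), Fraction(0))
        for g, members in GROUPS.items()
    }
    return CompositionEstimate(counts=dict(counts), n_germ=n_germ, gcs=gcs, groups=groups)


def estimate_composition(
    annotations: Iterable[PointAnnotation | str],
) -> CompositionEstimate:
    """Point counts and %GCS from a slide's point annotations.

    %GCS_i = 100 * count_i / n_germ, where n_germ sums over the ten germ
    structures only; atresia, lysis, and non-germ structures are counted but
    excluded from the denominator. Raises ``ValueError`` when no germ-cell
    point is present.
    """
    counts: Counter[str] = Counter()
    for a in annotations:
        name = a.structure if isinstance(a, PointAnnotation) else str(a)
        counts[canonical_label(name)] += 1
    if not counts:
        raise ValueError("no annotations given")
    return estimate_counts(dict(counts))


def replicate_composition(
    labels: LabelImage,
    n_replicates: int,
    seeds: Optional[Sequence[int]] = None,
    n_target: int = 550,
    mask: Optional[TissueMask | np.ndarray] = None,
) -> pd.DataFrame:
    """Mean and SE of %GCS across independent grid offsets on one section.

    Returns a frame indexed by germ structure with columns ``mean``, ``se``,
    and ``n_replicates``. Grids that yield no germ point are skipped.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    if seeds is None:
        seeds = list(range(n_replicates))
    elif len(seeds) != n_replicates:
        raise ValueError("len(seeds) must equal n_replicates")
    m = labels.labels > 0 if mask is None else mask
    rows = []
    for sd in seeds:
        grid = make_grid(m, n_target=n_target, seed=int(sd))
        est = estimate_composition(annotate_points(grid, labels))
        rows.append({s: float(est.gcs[s]) for s in GERM_STAGES})
    frame = pd.DataFrame(rows)
    out = pd.DataFrame(
        {
            "mean": frame.mean(axis=0),
            "se": frame.std(axis=0, ddof=1) / math.sqrt(len(frame)),
        }
    )
    out["n_replicates"] = len(frame)
    out.index.name = "structure"
    return out


# Re-export for annotation consumers that care about the atresia labels.
ATRESIA = ATRESIA_LABELS
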