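"""Synthetic ovarian cross-sections and fish populations with known truth.

``generate_section`` renders a label image of an ovary section (wall ring,
central lumen, germinal epithelium, blood vessels) and packs it with
non-overlapping circular follicles whose diameters follow each stage's
configured distribution, until the realized germ-area composition is within
tolerance of a target. Because every structure is stamped onto an integer
label array, the ground-truth area fractions are exact pixel counts.

``generate_population`` draws a fish population whose maturity-by-length
follows a configurable logistic curve, with per-fish germ-cell compositions
and body/gonad weights, so the ogive stage can be tested against known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.special import expit
from skimage.draw import disk as _disk_coords
from skimage.draw import ellipse as _ellipse_coords

from .stages import (
    ATRESIA_LABELS,
    DEFAULT_STAGES,
    GERM_STAGES,
    GROUPS,
    StagePrototype,
    sample_stage_diameter,
)

__all__ = [
    "SectionSpec",
    "LabelImage",
    "PopulationSpec",
    "expand_composition",
    "generate_section",
    "render_grayscale",
    "default_palette",
    "generate_population",
    "draw_composition_counts",
    "LABEL_CODES",
]

# Fixed label codes. Germ stages occupy 10 + rank; the zona pellucida annulus
# of a stage occupies 30 + rank and is resolved to its owner stage.
LABEL_CODES: dict[str, int] = {
    "background": 0,
    "wall": 1,
    "lumen": 2,
    "epithelium": 3,
    "blood_vessel": 4,
    "aoa": 5,
    "aob": 6,
    "lysis": 7,
}
for _i, _s in enumerate(GERM_STAGES):
    LABEL_CODES[_s] = 10 + _i
_ZP_CODE = {s: 30 + i for i, s in enumerate(GERM_STAGES)}


@dataclass
class SectionSpec:
    """Geometry, scale, and target composition of one synthetic section.

    ``composition`` maps germ structures (stage ids or display groups such as
    ``pca``/``vit``) to target germ-area fractions summing to 1. Scale is
    pixels per µm (default 0.5, i.e. 1 px = 2 µm).
    """

    width: int = 1200
    height: int = 900
    px_per_um: float = 0.5
    composition: Mapping[str, float] = field(default_factory=lambda: {"pca": 1.0})
    seed: int = 0
    germ_fill: float = 0.45        # germ area as a fraction of epithelium area
    tolerance: float = 0.02        # max |realized - target| per structure
    wall_px: int = 6
    lumen_frac: float = 0.12
    n_vessels: int = 4
    n_atresia: Mapping[str, int] = field(default_factory=dict)
    include_zp: bool = True
    max_failures: int = 20000

    def __post_init__(self) -> None:
        if self.px_per_um <= 0:
            raise ValueError("px_per_um must be > 0")
        total = float(sum(self.composition.values()))
        if any(v < 0 for v in self.composition.values()) or abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"composition fractions must be >= 0 and sum to 1 (got {total})"
            )


@dataclass
class LabelImage:
    """A labelled section with exact ground-truth area fractions.

    ``truth`` holds each germ stage's exact pixel-area fraction among germ
    pixels (zona pellucida pixels attributed to their owner stage);
    ``truth_counts`` the underlying integer pixel counts.
    """

    labels: np.ndarray
    legend: dict[int, str]
    zp_owner: dict[int, str]
    truth: dict[str, float]
    truth_counts: dict[str, int]
    spec: Optional[SectionSpec] = None
    gray: Optional[np.ndarray] = None

    def structure_at(self, x: int, y: int, zp_to_owner: bool = True) -> str:
        """Structure name at pixel (x=column, y=row)."""
        code = int(self.labels[y, x])
        if zp_to_owner and code in self.zp_owner:
            return self.zp_owner[code]
        return self.legend.get(code, "unknown")

    def truth_groups(self) -> dict[str, float]:
        """Truth fractions aggregated to display groups."""
        return {
            g: sum(self.truth.get(s, 0.0) for s in members)
            for g, members in GROUPS.items()
        }


def expand_composition(composition: Mapping[str, float]) -> dict[str, float]:
    """Expand display-group keys (pca, vit, ...) to per-stage fractions.

    Group mass is split equally among member stages. Stage-level keys pass
    through; unknown keys raise ``KeyError``.
    """
    out: dict[str, float] = {}
    for key, frac in composition.items():
        if key in GERM_STAGES:
            out[key] = out.get(key, 0.0) + float(frac)
        elif key in GROUPS:
            members = GROUPS[key]
            for s in members:
                out[s] = out.get(s, 0.0) + float(frac) / len(members)
        else:
            raise KeyError(f"unknown composition key: {key!r}")
    return out


def _stamp_check(labels: np.ndarray, rr: np.ndarray, cc: np.ndarray, free_code: int) -> bool:
    """True if every (rr, cc) pixel currently holds ``free_code``."""
    if rr.size == 0:
        return False
    if rr.min() < 0 or cc.min() < 0:
        return False
    if rr.max() >= labels.shape[0] or cc.max() >= labels.shape[1]:
        return False
    return bool(np.all(labels[rr, cc] == free_code))


def generate_section(
    spec: SectionSpec,
    stages: Optional[Mapping[str, StagePrototype]] = None,
) -> LabelImage:
    """Render a label image whose germ composition matches ``spec`` targets.

    Follicles are placed by rejection sampling (uniform centers over the
    epithelium, no overlap) largest stage first, each stage until its pixel
    area is within the per-structure slack of its target. Raises
    ``RuntimeError`` reporting achieved fractions when the target cannot be
    reached within ``spec.max_failures`` rejected placements.
    """
    table = dict(DEFAULT_STAGES if stages is None else stages)
    comp = expand_composition(spec.composition)
    rng = np.random.default_rng(spec.seed)

    h, w = spec.height, spec.width
    labels = np.zeros((h, w), dtype=np.int16)
    cy, cx = h / 2.0, w / 2.0
    ry, rx = 0.45 * h, 0.45 * w

    rr, cc = _ellipse_coords(cy, cx, ry, rx, shape=(h, w))
    labels[rr, cc] = LABEL_CODES["wall"]
    rr, cc = _ellipse_coords(cy, cx, ry - spec.wall_px, rx - spec.wall_px, shape=(h, w))
    labels[rr, cc] = LABEL_CODES["epithelium"]
    if spec.lumen_frac > 0:
        rr, cc = _ellipse_coords(
            cy, cx, spec.lumen_frac * ry, spec.lumen_frac * rx, shape=(h, w)
        )
        labels[rr, cc] = LABEL_CODES["lumen"]

    epi_code = LABEL_CODES["epithelium"]
    epi_rows, epi_cols = np.nonzero(labels == epi_code)
    if epi_rows.size == 0:
        raise RuntimeError("section too small: no epithelium interior")

    # Small round blood vessels scattered in the epithelium.
    placed_vessels = 0
    guard = 0
    while placed_vessels < spec.n_vessels and guard < 1000:
        guard += 1
        i = rng.integers(epi_rows.size)
        r = int(rng.integers(3, 7))
        vr, vc = _disk_coords((epi_rows[i], epi_cols[i]), r, shape=(h, w))
        if _stamp_check(labels, vr, vc, epi_code):
            labels[vr, vc] = LABEL_CODES["blood_vessel"]
            placed_vessels += 1

    a_epi = int(np.count_nonzero(labels == epi_code))
    a_total = spec.germ_fill * a_epi
    targets = {s: comp[s] * a_total for s in comp}
    # Each stage keeps packing until it reaches its target and rejects discs
    # that would overshoot target + slack: per-stage area error stays within
    # [0, slack], so realized fractions deviate by at most ~slack/a_total.
    slack = 0.25 * spec.tolerance * a_total

    areas: dict[str, int] = {s: 0 for s in comp}
    order = sorted(comp, key=lambda s: -table[s].mean_diameter)

    for s in order:
        if targets[s] <= 0:
            continue
        failures = 0  # per-stage rejection budget
        proto = table[s]
        zp_px = 0
        if spec.include_zp and proto.zp_mean is not None:
            zp_px = max(1, int(round(proto.zp_mean * spec.px_per_um)))
        while areas[s] < targets[s]:
            if failures > spec.max_failures:
                achieved = _fractions(areas)
                raise RuntimeError(
                    "could not reach target composition within "
                    f"{spec.max_failures} rejected placements; achieved {achieved}"
                )
            d_um = sample_stage_diameter(proto, rng)
            r_px = max(1, int(round(d_um * spec.px_per_um / 2.0)))
            i = int(rng.integers(epi_rows.size))
            center = (int(epi_rows[i]), int(epi_cols[i]))
            remaining = targets[s] - areas[s]

            stage_zp = zp_px
            if s != "POF" and math.pi * (r_px + stage_zp) ** 2 > remaining + slack:
                # the sampled follicle would overshoot: stamp a smaller filler
                # disc sized to the remaining gap instead (no zp annulus);
                # keeps per-stage area within one pixel-rounding of target
                r_px = int(math.floor(math.sqrt(remaining / math.pi)))
                stage_zp = 0
                if r_px < 1:
                    break

            if s == "POF":
                gap0 = float(rng.uniform(0, 2 * math.pi))
                rr_o, cc_o = _disk_coords(center, r_px, shape=(h, w))
                if not _stamp_check(labels, rr_o, cc_o, epi_code):
                    failures += 1
                    continue
                shell = max(2, int(round(15 * spec.px_per_um)))
                rr_i, cc_i = _disk_coords(center, max(1, r_px - shell), shape=(h, w))
                ring = np.ones((h, w), dtype=bool)
                ring[:] = False
                ring[rr_o, cc_o] = True
                ring[rr_i, cc_i] = False
                ring_r, ring_c = np.nonzero(ring)
                ang = np.arctan2(ring_r - center[0], ring_c - center[1]) % (2 * math.pi)
                keep = ((ang - gap0) % (2 * math.pi)) > (math.pi / 3)  # 60 deg opening
                ring_r, ring_c = ring_r[keep], ring_c[keep]
                add = ring_r.size
                if areas[s] + add > targets[s] + slack:
                    if areas[s] >= targets[s] - slack:
                        break  # close enough; smaller shells are not sampleable
                    failures += 1
                    continue
                labels[ring_r, ring_c] = LABEL_CODES[s]
                areas[s] += add
                continue

            rr_t, cc_t = _disk_coords(center, r_px + stage_zp, shape=(h, w))
            if not _stamp_check(labels, rr_t, cc_t, epi_code):
                failures += 1
                continue
            add = rr_t.size  # oocyte + zp both attributed to the stage
            if areas[s] + add > targets[s] + slack:
                failures += 1
                continue
            if stage_zp > 0:
                labels[rr_t, cc_t] = _ZP_CODE[s]
                rr_c, cc_c = _disk_coords(center, r_px, shape=(h, w))
                labels[rr_c, cc_c] = LABEL_CODES[s]
            else:
                labels[rr_t, cc_t] = LABEL_CODES[s]
            areas[s] += add

    # Optional atretic structures / lysis areas (not part of germ truth).
    for lab, n in spec.n_atresia.items():
        if lab not in ATRESIA_LABELS:
            raise KeyError(f"unknown atresia label: {lab!r}")
        placed = 0
        guard = 0
        while placed < n and guard < 5000:
            guard += 1
            i = int(rng.integers(epi_rows.size))
            r = int(rng.integers(5, 12))
            ar, ac = _disk_coords((int(epi_rows[i]), int(epi_cols[i])), r, shape=(h, w))
            if _stamp_check(labels, ar, ac, epi_code):
                labels[ar, ac] = LABEL_CODES[lab]
                placed += 1

    # Exact truth from the stamped pixel counts.
    counts = np.bincount(labels.ravel(), minlength=64)
    truth_counts: dict[str, int] = {}
    for s in GERM_STAGES:
        c = int(counts[LABEL_CODES[s]])
        if s in _ZP_CODE and _ZP_CODE[s] < counts.size:
            c += int(counts[_ZP_CODE[s]])
        if c:
            truth_counts[s] = c
    n_germ_px = sum(truth_counts.values())
    if n_germ_px == 0:
        raise RuntimeError("no germ structures were placed")
    truth = {s: c / n_germ_px for s, c in truth_counts.items()}

    realized = _fractions(areas)
    for s, target in comp.items():
        if abs(realized.get(s, 0.0) - target) > spec.tolerance:
            raise RuntimeError(
                f"composition outside tolerance for {s!r}: achieved {realized}"
            )

    legend = {code: name for name, code in LABEL_CODES.items()}
    zp_owner = {code: s for s, code in _ZP_CODE.items()}
    for code, s in zp_owner.items():
        legend[code] = f"zp:{s}"
    return LabelImage(
        labels=labels,
        legend=legend,
        zp_owner=zp_owner,
        truth=truth,
        truth_counts=truth_counts,
        spec=spec,
    )


def _fractions(areas: Mapping[str, int]) -> dict[str, float]:
    total = sum(areas.values())
    if total == 0:
        return {s: 0.0 for s in areas}
    return {s: a / total for s, a in areas.items()}


def default_palette(label_image: LabelImage) -> dict[str, int]:
    """Gray level per structure name; background lighter than all tissue."""
    pal = {
        "background": 235,
        "wall": 60,
        "lumen": 205,
        "epithelium": 150,
        "blood_vessel": 90,
        "aoa": 100,
        "aob": 105,
        "lysis": 110,
    }
    for i, s in enumerate(GERM_STAGES):
        pal[s] = 40 + 10 * i
        pal[f"zp:{s}"] = 45
    return pal


def render_grayscale(
    label_image: LabelImage,
    palette: Optional[Mapping[str, int]] = None,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Deterministic 8-bit grayscale rendering of a label image.

    Every label present in the image must have a palette entry (keyed by its
    legend name); optional additive Gaussian noise with the stated sd.
    """
    pal = default_palette(label_image) if palette is None else dict(palette)
    labels = label_image.labels
    present = np.unique(labels)
    lut = np.zeros(int(present.max()) + 1, dtype=np.float64)
    for code in present:
        name = label_image.legend.get(int(code), "unknown")
        if name not in pal:
            raise KeyError(f"palette has no entry for label {name!r}")
        lut[int(code)] = pal[name]
    gray = lut[labels]
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        gray = gray + rng.normal(0.0, noise_sd, size=gray.shape)
    out = np.clip(np.round(gray), 0, 255).astype(np.uint8)
    label_image.gray = out
    return out


# ---------------------------------------------------------------------------
# Population generator
# ---------------------------------------------------------------------------

_DEFAULT_TEMPLATES: dict[str, dict[str, float]] = {
    "immature": {"pca": 0.88, "cao": 0.12},
    "mature": {"pca": 0.32, "cao": 0.12, "vit": 0.28, "pho": 0.12, "ho": 0.06, "POF": 0.10},
}

# Mean/sd of the gonadosomatic index by maturity phase, percent. Configurable
# plumbing: the study reports only phase means (highest ~22% for phase C).
_DEFAULT_GSI = {
    "A": (0.7, 0.25),
    "B": (3.0, 1.2),
    "C": (22.0, 4.0),
    "D": (5.0, 1.8),
}


@dataclass
class PopulationSpec:
    """Sampling frame for a synthetic fish population."""

    n_fish: int = 151
    length_range: tuple[float, float] = (12.0, 30.0)
    true_L50: float = 20.6
    logistic_slope: float = 1.5   # per cm
    months: tuple[int, ...] = tuple(range(1, 13))
    seed: int = 0
    templates: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: _DEFAULT_TEMPLATES
    )
    month_templates: Mapping[int, Mapping[str, float]] = field(default_factory=dict)
    concentration: float = 150.0  # Dirichlet concentration around the template
    gsi_profile: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: _DEFAULT_GSI
    )
    lw_a: float = 0.0085          # length-weight: soma grams = a * L^b
    lw_b: float = 3.05

    def __post_init__(self) -> None:
        if self.n_fish < 1:
            raise ValueError("n_fish must be >= 1")
        lo, hi = self.length_range
        if not (lo < self.true_L50 < hi):
            raise ValueError("true_L50 must lie within length_range")


def _dirichlet_around(
    template: Mapping[str, float], conc: float, rng: np.random.Generator
) -> dict[str, float]:
    """Dirichlet draw with mean equal to the (stage-expanded) template."""
    tpl = expand_composition(template)
    keys = [k for k, v in tpl.items() if v > 0]
    alpha = np.array([tpl[k] for k in keys]) * conc
    draw = rng.dirichlet(alpha)
    out = {k: 0.0 for k in tpl}
    for k, v in zip(keys, draw):
        out[k] = float(v)
    return out


def generate_population(
    pop: PopulationSpec,
    stages: Optional[Mapping[str, StagePrototype]] = None,
) -> pd.DataFrame:
    """Draw a population whose maturity follows logistic(length; L50, slope).

    Returns a frame with one row per fish: biometrics, sampling month, the
    latent true maturity flag, and per-stage composition fraction columns
    (``comp_<stage>``). Gonad weights are set so GSI follows the configured
    per-phase profile.
    """
    from . import staging  # deferred: staging imports stages only

    rng = np.random.default_rng(pop.seed)
    n = pop.n_fish
    lengths = rng.uniform(*pop.length_range, size=n)
    p_mat = expit(pop.logistic_slope * (lengths - pop.true_L50))
    mature = rng.random(n) < p_mat
    months = rng.choice(np.asarray(pop.months), size=n)

    rows = []
    for i in range(n):
        if mature[i] and int(months[i]) in pop.month_templates:
            template = pop.month_templates[int(months[i])]
        else:
            template = pop.templates["mature" if mature[i] else "immature"]
        comp = _dirichlet_around(template, pop.concentration, rng)

        pseudo_counts = {s: int(round(1000 * f)) for s, f in comp.items() if f > 0}
        phase = staging.assign_phase_from_counts(pseudo_counts).phase
        mu, sd = pop.gsi_profile.get(phase, (1.0, 0.5))
        gsi = max(0.05, float(rng.normal(mu, sd)))
        soma = pop.lw_a * lengths[i] ** pop.lw_b
        gonad = gsi / 100.0 * soma
        row = {
            "fish_id": f"F{i:04d}",
            "month": int(months[i]),
            "length_cm": float(lengths[i]),
            "ungutted_weight_g": float(soma + gonad),
            "gonad_weight_g": float(gonad),
            "true_mature": bool(mature[i]),
            "visual_phase": phase,
        }
        for s in GERM_STAGES:
            row[f"comp_{s}"] = comp.get(s, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def draw_composition_counts(
    composition: Mapping[str, float],
    n_germ: int,
    rng: np.random.Generator,
) -> dict[str, int]:
    """Multinomial point counts emulating a stereology read of a composition."""
    comp = expand_composition(composition)
    keys = list(comp)
    draws = rng.multinomial(n_germ, np.array([comp[k] for k in keys]))
    return {k: int(c) for k, c in zip(keys, draws) if c > 0}
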