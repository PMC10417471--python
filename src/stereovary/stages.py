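"""Germ-cell stage taxonomy for ovarian cross-sections.

Defines the ordered developmental stages of the female germline (oogonia
through hydrated oocyte, plus the post-ovulatory follicle), their default
follicle-diameter distributions and zona-pellucida thicknesses, the display
grouping used in summaries (``pca``/``cao``/``vit``/``pho``/``ho``/``POF``),
and the controlled vocabulary of non-germ structures that a stereology
sampling point may land on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "StagePrototype",
    "DEFAULT_STAGES",
    "GERM_STAGES",
    "STAGE_RANK",
    "GROUPS",
    "GROUP_ORDER",
    "GROUP_OF",
    "ATRESIA_LABELS",
    "NON_GERM_LABELS",
    "ALL_LABELS",
    "canonical_label",
    "get_stage",
    "sample_stage_diameter",
]


@dataclass(frozen=True)
class StagePrototype:
    """Identity and morphometry of one germ-cell stage.

    Parameters
    ----------
    stage_id : str
        One of ``og, po1, po2, cao, vit1, vit2, vit3, pho, ho, POF``.
    mean_diameter, sd_diameter : float
        Follicle diameter distribution in µm.
    rank : int
        Ordinal position in the developmental sequence (og=0 ... POF=9).
    zp_mean, zp_sd : float, optional
        Zona pellucida thickness in µm, absent for stages where it has not
        yet formed (or is not measured).
    """

    stage_id: str
    mean_diameter: float
    sd_diameter: float
    rank: int
    zp_mean: Optional[float] = None
    zp_sd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mean_diameter <= 0:
            raise ValueError(f"{self.stage_id}: mean_diameter must be > 0")
        if self.sd_diameter < 0:
            raise ValueError(f"{self.stage_id}: sd_diameter must be >= 0")
        if self.zp_mean is not None and self.zp_mean <= 0:
            raise ValueError(f"{self.stage_id}: zp_mean must be > 0")


# Default follicle diameters (µm) and zona pellucida thicknesses (µm).
# The POF has no follicle diameter of its own; the value below is a rendering
# size for the collapsed theca/granulosa shell, not a biological measurement.
DEFAULT_STAGES: dict[str, StagePrototype] = {
    "og": StagePrototype("og", 14.3, 4.6, 0),
    "po1": StagePrototype("po1", 29.6, 5.4, 1),
    "po2": StagePrototype("po2", 82.7, 15.9, 2),
    "cao": StagePrototype("cao", 153.1, 17.8, 3),
    "vit1": StagePrototype("vit1", 191.5, 29.1, 4),
    "vit2": StagePrototype("vit2", 380.0, 57.2, 5, zp_mean=9.2, zp_sd=1.6),
    "vit3": StagePrototype("vit3", 629.5, 88.5, 6, zp_mean=53.81, zp_sd=5.10),
    "pho": StagePrototype("pho", 847.2, 104.0, 7, zp_mean=33.1, zp_sd=3.5),
    "ho": StagePrototype("ho", 958.7, 60.7, 8, zp_mean=40.4, zp_sd=5.0),
    "POF": StagePrototype("POF", 300.0, 60.0, 9),
}

#: Germ structures counted in %GCS, in developmental order.
GERM_STAGES: tuple[str, ...] = (
    "og", "po1", "po2", "cao", "vit1", "vit2", "vit3", "pho", "ho", "POF",
)

STAGE_RANK: dict[str, int] = {s: i for i, s in enumerate(GERM_STAGES)}

#: Display groups used by summary figures and the most-advanced-stage rule.
GROUPS: dict[str, tuple[str, ...]] = {
    "pca": ("og", "po1", "po2"),
    "cao": ("cao",),
    "vit": ("vit1", "vit2", "vit3"),
    "pho": ("pho",),
    "ho": ("ho",),
    "POF": ("POF",),
}
GROUP_ORDER: tuple[str, ...] = ("pca", "cao", "vit", "pho", "ho", "POF")
GROUP_OF: dict[str, str] = {s: g for g, members in GROUPS.items() for s in members}

#: Degeneration labels: counted at points but excluded from n_germ.
ATRESIA_LABELS: tuple[str, ...] = ("aoa", "aob", "lysis")

#: Non-germ structures a sampling point may hit.
NON_GERM_LABELS: tuple[str, ...] = (
    "wall", "epithelium", "lumen", "blood_vessel", "unknown",
)

ALL_LABELS: tuple[str, ...] = GERM_STAGES + ATRESIA_LABELS + NON_GERM_LABELS

# Unicode / legacy spellings accepted on input.
_ALIASES = {
    "aoα": "aoa",
    "aoβ": "aob",
    "ao_alpha": "aoa",
    "ao_beta": "aob",
    "pof": "POF",
    "bv": "blood_vessel",
    "blood vessel": "blood_vessel",
}


def canonical_label(label: str) -> str:
    """Normalize a structure label to the controlled vocabulary.

    Raises ``KeyError`` for labels outside the vocabulary.
    """
    lab = _ALIASES.get(label, label)
    lab = _ALIASES.get(lab.strip(), lab.strip())
    if lab in ALL_LABELS:
        return lab
    raise KeyError(f"unknown structure label: {label!r}")


def get_stage(stage_id: str, stages: Optional[dict[str, StagePrototype]] = None) -> StagePrototype:
    """Look up a stage prototype, raising ``KeyError`` for unknown ids."""
    table = DEFAULT_STAGES if stages is None else stages
    if stage_id not in table:
        raise KeyError(f"unknown stage_id: {stage_id!r}")
    return table[stage_id]


def sample_stage_diameter(
    stage: StagePrototype,
    rng: np.random.Generator,
    size: int | None = None,
) -> float | np.ndarray:
    """Draw follicle diameters (µm) from the stage's truncated normal.

    The normal(mean, sd) is truncated below at max(mean - 3*sd, 1.0 µm) so
    draws are always positive. ``sd_diameter == 0`` returns the mean exactly.
    """
    if stage.sd_diameter == 0:
        if size is None:
            return float(stage.mean_diameter)
        return np.full(size, float(stage.mean_diameter))
    lo = max(stage.mean_diameter - 3.0 * stage.sd_diameter, 1.0)
    a = (lo - stage.mean_diameter) / stage.sd_diameter
    draws = stats.truncnorm.rvs(
        a, np.inf, loc=stage.mean_diameter, scale=stage.sd_diameter,
        size=1 if size is None else size, random_state=rng,
    )
    return float(draws[0]) if size is None else draws
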