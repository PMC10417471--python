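"""Maturity staging from germ-cell composition.

Rules operate on presence/absence of germ structures in a point-count
composition: the most-advanced-stage classifier, two binary maturity rules
(vitellogenesis presence — used for the ogive — and cortical-alveoli
presence), and the A-D maturity-phase call with D > C > B > A precedence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .stages import ATRESIA_LABELS, GERM_STAGES, GROUP_OF, GROUP_ORDER, GROUPS, STAGE_RANK
from .stereology import CompositionEstimate, estimate_counts

__all__ = [
    "WallFeatures",
    "PhaseCall",
    "MATURITY_RULES",
    "most_advanced_stage",
    "is_mature",
    "assign_phase",
    "assign_phase_from_counts",
    "stage_records",
    "summarize",
]

logger = logging.getLogger(__name__)

MATURITY_RULES = ("vit_presence", "cao_presence")

# Stages whose presence marks maturity under each rule.
_MATURE_STAGES = {
    "vit_presence": frozenset(s for s in GERM_STAGES if STAGE_RANK[s] >= STAGE_RANK["vit1"]),
    "cao_presence": frozenset(s for s in GERM_STAGES if STAGE_RANK[s] >= STAGE_RANK["cao"]),
}

_LATE_VIT = frozenset({"vit3", "pho", "ho"})   # phase C markers
_EARLY_DEV = frozenset({"cao", "vit1", "vit2"})  # phase B markers


@dataclass(frozen=True)
class WallFeatures:
    """Ovarian-wall evidence separating regenerating (D) from immature (A)."""

    thick_wall: bool = False
    muscle_bundles: bool = False

    @property
    def regression_evidence(self) -> bool:
        return self.thick_wall or self.muscle_bundles


@dataclass(frozen=True)
class PhaseCall:
    phase: str                      # A, B, C or D
    rule_fired: str
    evidence: tuple[str, ...] = field(default_factory=tuple)


def _present(est: CompositionEstimate, min_count: int = 1) -> set[str]:
    return {
        s for s in GERM_STAGES if est.counts.get(s, 0) >= min_count
    }


def most_advanced_stage(est: CompositionEstimate, min_count: int = 1) -> str:
    """Display group of the highest-ranked germ structure present.

    POF ranks above ho: a post-ovulatory follicle evidences completed
    spawning and is treated as the terminal category.
    """
    if est.n_germ <= 0:
        raise ValueError("no germ-cell points: most advanced stage undefined")
    present = _present(est, min_count)
    if not present:
        raise ValueError(f"no structure reaches min_count={min_count}")
    top = max(present, key=lambda s: STAGE_RANK[s])
    return GROUP_OF[top]


def is_mature(
    est: CompositionEstimate,
    rule: str = "vit_presence",
    min_count: int = 1,
) -> bool:
    """Binary maturity from structure presence.

    ``vit_presence`` (default, the ogive rule): mature iff any vitellogenic
    or later structure is present. ``cao_presence``: mature iff cortical
    alveoli or any later structure is present.
    """
    if rule not in _MATURE_STAGES:
        raise ValueError(f"unknown maturity rule: {rule!r}")
    if est.n_germ <= 0:
        raise ValueError("no germ-cell points: maturity undefined")
    return bool(_present(est, min_count) & _MATURE_STAGES[rule])


def assign_phase(
    est: CompositionEstimate,
    wall_features: Optional[WallFeatures] = None,
    min_count: int = 1,
) -> PhaseCall:
    """Maturity phase A-D with precedence D > C > B > A.

    D: post-ovulatory follicles present, or atresia together with wall-level
    regression evidence; D also covers regenerating pca-only ovaries when
    wall features say so. C: late vitellogenic / maturing oocytes (vit3, pho,
    ho) present without POF. B: cao or early/mid vitellogenesis present.
    A: only precortical stages.
    """
    if est.n_germ <= 0:
        raise ValueError("no germ-cell points: phase undefined")
    present = _present(est, min_count)
    atresia = {
        a for a in ATRESIA_LABELS if est.counts.get(a, 0) >= min_count
    }

    if "POF" in present:
        return PhaseCall("D", "pof_present", ("POF",))
    if atresia and wall_features is not None and wall_features.regression_evidence:
        return PhaseCall("D", "atresia_with_regression", tuple(sorted(atresia)))
    late = present & _LATE_VIT
    if late:
        return PhaseCall("C", "late_vitellogenic_or_maturing", tuple(sorted(late)))
    early = present & _EARLY_DEV
    if early:
        return PhaseCall("B", "cao_or_early_vitellogenesis", tuple(sorted(early)))
    if wall_features is not None and wall_features.regression_evidence:
        return PhaseCall("D", "regenerating_wall", tuple(sorted(present)))
    return PhaseCall("A", "pca_only", tuple(sorted(present)))


def assign_phase_from_counts(
    counts: Mapping[str, int],
    wall_features: Optional[WallFeatures] = None,
    min_count: int = 1,
) -> PhaseCall:
    """Convenience wrapper building the estimate from raw counts."""
    return assign_phase(estimate_counts(dict(counts)), wall_features, min_count)


def stage_records(
    records: pd.DataFrame,
    estimates: Mapping[str, CompositionEstimate],
    min_count: int = 1,
) -> pd.DataFrame:
    """Attach staging columns to a biometrics frame keyed by ``fish_id``.

    Adds most_advanced, mature_vit, mature_cao, phase, rule_fired, and the
    per-group %GCS columns (gcs_pca ... gcs_POF). Fish without an estimate
    (or without germ points) are flagged in ``staged`` and left NaN.
    """
    out = records.copy()
    cols = ["most_advanced", "mature_vit", "mature_cao", "phase", "rule_fired"]
    for c in cols:
        out[c] = pd.NA
    for g in GROUP_ORDER:
        out[f"gcs_{g}"] = float("nan")
    out["staged"] = False
    for idx, row in out.iterrows():
        est = estimates.get(row["fish_id"])
        if est is None or est.n_germ <= 0:
            logger.warning("fish %s has no usable composition; excluded", row["fish_id"])
            continue
        call = assign_phase(est, min_count=min_count)
        out.at[idx, "most_advanced"] = most_advanced_stage(est, min_count)
        out.at[idx, "mature_vit"] = is_mature(est, "vit_presence", min_count)
        out.at[idx, "mature_cao"] = is_mature(est, "cao_presence", min_count)
        out.at[idx, "phase"] = call.phase
        out.at[idx, "rule_fired"] = call.rule_fired
        for g in GROUP_ORDER:
            out.at[idx, f"gcs_{g}"] = float(est.groups[g])
        out.at[idx, "staged"] = True
    return out


def _group_key(records: pd.DataFrame, group_by: str) -> pd.Series:
    if group_by == "month":
        return records["month"]
    if group_by == "length_class":
        return records["length_cm"].astype(float).apply(lambda v: int(v))
    if group_by == "visual_phase":
        return records["visual_phase"]
    raise ValueError(f"unknown group_by: {group_by!r}")


def summarize(
    records: pd.DataFrame,
    group_by: str = "month",
    estimates: Optional[Mapping[str, CompositionEstimate]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group distribution of most-advanced stage and mean %GCS.

    Returns ``(advanced, gcs)``. ``advanced`` has one row per group with
    ``n`` and the percentage of individuals in each most-advanced category
    (rows sum to 100). ``gcs`` holds the mean germ-cell surface percentage
    per display group: pooled over all germ points of the group's fish when
    per-fish ``estimates`` are given (counts-weighted, as when percentages
    are computed from the group's total germ-cell population), otherwise the
    unweighted mean of per-fish percentages.
    """
    staged = records[records["staged"]] if "staged" in records else records
    if staged.empty:
        raise ValueError("no staged records to summarize")
    key = _group_key(staged, group_by)

    adv_rows, gcs_rows = {}, {}
    for grp, sub in staged.groupby(key):
        n = len(sub)
        if n == 0:
            logger.info("group %r empty; dropped", grp)
            continue
        dist = {
            f"pct_{g}": 100.0 * (sub["most_advanced"] == g).sum() / n
            for g in GROUP_ORDER
        }
        adv_rows[grp] = {"n": n, **dist}
        if estimates is not None:
            pooled = {s: 0 for s in GERM_STAGES}
            for fid in sub["fish_id"]:
                est = estimates.get(fid)
                if est is None:
                    continue
                for s in GERM_STAGES:
                    pooled[s] += est.counts.get(s, 0)
            total = sum(pooled.values())
            gcs_rows[grp] = {
                "n": n,
                **{
                    f"gcs_{g}": 100.0 * sum(pooled[s] for s in GROUPS[g]) / total
                    for g in GROUP_ORDER
                },
            }
        else:
            gcs_rows[grp] = {
                "n": n,
                **{f"gcs_{g}": sub[f"gcs_{g}"].mean() for g in GROUP_ORDER},
            }
    advanced = pd.DataFrame.from_dict(adv_rows, orient="index").sort_index()
    gcs = pd.DataFrame.from_dict(gcs_rows, orient="index").sort_index()
    advanced.index.name = gcs.index.name = group_by
    return advanced, gcs
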