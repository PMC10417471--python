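"""File I/O, run configuration, and the end-to-end pipeline.

Annotations travel as CSV (slide_id, point_id, x, y, structure) with a
configurable label-mapping table; label images as integer TIFF plus a JSON
sidecar carrying the legend and exact truth; every pipeline run emits a
manifest naming its seed and config hash so re-runs are reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .ogive import bootstrap_L50, fit_ogive
from .stages import GERM_STAGES, canonical_label
from .staging import stage_records, summarize
from .stereology import (
    CompositionEstimate,
    PointAnnotation,
    estimate_composition,
    estimate_counts,
)
from .synthetic import (
    LabelImage,
    PopulationSpec,
    SectionSpec,
    draw_composition_counts,
    generate_population,
)

__all__ = [
    "RunConfig",
    "read_annotations",
    "write_annotations",
    "write_label_image",
    "read_label_image",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

_ANNOT_COLS = ("point_id", "x", "y", "structure")


def read_annotations(
    path,
    mapping: Optional[Mapping[str, str]] = None,
    policy: str = "error",
) -> dict[str, list[PointAnnotation]]:
    """Read a point-annotation CSV into per-slide annotation lists.

    Raw labels are first translated through ``mapping``; labels still outside
    the controlled vocabulary are handled per ``policy``: ``error`` (raise,
    naming the label), ``drop`` (discard the point), or ``unknown`` (keep it
    under the ``unknown`` structure). Duplicate point ids within a slide are
    an error.
    """
    if policy not in ("error", "drop", "unknown"):
        raise ValueError(f"unknown policy: {policy!r}")
    df = pd.read_csv(path)
    missing = set(_ANNOT_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"annotations file missing columns: {sorted(missing)}")
    if "slide_id" not in df.columns:
        df["slide_id"] = "slide"
    mapping = dict(mapping or {})

    out: dict[str, list[PointAnnotation]] = {}
    for slide, sub in df.groupby("slide_id", sort=False):
        if sub["point_id"].duplicated().any():
            dup = sub.loc[sub["point_id"].duplicated(), "point_id"].iloc[0]
            raise ValueError(f"duplicate point_id {dup!r} on slide {slide!r}")
        anns: list[PointAnnotation] = []
        for _, row in sub.iterrows():
            raw = str(row["structure"])
            lab = mapping.get(raw, raw)
            try:
                lab = canonical_label(lab)
            except KeyError:
                if policy == "error":
                    raise ValueError(
                        f"unmapped structure label {raw!r} on slide {slide!r}"
                    ) from None
                if policy == "drop":
                    continue
                lab = "unknown"
            anns.append(
                PointAnnotation(
                    point_id=int(row["point_id"]),
                    x=float(row["x"]),
                    y=float(row["y"]),
                    structure=lab,
                )
            )
        out[str(slide)] = anns
    return out


def write_annotations(annotations: Mapping[str, list[PointAnnotation]], path) -> None:
    rows = [
        {"slide_id": slide, "point_id": a.point_id, "x": a.x, "y": a.y,
         "structure": a.structure}
        for slide, anns in annotations.items()
        for a in anns
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_label_image(li: LabelImage, path) -> Path:
    """Write labels as integer TIFF with a JSON truth sidecar alongside."""
    path = Path(path)
    tifffile.imwrite(path, li.labels.astype(np.uint16))
    sidecar = {
        "legend": {str(k): v for k, v in li.legend.items()},
        "zp_owner": {str(k): v for k, v in li.zp_owner.items()},
        "truth": li.truth,
        "truth_counts": li.truth_counts,
        "spec": dataclasses.asdict(li.spec) if li.spec is not None else None,
        "seed": li.spec.seed if li.spec is not None else None,
    }
    side_path = path.with_suffix(".json")
    side_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return side_path


def read_label_image(path) -> LabelImage:
    path = Path(path)
    labels = tifffile.imread(path).astype(np.int16)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec = None
    if meta.get("spec"):
        d = dict(meta["spec"])
        d["composition"] = dict(d.get("composition", {}))
        d["n_atresia"] = dict(d.get("n_atresia", {}))
        spec = SectionSpec(**d)
    return LabelImage(
        labels=labels,
        legend={int(k): v for k, v in meta["legend"].items()},
        zp_owner={int(k): v for k, v in meta["zp_owner"].items()},
        truth=dict(meta["truth"]),
        truth_counts={k: int(v) for k, v in meta["truth_counts"].items()},
        spec=spec,
    )


@dataclass
class RunConfig:
    """Configuration for an end-to-end pipeline run."""

    mode: str = "synthetic"                  # synthetic | annotations
    out_dir: str = "results"
    seed: int = 0
    # synthetic mode
    n_fish: int = 151
    true_L50: float = 20.6
    logistic_slope: float = 1.5
    length_range: tuple[float, float] = (12.0, 30.0)
    # annotations mode
    annotations_path: Optional[str] = None
    biometrics_path: Optional[str] = None
    label_mapping: dict[str, str] = field(default_factory=dict)
    mapping_policy: str = "error"
    # grid / read emulation
    n_points_range: tuple[int, int] = (500, 600)
    germ_point_share: float = 0.65
    # staging / ogive
    maturity_rule: str = "vit_presence"
    bootstrap_reps: int = 1000
    use_class_midpoints: bool = False

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        cfg = cls(**data)
        for name in ("length_range", "n_points_range"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def canonical_json(self) -> str:
        # out_dir is excluded: where results land must not change their hash
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        return json.dumps(d, sort_keys=True, default=list)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]

    def validate(self) -> None:
        if self.mode not in ("synthetic", "annotations"):
            raise ValueError(f"unknown mode: {self.mode!r}")
        if self.mode == "annotations":
            for p in (self.annotations_path, self.biometrics_path):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"required input not found: {p}")


def _synthetic_estimates(
    pop: pd.DataFrame, cfg: RunConfig, rng: np.random.Generator
) -> dict[str, CompositionEstimate]:
    """Emulate a stereology read of each fish's true composition."""
    lo, hi = cfg.n_points_range
    out = {}
    for _, row in pop.iterrows():
        comp = {
            s: row[f"comp_{s}"] for s in GERM_STAGES if row.get(f"comp_{s}", 0) > 0
        }
        n_points = int(rng.integers(lo, hi + 1))
        n_germ = max(1, int(round(cfg.germ_point_share * n_points)))
        counts = draw_composition_counts(comp, n_germ, rng)
        out[row["fish_id"]] = estimate_counts(counts)
    return out


def _ogive_report(staged: pd.DataFrame, cfg: RunConfig) -> dict:
    """Fit and bootstrap the ogive under both maturity rules."""
    report: dict = {}
    for rule, col in (("vit_presence", "mature_vit"), ("cao_presence", "mature_cao")):
        sub = staged[staged["staged"]]
        lengths = sub["length_cm"].astype(float).to_numpy()
        mature = sub[col].astype(bool).to_numpy()
        try:
            fit = fit_ogive(lengths, mature, use_class_midpoints=cfg.use_class_midpoints)
            entry: dict = {"fit": fit.as_dict()}
            if fit.converged:
                boot = bootstrap_L50(
                    lengths, mature, reps=cfg.bootstrap_reps, seed=cfg.seed,
                    use_class_midpoints=cfg.use_class_midpoints,
                )
                entry["bootstrap"] = {
                    "reps": boot.reps,
                    "L50_median": boot.L50_median,
                    "ci": [boot.ci_low, boot.ci_high],
                    "n_dropped": boot.n_dropped,
                    "seed": boot.seed,
                }
                entry["l50_values"] = boot.l50_values.tolist()
            else:
                entry["bootstrap"] = None
            report[rule] = entry
        except ValueError as exc:
            report[rule] = {"error": str(exc)}
    return report


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full pipeline and write all outputs under ``cfg.out_dir``.

    Deterministic given the config seed; every output directory contains a
    ``manifest.json`` naming the seed, config hash, and package versions.
    Returns the in-memory results (staged frame, summaries, ogive report).
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    try:
        if cfg.mode == "synthetic":
            pop = generate_population(
                PopulationSpec(
                    n_fish=cfg.n_fish, true_L50=cfg.true_L50,
                    logistic_slope=cfg.logistic_slope,
                    length_range=cfg.length_range, seed=cfg.seed,
                )
            )
            estimates = _synthetic_estimates(pop, cfg, rng)
            records = pop
        else:
            per_slide = read_annotations(
                cfg.annotations_path, cfg.label_mapping, cfg.mapping_policy
            )
            estimates = {}
            for slide, anns in per_slide.items():
                try:
                    estimates[slide] = estimate_composition(anns)
                except ValueError:
                    logger.warning("slide %s has no germ points; excluded", slide)
            records = pd.read_csv(cfg.biometrics_path)
    except Exception as exc:
        raise RuntimeError(f"[inputs] {exc}") from exc

    try:
        staged = stage_records(records, estimates)
        staged.to_csv(out / "staged_records.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"[staging] {exc}") from exc

    try:
        summaries = {}
        for key in ("month", "length_class", "visual_phase"):
            if key == "visual_phase" and "visual_phase" not in staged:
                continue
            adv, gcs = summarize(staged, group_by=key, estimates=estimates)
            adv.to_csv(out / f"summary_advanced_by_{key}.csv")
            gcs.to_csv(out / f"summary_gcs_by_{key}.csv")
            summaries[key] = (adv, gcs)
    except Exception as exc:
        raise RuntimeError(f"[summaries] {exc}") from exc

    try:
        report = _ogive_report(staged, cfg)
        per_rep = {
            rule: rep.get("l50_values", [])
            for rule, rep in report.items()
        }
        pd.DataFrame.from_dict(per_rep, orient="index").T.to_csv(
            out / "ogive_bootstrap_l50.csv", index=False
        )
        slim = {
            rule: {k: v for k, v in rep.items() if k != "l50_values"}
            for rule, rep in report.items()
        }
        (out / "ogive_report.json").write_text(
            json.dumps(slim, indent=1, sort_keys=True)
        )
    except Exception as exc:
        raise RuntimeError(f"[ogive] {exc}") from exc

    manifest = {
        "package": "stereovary",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": json.loads(cfg.canonical_json()),
        "mode": cfg.mode,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    return {
        "staged": staged,
        "summaries": summaries,
        "ogive": report,
        "manifest": manifest,
        "estimates": estimates,
    }
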