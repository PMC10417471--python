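"""Fish biometrics: gonadosomatic index and nuclear/cytoplasmic ratio."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

__all__ = ["FishRecord", "CellMeasure", "gsi", "nc_ratio", "classify_primary_oocyte",
           "read_biometrics", "write_biometrics"]


@dataclass
class FishRecord:
    fish_id: str
    month: Optional[int] = None
    total_length: Optional[float] = None      # cm
    ungutted_weight: Optional[float] = None   # g
    gonad_weight: Optional[float] = None      # g, ventral ovary
    visual_phase: Optional[str] = None        # A-F
    gsi: Optional[float] = None               # percent

    def __post_init__(self) -> None:
        for name in ("total_length", "ungutted_weight", "gonad_weight"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0 (got {v})")
        if (
            self.gonad_weight is not None
            and self.ungutted_weight is not None
            and self.gonad_weight >= self.ungutted_weight
        ):
            raise ValueError("gonad_weight must be smaller than ungutted_weight")


@dataclass(frozen=True)
class CellMeasure:
    """Nucleus and follicle diameters (µm) of one measured cell."""

    stage_id: str
    nucleus_diameter: float
    follicle_diameter: float
    zp_thickness: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 < self.nucleus_diameter <= self.follicle_diameter):
            raise ValueError("need 0 < nucleus_diameter <= follicle_diameter")


def gsi(
    gonad_weight: float,
    ungutted_weight: float,
    denominator: str = "ovary_free",
) -> float:
    """Gonadosomatic index in percent.

    Default: 100 * gonad / (ungutted - gonad), i.e. the ovary weight relative
    to the ungutted ovary-free body weight. ``denominator="ungutted"`` uses
    the whole ungutted weight instead.
    """
    if gonad_weight < 0 or ungutted_weight <= 0:
        raise ValueError("weights must be positive")
    if gonad_weight >= ungutted_weight:
        raise ValueError("gonad_weight must be smaller than ungutted_weight")
    if denominator == "ovary_free":
        return 100.0 * gonad_weight / (ungutted_weight - gonad_weight)
    if denominator == "ungutted":
        return 100.0 * gonad_weight / ungutted_weight
    raise ValueError(f"unknown denominator: {denominator!r}")


def nc_ratio(m: CellMeasure) -> float:
    """Nuclear/cytoplasmic ratio: nucleus diameter over follicle diameter."""
    return m.nucleus_diameter / m.follicle_diameter


def classify_primary_oocyte(ratio: float) -> str:
    """Split primary oocytes on the N/C ratio: >= 0.5 -> po1, < 0.5 -> po2."""
    if not (0 < ratio <= 1):
        raise ValueError("N/C ratio must be in (0, 1]")
    return "po1" if ratio >= 0.5 else "po2"


_BIOMETRIC_COLS = {
    "fish_id": "fish_id",
    "month": "month",
    "length_cm": "total_length",
    "ungutted_weight_g": "ungutted_weight",
    "gonad_weight_g": "gonad_weight",
    "visual_phase": "visual_phase",
}


def read_biometrics(path) -> list[FishRecord]:
    """Read a biometrics CSV (fish_id, month, length_cm, ungutted_weight_g,
    gonad_weight_g, visual_phase) into FishRecord objects, computing GSI when
    both weights are present."""
    df = pd.read_csv(path)
    missing = {"fish_id"} - set(df.columns)
    if missing:
        raise ValueError(f"biometrics file missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for col, attr in _BIOMETRIC_COLS.items():
            if col in df.columns and pd.notna(row[col]):
                v = row[col]
                if attr == "month":
                    v = int(v)
                elif attr in ("total_length", "ungutted_weight", "gonad_weight"):
                    v = float(v)
                kwargs[attr] = v
        rec = FishRecord(**kwargs)
        if rec.gonad_weight is not None and rec.ungutted_weight is not None:
            rec.gsi = gsi(rec.gonad_weight, rec.ungutted_weight)
        records.append(rec)
    return records


def write_biometrics(records: list[FishRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "fish_id": r.fish_id,
                "month": r.month,
                "length_cm": r.total_length,
                "ungutted_weight_g": r.ungutted_weight,
                "gonad_weight_g": r.gonad_weight,
                "visual_phase": r.visual_phase,
                "gsi": r.gsi,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
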