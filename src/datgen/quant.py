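"""Striatal VOI quantification on delayed (real or generated) SUVR volumes.

The specific-to-non-specific binding ratio of a region R against the
occipital reference O is

    SNBR = (mean_R - mean_O) / mean_O,

reported per hemisphere and as the bilateral mean for the whole striatum
(WS), putamen (P = AP u PP), anterior/posterior putamen, caudate and ventral
striatum.  Composite regions are computed over the union mask, not by
averaging subregion SNBRs.  Four inter-subregional ratios of bilateral-mean
SNBRs capture the spatial gradient of binding loss: CA/P, PP/AP, CA/VS
("C" in the conventional ratio naming read as caudate) and P/VS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phantom import RegionAtlas, STRIATAL_REGIONS

SNBR_REGIONS = ("WS", "P", "AP", "PP", "CA", "VS")
ISR_PAIRS = (("CA", "P"), ("PP", "AP"), ("CA", "VS"), ("P", "VS"))


def voi_mean(volume: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of the voxels under a boolean mask."""
    if mask.shape != volume.shape:
        raise ValueError("mask shape does not match volume shape")
    if not mask.any():
        raise ValueError("VOI mask is empty")
    return float(volume[mask].mean())


def snbr(volume: np.ndarray, atlas: RegionAtlas, region: str,
         hemisphere: str | None = None) -> float:
    """SNBR of one region (optionally one hemisphere) against the occipital
    reference; invariant to global rescaling of the volume."""
    ref = voi_mean(volume, atlas.mask("occipital"))
    if ref <= 0:
        raise ValueError(f"occipital reference mean must be positive, got {ref}")
    target = voi_mean(volume, atlas.mask(region, hemisphere))
    return (target - ref) / ref


@dataclass
class SnbrTable:
    """values[(region, hemisphere)] with hemisphere in {"L", "R", "mean"}."""

    values: dict[tuple[str, str], float]

    def __getitem__(self, key):
        region, hemi = key if isinstance(key, tuple) else (key, "mean")
        return self.values[(region, hemi)]

    def bilateral(self, region: str) -> float:
        return self.values[(region, "mean")]

    def to_frame(self, subject_id: str = "") -> pd.DataFrame:
        rows = [{"subject_id": subject_id, "region": r, "hemisphere": h,
                 "snbr": v} for (r, h), v in self.values.items()]
        return pd.DataFrame(rows)


@dataclass
class IsrTable:
    """Inter-subregional ratios of bilateral-mean SNBRs; a ratio whose
    denominator SNBR is non-positive is NaN with the reason recorded."""

    values: dict[str, float]
    undefined: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def to_frame(self, subject_id: str = "") -> pd.DataFrame:
        rows = [{"subject_id": subject_id, "ratio": k, "value": v,
                 "note": self.undefined.get(k, "")}
                for k, v in self.values.items()]
        return pd.DataFrame(rows)


def snbr_table(volume: np.ndarray, atlas: RegionAtlas) -> SnbrTable:
    """All six regional SNBRs per hemisphere plus bilateral means."""
    for r in STRIATAL_REGIONS:
        for h in ("L", "R"):
            if not atlas.mask(r, h).any():
                raise ValueError(f"atlas is missing region {r}/{h}")
    values: dict[tuple[str, str], float] = {}
    for region in SNBR_REGIONS:
        left = snbr(volume, atlas, region, "L")
        right = snbr(volume, atlas, region, "R")
        values[(region, "L")] = left
        values[(region, "R")] = right
        values[(region, "mean")] = 0.5 * (left + right)
    return SnbrTable(values)


def isr_table(table: SnbrTable) -> IsrTable:
    values: dict[str, float] = {}
    undefined: dict[str, str] = {}
    for num, den in ISR_PAIRS:
        name = f"{num}/{den}"
        d = table.bilateral(den)
        if d <= 0:
            values[name] = float("nan")
            undefined[name] = f"denominator SNBR({den}) = {d:.4g} <= 0"
        else:
            values[name] = table.bilateral(num) / d
    return IsrTable(values, undefined)
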