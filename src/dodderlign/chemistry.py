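"""Lignin chemistry summaries: %ABSL and pyrolysis composition.

Acetyl-bromide soluble lignin (%ABSL) is a Beer–Lambert total-lignin
measure: absorbance divided by the extinction coefficient and path
length gives concentration (mg/mL), which times the extraction volume
and over the biomass gives the lignin mass fraction,

    %ABSL = A / (epsilon * path) * (volume / biomass) * 100

with epsilon = 17.2 mL mg^-1 cm^-1 (the N. benthamiana stem coefficient,
as no tomato-specific value exists) and a 1-cm (10-mm cuvette) path.

Pyrolysis GC-MS peak areas are normalized per sample to fractions and
summed by monolignol class: H (p-coumaryl), G (coniferyl), S (sinapyl),
p-coumarate, other.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

CLASSES = ("H", "G", "S", "p-coumarate", "other")


@dataclass
class AbsorbanceRecord:
    """One acetyl-bromide assay measurement."""

    absorbance: float
    biomass_mg: float
    volume_mL: float
    path_cm: float = 1.0
    extinction: float = 17.2

    def __post_init__(self) -> None:
        if self.absorbance < 0:
            raise ValueError("absorbance must be >= 0")
        if min(self.biomass_mg, self.volume_mL, self.path_cm, self.extinction) <= 0:
            raise ValueError(
                "biomass, volume, path length and extinction must be positive"
            )


def absl_percent(rec: AbsorbanceRecord) -> float:
    """Percent acetyl-bromide soluble lignin for one record."""
    return (
        rec.absorbance
        / (rec.extinction * rec.path_cm)
        * (rec.volume_mL / rec.biomass_mg)
        * 100.0
    )


def normalize_pyrogram(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Per-compound area fractions and per-class summed fractions.

    ``table`` needs columns compound, class (one of H, G, S,
    p-coumarate, other) and area.  Fractions sum to 1.
    """
    for col in ("compound", "class", "area"):
        if col not in table.columns:
            raise ValueError(f"pyrogram table lacks column {col!r}")
    bad = set(table["class"]) - set(CLASSES)
    if bad:
        raise ValueError(f"unknown compound class(es): {sorted(bad)}")
    if (table["area"] < 0).any():
        raise ValueError("peak areas must be >= 0")
    total = table["area"].sum()
    if total <= 0:
        raise ValueError("total peak area must be positive")
    out = table.copy()
    out["fraction"] = out["area"] / total
    class_sums = out.groupby("class")["fraction"].sum().reindex(
        CLASSES, fill_value=0.0
    )
    return out, class_sums
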