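"""Derived morphological measures for the cohort table."""
from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd


def effective_diameter(pinna_width_mm: float, pinna_length_mm: float) -> float:
    """Effective pinna diameter: sqrt(pinna length x pinna width), in mm.

    The geometric mean of the two caliper measurements; symmetric in its
    arguments and bounded between them.
    """
    if pinna_width_mm <= 0 or pinna_length_mm <= 0:
        raise ValueError("pinna dimensions must be positive")
    return math.sqrt(pinna_length_mm * pinna_width_mm)


@dataclass(frozen=True)
class MorphologyRecord:
    """One animal's caliper/scale measurements plus derived quantities.

    Lengths in mm (caliper resolution 0.01 mm; derived values unrounded),
    weight in g.
    """

    animal: str
    sex: str
    genotype: str
    pinna_width_mm: float
    pinna_length_mm: float
    interpinna_mm: float
    nose_to_pinna_mm: float
    weight_g: float

    def __post_init__(self) -> None:
        for name in ("pinna_width_mm", "pinna_length_mm", "interpinna_mm",
                     "nose_to_pinna_mm", "weight_g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def effective_diameter_mm(self) -> float:
        return effective_diameter(self.pinna_width_mm, self.pinna_length_mm)


def morphology_table(metadata: pd.DataFrame) -> pd.DataFrame:
    """Add the derived effective diameter to a cohort metadata table."""
    required = {"animal", "sex", "genotype", "pinna_width_mm", "pinna_length_mm"}
    missing = required - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(missing)}")
    out = metadata.copy()
    out["effective_diameter_mm"] = [
        effective_diameter(w, l)
        for w, l in zip(out["pinna_width_mm"], out["pinna_length_mm"])
    ]
    return out
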