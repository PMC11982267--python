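"""Plate-assay arithmetic: LDH cell death, dual-luciferase ratio, densitometry."""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "relative_cell_death",
    "relative_luciferase",
    "normalize_to_control_mean",
    "process_plate",
]


def relative_cell_death(abs_supernatant: float, abs_attached: float) -> float:
    """Fraction of LDH released: sup / (sup + attached), in [0, 1]."""
    if abs_supernatant < 0 or abs_attached < 0:
        raise ValueError("absorbances must be non-negative")
    total = abs_supernatant + abs_attached
    if total == 0:
        raise ValueError("relative cell death undefined: both absorbances zero")
    return abs_supernatant / total


def relative_luciferase(firefly: float, renilla: float) -> float:
    """Firefly luminescence divided by the Renilla internal-control reading."""
    if firefly < 0 or renilla < 0:
        raise ValueError("luminescence readings must be non-negative")
    if renilla == 0:
        raise ValueError("relative luciferase undefined: Renilla reading is zero")
    return firefly / renilla


def normalize_to_control_mean(
    values: Sequence[float], control_indices: Sequence[int]
) -> np.ndarray:
    """Express every value relative to the mean of the control values.

    The mean of the normalized controls is exactly 1; scaling all inputs by a
    positive constant leaves the output unchanged.
    """
    arr = np.asarray(values, dtype=float)
    idx = list(control_indices)
    if not idx:
        raise ValueError("at least one control index required")
    mean = arr[idx].mean()
    if mean <= 0:
        raise ValueError(f"control mean must be positive (got {mean})")
    return arr / mean


def process_plate(plate: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Apply an assay formula row-wise to a plate table.

    Modes: ``ldh`` (needs absorbance_supernatant/absorbance_attached),
    ``luciferase`` (firefly/renilla), ``densitometry`` (band_intensity plus a
    ``group`` column whose ``control`` rows define the reference mean).
    """
    if mode == "ldh":
        _need(plate, ["absorbance_supernatant", "absorbance_attached"])
        out = plate.copy()
        out["relative_cell_death"] = [
            relative_cell_death(s, a)
            for s, a in zip(plate["absorbance_supernatant"], plate["absorbance_attached"])
        ]
        return out
    if mode == "luciferase":
        _need(plate, ["firefly", "renilla"])
        out = plate.copy()
        out["relative_luciferase"] = [
            relative_luciferase(f, r) for f, r in zip(plate["firefly"], plate["renilla"])
        ]
        return out
    if mode == "densitometry":
        _need(plate, ["band_intensity", "group"])
        controls = [i for i, g in enumerate(plate["group"]) if g == "control"]
        out = plate.copy()
        out["relative_intensity"] = normalize_to_control_mean(
            plate["band_intensity"].to_numpy(), controls
        )
        return out
    raise ValueError(f"unknown assay mode {mode!r}")


def _need(plate: pd.DataFrame, columns: list[str]) -> None:
    missing = [c for c in columns if c not in plate.columns]
    if missing:
        raise ValueError(f"plate table missing columns: {missing}")
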