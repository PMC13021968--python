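"""Secondary screen on a synaptic-vesicle marker (Syt:eGFP fluorescence).

Genes that pass the primary memory screen are retested for an effect on
synaptic-vesicle abundance, read out as Syt:eGFP fluorescence in a fixed ROI
(the mushroom-body heel, the dopaminergic cell bodies, or the whole brain).
Left and right hemisphere values are averaged per animal, per-line means are
expressed as a ratio to the control mean, and ratios more than 25% from 1
are called.  A secondary hit is carried forward only when its direction
matches the memory direction: a high-memory gene must *increase* the marker
(more vesicles), a low-memory gene must decrease it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateReferenceError, FormatError, MissingDataError

__all__ = [
    "ROIMeasurement",
    "SecondaryCall",
    "animal_intensity",
    "percent_of_control",
    "call_secondary",
    "secondary_concordance",
    "read_roi_table",
    "run_secondary_screen",
]

REGIONS = ("heel", "cell_body", "whole_brain")
HEMISPHERES = ("left", "right")
SCREEN_N_ANIMALS = 6


@dataclass(frozen=True)
class ROIMeasurement:
    """Mean fluorescence of one ROI in one hemisphere of one animal."""

    animal_id: str
    genotype: str
    region: str
    hemisphere: str
    mean_intensity: float

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}, got {self.region!r}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be one of {HEMISPHERES}")
        if self.mean_intensity < 0:
            raise ValueError("mean_intensity must be nonnegative")


@dataclass(frozen=True)
class SecondaryCall:
    """Per-line secondary-screen result."""

    gene_id: str
    line_id: str
    fi_ratio: float
    hit_direction: str  # "increase", "decrease" or "none"
    concordant: bool = False


def animal_intensity(measurements: Sequence[ROIMeasurement]) -> float:
    """Single per-animal value: mean of the available hemisphere ROIs.

    Both hemispheres are measured when possible; an obscured hemisphere may
    be excluded, in which case the remaining one stands alone.  Whole-brain
    ROIs are single measurements, so two entries for that region are a
    contract violation.
    """
    if not measurements:
        raise MissingDataError("no hemisphere measurements for this animal/region")
    regions = {m.region for m in measurements}
    if len(regions) != 1:
        raise ValueError(f"mixed regions in one animal summary: {sorted(regions)}")
    region = regions.pop()
    if region == "whole_brain" and len(measurements) > 1:
        raise ValueError("whole_brain is a single ROI; got multiple measurements")
    if len(measurements) > 2:
        raise ValueError("at most two hemisphere measurements per animal/region")
    return float(np.mean([m.mean_intensity for m in measurements]))


def percent_of_control(
    values: Sequence[float], control_values: Sequence[float]
) -> list[float]:
    """Express values as percent of the control-group mean.

    The control group's own normalized mean is exactly 100 by construction.
    """
    ref = float(np.mean(control_values))
    if ref <= 0:
        raise DegenerateReferenceError(f"control mean is {ref} <= 0; cannot normalize")
    return [100.0 * v / ref for v in values]


def call_secondary(
    rnai_mean_fi: float, control_mean_fi: float, threshold: float = 0.25
) -> tuple[float, str]:
    """Fluorescence-intensity ratio (RNAi / control) and its direction call.

    Strict thresholds, like the primary screen: a ratio of exactly 1.25 or
    0.75 is not a hit.
    """
    if control_mean_fi <= 0:
        raise DegenerateReferenceError(
            f"control mean fluorescence must be positive, got {control_mean_fi}"
        )
    ratio = rnai_mean_fi / control_mean_fi
    if ratio > 1.0 + threshold:
        direction = "increase"
    elif ratio < 1.0 - threshold:
        direction = "decrease"
    else:
        direction = "none"
    return ratio, direction


def secondary_concordance(hit_direction: str, primary_class: str) -> bool:
    """SV-marker direction must match the memory direction.

    High memory with increased vesicle marker, or low memory with decreased
    marker, is the pattern produced by the cohesin-subunit knockdown the
    screen models.
    """
    return (primary_class == "high" and hit_direction == "increase") or (
        primary_class == "low" and hit_direction == "decrease"
    )


# ---------------------------------------------------------------------------
# table-level screen runner

_ROI_COLS = ["animal_id", "line_id", "gene_id", "genotype", "region", "hemisphere", "mean_intensity"]


def read_roi_table(path) -> pd.DataFrame:
    """Read an ROI fluorescence TSV (one row per animal x hemisphere)."""
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in _ROI_COLS[:-1]})
    missing = set(_ROI_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    df["mean_intensity"] = df["mean_intensity"].astype(float)
    return df


def run_secondary_screen(
    table: pd.DataFrame,
    primary_classes: dict[str, str],
    threshold: float = 0.25,
    control_line_id: str = "control",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every RNAi line in a secondary-screen ROI table.

    ``primary_classes`` maps gene_id to its primary hit class ("high"/"low")
    and defines the expected direction.  Returns per-line calls and the
    per-animal values normalized to percent of control (for plotting).
    """
    per_animal = (
        table.groupby(["line_id", "gene_id", "animal_id"], sort=True)["mean_intensity"]
        .apply(lambda g: float(np.mean(g)))
        .reset_index(name="intensity")
    )
    ctrl = per_animal.loc[per_animal["line_id"] == control_line_id, "intensity"]
    if ctrl.empty:
        raise MissingDataError(f"no control animals (line_id == {control_line_id!r})")
    control_mean = float(ctrl.mean())

    per_animal["pct_of_control"] = percent_of_control(
        per_animal["intensity"].tolist(), ctrl.tolist()
    )

    calls: list[dict] = []
    lines = per_animal[per_animal["line_id"] != control_line_id]
    for (line_id, gene_id), grp in lines.groupby(["line_id", "gene_id"], sort=True):
        if len(grp) < SCREEN_N_ANIMALS:
            warnings.warn(
                f"{line_id}: only {len(grp)} animals (screening mode expects "
                f"{SCREEN_N_ANIMALS})",
                stacklevel=2,
            )
        ratio, direction = call_secondary(float(grp["intensity"].mean()), control_mean, threshold)
        primary_class = primary_classes.get(str(gene_id), "none")
        calls.append(
            {
                "gene_id": gene_id,
                "line_id": line_id,
                "n_animals": len(grp),
                "fi_ratio": ratio,
                "hit_direction": direction,
                "concordant": secondary_concordance(direction, primary_class),
            }
        )
    return pd.DataFrame(calls), per_animal
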