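"""Primary behavioral screen: performance indices, trimming, and hit calls.

Aversive olfactory memory is read out as a performance index (PI),

    PI = (CS- - CS+) / (CS- + CS+),

where CS+ / CS- count flies choosing the shocked / unshocked odor arm of a
T-maze.  Each data point counterbalances the trained odor across two vials of
~60 flies and averages the two half-PIs.  A line is screened with four data
points; the single point farthest from the four-point mean is discarded, and
the trimmed mean is divided by the library-matched control average across the
whole screen to give a memory score.  Scores more than 25% away from 1 are
potential hits, and a hit is carried forward only when its direction is
concordant with the gene's transcriptional change (high memory with a
significant decrease, low memory with a significant increase — the direction
expected if the gene acts like the cohesin subunit whose knockdown defined
the DEG list).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .deg_catalog import DEGRecord
from .errors import (
    DegenerateReferenceError,
    FormatError,
    MissingReferenceError,
    UndefinedPIError,
)

__all__ = [
    "ChoiceCounts",
    "PIReplicate",
    "PrimaryCall",
    "performance_index",
    "counterbalanced_pi",
    "trim_replicates",
    "control_reference",
    "call_primary",
    "primary_concordance",
    "read_primary_table",
    "run_primary_screen",
]

CONTROL_LINE_ID = "control"


@dataclass(frozen=True)
class ChoiceCounts:
    """Fly counts from one T-maze choice test."""

    n_cs_minus: int
    n_cs_plus: int

    def __post_init__(self) -> None:
        if self.n_cs_minus < 0 or self.n_cs_plus < 0:
            raise ValueError("choice counts must be nonnegative")


@dataclass(frozen=True)
class PIReplicate:
    """One counterbalanced PI data point for a genotype on a given day."""

    genotype: str
    line_id: str
    library: str
    day: int
    pi: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.pi <= 1.0:
            raise ValueError(f"PI must lie in [-1, 1], got {self.pi}")

    @property
    def is_control(self) -> bool:
        return self.line_id == CONTROL_LINE_ID


@dataclass(frozen=True)
class PrimaryCall:
    """Per-line primary-screen result."""

    gene_id: str
    line_id: str
    trimmed_mean_pi: float
    memory_score: float
    hit_class: str  # "high", "low" or "none"
    concordant: bool = False


def performance_index(c: ChoiceCounts) -> float:
    """PI = (CS- - CS+)/(CS- + CS+); in [-1, 1], +1 = perfect avoidance."""
    total = c.n_cs_minus + c.n_cs_plus
    if total == 0:
        raise UndefinedPIError("PI undefined: no flies counted in either arm")
    return (c.n_cs_minus - c.n_cs_plus) / total


def counterbalanced_pi(half_a: ChoiceCounts, half_b: ChoiceCounts) -> float:
    """Mean of the two half-PIs of an odor-counterbalanced pair (one data point)."""
    return 0.5 * (performance_index(half_a) + performance_index(half_b))


def trim_replicates(values: Sequence[float]) -> list[float]:
    """Drop the one value farthest from the four-point mean.

    The screen collects n = 4 data points per line and discards the single
    point with the largest absolute deviation from their mean, so a stray
    vial cannot dominate the line's score.  Ties are broken by dropping the
    first such value in input order (deterministic).  Lists of length <= 3
    are returned unchanged with a warning.
    """
    vals = list(values)
    if len(vals) <= 3:
        warnings.warn(
            f"trim_replicates expects 4 values, got {len(vals)}; returning unchanged",
            stacklevel=2,
        )
        return vals
    if len(vals) != 4:
        raise ValueError(f"trim_replicates expects exactly 4 values, got {len(vals)}")
    mean = sum(vals) / 4.0
    drop = max(range(4), key=lambda i: (abs(vals[i] - mean), -i))
    return [v for i, v in enumerate(vals) if i != drop]


def control_reference(replicates: Sequence[PIReplicate], library: str) -> float:
    """Screen-wide mean control PI for one RNAi library.

    Controls are interleaved throughout the screen and averaged globally per
    library; every line from that library is scored against this single
    reference.
    """
    vals = [r.pi for r in replicates if r.is_control and r.library == library]
    if not vals:
        raise MissingReferenceError(f"no control replicates for library {library!r}")
    ref = float(np.mean(vals))
    if ref <= 0:
        raise DegenerateReferenceError(
            f"control reference for library {library!r} is {ref:.4f} <= 0; "
            "memory-score ratios are undefined"
        )
    return ref


def call_primary(
    mean_pi: float, reference: float, threshold: float = 0.25
) -> tuple[float, str]:
    """Memory score (mean PI / control reference) and its hit class.

    ``high`` iff score exceeds 1 + threshold strictly, ``low`` iff it falls
    strictly below 1 - threshold; a score of exactly 1.25 or 0.75 is not a
    hit.
    """
    if reference <= 0:
        raise DegenerateReferenceError(f"control reference must be positive, got {reference}")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    score = mean_pi / reference
    if score - 1.0 > threshold:
        hit = "high"
    elif 1.0 - score > threshold:
        hit = "low"
    else:
        hit = "none"
    return score, hit


def primary_concordance(call: PrimaryCall, deg: DEGRecord, alpha: float = 0.05) -> bool:
    """True when the memory hit direction matches the transcriptional direction.

    A high memory score is concordant with a significantly *down*-regulated
    gene, and a low score with a significantly *up*-regulated gene — the
    pattern expected for genes acting downstream of a learning-suppressing
    regulator.  Genes with log2fc exactly 0 have no direction and are never
    concordant.
    """
    if deg.gene_id != call.gene_id:
        raise ValueError(f"DEG record {deg.gene_id} does not match call {call.gene_id}")
    if not deg.padj < alpha:
        return False
    return (call.hit_class == "high" and deg.log2fc < 0) or (
        call.hit_class == "low" and deg.log2fc > 0
    )


# ---------------------------------------------------------------------------
# table-level screen runner

_COUNT_COLS = ["n_cs_minus_a", "n_cs_plus_a", "n_cs_minus_b", "n_cs_plus_b"]
_BASE_COLS = ["line_id", "gene_id", "library", "day", "replicate_index"]


def read_primary_table(path) -> pd.DataFrame:
    """Read a primary-screen TSV.

    Each row is one data point: either four counterbalanced choice counts
    (``n_cs_minus_a``, ``n_cs_plus_a``, ``n_cs_minus_b``, ``n_cs_plus_b``) or
    a precomputed ``pi`` column.  Control rows carry line_id ``control``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"line_id": str, "gene_id": str})
    missing = set(_BASE_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    if "pi" not in df.columns and set(_COUNT_COLS) - set(df.columns):
        raise FormatError(
            f"{path}: need either a 'pi' column or count columns {_COUNT_COLS}"
        )
    return df


def _row_pi(row) -> float:
    if "pi" in row.index and not pd.isna(row["pi"]):
        return float(row["pi"])
    return counterbalanced_pi(
        ChoiceCounts(int(row["n_cs_minus_a"]), int(row["n_cs_plus_a"])),
        ChoiceCounts(int(row["n_cs_minus_b"]), int(row["n_cs_plus_b"])),
    )


def run_primary_screen(
    table: pd.DataFrame,
    degs: dict[str, DEGRecord],
    threshold: float = 0.25,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[dict]]:
    """Score every RNAi line in a primary-screen table.

    Returns a per-line calls DataFrame (gene_id, line_id, n_replicates,
    trimmed_mean_pi, memory_score, hit_class, concordant) and a trim log
    recording every dropped data point.
    """
    pis = table.apply(_row_pi, axis=1)
    work = table.assign(pi=pis)

    replicates = [
        PIReplicate(
            genotype=str(r.line_id),
            line_id=str(r.line_id),
            library=str(r.library),
            day=int(r.day),
            pi=float(r.pi),
        )
        for r in work.itertuples(index=False)
    ]
    refs = {
        lib: control_reference(replicates, lib)
        for lib in sorted(work.loc[work["line_id"] == CONTROL_LINE_ID, "library"].unique())
    }

    calls: list[dict] = []
    trim_log: list[dict] = []
    lines = work[work["line_id"] != CONTROL_LINE_ID]
    for (line_id, gene_id, library), grp in lines.groupby(
        ["line_id", "gene_id", "library"], sort=True
    ):
        vals = [float(v) for v in grp.sort_values("replicate_index")["pi"]]
        if len(vals) == 4:
            mean = sum(vals) / 4.0
            drop_idx = max(range(4), key=lambda i: (abs(vals[i] - mean), -i))
            kept = [v for i, v in enumerate(vals) if i != drop_idx]
            trim_log.append(
                {
                    "line_id": line_id,
                    "gene_id": gene_id,
                    "dropped_value": vals[drop_idx],
                    "dropped_replicate": drop_idx,
                    "reason": "farthest from 4-replicate mean",
                }
            )
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                kept = trim_replicates(vals) if len(vals) <= 3 else vals
        if library not in refs:
            raise MissingReferenceError(f"no control replicates for library {library!r}")
        mean_pi = float(np.mean(kept))
        score, hit = call_primary(mean_pi, refs[library], threshold)
        deg = degs.get(str(gene_id))
        call = PrimaryCall(str(gene_id), str(line_id), mean_pi, score, hit)
        conc = primary_concordance(call, deg, alpha) if deg is not None else False
        calls.append(
            {
                "gene_id": gene_id,
                "line_id": line_id,
                "library": library,
                "n_replicates": len(vals),
                "trimmed_mean_pi": mean_pi,
                "memory_score": score,
                "hit_class": hit,
                "concordant": conc,
            }
        )
    return pd.DataFrame(calls), trim_log
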