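"""Stimulus-locked fluorescence quantification (dopamine-sensor ΔF/F).

A fly expressing a fluorescent dopamine sensor receives 12 electric shock
pulses (90 V, 1.25 s each, 5 s onset-to-onset) after a 45 s baseline, while
fluorescence is recorded at 4 Hz for 150 s.  Responses are expressed as

    ΔF/F(t) = ((F_t - F_0) / F_0) x 100%,   F_0 = mean F over the 5 s
                                            preceding the first shock,

and the sustained-release statistic is the trapezoidal area under ΔF/F over
the second half of the train (from the onset of pulse 7 to one full
inter-onset interval after the onset of pulse 12).  Sustained responses over
late pulses — instead of the normal pulse-to-pulse depression — indicate an
enlarged releasable vesicle pool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateReferenceError, FormatError, ProtocolError
from .triage import GroupComparison, two_group_test

__all__ = [
    "ShockProtocol",
    "ShockTrace",
    "DFFTrace",
    "compute_dff",
    "shock_onsets",
    "second_half_auc",
    "compare_shock_responses",
    "read_trace_table",
]


@dataclass(frozen=True)
class ShockProtocol:
    """A train of electric shock pulses within a fixed-length recording."""

    n_pulses: int = 12
    pulse_duration: float = 1.25  # s
    inter_onset_interval: float = 5.0  # s, onset to onset
    amplitude_volts: float = 90.0  # metadata only
    first_onset: float = 45.0  # s, end of baseline

    def __post_init__(self) -> None:
        if self.n_pulses < 1:
            raise ProtocolError("n_pulses must be >= 1")
        if not self.pulse_duration < self.inter_onset_interval:
            raise ProtocolError(
                f"pulse_duration {self.pulse_duration} must be shorter than the "
                f"inter-onset interval {self.inter_onset_interval}"
            )

    @property
    def baseline_window(self) -> tuple[float, float]:
        """[first_onset - 5 s, first_onset): the F_0 window."""
        return (self.first_onset - 5.0, self.first_onset)


@dataclass(frozen=True)
class ShockTrace:
    """One raw fluorescence time series with its sampling metadata."""

    values: tuple[float, ...]
    sample_rate: float = 4.0  # Hz
    total_duration: float = 150.0  # s: 45 baseline + 60 shock + 45 recovery

    def __post_init__(self) -> None:
        expected = round(self.sample_rate * self.total_duration)
        if len(self.values) != expected:
            raise ProtocolError(
                f"trace length {len(self.values)} != sample_rate x duration = {expected}"
            )
        if any(v < 0 for v in self.values):
            raise ProtocolError("raw fluorescence must be nonnegative")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.sample_rate


@dataclass(frozen=True)
class DFFTrace:
    """ΔF/F trace in percent, zero-mean over its baseline window."""

    values: tuple[float, ...]
    sample_rate: float
    baseline_window: tuple[float, float]

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.sample_rate


def shock_onsets(protocol: ShockProtocol, total_duration: float = 150.0) -> list[float]:
    """Onset times of every pulse; errors if the train overruns the recording."""
    onsets = [
        protocol.first_onset + k * protocol.inter_onset_interval
        for k in range(protocol.n_pulses)
    ]
    if onsets[-1] + protocol.pulse_duration > total_duration:
        raise ProtocolError(
            f"shock train ends at {onsets[-1] + protocol.pulse_duration:.2f} s, "
            f"beyond the {total_duration:.2f} s recording"
        )
    return onsets


def compute_dff(trace: ShockTrace, protocol: ShockProtocol) -> DFFTrace:
    """ΔF/F in percent against the mean of the 5 s pre-shock baseline."""
    lo, hi = protocol.baseline_window
    t = trace.times
    mask = (t >= lo) & (t < hi)
    if not mask.any():
        raise ProtocolError("baseline window lies outside the recording")
    f = np.asarray(trace.values, dtype=float)
    f0 = float(f[mask].mean())
    if f0 <= 0:
        raise DegenerateReferenceError(f"baseline fluorescence F0 = {f0} <= 0")
    dff = (f - f0) / f0 * 100.0
    return DFFTrace(tuple(dff), trace.sample_rate, (lo, hi))


def second_half_auc(dff: DFFTrace, protocol: ShockProtocol) -> float:
    """Trapezoidal AUC (%·s) over the second half of the shock train.

    The window runs from the onset of pulse 7 to one inter-onset interval
    after the onset of the last pulse, so every late pulse contributes its
    full 5 s epoch.  Requires the default 12-pulse protocol's shape
    (n_pulses >= 7).
    """
    if protocol.n_pulses < 7:
        raise ProtocolError("second-half quantification needs at least 7 pulses")
    onsets = shock_onsets(protocol)
    start = onsets[6]
    end = onsets[-1] + protocol.inter_onset_interval
    t = dff.times
    if start < t[0] or end > t[-1] + 1e-9:
        raise ProtocolError(
            f"AUC window [{start}, {end}] s outside the trace span [{t[0]}, {t[-1]}] s"
        )
    mask = (t >= start - 1e-9) & (t <= end + 1e-9)
    return float(np.trapezoid(np.asarray(dff.values)[mask], t[mask]))


def compare_shock_responses(
    group_a: Sequence[float], group_b: Sequence[float], force: str | None = "mann_whitney"
) -> GroupComparison:
    """Compare per-animal AUC values between two genotypes.

    AUC distributions are not assumed normal, so the default is a two-sided
    Mann-Whitney U test; pass ``force=None`` to let Shapiro-Wilk gate the
    choice instead.
    """
    return two_group_test(group_a, group_b, force=force)


def read_trace_table(path, sample_rate: float = 4.0, total_duration: float = 150.0) -> list[ShockTrace]:
    """Read traces from a TSV/CSV with columns time_s plus one column per
    recording (or a single ``fluorescence`` column)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if "time_s" not in df.columns:
        raise FormatError(f"{path}: missing required column 'time_s'")
    value_cols = [c for c in df.columns if c != "time_s"]
    if not value_cols:
        raise FormatError(f"{path}: no fluorescence columns")
    return [
        ShockTrace(tuple(df[c].astype(float)), sample_rate, total_duration)
        for c in value_cols
    ]
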