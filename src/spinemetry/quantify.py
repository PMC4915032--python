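"""Scalar quantification indices for electrophysiology, behaviour and
radioligand binding.

All amplitude-based indices work on magnitudes: raw EPSCs are inward
(negative) currents in acquisition files, but every ratio here is
reported as a positive fraction or percentage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import SweepSeries

__all__ = [
    "LtpResult",
    "SweepPair",
    "BindingPoint",
    "SpecificBindingResult",
    "QuantificationError",
    "normalize_timecourse",
    "paired_pulse_ratio",
    "nmdar_ampar_ratio",
    "tonic_current_shift",
    "displacement_index",
    "novel_arm_fraction",
    "specific_binding",
    "mean_specific_binding",
]


class QuantificationError(ValueError):
    """Inputs outside the valid domain of an index."""


@dataclass
class LtpResult:
    """Baseline-normalized EPSC time course and LTP magnitude.

    ``ltp_percent`` is the mean normalized amplitude inside the post
    window (30-40 min after induction by convention) times 100; a flat
    series therefore reads 100%.
    """

    times: np.ndarray
    normalized: np.ndarray              # fraction of baseline
    baseline_mean: float                # pA
    ltp_percent: float

    def __post_init__(self) -> None:
        if self.ltp_percent < 0:
            raise QuantificationError("ltp_percent must be >= 0")


@dataclass(frozen=True)
class SweepPair:
    """Averaged paired-pulse responses (typically 40 ms apart)."""

    amp1: float                         # pA, magnitude of first response
    amp2: float
    n_sweeps: int = 5

    def __post_init__(self) -> None:
        if abs(self.amp1) == 0:
            raise QuantificationError("amp1 must be nonzero")


@dataclass(frozen=True)
class BindingPoint:
    """One radioligand binding measurement."""

    total_bound: float                  # fmol
    nonspecific_bound: float            # fmol
    protein: float                      # mg

    def __post_init__(self) -> None:
        if self.protein <= 0:
            raise QuantificationError("protein mass must be > 0")
        if self.total_bound < 0 or self.nonspecific_bound < 0:
            raise QuantificationError("bound amounts must be >= 0")


@dataclass(frozen=True)
class SpecificBindingResult:
    value: float                        # fmol per mg protein
    clipped: bool                       # negative difference clipped to 0


def normalize_timecourse(series: SweepSeries) -> LtpResult:
    """Normalize sweep amplitudes to the baseline-window mean.

    Requires at least 3 baseline sweeps. Scale-invariant: multiplying
    all amplitudes by a constant leaves the normalized series unchanged.
    """
    t = series.timestamps
    amp = np.abs(series.amplitudes)
    b0, b1 = series.baseline_window
    # half-open window: a sweep exactly at the induction onset is post
    base = amp[(t >= b0) & (t < b1)] if b1 == series.event_time \
        else amp[(t >= b0) & (t <= b1)]
    if base.size < 3:
        raise QuantificationError("need >= 3 baseline sweeps")
    baseline_mean = float(base.mean())
    if baseline_mean == 0:
        raise QuantificationError("baseline mean is zero")
    norm = amp / baseline_mean
    p0, p1 = series.post_window
    post = norm[(t >= p0) & (t <= p1)]
    if post.size == 0:
        raise QuantificationError("post window contains no sweeps")
    return LtpResult(times=t, normalized=norm, baseline_mean=baseline_mean,
                     ltp_percent=float(post.mean() * 100.0))


def paired_pulse_ratio(pair: SweepPair) -> float:
    """PPR = amp2 / amp1 (dimensionless, magnitudes)."""
    return abs(pair.amp2) / abs(pair.amp1)


def nmdar_ampar_ratio(nmdar_amp: float, ampar_amp: float) -> float:
    """|NMDAR| / |AMPAR| x 100 (%), sign convention immaterial."""
    if ampar_amp == 0:
        raise QuantificationError("AMPAR amplitude must be nonzero")
    return abs(nmdar_amp) / abs(ampar_amp) * 100.0


def tonic_current_shift(
    times,
    holding_pA,
    drug_onset: float,
    *,
    window: float = 60.0,
    drug_duration: float = 360.0,
) -> float:
    """Tonic current revealed by an antagonist (pA).

    Difference between the mean holding current over the last ``window``
    seconds of baseline and over the last ``window`` seconds of a
    ``drug_duration`` application (default: last minute of baseline vs
    last minute of a 6-min application).
    """
    t = np.asarray(times, dtype=float)
    h = np.asarray(holding_pA, dtype=float)
    drug_end = drug_onset + drug_duration
    if t[0] > drug_onset - window or t[-1] < drug_end - 1e-9:
        raise QuantificationError("series does not cover both windows")
    base = h[(t >= drug_onset - window) & (t < drug_onset)]
    post = h[(t >= drug_end - window) & (t <= drug_end)]
    if base.size == 0 or post.size == 0:
        raise QuantificationError("empty averaging window")
    return float(base.mean() - post.mean())


def displacement_index(t_novel: float, t_familiar: float) -> float:
    """(T_novel x 100) / (T_novel + T_familiar), in percent."""
    if t_novel < 0 or t_familiar < 0:
        raise QuantificationError("exploration times must be >= 0")
    total = t_novel + t_familiar
    if total == 0:
        raise QuantificationError("no exploration time recorded")
    return t_novel * 100.0 / total


def novel_arm_fraction(arm_times, novel_arm: int | str = 0) -> float:
    """Percent of total maze time spent in the novel arm.

    ``arm_times`` is a sequence of per-arm occupancy times or a mapping
    arm-id -> time; ``novel_arm`` selects the novel one.
    """
    if isinstance(arm_times, dict):
        if novel_arm not in arm_times:
            raise QuantificationError(f"unknown arm {novel_arm!r}")
        novel = float(arm_times[novel_arm])
        total = float(sum(arm_times.values()))
    else:
        arr = np.asarray(arm_times, dtype=float)
        novel = float(arr[int(novel_arm)])
        total = float(arr.sum())
    if np.any(np.asarray(list(arm_times.values()) if isinstance(arm_times, dict)
                         else arm_times, dtype=float) < 0):
        raise QuantificationError("arm times must be >= 0")
    if total == 0:
        raise QuantificationError("no maze time recorded")
    return novel * 100.0 / total


def specific_binding(point: BindingPoint) -> SpecificBindingResult:
    """(total - nonspecific) / protein, in fmol per mg protein.

    Duplicate noise can push the difference below zero; such values are
    clipped to 0 and flagged rather than rejected.
    """
    diff = point.total_bound - point.nonspecific_bound
    clipped = diff < 0
    return SpecificBindingResult(value=max(diff, 0.0) / point.protein,
                                 clipped=bool(clipped))


def mean_specific_binding(points) -> SpecificBindingResult:
    """Mean specific binding over duplicate assay points."""
    points = list(points)
    if not points:
        raise QuantificationError("no binding points")
    results = [specific_binding(p) for p in points]
    return SpecificBindingResult(
        value=float(np.mean([r.value for r in results])),
        clipped=any(r.clipped for r in results))
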