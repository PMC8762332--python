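"""Polysome-profile quantification from sucrose-gradient absorbance traces.

The polysome-to-monosome (P:M) ratio is the area under the A254 trace over
an operator-chosen polysome interval divided by the area over the monosome
(80S) interval, after baseline subtraction. Protein distributions across
collected gradient fractions are expressed as percent of total signal and
compared between conditions by pooling early (mRNP) versus late
(ribosome-containing) fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .structure import GroupComparison, compare_groups

__all__ = [
    "GradientTrace",
    "PMResult",
    "FractionDistribution",
    "pm_ratio",
    "fraction_distribution",
    "partition_compare",
]


@dataclass
class GradientTrace:
    """Sedimentation position vs absorbance at 254 nm."""

    position: np.ndarray
    a254: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.a254 = np.asarray(self.a254, dtype=float)
        if len(self.position) != len(self.a254):
            raise ValueError("position and a254 must have equal length")
        if len(self.position) < 3:
            raise ValueError("trace needs >= 3 points")
        if not (np.diff(self.position) > 0).all():
            raise ValueError("positions must be strictly increasing")


@dataclass
class PMResult:
    monosome_area: float
    polysome_area: float
    pm_ratio: float


@dataclass
class FractionDistribution:
    """Per-fraction signal and its percent-of-total."""

    signal: np.ndarray
    percent: np.ndarray


def _interval_area(trace: GradientTrace, interval: tuple[float, float],
                   baseline: float | str) -> float:
    lo, hi = interval
    if not (trace.position[0] <= lo < hi <= trace.position[-1]):
        raise ValueError(f"interval {interval} outside trace range")
    inside = (trace.position > lo) & (trace.position < hi)
    x = np.concatenate(([lo], trace.position[inside], [hi]))
    y = np.interp(x, trace.position, trace.a254)
    if baseline == "linear":
        # straight line between the trace values at the interval endpoints
        base = np.interp(x, [lo, hi], [y[0], y[-1]])
    else:
        base = float(baseline)
    return float(np.trapezoid(np.clip(y - base, 0.0, None), x))


def pm_ratio(trace: GradientTrace, mono_interval: tuple[float, float],
             poly_interval: tuple[float, float],
             baseline: float | str = 0.0) -> PMResult:
    """Polysome/monosome area ratio by trapezoidal integration.

    ``baseline`` is either a constant absorbance or ``"linear"`` for a
    per-interval straight line through the trace values at the interval
    endpoints. Baseline-subtracted values are clipped at zero before
    integration. The two intervals must not overlap.
    """
    m_lo, m_hi = mono_interval
    p_lo, p_hi = poly_interval
    if max(m_lo, p_lo) < min(m_hi, p_hi):
        raise ValueError("monosome and polysome intervals overlap")
    mono = _interval_area(trace, mono_interval, baseline)
    poly = _interval_area(trace, poly_interval, baseline)
    if mono <= 0.0:
        raise ValueError("monosome area is zero; P:M ratio undefined")
    return PMResult(monosome_area=mono, polysome_area=poly,
                    pm_ratio=poly / mono)


def fraction_distribution(signals: Sequence[float]) -> FractionDistribution:
    """Percent-of-total signal per collected gradient fraction."""
    signal = np.asarray(signals, dtype=float)
    if len(signal) < 1:
        raise ValueError("need >= 1 fraction")
    if (signal < 0).any():
        raise ValueError("fraction signals must be >= 0")
    total = signal.sum()
    if total <= 0:
        raise ValueError("total signal must be > 0")
    return FractionDistribution(signal=signal, percent=100.0 * signal / total)


def partition_compare(dists_a: Sequence[FractionDistribution],
                      dists_b: Sequence[FractionDistribution],
                      split_index: int,
                      alpha: float = 0.05) -> GroupComparison:
    """Compare pooled late-fraction mass between two replicate groups.

    ``split_index`` is the 1-based fraction number at which the
    ribosome-containing region starts; the statistic per replicate is the
    summed percent mass at or after that fraction, compared between
    conditions by the unpaired Student t test.
    """
    if len(dists_a) < 2 or len(dists_b) < 2:
        raise ValueError("need >= 2 replicate distributions per condition")
    if split_index < 1:
        raise ValueError("split_index is a 1-based fraction number")
    late_a = [float(d.percent[split_index - 1:].sum()) for d in dists_a]
    late_b = [float(d.percent[split_index - 1:].sum()) for d in dists_b]
    return compare_groups(late_a, late_b, alpha=alpha)
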