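"""Plating and growth phenotypes: efficiency of plating, MIC calling from
CFU series, exponential growth-rate fitting, and MIC fold-changes."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


class MICAboveRangeError(ValueError):
    """No tested concentration abolished growth; the MIC exceeds the range."""


@dataclass
class PlatingSeries:
    """Replicate CFU counts per ascending drug concentration (μg/mL)."""

    concentrations: list[float]
    counts: dict[float, list[int]]
    reference_cfu: list[int]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.concentrations, self.concentrations[1:])):
            raise ValueError("concentrations must be strictly increasing")
        for conc in self.concentrations:
            if conc not in self.counts:
                raise ValueError(f"no counts for concentration {conc}")
            if any(c < 0 for c in self.counts[conc]):
                raise ValueError("CFU counts must be non-negative")
        if not self.reference_cfu or any(c <= 0 for c in self.reference_cfu):
            raise ValueError("reference CFU must be positive")

    def mean_eop(self, concentration: float) -> float:
        ref = float(np.mean(self.reference_cfu))
        return float(np.mean(self.counts[concentration])) / ref


@dataclass
class GrowthCurve:
    """Optical density (or CFU/mL) over time, with an optional fit window."""

    times: Sequence[float]
    densities: Sequence[float]
    window: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if len(self.times) != len(self.densities):
            raise ValueError("times and densities differ in length")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")


def eop(treated_cfu: float, reference_cfu: float) -> float:
    """Efficiency of plating: treated-plate CFU over control-plate CFU."""
    if reference_cfu <= 0:
        raise ZeroDivisionError("reference CFU must be positive")
    if treated_cfu < 0:
        raise ValueError("CFU must be non-negative")
    return treated_cfu / reference_cfu


def mic_from_series(series: PlatingSeries) -> float:
    """Lowest tested concentration from which growth is abolished.

    "No visible growth" is operationalized as zero CFU in every replicate at
    that concentration and at every higher tested concentration. If even the
    highest concentration grows, the MIC lies above the tested range.
    """
    mic = None
    for conc in reversed(series.concentrations):
        if all(c == 0 for c in series.counts[conc]):
            mic = conc
        else:
            break
    if mic is None:
        raise MICAboveRangeError(
            f"growth at every concentration up to {series.concentrations[-1]}"
        )
    return mic


def growth_rate(
    curve: GrowthCurve,
    reference_rate: Optional[float] = None,
) -> float:
    """Exponential growth rate (per hour) by log-linear least squares.

    The fit uses the curve's window, defaulting to points whose density lies
    between 10% and 90% of the maximum (the exponential phase of a typical
    batch culture); at least 3 points are required. With ``reference_rate``
    the slope is returned normalized by it.
    """
    t = np.asarray(curve.times, dtype=float)
    d = np.asarray(curve.densities, dtype=float)
    if (d <= 0).any():
        raise ValueError("densities must be positive for log-linear fitting")
    if curve.window is not None:
        mask = (t >= curve.window[0]) & (t <= curve.window[1])
    else:
        dmax = d.max()
        mask = (d >= 0.1 * dmax) & (d <= 0.9 * dmax)
    if mask.sum() < 3:
        raise ValueError(f"only {int(mask.sum())} points in the fit window; need ≥3")
    slope = float(np.polyfit(t[mask], np.log(d[mask]), 1)[0])
    if reference_rate is not None:
        if reference_rate <= 0:
            raise ValueError("reference rate must be positive")
        return slope / reference_rate
    return slope


def mic_fold_change(evolved_mic: float, ancestral_mic: float) -> float:
    if ancestral_mic <= 0:
        raise ZeroDivisionError("ancestral MIC must be positive")
    return evolved_mic / ancestral_mic


def summarize_folds(folds: Sequence[float]) -> tuple[float, float]:
    """Mean and sample SD (n−1) of a cohort's MIC fold-changes."""
    arr = np.asarray(folds, dtype=float)
    if arr.size == 0:
        raise ValueError("no fold-changes to summarize")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd
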