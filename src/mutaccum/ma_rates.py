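"""Mutation-rate estimation from mutation-accumulation (MA) lines.

The genome-wide rate is the pooled estimator μ = m / Σᵢ(Nᵢ·Tᵢ): total events
over total site·divisions, with Nᵢ the analyzed sites and Tᵢ the cell
divisions of line i. Uncertainty is reported two ways, as in common MA
practice: the SEM of per-line rates (SD/√n), and the exact Poisson interval
on the pooled count obtained from χ² quantiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .annotation import SiteOpportunities
from .core import LineMetadata, MutationRecord, SPECTRUM_CLASSES, index_metadata


@dataclass
class RateEstimate:
    """Point rate with SEM and exact Poisson CI, per site per cell division."""

    m: int
    denominator: float
    rate: float
    sem: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    label: str = ""


@dataclass(frozen=True)
class BottleneckRegime:
    """Single-colony transfer regime: g doublings per cycle, then one cell."""

    g: float
    transfers: int = 40

    def __post_init__(self) -> None:
        if self.g <= 0:
            raise ValueError("cell divisions per cycle must be positive")

    @property
    def total_divisions(self) -> float:
        return self.g * self.transfers


def poisson_ci(m: int, denominator: float, level: float = 0.95) -> tuple[float, float]:
    """Exact Poisson confidence interval for a rate, via χ² quantiles.

    low = χ²_{α/2}(2m)/2 / denominator (0 when m = 0),
    high = χ²_{1−α/2}(2m+2)/2 / denominator, with α = 1 − level.
    """
    if m != int(m) or m < 0:
        raise ValueError(f"event count must be a non-negative integer, got {m}")
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    m = int(m)
    alpha = 1.0 - level
    low = 0.0 if m == 0 else 0.5 * stats.chi2.ppf(alpha / 2, 2 * m) / denominator
    high = 0.5 * stats.chi2.ppf(1 - alpha / 2, 2 * m + 2) / denominator
    return low, high


def _select(records: Iterable[MutationRecord], mclass: str) -> list[MutationRecord]:
    if mclass == "BPS":
        return [r for r in records if r.mclass == "BPS"]
    if mclass == "indel":
        return [r for r in records if r.mclass in ("insertion", "deletion")]
    if mclass in ("insertion", "deletion"):
        return [r for r in records if r.mclass == mclass]
    raise ValueError(f"unknown mutation class {mclass!r}")


def estimate_rate(
    records: Iterable[MutationRecord],
    metadata: Sequence[LineMetadata],
    mclass: str = "BPS",
    level: float = 0.95,
    label: str = "",
) -> RateEstimate:
    """Pooled MA rate for one mutation class with SEM and Poisson CI.

    Indels share the all-sites denominator with base substitutions. Every
    record's sample must appear in the metadata; lines without mutations
    still contribute their N·T to the denominator and a zero to the SEM.
    """
    meta = index_metadata(metadata)
    if not meta:
        raise ValueError("empty metadata")
    selected = _select(records, mclass)
    counts: dict[str, int] = {s: 0 for s in meta}
    for r in selected:
        if r.sample not in meta:
            raise KeyError(f"record sample {r.sample!r} missing from metadata")
        counts[r.sample] += 1
    denominator = sum(md.N * md.T for md in meta.values())
    if denominator <= 0:
        raise ValueError("denominator Σ(N×T) is zero")
    m = len(selected)
    rate = m / denominator
    per_line = np.array([counts[s] / (md.N * md.T) for s, md in meta.items()])
    n = len(per_line)
    sem = float(per_line.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    low, high = poisson_ci(m, denominator, level)
    return RateEstimate(
        m=m, denominator=denominator, rate=rate, sem=sem,
        ci_low=low, ci_high=high, level=level, label=label or mclass,
    )


def conditional_spectrum_rates(
    spectrum: Mapping[str, int],
    opportunities: SiteOpportunities,
    metadata: Sequence[LineMetadata],
    level: float = 0.95,
) -> dict[str, RateEstimate]:
    """Per-class conditional rates: class count over origin-pair site·divisions.

    A:T-origin classes divide by the genome's A/T site count, G:C-origin
    classes by the G/C count, each multiplied by the summed divisions ΣᵢTᵢ
    (site counts are genome-wide, identical across lines).
    """
    total_T = sum(md.T for md in metadata)
    out: dict[str, RateEstimate] = {}
    for cls in SPECTRUM_CLASSES:
        sites = opportunities.pair_sites(cls)
        if sites <= 0:
            raise ValueError(f"no opportunity sites for class {cls}")
        denom = sites * total_T
        m = int(spectrum.get(cls, 0))
        low, high = poisson_ci(m, denom, level)
        out[cls] = RateEstimate(
            m=m, denominator=denom, rate=m / denom, sem=float("nan"),
            ci_low=low, ci_high=high, level=level, label=cls,
        )
    return out


def fourfold_rate(
    records: Iterable[MutationRecord],
    fourfold_sites: set[tuple[str, int]],
    metadata: Sequence[LineMetadata],
    level: float = 0.95,
) -> RateEstimate:
    """Mutation rate restricted to 4-fold degenerate third-codon positions."""
    if not fourfold_sites:
        raise ValueError("empty 4-fold site set")
    hits = [
        r for r in records if r.mclass == "BPS" and (r.contig, r.position) in fourfold_sites
    ]
    denom = len(fourfold_sites) * sum(md.T for md in metadata)
    m = len(hits)
    low, high = poisson_ci(m, denom, level)
    return RateEstimate(
        m=m, denominator=denom, rate=m / denom, sem=float("nan"),
        ci_low=low, ci_high=high, level=level, label="fourfold",
    )


def effective_population_size(regime: BottleneckRegime | float) -> float:
    """Harmonic-mean Ne of one single-cell-bottleneck colony growth cycle.

    A colony grows from one cell by binary fission through g doublings, so
    the per-generation population sizes are 2⁰, 2¹, …; the effective size is
    the harmonic mean over the cycle, Ne = g / Σᵢ 2⁻ⁱ, with a fractional
    final generation weighted by g − ⌊g⌋. Ne → g/2 for large g; Ne(1) = 1.
    """
    g = regime.g if isinstance(regime, BottleneckRegime) else float(regime)
    if g <= 0:
        raise ValueError("g must be positive")
    whole = int(math.floor(g))
    frac = g - whole
    weight_sum = sum(2.0 ** -i for i in range(whole))
    if frac > 0:
        weight_sum += frac * 2.0 ** -whole
    return g / weight_sum
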