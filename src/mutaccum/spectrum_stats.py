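"""Contingency and goodness-of-fit tests on mutation category counts.

The 2×2 Pearson χ² uses the Yates continuity correction by default, with
each |O−E| reduced by 0.5 and floored at 0 — small-count spectrum tables
routinely have |O−E| < 0.5, where the floored statistic is exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy import stats

from .core import (
    MutationRecord,
    SPECTRUM_CLASSES,
    TRANSITION_CLASSES,
    TRANSVERSION_CLASSES,
)


@dataclass
class SpectrumCounts:
    """Counts of the six collapsed BPS classes plus small indels."""

    by_class: dict[str, int] = field(default_factory=dict)
    insertions: int = 0
    deletions: int = 0

    def __post_init__(self) -> None:
        self.by_class = {c: int(self.by_class.get(c, 0)) for c in SPECTRUM_CLASSES}

    @property
    def transitions(self) -> int:
        return sum(self.by_class[c] for c in TRANSITION_CLASSES)

    @property
    def transversions(self) -> int:
        return sum(self.by_class[c] for c in TRANSVERSION_CLASSES)

    @property
    def bps_total(self) -> int:
        return self.transitions + self.transversions

    @property
    def indel_total(self) -> int:
        return self.insertions + self.deletions

    def proportions(self) -> dict[str, float]:
        """Class proportions as reported in spectrum tables: each transition
        class within transitions, each transversion class within
        transversions, and transitions/transversions within the BPS total."""
        out: dict[str, float] = {}
        ts, tv, total = self.transitions, self.transversions, self.bps_total
        for c in TRANSITION_CLASSES:
            out[c] = self.by_class[c] / ts if ts else 0.0
        for c in TRANSVERSION_CLASSES:
            out[c] = self.by_class[c] / tv if tv else 0.0
        out["transitions"] = ts / total if total else 0.0
        out["transversions"] = tv / total if total else 0.0
        indels = self.indel_total
        out["insertions"] = self.insertions / indels if indels else 0.0
        out["deletions"] = self.deletions / indels if indels else 0.0
        return out


@dataclass
class TestResult:
    statistic: float
    df: int
    p: float
    correction: str = "none"

    def __post_init__(self) -> None:
        if self.statistic < 0 or not 0 <= self.p <= 1:
            raise ValueError("invalid test result")


def spectrum_counts(records: Iterable[MutationRecord]) -> SpectrumCounts:
    """Partition annotated records into the 6 BPS classes and indels."""
    by_class = {c: 0 for c in SPECTRUM_CLASSES}
    ins = dels = 0
    for r in records:
        if r.mclass == "insertion":
            ins += 1
        elif r.mclass == "deletion":
            dels += 1
        else:
            if r.spectrum_class is None:
                raise ValueError(
                    f"BPS record at {r.contig}:{r.position} lacks a spectrum class; "
                    "annotate records first"
                )
            by_class[r.spectrum_class] += 1
    return SpectrumCounts(by_class=by_class, insertions=ins, deletions=dels)


def ts_tv_ratio(spectrum: SpectrumCounts) -> float:
    if spectrum.transversions == 0:
        raise ZeroDivisionError("transition/transversion ratio undefined: no transversions")
    return spectrum.transitions / spectrum.transversions


def chi2_2x2(table, yates: bool = True) -> TestResult:
    """Pearson χ² on a 2×2 table, Yates-corrected by default.

    With Yates, each |O−E| is reduced by 0.5 and floored at 0, so a table
    whose observed counts all sit within half a count of expectation scores
    exactly 0.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError(f"expected a 2×2 table, got shape {obs.shape}")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("2×2 test undefined with a zero margin")
    expected = np.outer(rows, cols) / obs.sum()
    dev = np.abs(obs - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    statistic = float((dev ** 2 / expected).sum())
    return TestResult(
        statistic=statistic,
        df=1,
        p=float(stats.chi2.sf(statistic, 1)),
        correction="yates" if yates else "none",
    )


def ns_s_neutrality_test(
    observed_nonsyn: int, observed_syn: int, expected_ratio: float
) -> TestResult:
    """1-df goodness-of-fit of observed (nonsyn, syn) counts against the
    neutral expectation r : 1 from site-opportunity counting.

    The expected ratio is treated as known without error, so the test has a
    single degree of freedom.
    """
    if observed_nonsyn < 0 or observed_syn < 0:
        raise ValueError("counts must be non-negative")
    total = observed_nonsyn + observed_syn
    if total == 0:
        raise ValueError("no substitutions to test")
    if expected_ratio <= 0:
        raise ValueError("expected nonsyn:syn ratio must be positive")
    p_nonsyn = expected_ratio / (1.0 + expected_ratio)
    statistic, p = stats.chisquare(
        [observed_nonsyn, observed_syn],
        f_exp=[total * p_nonsyn, total * (1 - p_nonsyn)],
    )
    return TestResult(statistic=float(statistic), df=1, p=float(p), correction="none")


def compare_spectra(a: SpectrumCounts, b: SpectrumCounts, yates: bool = True) -> dict[str, TestResult]:
    """Paired group comparisons: ts/tv and insertion/deletion 2×2 tests.

    Comparisons whose table has a zero margin (e.g. no indels observed in
    either group) are omitted from the result."""
    tables = {
        "ts_tv": [[a.transitions, a.transversions], [b.transitions, b.transversions]],
        "ins_del": [[a.insertions, a.deletions], [b.insertions, b.deletions]],
    }
    out: dict[str, TestResult] = {}
    for name, table in tables.items():
        arr = np.asarray(table)
        if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
            continue
        out[name] = chi2_2x2(table, yates=yates)
    return out
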