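"""Selection detection: gene-level hotspot tests, population allele-frequency
summaries, and Ka/Ks from observed mutation events.

The hotspot test assumes mutational homogeneity: under the null, hits land
on a gene in proportion to its length, so the per-gene expectation is
M·L_g/L_total and the p-value is the upper Poisson tail, Bonferroni-adjusted
over the annotation. Ka/Ks counts observed events per fractional site (no
multiple-hit correction — within-experiment counts are sparse); genes with
zero synonymous events get a pseudo-Ks from a through-origin regression of
synonymous counts on synonymous sites across the genes that do have them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import SiteOpportunities
from .core import GeneModel, MutationRecord


@dataclass
class GeneHitResult:
    gene_id: str
    length: int
    observed: int
    expected: float
    p_raw: float
    p_adj: float
    significant: bool


@dataclass
class KaKsRecord:
    gene_id: str
    nonsyn_count: int
    syn_count: int
    nonsyn_sites: float
    syn_sites: float
    ka: float
    ks: float
    ratio: float
    calibrated: bool


def gene_hit_test(
    records: Sequence[MutationRecord],
    genes: Sequence[GeneModel],
    total_sites: float,
    alpha: float = 0.05,
    family: str = "all",
) -> list[GeneHitResult]:
    """Poisson upper-tail test of per-gene mutation hits with Bonferroni.

    ``family`` chooses the Bonferroni multiplier: every annotated gene
    ("all", the default — conservative and deterministic) or only genes with
    at least one hit ("hit").
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if total_sites <= 0:
        raise ValueError("total_sites must be positive")
    if family not in ("all", "hit"):
        raise ValueError("family must be 'all' or 'hit'")
    gene_index = {g.gene_id: g for g in genes}
    observed: dict[str, int] = {g.gene_id: 0 for g in genes}
    m_total = len(records)
    for r in records:
        for gid in r.genes:
            if gid not in gene_index:
                raise KeyError(f"record attributed to unannotated gene {gid!r}")
            observed[gid] += 1
    n_tests = len(genes) if family == "all" else max(1, sum(1 for v in observed.values() if v))
    results = []
    for gid, g in gene_index.items():
        expected = m_total * g.length / total_sites
        obs = observed[gid]
        # P(Poisson(expected) >= obs); sf(k-1) is the inclusive upper tail
        p_raw = 1.0 if obs == 0 else float(stats.poisson.sf(obs - 1, expected))
        p_adj = min(1.0, p_raw * n_tests)
        results.append(
            GeneHitResult(
                gene_id=gid, length=g.length, observed=obs, expected=expected,
                p_raw=p_raw, p_adj=p_adj, significant=p_adj < alpha,
            )
        )
    results.sort(key=lambda r: (r.p_adj, r.p_raw, r.gene_id))
    return results


def filter_population_variants(
    records: Iterable[MutationRecord], min_freq: float = 0.05
) -> list[MutationRecord]:
    """Keep records with allele frequency strictly above the threshold."""
    out = []
    for r in records:
        if r.allele_frequency is None:
            raise ValueError(
                f"population record at {r.contig}:{r.position} lacks an allele frequency"
            )
        if r.allele_frequency > min_freq:
            out.append(r)
    return out


def mean_allele_frequency_by_gene(
    records: Sequence[MutationRecord],
    genes: Sequence[GeneModel],
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Mean mutant allele frequency per gene × group over variant sites.

    Each retained record contributes its frequency to every gene it is
    attributed to; intergenic records are assigned to a pseudo-gene labelled
    by the nearest annotated gene. Genes with no variants in a group are
    absent (frequency-zero sites are unobservable in population calls).
    """
    by_contig: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).append(g)
    for lst in by_contig.values():
        lst.sort(key=lambda g: g.start)

    rows = []
    for r in records:
        if r.allele_frequency is None:
            raise ValueError(f"record at {r.contig}:{r.position} lacks an allele frequency")
        group = groups.get(r.sample, "other")
        targets = list(r.genes)
        if not targets:
            nearest = _nearest_gene(by_contig.get(r.contig, []), r.position)
            targets = [f"intergenic_near_{nearest.gene_id}" if nearest else "intergenic"]
        for gid in targets:
            rows.append({"gene_id": gid, "group": group, "frequency": r.allele_frequency})
    if not rows:
        return pd.DataFrame(columns=["gene_id", "group", "mean_frequency", "n_sites"])
    frame = pd.DataFrame(rows)
    out = (
        frame.groupby(["gene_id", "group"])["frequency"]
        .agg(mean_frequency="mean", n_sites="size")
        .reset_index()
    )
    return out.sort_values(["group", "mean_frequency"], ascending=[True, False]).reset_index(drop=True)


def _nearest_gene(sorted_genes: list[GeneModel], position: int) -> Optional[GeneModel]:
    best, best_dist = None, None
    for g in sorted_genes:
        if g.start <= position <= g.end:
            return g
        dist = g.start - position if position < g.start else position - g.end
        if best_dist is None or dist < best_dist:
            best, best_dist = g, dist
    return best


def calibrate_ks(
    calibration: Sequence[tuple[float, int]],
    target_syn_sites: float,
    floor: float = 0.5,
) -> float:
    """Pseudo-Ks for a gene with zero synonymous events.

    Least-squares regression through the origin of synonymous event count on
    synonymous site count over genes with ≥1 synonymous event; the predicted
    count at the target gene's synonymous sites, floored at half a count,
    divided by its synonymous sites.
    """
    if len(calibration) < 2:
        raise ValueError("need at least 2 genes with synonymous events for calibration")
    if target_syn_sites <= 0:
        raise ValueError("target gene has no synonymous sites")
    x = np.array([c[0] for c in calibration], dtype=float)
    y = np.array([c[1] for c in calibration], dtype=float)
    slope = float((x * y).sum() / (x * x).sum())
    predicted = max(slope * target_syn_sites, floor)
    return predicted / target_syn_sites


def ka_ks(
    records: Sequence[MutationRecord],
    opportunities: SiteOpportunities,
    min_calibration_genes: int = 2,
) -> list[KaKsRecord]:
    """Per-gene Ka, Ks and their ratio from annotated, filtered records.

    Only genes carrying at least one coding substitution are reported. Genes
    with zero synonymous events receive a calibrated pseudo-Ks (flagged);
    calibration needs ≥2 genes with synonymous events, else those genes get
    an undefined (NaN) ratio.
    """
    counts: dict[str, list[int]] = {}
    for r in records:
        if r.effect not in ("synonymous", "nonsynonymous"):
            continue
        for gid in r.genes:
            ns_s = counts.setdefault(gid, [0, 0])
            ns_s[0 if r.effect == "nonsynonymous" else 1] += 1

    calibration = []
    for gid, (ns, s) in counts.items():
        sites = opportunities.per_gene.get(gid)
        if sites is not None and s > 0 and sites.syn_sites > 0:
            calibration.append((sites.syn_sites, s))

    out = []
    for gid, (ns, s) in counts.items():
        sites = opportunities.per_gene.get(gid)
        if sites is None:
            raise KeyError(f"gene {gid!r} missing from site opportunities")
        if sites.syn_sites <= 0:
            raise ValueError(f"gene {gid!r} has zero synonymous sites")
        ka = ns / sites.nonsyn_sites
        if s > 0:
            ks = s / sites.syn_sites
            calibrated = False
        elif len(calibration) >= min_calibration_genes:
            ks = calibrate_ks(calibration, sites.syn_sites)
            calibrated = True
        else:
            ks = float("nan")
            calibrated = True
        ratio = ka / ks if ks and ks == ks else float("nan")
        out.append(
            KaKsRecord(
                gene_id=gid, nonsyn_count=ns, syn_count=s,
                nonsyn_sites=sites.nonsyn_sites, syn_sites=sites.syn_sites,
                ka=ka, ks=ks, ratio=ratio, calibrated=calibrated,
            )
        )
    out.sort(key=lambda r: r.gene_id)
    return out


def aggregate_ka_ks(records: Sequence[KaKsRecord]) -> float:
    """Pooled Ka/Ks: summed counts over summed sites across genes."""
    ns = sum(r.nonsyn_count for r in records)
    s = sum(r.syn_count for r in records)
    ns_sites = sum(r.nonsyn_sites for r in records)
    s_sites = sum(r.syn_sites for r in records)
    if s == 0 or ns_sites == 0:
        raise ValueError("aggregate Ka/Ks undefined without synonymous events")
    return (ns / ns_sites) / (s / s_sites)
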