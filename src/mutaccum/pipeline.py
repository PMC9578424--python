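"""End-to-end orchestration: simulate → annotate → rates/spectrum/scan/
phenotype → report, plus the printed-counts fixture of the emulated MA
study for desk-scale arithmetic checks.

A pipeline run is a pure function of (config, seed): all randomness flows
from one seed through spawned child streams, and reruns produce
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import annotate_all, count_site_opportunities
from .core import LineMetadata
from .io_formats import as_frame, write_fasta, write_gff, write_table
from .ma_rates import (
    BottleneckRegime,
    RateEstimate,
    conditional_spectrum_rates,
    effective_population_size,
    estimate_rate,
    fourfold_rate,
    poisson_ci,
)
from .phenotype import GrowthCurve, growth_rate, mic_fold_change, mic_from_series, summarize_folds
from .selection_scan import (
    filter_population_variants,
    gene_hit_test,
    ka_ks,
    mean_allele_frequency_by_gene,
)
from .spectrum_stats import SpectrumCounts, compare_spectra, spectrum_counts, ts_tv_ratio
from .synthetic_data import (
    EvoSimConfig,
    MASimConfig,
    make_reference,
    simulate_evolution,
    simulate_ma,
    simulate_plating,
)

#: E. coli MG1655 chromosome length (bp), the default analyzed-sites fallback
ECOLI_GENOME_LENGTH = 4_641_652

# printed Table-2-style counts of the emulated study
_CONTROL_CLASSES = {
    "A:T>G:C": 19, "G:C>A:T": 35, "A:T>T:A": 13,
    "A:T>C:G": 18, "G:C>C:G": 5, "G:C>T:A": 15,
}
_TREATMENT_CLASSES = {
    "A:T>G:C": 23, "G:C>A:T": 34, "A:T>T:A": 14,
    "A:T>C:G": 13, "G:C>C:G": 2, "G:C>T:A": 12,
}


def table2_fixture() -> dict:
    """The study's printed spectrum counts and line metadata, executable.

    Control: 142 lines, T = 1099 divisions; treatment: 172 lines, T = 1112;
    analyzed sites default to the full chromosome length per line (the
    per-line analyzed-site tables are not distributed with the counts).
    """
    control = SpectrumCounts(by_class=dict(_CONTROL_CLASSES), insertions=7, deletions=7)
    treatment = SpectrumCounts(by_class=dict(_TREATMENT_CLASSES), insertions=7, deletions=9)
    control_meta = [
        LineMetadata(sample=f"ctrl{i + 1:03d}", T=1099, N=ECOLI_GENOME_LENGTH, group="control")
        for i in range(142)
    ]
    treatment_meta = [
        LineMetadata(sample=f"agnp{i + 1:03d}", T=1112, N=ECOLI_GENOME_LENGTH, group="treatment")
        for i in range(172)
    ]
    return {
        "control": control,
        "treatment": treatment,
        "control_metadata": control_meta,
        "treatment_metadata": treatment_meta,
        "regimes": {
            "control": BottleneckRegime(g=27.48, transfers=40),
            "treatment": BottleneckRegime(g=27.81, transfers=40),
        },
    }


def printed_count_statistics(level: float = 0.95) -> dict[str, float]:
    """Recompute the study's headline desk-scale statistics from the fixture.

    Everything here is arithmetic on printed counts: pooled BPS and indel
    rates with exact Poisson CIs, ts/tv ratios, Yates χ² contrasts, and the
    harmonic-mean bottleneck Ne.
    """
    fx = table2_fixture()
    out: dict[str, float] = {}
    for group in ("control", "treatment"):
        spec: SpectrumCounts = fx[group]
        meta: list[LineMetadata] = fx[f"{group}_metadata"]
        denom = sum(md.N * md.T for md in meta)
        for label, m in (("bps", spec.bps_total), ("indel", spec.indel_total)):
            low, high = poisson_ci(m, denom, level)
            out[f"{group}_{label}_rate"] = m / denom
            out[f"{group}_{label}_ci_low"] = low
            out[f"{group}_{label}_ci_high"] = high
        out[f"{group}_ts_tv"] = ts_tv_ratio(spec)
        out[f"{group}_ne"] = effective_population_size(fx["regimes"][group])
    tests = compare_spectra(fx["control"], fx["treatment"])
    out["ts_tv_chi2"] = tests["ts_tv"].statistic
    out["ts_tv_p"] = tests["ts_tv"].p
    out["ins_del_chi2"] = tests["ins_del"].statistic
    out["ins_del_p"] = tests["ins_del"].p
    return out


@dataclass
class RunConfig:
    """One reproducible pipeline run."""

    seed: int = 0
    outdir: str = "results/pipeline"
    ci_level: float = 0.95
    min_allele_frequency: float = 0.05
    alpha: float = 0.05
    bonferroni_family: str = "all"
    ma_control: MASimConfig = field(
        default_factory=lambda: MASimConfig(
            genome_length=200_000, gene_fraction=0.85, mean_gene_length=900,
            bps_rate=5e-8, indel_rate=7e-9, lines=60, g=27.48,
            group="control", sample_prefix="ctrl",
        )
    )
    ma_treatment: MASimConfig = field(
        default_factory=lambda: MASimConfig(
            genome_length=200_000, gene_fraction=0.85, mean_gene_length=900,
            bps_rate=5e-8, indel_rate=7e-9, lines=60, g=27.81,
            group="treatment", sample_prefix="agnp",
        )
    )
    evo: EvoSimConfig = field(
        default_factory=lambda: EvoSimConfig(
            population_size=100_000, mutation_rate=2e-9,
            locus_mutation_rate=1e-4, populations=12,
        )
    )
    evo_selected_fraction_of_genome: float = 0.5  # where the selected locus sits
    evo_selection_coefficient: float = 0.1
    ancestor_mic_profile: dict = field(
        default_factory=lambda: {0: 1.0, 20: 0.5, 40: 0.1, 60: 0.0, 80: 0.0, 100: 0.0}
    )
    reference_cfu: int = 1000
    plating_replicates: int = 3

    def __post_init__(self) -> None:
        for name in ("ci_level", "min_allele_frequency", "alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("ma_control", "ma_treatment"):
            if key in raw:
                raw[key] = MASimConfig(**raw[key])
        if "evo" in raw:
            raw["evo"] = EvoSimConfig(**raw["evo"])
        return cls(**raw)


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Execute every stage and write rates/spectrum/scan/phenotype tables.

    Returns a mapping of output name to file path. Identical config and seed
    give byte-identical outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(6)]
    rng_ref, rng_ctrl, rng_trt, rng_evo, rng_plate, rng_growth = streams

    # --- reference and simulated cohorts -----------------------------------
    genome, genes = make_reference(config.ma_control, rng_ref)
    write_fasta(genome, outdir / "reference.fa")
    write_gff(genes, outdir / "genes.gff3")
    ctrl_records, ctrl_meta = simulate_ma(genome, genes, config.ma_control, rng_ctrl)
    trt_records, trt_meta = simulate_ma(genome, genes, config.ma_treatment, rng_trt)
    ctrl_records = annotate_all(genome, genes, ctrl_records)
    trt_records = annotate_all(genome, genes, trt_records)
    write_table(ctrl_records + trt_records, outdir / "ma_calls.tsv")
    write_table(ctrl_meta + trt_meta, outdir / "ma_lines.tsv")
    opps = count_site_opportunities(genome, genes)

    # --- rates --------------------------------------------------------------
    rate_rows = []
    for group, records, meta in (
        ("control", ctrl_records, ctrl_meta),
        ("treatment", trt_records, trt_meta),
    ):
        for mclass in ("BPS", "indel"):
            est = estimate_rate(records, meta, mclass, level=config.ci_level)
            rate_rows.append(_rate_row(group, est))
        if opps.fourfold_sites:
            rate_rows.append(_rate_row(group, fourfold_rate(records, opps.fourfold_sites, meta, config.ci_level)))
        spec = spectrum_counts(records)
        for cls, est in conditional_spectrum_rates(spec.by_class, opps, meta, config.ci_level).items():
            rate_rows.append(_rate_row(group, est))
    rates_frame = pd.DataFrame(rate_rows)
    write_table(rates_frame, outdir / "rates.tsv")

    # --- spectrum -----------------------------------------------------------
    ctrl_spec = spectrum_counts(ctrl_records)
    trt_spec = spectrum_counts(trt_records)
    tests = compare_spectra(ctrl_spec, trt_spec)
    spec_rows = []
    for group, spec in (("control", ctrl_spec), ("treatment", trt_spec)):
        props = spec.proportions()
        for cls, n in spec.by_class.items():
            spec_rows.append({"group": group, "category": cls, "count": n, "proportion": props[cls]})
        for cat, n in (
            ("transitions", spec.transitions), ("transversions", spec.transversions),
            ("insertions", spec.insertions), ("deletions", spec.deletions),
        ):
            spec_rows.append({"group": group, "category": cat, "count": n, "proportion": props[cat]})
    for name, tr in tests.items():
        spec_rows.append({"group": "comparison", "category": f"chi2_{name}", "count": tr.statistic, "proportion": tr.p})
    write_table(pd.DataFrame(spec_rows), outdir / "spectrum.tsv")

    # --- selection scan -----------------------------------------------------
    evo_cfg = dataclasses.replace(
        config.evo,
        selected_loci={
            int(config.evo_selected_fraction_of_genome * genome.total_length) or 1:
                config.evo_selection_coefficient
        },
    )
    evo_records = simulate_evolution(genome, genes, evo_cfg, rng_evo)
    evo_records = annotate_all(genome, genes, evo_records)
    kept = filter_population_variants(evo_records, config.min_allele_frequency)
    write_table(kept, outdir / "population_calls.tsv")
    groups = {r.sample: evo_cfg.group for r in kept}
    afreq = mean_allele_frequency_by_gene(kept, genes, groups)
    write_table(afreq, outdir / "allele_frequencies.tsv")
    kaks = ka_ks(kept, opps) if kept else []
    hits = gene_hit_test(
        trt_records, genes, genome.non_n_length(),
        alpha=config.alpha, family=config.bonferroni_family,
    )
    scan = as_frame(hits)
    if kaks:
        scan = scan.merge(as_frame(kaks), on="gene_id", how="left")
    write_table(scan, outdir / "scan.tsv")

    # --- phenotype ----------------------------------------------------------
    ancestor = simulate_plating(
        config.ancestor_mic_profile, config.reference_cfu,
        config.plating_replicates, rng_plate,
    )
    ancestral_mic = mic_from_series(ancestor)
    evolved_profile = {c: e for c, e in zip(
        sorted(config.ancestor_mic_profile),
        [1.0, 0.8, 0.5, 0.3, 0.1, 0.0],
    )}
    evolved = simulate_plating(evolved_profile, config.reference_cfu, config.plating_replicates, rng_plate)
    try:
        evolved_mic = mic_from_series(evolved)
        fold = mic_fold_change(evolved_mic, ancestral_mic)
    except ValueError:
        evolved_mic, fold = float("nan"), float("nan")
    times = np.arange(0.0, 8.0, 0.5)
    anc_curve = GrowthCurve(times, 0.01 * np.exp(0.58 * times) * np.exp(rng_growth.normal(0, 0.01, times.size)))
    evo_curve = GrowthCurve(times, 0.01 * np.exp(0.53 * times) * np.exp(rng_growth.normal(0, 0.01, times.size)))
    anc_rate = growth_rate(anc_curve)
    phen_rows = [
        {"metric": "ancestral_mic", "value": ancestral_mic},
        {"metric": "evolved_mic", "value": evolved_mic},
        {"metric": "mic_fold_change", "value": fold},
        {"metric": "ancestor_growth_rate", "value": anc_rate},
        {"metric": "evolved_growth_rate", "value": growth_rate(evo_curve)},
        {"metric": "evolved_relative_growth_rate", "value": growth_rate(evo_curve, reference_rate=anc_rate)},
    ]
    for conc in ancestor.concentrations:
        phen_rows.append({"metric": f"ancestor_eop_{conc:g}", "value": ancestor.mean_eop(conc)})
    write_table(pd.DataFrame(phen_rows), outdir / "phenotype.tsv")

    # --- run log ------------------------------------------------------------
    log = {
        "package_version": __version__,
        "seed": config.seed,
        "ci_level": config.ci_level,
        "ci_construction": "exact Poisson via chi-square quantiles",
        "min_allele_frequency": config.min_allele_frequency,
        "alpha": config.alpha,
        "bonferroni_family": config.bonferroni_family,
        "bonferroni_family_size": len(genes) if config.bonferroni_family == "all" else None,
        "per_line_analyzed_sites": "full genome length (per-line site tables absent)",
        "genome_length": genome.total_length,
        "genes": len(genes),
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {
        "rates": str(outdir / "rates.tsv"),
        "spectrum": str(outdir / "spectrum.tsv"),
        "scan": str(outdir / "scan.tsv"),
        "phenotype": str(outdir / "phenotype.tsv"),
        "run_log": str(outdir / "run_log.json"),
    }


def _rate_row(group: str, est: RateEstimate) -> dict:
    return {
        "group": group, "label": est.label, "m": est.m,
        "denominator": est.denominator, "rate": est.rate, "sem": est.sem,
        "ci_low": est.ci_low, "ci_high": est.ci_high, "level": est.level,
    }
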