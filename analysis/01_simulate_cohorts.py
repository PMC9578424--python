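#!/usr/bin/env python
"""Generate the synthetic study inputs: a reference genome with annotation,
two MA cohorts (control vs sublethal-AgNPs-style treatment), serial-transfer
evolution populations with a selectable resistance locus, and plating series.

Desk-scale study conditions: 200 kb genome (85% coding), 60 MA lines per
group at 27.48 / 27.81 divisions per transfer x 40 transfers, BPS rate
scaled so each cohort accumulates ~100 mutations (matching the pooled count
the rate estimator sees in the emulated design); 12 + 12 evolution
populations at scaled census 1e5 with 1:1000 daily bottlenecks.

Writes results/simulated/{reference.fa, genes.gff3, ma_calls.tsv,
ma_lines.tsv, population_calls.tsv, plating.tsv}.
"""

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from mutaccum import (
    EvoSimConfig,
    MASimConfig,
    make_reference,
    simulate_evolution,
    simulate_ma,
    simulate_plating,
    write_table,
)
from mutaccum.io_formats import write_fasta, write_gff

SEED = 20220912
OUT = Path("results/simulated")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(SEED).spawn(5)]
    rng_ref, rng_ctrl, rng_trt, rng_evo, rng_plate = streams

    ma_base = dict(
        genome_length=200_000, gene_fraction=0.85, mean_gene_length=900,
        bps_rate=8e-9, indel_rate=1.1e-9, lines=60,
    )
    ctrl_cfg = MASimConfig(g=27.48, group="control", sample_prefix="ctrl", **ma_base)
    trt_cfg = MASimConfig(g=27.81, group="treatment", sample_prefix="agnp", **ma_base)

    genome, genes = make_reference(ctrl_cfg, rng_ref)
    write_fasta(genome, OUT / "reference.fa")
    write_gff(genes, OUT / "genes.gff3")
    print(f"reference: {genome.total_length:,} bp, {len(genes)} CDS genes")

    ctrl_records, ctrl_meta = simulate_ma(genome, genes, ctrl_cfg, rng_ctrl)
    trt_records, trt_meta = simulate_ma(genome, genes, trt_cfg, rng_trt)
    write_table(ctrl_records + trt_records, OUT / "ma_calls.tsv")
    write_table(ctrl_meta + trt_meta, OUT / "ma_lines.tsv")
    print(
        f"MA cohorts: control {len(ctrl_records)} mutations / {len(ctrl_meta)} lines, "
        f"treatment {len(trt_records)} / {len(trt_meta)}"
    )

    # evolution: treated populations carry a selectable resistance locus
    # (a cusS-like target) at the middle of the genome; controls are neutral
    locus = genome.total_length // 2
    evo_trt = EvoSimConfig(
        population_size=100_000, mutation_rate=2e-8, transfers=40,
        selected_loci={locus: 0.1}, locus_mutation_rate=1e-4,
        populations=12, group="treatment", sample_prefix="evoLS",
    )
    evo_ctrl = dataclasses.replace(
        evo_trt, selected_loci={}, locus_mutation_rate=0.0,
        group="control", sample_prefix="evoLL",
    )
    trt_pop = simulate_evolution(genome, genes, evo_trt, rng_evo)
    ctrl_pop = simulate_evolution(genome, genes, evo_ctrl, rng_evo)
    write_table(trt_pop + ctrl_pop, OUT / "population_calls.tsv")
    swept = {r.sample for r in trt_pop if r.position == locus and r.allele_frequency > 0.5}
    print(
        f"evolution: treated populations with selected locus above 50%: "
        f"{len(swept)}/12; control variant records: {len(ctrl_pop)}"
    )

    profile = {0: 1.0, 20: 0.5, 40: 0.1, 60: 0.0, 80: 0.0, 100: 0.0}
    series = simulate_plating(profile, reference_cfu=1000, replicates=3, rng=rng_plate)
    rows = [
        {"concentration": c, "replicate": i + 1, "cfu": n,
         "reference_cfu": series.reference_cfu[i]}
        for c in series.concentrations for i, n in enumerate(series.counts[c])
    ]
    write_table(pd.DataFrame(rows), OUT / "plating.tsv")
    print(f"plating series: {len(rows)} counts over {len(series.concentrations)} concentrations")


if __name__ == "__main__":
    main()
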