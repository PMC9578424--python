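#!/usr/bin/env python
"""Scan the evolved populations for selection: allele-frequency filtering at
>5%, per-gene mean mutant allele frequencies by group, Ka/Ks with
zero-synonymous calibration, convergence across parallel populations, and
the per-gene Poisson hotspot test.

Reads results/simulated/; writes results/scan.tsv and
results/allele_frequencies.tsv.
"""

import sys
from collections import defaultdict
from pathlib import Path

from mutaccum import (
    annotate_all,
    count_site_opportunities,
    filter_population_variants,
    gene_hit_test,
    ka_ks,
    mean_allele_frequency_by_gene,
    read_fasta,
    read_gff,
    read_mutations,
    write_table,
)
from mutaccum.io_formats import as_frame
from mutaccum.synthetic_data import DEFAULT_SPECTRUM

SIM = Path("results/simulated")
OUT = Path("results")
MIN_FREQ = 0.05
ALPHA = 0.05


def main() -> None:
    if not (SIM / "population_calls.tsv").exists():
        sys.exit("missing simulated inputs; run analysis/01_simulate_cohorts.py first")
    genome = read_fasta(SIM / "reference.fa")
    genes = read_gff(SIM / "genes.gff3")
    records = annotate_all(genome, genes, read_mutations(SIM / "population_calls.tsv"))
    kept = filter_population_variants(records, MIN_FREQ)
    print(f"{len(kept)}/{len(records)} variants above {MIN_FREQ:.0%} allele frequency")

    groups = {r.sample: ("treatment" if r.sample.startswith("evoLS") else "control")
              for r in kept}
    afreq = mean_allele_frequency_by_gene(kept, genes, groups)
    write_table(afreq, OUT / "allele_frequencies.tsv")
    top = afreq[afreq.group == "treatment"].head(3)
    print("top treatment genes by mean mutant allele frequency:")
    for row in top.itertuples(index=False):
        print(f"  {row.gene_id}: {row.mean_frequency:.2f} over {row.n_sites} sites")

    # convergence: genes mutated above threshold in >=2 parallel populations
    pops_per_gene = defaultdict(set)
    for r in kept:
        if groups[r.sample] == "treatment":
            for gid in r.genes:
                pops_per_gene[gid].add(r.sample)
    convergent = sorted(g for g, pops in pops_per_gene.items() if len(pops) >= 2)
    print(f"convergent treatment genes (≥2 populations): {convergent or 'none'}")

    opps = count_site_opportunities(genome, genes, spectrum_weights=DEFAULT_SPECTRUM)
    kaks = ka_ks([r for r in kept if groups[r.sample] == "treatment"], opps)
    hits = gene_hit_test(
        [r for r in kept if groups[r.sample] == "treatment"], genes,
        genome.non_n_length(), alpha=ALPHA,
    )
    scan = as_frame(hits)
    if kaks:
        scan = scan.merge(as_frame(kaks), on="gene_id", how="left")
    write_table(scan, OUT / "scan.tsv")

    significant = [h for h in hits if h.significant]
    print(f"hotspot test: {len(significant)} gene(s) significant after Bonferroni "
          f"over {len(genes)} genes")
    for h in significant:
        k = next((x for x in kaks if x.gene_id == h.gene_id), None)
        ratio = f", Ka/Ks {k.ratio:.2f}{' (calibrated Ks)' if k.calibrated else ''}" if k else ""
        print(f"  {h.gene_id}: observed {h.observed} vs expected {h.expected:.2f}, "
              f"p_adj {h.p_adj:.2e}{ratio}")


if __name__ == "__main__":
    main()
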