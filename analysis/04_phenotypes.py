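#!/usr/bin/env python
"""Plating and growth phenotypes: EOP survival curve and MIC of the
simulated ancestor, MIC fold-changes of an evolved cohort, and normalized
growth rates of evolved clones.

Reads results/simulated/plating.tsv; writes results/phenotype.tsv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from mutaccum import (
    GrowthCurve,
    PlatingSeries,
    growth_rate,
    mic_fold_change,
    mic_from_series,
    simulate_plating,
    summarize_folds,
    write_table,
)

SIM = Path("results/simulated")
OUT = Path("results")
SEED = 414


def main() -> None:
    if not (SIM / "plating.tsv").exists():
        sys.exit("missing simulated inputs; run analysis/01_simulate_cohorts.py first")
    frame = pd.read_csv(SIM / "plating.tsv", sep="\t")
    concs = sorted(frame.concentration.unique())
    series = PlatingSeries(
        [float(c) for c in concs],
        {float(c): frame.loc[frame.concentration == c, "cfu"].astype(int).tolist() for c in concs},
        frame.reference_cfu.astype(int).tolist(),
    )
    rows = []
    for c in series.concentrations:
        rows.append({"metric": f"ancestor_eop_{c:g}", "value": series.mean_eop(c)})
    ancestral_mic = mic_from_series(series)
    rows.append({"metric": "ancestral_mic", "value": ancestral_mic})
    print(f"ancestor: EOP falls to zero at {ancestral_mic:g} ug/mL (the MIC)")

    # evolved cohort: 12 lines whose true MICs sit at 4-8x the ancestor
    rng = np.random.default_rng(SEED)
    folds = []
    for i, true_fold in enumerate([4, 4, 4, 8, 8, 4, 4, 8, 4, 8, 4, 4]):
        profile = {c: (1.0 if c < true_fold * ancestral_mic else 0.0)
                   for c in [0, 60, 120, 240, 480, 960]}
        evolved = simulate_plating(profile, 1000, replicates=3, rng=rng)
        folds.append(mic_fold_change(mic_from_series(evolved), ancestral_mic))
    mean_fold, sd_fold = summarize_folds(folds)
    rows.append({"metric": "evolved_mic_fold_mean", "value": mean_fold})
    rows.append({"metric": "evolved_mic_fold_sd", "value": sd_fold})
    print(f"evolved cohort: MIC fold-change {mean_fold:.2f}x ancestral (SD {sd_fold:.2f})")

    times = np.linspace(0, 6, 13)
    anc = GrowthCurve(times, 0.02 * np.exp(0.58 * times) * np.exp(rng.normal(0, 0.01, times.size)))
    evo = GrowthCurve(times, 0.02 * np.exp(0.53 * times) * np.exp(rng.normal(0, 0.01, times.size)))
    anc_rate = growth_rate(anc)
    rel = growth_rate(evo, reference_rate=anc_rate)
    rows.append({"metric": "ancestor_growth_rate", "value": anc_rate})
    rows.append({"metric": "evolved_growth_rate", "value": growth_rate(evo)})
    rows.append({"metric": "evolved_relative_growth_rate", "value": rel})
    print(f"growth: ancestor {anc_rate:.2f}/h, evolved clone {rel:.2f}x ancestral")

    write_table(pd.DataFrame(rows), OUT / "phenotype.tsv")


if __name__ == "__main__":
    main()
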