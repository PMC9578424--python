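import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mutaccum import (
    EvoSimConfig,
    GeneModel,
    MASimConfig,
    MutationRecord,
    aggregate_ka_ks,
    annotate_all,
    calibrate_ks,
    count_site_opportunities,
    filter_population_variants,
    gene_hit_test,
    ka_ks,
    make_reference,
    mean_allele_frequency_by_gene,
    simulate_evolution,
)
from mutaccum.annotation import GeneSites, SiteOpportunities
from mutaccum.synthetic_data import DEFAULT_SPECTRUM


def _pop_rec(sample, pos, freq, genes=(), effect=None):
    return MutationRecord(
        sample, "chr1", pos, "G", "A", allele_frequency=freq,
        genes=tuple(genes), effect=effect, spectrum_class="G:C>A:T",
    )


def _genes(n, length=1000):
    return [
        GeneModel(f"g{i:04d}", "chr1", 1 + i * (length + 10), i * (length + 10) + length, "+")
        for i in range(n)
    ]


class TestGeneHitTest:
    def test_poisson_tail_and_bonferroni_hand_example(self):
        genes = _genes(4000)
        records = [_pop_rec("p", 5, 0.5, genes=["g0000"]) for _ in range(3)]
        records += [_pop_rec("p", 6, 0.5, genes=[]) for _ in range(97)]
        results = gene_hit_test(records, genes, total_sites=1e6 * 4, alpha=0.05)
        top = results[0]
        assert top.gene_id == "g0000"
        assert top.expected == pytest.approx(100 * 1000 / 4e6)
        # oracle: direct Poisson tail sum for P(X >= 3), mean 0.025
        lam = top.expected
        tail = 1 - sum(np.exp(-lam) * lam**k / math.factorial(k) for k in range(3))
        assert top.p_raw == pytest.approx(tail, rel=1e-9)
        assert top.p_adj == pytest.approx(min(1, tail * 4000))

    def test_spec_scale_example(self):
        """M=100 over 10^6 sites, one 1 kb gene with 3 hits: expected 0.1,
        p_raw 1.547e-4, Bonferroni over 4000 genes gives 0.619."""
        lam = 100 * 1000 / 1e6
        p_raw = float(stats.poisson.sf(2, lam))
        assert p_raw == pytest.approx(1.547e-4, rel=1e-3)
        assert min(1, p_raw * 4000) == pytest.approx(0.619, abs=1e-3)

    def test_zero_observed_p_one(self):
        genes = _genes(3)
        results = gene_hit_test([], genes, total_sites=1e5)
        assert all(r.p_raw == 1.0 and not r.significant for r in results)

    def test_family_hit_option_smaller_multiplier(self):
        genes = _genes(10)
        records = [_pop_rec("p", 5, 0.5, genes=["g0000"])] * 3
        all_fam = gene_hit_test(records, genes, 1e6, family="all")[0]
        hit_fam = gene_hit_test(records, genes, 1e6, family="hit")[0]
        assert hit_fam.p_adj == pytest.approx(all_fam.p_raw * 1)
        assert all_fam.p_adj == pytest.approx(all_fam.p_raw * 10)

    def test_unannotated_gene_rejected(self):
        with pytest.raises(KeyError):
            gene_hit_test([_pop_rec("p", 5, 0.5, genes=["ghost"])], _genes(2), 1e5)

    def test_familywise_error_controlled_under_uniform_null(self):
        """With equal-length genes and uniformly placed hits, Bonferroni keeps
        the fraction of experiments with any rejection at or below alpha."""
        rng = np.random.default_rng(7)
        n_genes, length, m = 200, 300, 60
        genes = _genes(n_genes, length)
        total = n_genes * length
        false_hits = 0
        for _ in range(200):
            gene_ids = rng.integers(n_genes, size=m)
            records = [
                _pop_rec("p", 5, 0.5, genes=[f"g{gid:04d}"]) for gid in gene_ids
            ]
            results = gene_hit_test(records, genes, total_sites=total, alpha=0.05)
            false_hits += any(r.significant for r in results)
        assert false_hits / 200 <= 0.05


class TestFilterPopulationVariants:
    def test_strict_inequality(self):
        records = [_pop_rec("p", i, f) for i, f in enumerate([0.04, 0.05, 0.051, 0.5], 1)]
        kept = filter_population_variants(records, 0.05)
        assert [r.allele_frequency for r in kept] == [0.051, 0.5]

    def test_empty(self):
        assert filter_population_variants([], 0.05) == []

    def test_zero_threshold_keeps_positive(self):
        records = [_pop_rec("p", 1, 0.001)]
        assert filter_population_variants(records, 0.0) == records

    def test_missing_frequency_rejected(self):
        with pytest.raises(ValueError):
            filter_population_variants([MutationRecord("p", "c", 1, "A", "G")], 0.05)

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.floats(0.001, 1.0), max_size=20), st.floats(0, 0.5))
    def test_idempotent(self, freqs, threshold):
        records = [_pop_rec("p", i + 1, f) for i, f in enumerate(freqs)]
        once = filter_population_variants(records, threshold)
        assert filter_population_variants(once, threshold) == once


class TestMeanAlleleFrequency:
    def test_mean_over_two_populations(self):
        genes = _genes(2)
        records = [
            _pop_rec("p1", 5, 0.2, genes=["g0000"]),
            _pop_rec("p2", 9, 0.6, genes=["g0000"]),
        ]
        table = mean_allele_frequency_by_gene(records, genes, {"p1": "a", "p2": "a"})
        row = table[table.gene_id == "g0000"].iloc[0]
        assert row.mean_frequency == pytest.approx(0.4)
        assert row.n_sites == 2

    def test_gene_without_variants_absent(self):
        genes = _genes(2)
        records = [_pop_rec("p1", 5, 0.2, genes=["g0000"])]
        table = mean_allele_frequency_by_gene(records, genes, {"p1": "a"})
        assert "g0001" not in set(table.gene_id)

    def test_intergenic_assigned_to_nearest_gene_pseudogene(self):
        genes = [GeneModel("near", "chr1", 100, 200, "+"), GeneModel("far", "chr1", 900, 990, "+")]
        records = [_pop_rec("p1", 220, 0.3, genes=[])]
        table = mean_allele_frequency_by_gene(records, genes, {"p1": "a"})
        assert list(table.gene_id) == ["intergenic_near_near"]

    def test_groups_kept_separate(self):
        genes = _genes(1)
        records = [
            _pop_rec("p1", 5, 0.2, genes=["g0000"]),
            _pop_rec("p2", 5, 0.8, genes=["g0000"]),
        ]
        table = mean_allele_frequency_by_gene(records, genes, {"p1": "ctl", "p2": "trt"})
        by_group = dict(zip(table.group, table.mean_frequency))
        assert by_group == {"ctl": pytest.approx(0.2), "trt": pytest.approx(0.8)}


class TestCalibrateKs:
    def test_through_origin_regression(self):
        assert calibrate_ks([(100, 1), (300, 3)], 200) == pytest.approx(0.01)

    def test_identical_genes_slope_is_ratio(self):
        assert calibrate_ks([(150, 3), (150, 3), (150, 3)], 150) == pytest.approx(3 / 150)

    def test_floor_at_half_count(self):
        assert calibrate_ks([(100, 1), (300, 3)], 10) == pytest.approx(0.05)

    def test_too_few_calibration_genes(self):
        with pytest.raises(ValueError):
            calibrate_ks([(100, 1)], 50)


class TestKaKs:
    def _opps(self):
        per_gene = {
            "g1": GeneSites("g1", syn_sites=250, nonsyn_sites=750, length=1000),
            "g2": GeneSites("g2", syn_sites=100, nonsyn_sites=300, length=400),
            "g3": GeneSites("g3", syn_sites=300, nonsyn_sites=900, length=1200),
        }
        return SiteOpportunities(per_gene=per_gene, at_sites=1, gc_sites=1)

    def _records(self):
        recs = []
        recs += [_pop_rec("p", 1, 0.5, ["g1"], "nonsynonymous")] * 2
        recs += [_pop_rec("p", 2, 0.5, ["g1"], "synonymous")]
        recs += [_pop_rec("p", 3, 0.5, ["g2"], "synonymous")] * 2
        recs += [_pop_rec("p", 4, 0.5, ["g3"], "nonsynonymous")] * 3
        return recs

    def test_hand_arithmetic(self):
        out = {k.gene_id: k for k in ka_ks(self._records(), self._opps())}
        g1 = out["g1"]
        assert g1.ka == pytest.approx(2 / 750)
        assert g1.ks == pytest.approx(1 / 250)
        assert g1.ratio == pytest.approx(2 / 3)
        assert not g1.calibrated

    def test_zero_nonsyn_ratio_zero(self):
        out = {k.gene_id: k for k in ka_ks(self._records(), self._opps())}
        assert out["g2"].ka == 0.0
        assert out["g2"].ratio == 0.0

    def test_zero_syn_gene_calibrated(self):
        out = {k.gene_id: k for k in ka_ks(self._records(), self._opps())}
        g3 = out["g3"]
        assert g3.calibrated
        # calibration genes: (250, 1), (100, 2); slope through origin
        slope = (250 * 1 + 100 * 2) / (250**2 + 100**2)
        assert g3.ks == pytest.approx(max(slope * 300, 0.5) / 300)

    def test_duplicating_populations_leaves_ratio_invariant(self):
        records = self._records()
        doubled = records + [
            MutationRecord("q", r.contig, r.position, r.ref, r.alt,
                           allele_frequency=r.allele_frequency, genes=r.genes,
                           effect=r.effect, spectrum_class=r.spectrum_class)
            for r in records
        ]
        once = {k.gene_id: k.ratio for k in ka_ks(records, self._opps())}
        twice = {k.gene_id: k.ratio for k in ka_ks(doubled, self._opps())}
        assert once["g1"] == pytest.approx(twice["g1"])

    def test_neutral_evolution_aggregate_near_one(self, sim_reference):
        """Neutral serial-transfer populations: pooled Ka/Ks across genes is
        ~1 when sites are weighted by the generating spectrum."""
        genome, genes = sim_reference
        opps = count_site_opportunities(genome, genes, spectrum_weights=DEFAULT_SPECTRUM)
        cfg = EvoSimConfig(
            population_size=100_000, bottleneck_fraction=0.01,
            generations_per_cycle=10, transfers=12, mutation_rate=1e-7,
            locus_mutation_rate=0.0, populations=6, detection_threshold=0.0, seed=1,
        )
        records = simulate_evolution(genome, genes, cfg, 1)
        ann = annotate_all(genome, genes, records)
        coding = [r for r in ann if r.effect in ("synonymous", "nonsynonymous")]
        result = ka_ks(coding, opps)
        assert len(result) >= 150
        assert aggregate_ka_ks(result) == pytest.approx(1.0, abs=0.15)

    def test_selected_locus_gene_exceeds_genome_median_frequency(self, sim_reference):
        """Positive selection (s=0.1) drives the focal gene's mean allele
        frequency above the genome-wide median in nearly all runs."""
        genome, genes = sim_reference
        focal = genes[len(genes) // 2]
        locus = (focal.start + focal.end) // 2
        wins = 0
        runs = 20
        for seed in range(runs):
            cfg = EvoSimConfig(
                population_size=100_000, bottleneck_fraction=0.01,
                generations_per_cycle=10, transfers=40, mutation_rate=5e-8,
                selected_loci={locus: 0.1}, locus_mutation_rate=1e-4,
                populations=2, detection_threshold=0.05, seed=seed,
            )
            records = simulate_evolution(genome, genes, cfg, seed)
            ann = annotate_all(genome, genes, records)
            table = mean_allele_frequency_by_gene(
                ann, genes, {r.sample: "trt" for r in ann}
            )
            focal_rows = table[table.gene_id == focal.gene_id]
            if focal_rows.empty:
                continue
            if focal_rows.iloc[0].mean_frequency > table.mean_frequency.median():
                wins += 1
        assert wins >= 0.95 * runs
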