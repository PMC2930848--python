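import math

import numpy as np
import pytest

from helpers import promoter_from_seq, random_dna

from cremag.background import compute_frequency_table, generate_random_background
from cremag.enrichment import (
    FilterParams,
    cpg_comparison,
    expected_genes,
    expected_hits,
    filter_hits,
    fold_and_z,
    proportion_p,
    run_enrichment,
)
from cremag.fixtures import FixtureSpec, cre_like_pfm, make_decoy_pwms, make_genome, plant_motifs
from cremag.io_formats import RunConfig
from cremag.pwm_engine import TFBSHit, pfm_to_pwm


def _hit(offset=10, conservation=0.5, coding=False, length=8, strand="+"):
    return TFBSHit(matrix_id="M", gene_id="G", tss_index=0, offset=offset,
                   strand=strand, length=length, rel_score=90.0,
                   conservation=conservation, coding=coding)


def _promoter(n=1000, conservation=None, coding=None):
    rng = np.random.default_rng(0)
    return promoter_from_seq(random_dna(rng, n), conservation=conservation,
                             coding_mask=coding)


class TestFilterHits:
    def test_conservation_threshold_counts(self):
        hits = [_hit(offset=10 * i, conservation=c)
                for i, c in enumerate([0.9] * 3 + [0.5] * 7)]
        prom = _promoter()
        kept, _ = filter_hits({0: hits}, {0: prom},
                              FilterParams(conservation_threshold=0.8,
                                           upstream_len=0, downstream_len=1000))
        assert len(kept) == 3

    def test_top_percent_takes_ceiling(self):
        hits = [_hit(offset=10 * i, conservation=0.5 + 0.05 * i)
                for i in range(5)]
        prom = _promoter()
        kept, _ = filter_hits({0: hits}, {0: prom},
                              FilterParams(conservation_threshold=0.0,
                                           top_percent_conserved=50.0,
                                           upstream_len=0, downstream_len=1000))
        assert len(kept) == 3  # ceil(0.5 * 5)
        assert min(h.conservation for h in kept) == pytest.approx(0.60)

    def test_max_conserved_caps_per_promoter(self):
        hits = {0: [_hit(offset=10 * i, conservation=0.9) for i in range(6)],
                1: [_hit(offset=10 * i, conservation=0.7) for i in range(4)]}
        proms = {0: _promoter(), 1: _promoter()}
        # distinct windows: avoid footprint dedup between the two promoters
        proms[1].window_start += 5000
        proms[1].window_end += 5000
        kept, _ = filter_hits(hits, proms,
                              FilterParams(conservation_threshold=0.0,
                                           max_conserved_tfbs=2,
                                           upstream_len=0, downstream_len=1000))
        assert len(kept) == 4  # exactly 2 per promoter

    def test_window_filter_drops_outside_footprints(self):
        hits = [_hit(offset=5), _hit(offset=500)]
        prom = _promoter()
        kept, _ = filter_hits({0: hits}, {0: prom},
                              FilterParams(conservation_threshold=0.0,
                                           upstream_len=0, downstream_len=100))
        assert [h.offset for h in kept] == [5]

    def test_coding_mode(self):
        hits = [_hit(offset=5, coding=True), _hit(offset=50, coding=False)]
        prom = _promoter()
        base = dict(conservation_threshold=0.0, upstream_len=0,
                    downstream_len=1000)
        kept_c, _ = filter_hits({0: hits}, {0: prom},
                                FilterParams(coding_mode="coding", **base))
        kept_n, _ = filter_hits({0: hits}, {0: prom},
                                FilterParams(coding_mode="noncoding", **base))
        assert [h.coding for h in kept_c] == [True]
        assert [h.coding for h in kept_n] == [False]

    def test_overlapping_promoters_deduplicate_footprints(self):
        # same genomic window twice: the identical physical site counts once
        hits = {0: [_hit(offset=10)], 1: [_hit(offset=10)]}
        proms = {0: _promoter(), 1: _promoter()}
        kept, length = filter_hits(hits, proms,
                                   FilterParams(conservation_threshold=0.0,
                                                upstream_len=0,
                                                downstream_len=1000))
        assert len(kept) == 1
        assert length == 1000  # effective length also deduplicated

    def test_effective_length_counts_conserved_bases(self):
        cons = np.zeros(1000)
        cons[100:400] = 0.9
        prom = _promoter(conservation=cons)
        _, length = filter_hits({0: []}, {0: prom},
                                FilterParams(conservation_threshold=0.8,
                                             upstream_len=0,
                                             downstream_len=1000))
        assert length == 300

    def test_stricter_filters_never_increase_hits(self):
        rng = np.random.default_rng(2)
        hits = [_hit(offset=int(rng.integers(0, 900)),
                     conservation=float(rng.uniform(0, 1)),
                     coding=bool(rng.integers(0, 2))) for _ in range(40)]
        prom = _promoter()
        base = len(filter_hits({0: hits}, {0: prom},
                               FilterParams(conservation_threshold=0.2,
                                            upstream_len=0,
                                            downstream_len=1000))[0])
        for params in (
            FilterParams(conservation_threshold=0.6, upstream_len=0,
                         downstream_len=1000),
            FilterParams(conservation_threshold=0.2, top_percent_conserved=20.0,
                         upstream_len=0, downstream_len=1000),
            FilterParams(conservation_threshold=0.2, max_conserved_tfbs=5,
                         upstream_len=0, downstream_len=1000),
        ):
            assert len(filter_hits({0: hits}, {0: prom}, params)[0]) <= base


class TestExpectedCounts:
    def test_expected_hits_arithmetic(self):
        assert expected_hits(1_500_000, 10.0) == pytest.approx(15.0)
        assert expected_hits(0, 10.0) == 0.0

    def test_expected_genes_poisson(self):
        val = expected_genes([1000.0] * 10, 100.0)
        assert val == pytest.approx(10 * (1 - math.exp(-0.1)), abs=1e-9)
        assert val == pytest.approx(0.9516, abs=1e-4)

    def test_expected_genes_zero_rate(self):
        assert expected_genes([1000.0] * 5, 0.0) == 0.0

    def test_expected_genes_saturates_at_gene_count(self):
        assert expected_genes([1e9] * 7, 1e6) == pytest.approx(7.0)


class TestFoldStatistics:
    def test_worked_example(self):
        df = fold_and_z({"a": 3.0, "b": 1.0, "c": 1.0, "d": 1.0, "e": 1.0})
        assert df.loc["a", "z"] == pytest.approx(1.78885, abs=1e-4)
        assert df.loc["a", "p"] == pytest.approx(0.0368, abs=1e-4)

    def test_z_identity(self):
        rng = np.random.default_rng(3)
        folds = {f"m{i}": float(rng.uniform(0, 5)) for i in range(40)}
        df = fold_and_z(folds)
        assert df["z"].mean() == pytest.approx(0.0, abs=1e-9)
        assert df["z"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_distribution(self):
        df = fold_and_z({"a": 2.0, "b": 2.0, "c": 2.0})
        assert (df["z"] == 0).all() and (df["p"] == 0.5).all()

    def test_below_mean_fold_never_enriched(self):
        df = fold_and_z({"a": 0.1, "b": 1.0, "c": 1.0, "d": 2.0})
        assert df.loc["a", "p"] > 0.5

    def test_too_few_matrices_rejected(self):
        with pytest.raises(ValueError):
            fold_and_z({"a": 1.0, "b": 2.0})


class TestProportionP:
    @pytest.mark.parametrize("obs,exp,want", [
        (45, 15.0, 1 / 3),
        (10, 25.0, 1.0),
        (0, 5.0, 1.0),
        (100, 0.0, 0.0),
    ])
    def test_values(self, obs, exp, want):
        assert proportion_p(obs, exp) == pytest.approx(want)


class TestCpgComparison:
    def test_query_at_genome_mean(self):
        q_mean, g_mean, p = cpg_comparison([500.0] * 10, 500.0, 100.0)
        assert p == pytest.approx(0.5)

    def test_three_sigma_enrichment(self):
        n, g_mean, g_sd = 16, 1000.0, 400.0
        lengths = [g_mean + 3 * g_sd / math.sqrt(n)] * n
        _, _, p = cpg_comparison(lengths, g_mean, g_sd)
        assert p == pytest.approx(1 - 0.99865, abs=1e-4)

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError):
            cpg_comparison([100.0], 50.0, 10.0)

    def test_zero_genome_sd_warns(self):
        with pytest.warns(UserWarning):
            _, _, p = cpg_comparison([10.0, 20.0], 15.0, 0.0)
        assert p == 1.0


class TestRunEnrichment:
    @pytest.fixture(scope="class")
    @staticmethod
    def planted_run():
        bundle = make_genome(FixtureSpec(seed=21, n_genes=24))
        cre = cre_like_pfm()
        query = bundle.gene_ids[:10]
        plant_motifs(bundle, cre, query, sites_per_promoter=2,
                     tss_choice="distal")
        pfms = make_decoy_pwms(14, seed=5,
                               avoid_consensus=(cre.consensus,)) + [cre]
        pwms = [pfm_to_pwm(p) for p in pfms]
        table = compute_frequency_table(
            generate_random_background(120_000, 17), pwms)
        config = RunConfig(upstream_len=1000, downstream_len=200,
                           random_occurrence=100.0)
        result = run_enrichment(query, bundle.genome, bundle.annotation,
                                bundle.conservation, pfms, table, config,
                                cage=bundle.cage, island_step=4)
        return bundle, cre, pfms, table, config, query, result

    def test_planted_matrix_ranks_first(self, planted_run):
        _, cre, *_, result = planted_run
        assert result.enrichment.iloc[0]["matrix_id"] == cre.id

    def test_all_probabilities_in_unit_interval(self, planted_run):
        *_, result = planted_run
        for col in ("tfbs_fold_p", "genes_fold_p", "proportion_p",
                    "bonferroni_p"):
            assert result.enrichment[col].between(0, 1).all()

    def test_sorted_by_tfbs_fold_p(self, planted_run):
        *_, result = planted_run
        p = result.enrichment["tfbs_fold_p"].to_numpy()
        assert (np.diff(p) >= 0).all()

    def test_deterministic_rerun(self, planted_run):
        bundle, cre, pfms, table, config, query, result = planted_run
        again = run_enrichment(query, bundle.genome, bundle.annotation,
                               bundle.conservation, pfms, table, config,
                               cage=bundle.cage, island_step=4)
        assert result.enrichment.equals(again.enrichment)
        assert result.per_gene.equals(again.per_gene)
        assert result.cpg.equals(again.cpg)

    def test_unresolved_gene_ids_listed(self, planted_run):
        bundle, cre, pfms, table, config, query, _ = planted_run
        with pytest.raises(ValueError, match="GX999"):
            run_enrichment(query + ["GX999"], bundle.genome, bundle.annotation,
                           bundle.conservation, pfms, table, config,
                           compute_cpg=False)

    def test_five_tables_present(self, planted_run):
        *_, result = planted_run
        assert not result.params.empty
        assert len(result.per_gene) == 10
        assert not result.enrichment.empty
        assert result.enrichment_extra.empty  # single repertoire supplied
        assert result.cpg["p_value"].between(0, 1).all()
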