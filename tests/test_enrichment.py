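import numpy as np
import pytest

from simenrich import (
    ListStatistics,
    NullConfig,
    ProteinRecord,
    Proteome,
    RoutConfig,
    build_null,
    dagostino_pearson,
    enrichment,
    proteome_profiles,
    rout_outliers,
    sample_random_lists,
)
from simenrich.enrichment import fold_enrichment_from_staa, log2_staa


def make_observed(staa, pct_single=50.0, pct_multiple=25.0, n=59):
    return ListStatistics(label="obs", n_proteins=n, pct_single=pct_single,
                          pct_multiple=pct_multiple, staa_value=staa,
                          total_sims=0, total_length=0)


def make_null(values, outliers=None):
    values = np.asarray(values, dtype=float)
    outliers = (np.zeros(values.size, bool) if outliers is None
                else np.asarray(outliers))
    retained = values[~outliers]
    from simenrich import NormalityResult, NullDistribution
    return NullDistribution(
        list_stats=[], staa_values=values, outlier_flags=outliers,
        retained_values=retained, log2_values=np.log2(retained[retained > 0]),
        n_zero_excluded=int((retained == 0).sum()),
        normality=NormalityResult(0.0, 1.0, retained.size),
        null_median=float(np.median(retained)),
        pct_single_median=45.0, pct_multiple_median=23.0,
    )


class TestSampling:
    def test_shapes_distinctness_and_determinism(self, synthetic_proteome):
        cfg = NullConfig(n_lists=20, list_size=10, seed=123)
        lists = sample_random_lists(synthetic_proteome, cfg)
        assert len(lists) == 20
        for pl in lists:
            assert len(pl.members) == 10
            assert len(set(pl.members)) == 10
            assert all(a in synthetic_proteome for a in pl.members)
        again = sample_random_lists(synthetic_proteome, cfg)
        assert [p.members for p in lists] == [p.members for p in again]
        other = sample_random_lists(synthetic_proteome,
                                    NullConfig(n_lists=20, list_size=10, seed=124))
        assert [p.members for p in lists] != [p.members for p in other]

    def test_list_size_equal_to_frame(self):
        proteome = Proteome([ProteinRecord(f"A{i}", "ACDE") for i in range(5)])
        lists = sample_random_lists(proteome, NullConfig(n_lists=3, list_size=5,
                                                         seed=0))
        for pl in lists:
            assert sorted(pl.members) == sorted(proteome.accessions)

    def test_frame_smaller_than_k_rejected(self):
        proteome = Proteome([ProteinRecord(f"A{i}", "ACDE") for i in range(5)])
        with pytest.raises(ValueError, match="frame"):
            sample_random_lists(proteome, NullConfig(n_lists=1, list_size=6, seed=0))

    def test_min_length_restricts_frame(self, tiny_proteome):
        cfg = NullConfig(n_lists=5, list_size=1, seed=0, min_length=50)
        lists = sample_random_lists(tiny_proteome, cfg)
        for pl in lists:
            assert pl.members == ["P00005"]  # the only protein >= 50 aa


class TestRout:
    def test_planted_contamination(self, rng):
        clean = rng.normal(10.0, 2.0, size=1000)
        # plant at center + 10 robust SDs
        planted = 10.0 + 10.0 * 2.0 * np.ones(5)
        x = np.concatenate([clean, planted])
        flags = rout_outliers(x, RoutConfig(q=0.01))
        assert flags[1000:].all()
        assert flags[:1000].sum() <= 10  # <= 1% false flags

    def test_single_extreme_among_identical(self):
        x = np.array([5.0] * 15 + [50.0])
        flags = rout_outliers(x)
        assert flags.sum() == 1 and flags[-1]

    def test_no_outliers_in_clean_normal(self, rng):
        x = rng.normal(size=500)
        assert rout_outliers(x).sum() <= 5

    def test_mad_cross_check_agrees_on_planted(self, rng):
        x = np.concatenate([rng.normal(size=200), [25.0, -30.0]])
        lor = rout_outliers(x, RoutConfig(q=0.01, method="lorentzian"))
        mad = rout_outliers(x, RoutConfig(q=0.01, method="mad"))
        assert lor[200:].all() and mad[200:].all()

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            rout_outliers(np.arange(9.0))

    def test_invalid_q_rejected(self):
        with pytest.raises(ValueError):
            RoutConfig(q=0.0)
        with pytest.raises(ValueError):
            RoutConfig(q=0.6)


class TestNormality:
    def test_matches_chi2_upper_tail(self, rng):
        from scipy.stats import chi2
        res = dagostino_pearson(rng.normal(size=200))
        assert res.k2 >= 0 and 0 <= res.p_value <= 1
        assert res.p_value == pytest.approx(chi2.sf(res.k2, 2))

    def test_strong_skew_rejected(self, rng):
        res = dagostino_pearson(rng.exponential(size=1000))
        assert res.p_value < 1e-3

    def test_small_n_and_zero_variance_rejected(self, rng):
        with pytest.raises(ValueError):
            dagostino_pearson(np.arange(19.0))
        with pytest.raises(ValueError):
            dagostino_pearson(np.full(50, 3.0))


class TestBuildNull:
    def test_pipeline_shape(self, synthetic_proteome):
        cfg = NullConfig(n_lists=60, list_size=15, seed=5)
        dist = build_null(synthetic_proteome, config=cfg)
        assert len(dist.list_stats) == 60
        assert dist.staa_values.shape == (60,)
        assert dist.n_retained == 60 - dist.n_outliers
        assert dist.retained_values.min() <= dist.null_median \
            <= dist.retained_values.max()
        assert dist.log2_values.size == (dist.retained_values > 0).sum()
        assert dist.normality.n == dist.log2_values.size

    def test_profiles_cache_equivalent(self, synthetic_proteome):
        cfg = NullConfig(n_lists=30, list_size=10, seed=2)
        profs = proteome_profiles(synthetic_proteome)
        a = build_null(synthetic_proteome, config=cfg)
        b = build_null(synthetic_proteome, config=cfg, profiles=profs)
        assert np.array_equal(a.staa_values, b.staa_values)

    def test_degenerate_identical_proteome_errors_on_zero_variance(self):
        proteome = Proteome([ProteinRecord(f"A{i}", "LLAL" + "A" * 96)
                             for i in range(40)])
        with pytest.raises(ValueError, match="zero-variance"):
            build_null(proteome, config=NullConfig(n_lists=30, list_size=5, seed=0))

    def test_exclude_query_removes_members_from_frame(self, synthetic_proteome):
        from simenrich import ProteinList
        query = ProteinList("q", members=synthetic_proteome.accessions[:50])
        cfg = NullConfig(n_lists=40, list_size=200, seed=9, exclude_query=True)
        lists = sample_random_lists(synthetic_proteome, cfg, query=query)
        banned = set(query.members)
        for pl in lists:
            assert not banned & set(pl.members)


class TestEnrichment:
    def test_hand_counted_empirical_p(self):
        null = make_null(np.arange(1.0, 101.0))
        res = enrichment(make_observed(95.0), null)
        assert res.exceed_count == 6
        assert res.empirical_p == pytest.approx(0.06)
        assert not res.is_upper_bound

    def test_observed_beyond_all_nulls_reports_bound(self):
        null = make_null(np.linspace(1, 10, 1000))
        res = enrichment(make_observed(50.0), null)
        assert res.exceed_count == 0
        assert res.is_upper_bound
        assert res.empirical_p == pytest.approx(1 / 1000)
        assert res.p_label == "< 0.001"

    def test_monotonicity(self):
        null = make_null(np.linspace(1, 10, 200))
        prev_p, prev_fold = 1.1, 0.0
        for staa in [2.0, 5.0, 8.0, 12.0]:
            res = enrichment(make_observed(staa), null)
            assert res.empirical_p <= prev_p
            assert res.fold_enrichment >= prev_fold
            prev_p, prev_fold = res.empirical_p, res.fold_enrichment

    def test_zero_null_median_rejected(self):
        null = make_null([0.0] * 50)
        with pytest.raises(ValueError):
            enrichment(make_observed(5.0), null)

    def test_worked_ratio_helpers(self):
        assert fold_enrichment_from_staa(18.42, 4.85) == pytest.approx(3.798, abs=5e-3)
        assert log2_staa(4.85) == pytest.approx(2.28, abs=5e-3)
        assert log2_staa(18.42) == pytest.approx(4.20, abs=5e-3)
        with pytest.raises(ValueError):
            log2_staa(0.0)
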