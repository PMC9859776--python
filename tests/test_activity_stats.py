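"""Enrichment inference: F/Student/Welch machinery, soil contrast, heatmap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hybridsip import enrichment_test, heatmap_matrix, soil_differential, variance_check
from hybridsip.activity_stats import enrichment_table, _benjamini_hochberg
from hybridsip.mapping import MappingResult
from hybridsip.virus_screen import VOTUCall


# ---------------------------------------------------------------------------
# textbook-formula oracles, written independently of the implementation


def _student_oracle(x, y):
    n1, n2 = len(x), len(y)
    s2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / (n1 + n2 - 2)
    t = (np.mean(y) - np.mean(x)) / np.sqrt(s2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), n1 + n2 - 2)
    return t, p


def _welch_oracle(x, y):
    n1, n2 = len(x), len(y)
    v1, v2 = np.var(x, ddof=1) / n1, np.var(y, ddof=1) / n2
    t = (np.mean(y) - np.mean(x)) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, p


def _f_oracle(x, y):
    f = np.var(x, ddof=1) / np.var(y, ddof=1)
    d1, d2 = len(x) - 1, len(y) - 1
    return 2 * min(stats.f.cdf(f, d1, d2), stats.f.sf(f, d1, d2))


class TestVarianceCheck:
    def test_identical_samples_homogeneous(self):
        x = [0.1, 0.2, 0.3]
        assert variance_check(x, x) is True

    def test_hundredfold_variance_ratio_rejected_at_n3(self):
        x = [0.0, 1.0, 2.0]  # variance 1
        y = [0.0, 10.0, 20.0]  # variance 100
        # F(2,2): p = 2*min(cdf, sf)(100) = 2/101 < 0.05
        assert variance_check(x, y) is False
        assert _f_oracle(y, x) < 0.05

    def test_zero_variance_against_positive_is_degenerate(self):
        assert variance_check([1.0, 1.0, 1.0], [0.0, 1.0, 2.0]) is False
        assert variance_check([0.0, 1.0, 2.0], [1.0, 1.0, 1.0]) is False

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            variance_check([1.0], [1.0, 2.0])


class TestEnrichmentTest:
    def test_equal_samples_not_enriched(self):
        call = enrichment_test([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert call.t_stat == 0.0
        assert call.p_value == 1.0
        assert not call.enriched

    def test_clear_enrichment_matches_textbook_formula(self):
        x12 = np.array([0.010, 0.012, 0.011])
        x13 = np.array([0.030, 0.028, 0.032])
        call = enrichment_test(x12, x13)
        assert call.enriched
        if call.test_used == "student":
            t, p = _student_oracle(x12, x13)
        else:
            t, p = _welch_oracle(x12, x13)
        assert call.t_stat == pytest.approx(t, abs=1e-10)
        assert call.p_value == pytest.approx(p, abs=1e-10)

    def test_direction_requirement_blocks_depletion_calls(self):
        call = enrichment_test([0.030, 0.028, 0.032], [0.010, 0.012, 0.011])
        assert call.p_value < 0.05
        assert not call.enriched  # significant, but 13C mean is lower

    @pytest.mark.filterwarnings("ignore:Precision loss")
    def test_degenerate_constant_groups(self):
        equal = enrichment_test([0.1, 0.1, 0.1], [0.1, 0.1, 0.1])
        assert equal.p_value == 1.0 and not equal.enriched
        apart = enrichment_test([0.0, 0.0, 0.0], [0.25, 0.25, 0.25])
        assert apart.p_value == 0.0 and apart.enriched

    def test_test_used_tracks_variance_homogeneity(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.normal(0, 1, 3)
            y = rng.normal(0.5, 1, 3)
            call = enrichment_test(x, y)
            assert (call.test_used == "student") == call.variance_homogeneous

    def test_enriched_is_antitone_in_alpha(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            x = rng.normal(0.01, 0.002, 3)
            y = rng.normal(0.02, 0.002, 3)
            strict = enrichment_test(x, y, alpha=0.01)
            loose = enrichment_test(x, y, alpha=0.10)
            if strict.enriched:
                assert loose.enriched

    def test_oracle_equivalence_over_random_draws(self):
        """Student, Welch and F all match textbook formulas to 1e-10."""
        rng = np.random.default_rng(2)
        for _ in range(200):
            n1, n2 = rng.integers(2, 8, 2)
            x = rng.normal(0, rng.uniform(0.5, 2), n1)
            y = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), n2)
            call = enrichment_test(x, y)
            oracle = _student_oracle if call.test_used == "student" else _welch_oracle
            t, p = oracle(x, y)
            assert call.t_stat == pytest.approx(t, abs=1e-10)
            assert call.p_value == pytest.approx(p, abs=1e-10)
            hom = _f_oracle(x, y) >= 0.05
            assert call.variance_homogeneous == hom


class TestEnrichmentTableAndBH:
    def test_bh_adjustment_is_monotone_and_conservative(self):
        p = np.array([0.001, 0.01, 0.02, 0.04, 0.5])
        adj = _benjamini_hochberg(p)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0).all()
        # classic BH: adjusted = p * n / rank, cummin from the largest
        expected = np.minimum.accumulate((p * 5 / np.arange(1, 6))[::-1])[::-1]
        assert np.allclose(adj, expected)

    def test_bh_flag_never_adds_calls(self):
        rng = np.random.default_rng(3)
        x12 = pd.DataFrame(rng.normal(0.01, 0.003, (10, 3)), index=[f"f{i}" for i in range(10)])
        x13 = pd.DataFrame(rng.normal(0.013, 0.003, (10, 3)), index=x12.index)
        plain = enrichment_table(x12, x13)
        corrected = enrichment_table(x12, x13, bh_correct=True)
        assert set(corrected[corrected.enriched].feature_id) <= set(
            plain[plain.enriched].feature_id
        )


class TestSoilDifferential:
    def test_soil_exclusive_feature_labelled_with_its_soil(self):
        by_soil = {
            "pH4.5": pd.DataFrame({"r1": [0.02], "r2": [0.025], "r3": [0.022]}, index=["v1"]),
            "pH7.5": pd.DataFrame({"r1": [0.0], "r2": [0.0], "r3": [0.0]}, index=["v1"]),
        }
        out = soil_differential(by_soil)
        assert list(out["label"]) == ["pH4.5"]

    def test_identical_proportions_are_ns(self):
        same = pd.DataFrame({"r1": [0.01], "r2": [0.01], "r3": [0.01]}, index=["v1"])
        out = soil_differential({"pH4.5": same, "pH7.5": same.copy()})
        assert list(out["label"]) == ["ns"]

    def test_requires_exactly_two_soils(self):
        df = pd.DataFrame({"r1": [0.01]}, index=["v1"])
        with pytest.raises(ValueError):
            soil_differential({"a": df})

    def test_default_scenario_soil_labels_match_truth(self, default_study):
        correct, total = default_study.soil_diff_accuracy()
        assert total == len(default_study.votus)
        assert correct == total


def _votu(cid, length):
    return VOTUCall(contig_id=cid, length=length, gc=0.36)


def _mapping(lib, cids, lengths, counts, depths, breadths):
    return MappingResult(
        library_id=lib,
        contig_ids=cids,
        lengths=np.array(lengths),
        counts=np.array(counts),
        depth=np.array(depths, dtype=float),
        breadth=np.array(breadths, dtype=float),
        unmapped=0,
        total_reads=int(np.sum(counts)),
    )


class TestHeatmap:
    def test_reads_per_kb_values_and_masking(self):
        mappings = {
            "L1": _mapping("L1", ["v1", "v2", "v3"], [10_000, 20_000, 15_000],
                           [100, 200, 80], [1.5, 1.5, 1.2], [0.9, 0.9, 0.5]),
            "L2": _mapping("L2", ["v1", "v2", "v3"], [10_000, 20_000, 15_000],
                           [0, 50, 10], [0.0, 0.4, 1.1], [0.0, 0.8, 0.8]),
        }
        votus = [_votu("v1", 10_000), _votu("v2", 20_000), _votu("v3", 15_000)]
        hm = heatmap_matrix(mappings, votus, ["L1", "L2"])
        # 100 reads on 10 kb -> ln(10)
        assert hm.values.loc["v1", "L1"] == pytest.approx(np.log(10.0))
        # reads-per-kb identity: 200 reads / 20 kb == 100 reads / 10 kb
        assert hm.values.loc["v2", "L1"] == pytest.approx(hm.values.loc["v1", "L1"])
        # masked: breadth 0.5 < 0.75
        assert hm.mask.loc["v3", "L1"]
        assert np.isnan(hm.values.loc["v3", "L1"])
        # masked: zero count
        assert hm.mask.loc["v1", "L2"]
        # masked: depth 0.4 < 1x
        assert hm.mask.loc["v2", "L2"]
        # unmasked entries are finite; ln(0) can never appear
        assert np.isfinite(hm.values.to_numpy()[~hm.mask.to_numpy()]).all()

    def test_default_study_heatmap_mask_consistency(self, default_study):
        hm = default_study.heatmap
        vals = hm.values.to_numpy()
        mask = hm.mask.to_numpy()
        assert np.isfinite(vals[~mask]).all()
        assert np.isnan(vals[mask]).all()
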