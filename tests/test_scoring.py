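import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmsort import scoring as sc
from dmsort import simulate as sim
from dmsort.counts import VariantCountTable
from dmsort.scoring import (
    LogRatioSeries,
    ScoringError,
    SortSeqEnrichment,
    combine_replicates,
    log_ratio_series,
    wls_slope,
)


def oracle_wls(t, M, V):
    """Independent oracle: solve the 2x2 weighted normal equations directly."""
    X = np.column_stack([np.ones_like(t), t])
    W = np.diag(1.0 / np.asarray(V))
    xtwx = X.T @ W @ X
    beta = np.linalg.solve(xtwx, X.T @ W @ np.asarray(M))
    cov = np.linalg.inv(xtwx)
    return beta[1], np.sqrt(cov[1, 1])


class TestWildtypeCounts:
    def test_pooled_synonymous_counts(self, tiny_library):
        spec = sim.SortSpec("surface", ["lo", "hi"], (0.5,), 100, 1)
        rows = []
        for v in tiny_library.variants:
            for b in ("lo", "hi"):
                rows.append(
                    {"axis": "surface", "replicate": 1, "bin": b,
                     "variant": v.variant_id, "position": v.position,
                     "wt_aa": v.wt_aa, "mut_aa": v.mut_aa,
                     "mut_codon": v.mut_codon, "kind": v.kind,
                     "count": 5 if v.kind == "synonymous" else 7}
                )
        table = VariantCountTable(pd.DataFrame(rows), pd.DataFrame())
        wt = sc.wildtype_counts(table, tiny_library)
        n_syn = len(tiny_library.synonymous)
        assert (wt["wt_count"] == 5 * n_syn).all()

    def test_design_without_synonymous_controls_is_an_error(self, tiny_library):
        import dataclasses

        bare = dataclasses.replace(tiny_library)
        bare.variants = tiny_library.missense
        bare.synonymous_positions = set()
        with pytest.raises(ScoringError):
            sc.wildtype_counts(VariantCountTable(pd.DataFrame(), pd.DataFrame()), bare)


class TestLogRatioSeries:
    def test_equal_counts_give_zero_log_ratio(self):
        series = log_ratio_series([9, 9, 9], [9, 9, 9])
        assert np.allclose(series.M, 0.0)

    def test_zero_variant_counts_use_the_pseudocount(self):
        series = log_ratio_series([0, 0, 0], [9, 9, 9])
        assert np.allclose(series.M, np.log(0.5 / 9.5))
        assert np.allclose(series.V, 1 / 0.5 + 1 / 9.5)

    def test_depth_invariance_at_large_counts(self):
        c = np.array([200, 400, 800])
        w = np.array([300, 300, 300])
        m1 = log_ratio_series(c, w).M
        m2 = log_ratio_series(2 * c, 2 * w).M
        assert np.max(np.abs(m1 - m2)) < 0.01

    def test_single_bin_is_insufficient(self):
        with pytest.raises(ScoringError):
            log_ratio_series([5], [5])


class TestWlsSlope:
    def test_flat_series_scores_zero(self):
        series = log_ratio_series([7, 7, 7, 7], [7, 7, 7, 7])
        slope, se = wls_slope(series)
        assert slope == pytest.approx(0.0)
        assert se > 0

    def test_two_point_slope_is_exact(self):
        series = LogRatioSeries("v", [0, 1], [0.0, 1.0], [1.0, 1.0])
        slope, _ = wls_slope(series)
        assert slope == pytest.approx(1.0)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            k = rng.integers(2, 8)
            t = np.arange(k, dtype=float)
            M = rng.normal(size=k)
            V = rng.uniform(0.05, 2.0, size=k)
            slope, se = wls_slope(LogRatioSeries("v", t, M, V))
            o_slope, o_se = oracle_wls(t, M, V)
            assert abs(slope - o_slope) < 1e-10
            assert abs(se - o_se) < 1e-10

    def test_affine_bin_relabeling_rescales_the_slope(self):
        rng = np.random.default_rng(1)
        t = np.arange(4, dtype=float)
        M = rng.normal(size=4)
        V = rng.uniform(0.1, 1.0, size=4)
        s1, _ = wls_slope(LogRatioSeries("v", t, M, V))
        s2, _ = wls_slope(LogRatioSeries("v", 2 * t + 3, M, V))
        assert s1 == pytest.approx(2 * s2)

    def test_single_coordinate_is_unscorable(self):
        with pytest.raises(ScoringError):
            wls_slope(LogRatioSeries("v", [1, 1], [0.0, 1.0], [1.0, 1.0]))


class TestCombineReplicates:
    def test_identical_replicates_have_no_between_variance(self):
        score, se, sigma2 = combine_replicates([1.5, 1.5], [0.2, 0.2])
        assert score == pytest.approx(1.5)
        assert sigma2 == 0.0
        assert se <= 0.2  # pooling never hurts when replicates agree

    def test_single_replicate_passes_through(self):
        score, se, sigma2 = combine_replicates([0.7], [0.3])
        assert (score, se, sigma2) == (0.7, 0.3, 0.0)

    def test_symmetric_disagreement_lands_at_the_midpoint(self):
        score, se, sigma2 = combine_replicates([0.0, 1.0], [0.1, 0.1])
        assert score == pytest.approx(0.5)
        # method-of-moments: sigma2 = (Q - 1) / C with equal weights w = 100
        w = 1 / 0.1**2
        q = w * (0.5**2) * 2
        c = 2 * w - 2 * w**2 / (2 * w)
        assert sigma2 == pytest.approx((q - 1) / c)
        assert sigma2 > 0

    @given(
        st.lists(
            st.tuples(
                st.floats(-5, 5),
                st.floats(0.01, 2.0),
            ),
            min_size=1,
            max_size=6,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_combined_score_lies_within_replicate_range(self, reps):
        s = [a for a, _ in reps]
        e = [b for _, b in reps]
        score, se, sigma2 = combine_replicates(s, e)
        assert min(s) - 1e-12 <= score <= max(s) + 1e-12
        assert se >= 0 and sigma2 >= 0
        if sigma2 == 0:
            assert se <= min(e) + 1e-12


@pytest.fixture(scope="module")
def fitted(surface_experiment):
    return SortSeqEnrichment.from_simulation(surface_experiment).fit()


class TestScoreExperiment:
    def test_synonymous_null_median_near_zero(self):
        from dmsort import workflows

        out = workflows.null_calibration(seed=3)
        assert abs(out["missense_median"]) <= 2 * out["pooled_se"]

    def test_variant_proportional_to_wildtype_scores_zero(self, tiny_library):
        spec = sim.SortSpec("surface", ["a", "b", "c"], (1 / 3, 2 / 3), 100, 1)
        syn_ids = {v.variant_id for v in tiny_library.synonymous}
        target = tiny_library.missense[0].variant_id
        rows = []
        wt_per_bin = {"a": 400, "b": 300, "c": 500}
        for v in tiny_library.variants:
            for b, wt_count in wt_per_bin.items():
                if v.variant_id == target:
                    count = 2 * wt_count  # proportional to the wildtype pool
                elif v.variant_id in syn_ids:
                    count = wt_count // len(syn_ids)
                else:
                    count = 1
                rows.append(
                    {"axis": "surface", "replicate": 1, "bin": b,
                     "variant": v.variant_id, "position": v.position,
                     "wt_aa": v.wt_aa, "mut_aa": v.mut_aa,
                     "mut_codon": v.mut_codon, "kind": v.kind, "count": count}
                )
        table = VariantCountTable(pd.DataFrame(rows), pd.DataFrame())
        res = sc.score_experiment(table, tiny_library, spec)
        score = res.set_index("variant").loc[target, "score"]
        assert abs(score) < 0.02

    def test_high_latent_variant_outscores_low_latent(self, surface_experiment, fitted):
        m = fitted.scores.merge(
            surface_experiment.truth.latents[["variant", "latent"]], on="variant"
        )
        hi = m.nlargest(20, "latent")["score"].mean()
        lo = m.nsmallest(20, "latent")["score"].mean()
        assert hi > lo

    def test_variant_absent_from_one_replicate_still_scored(self, surface_experiment, small_library):
        table = VariantCountTable.from_simulation(surface_experiment)
        victim = small_library.missense[0].variant_id
        df = table.df.copy()
        df.loc[(df["variant"] == victim) & (df["replicate"] == 1), "count"] = 0
        res = sc.score_experiment(
            VariantCountTable(df, table.unexpected), small_library,
            surface_experiment.sort_spec,
        )
        row = res.set_index("variant").loc[victim]
        assert row["n_replicates_observed"] == 1
        assert np.isfinite(row["score"])

    def test_log10_option_rescales_scores(self, surface_experiment, small_library, fitted):
        res10 = SortSeqEnrichment.from_simulation(surface_experiment).fit(log_base=10)
        ratio = res10.scores["score"] / fitted.scores["score"]
        assert np.allclose(ratio.dropna(), 1 / np.log(10))

    def test_replicate_correlation_reported(self, fitted):
        assert -1 <= fitted.replicate_correlation() <= 1

    def test_summary_mentions_axis_and_counts(self, fitted):
        text = fitted.summary()
        assert "surface" in text and "missense" in text
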