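"""Spike-in normalization, differential tables, qPCR and region densities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mycsetpoint import seqquant, simulate
from mycsetpoint.seqquant import (
    CountMatrix,
    compute_fpk,
    differential_table,
    normalization_scores,
    normalize,
    percent_input,
    region_fold_change,
    select_spikein_reference,
    threshold_fc,
)


class TestFPK:
    @pytest.mark.parametrize(
        "count,length,expected", [(100, 1000, 100.0), (50, 2500, 20.0), (0, 800, 0.0)]
    )
    def test_values(self, count, length, expected):
        fpk = compute_fpk(
            pd.DataFrame({"s": [count]}, index=["t"]),
            pd.Series([length], index=["t"]),
        )
        assert fpk.loc["t", "s"] == pytest.approx(expected)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            compute_fpk(
                pd.DataFrame({"s": [1]}, index=["t"]), pd.Series([0], index=["t"])
            )


def proportional_spike_fpk(n=60, n_samples=6, seed=0):
    """Spike-in FPK rows exactly proportional across samples."""
    rng = np.random.default_rng(seed)
    base = rng.uniform(5, 500, size=n)
    scale = np.array([1.0, 1.3, 0.8, 1.1, 1.6, 0.7])[:n_samples]
    mat = np.outer(base, scale)
    return pd.DataFrame(
        mat, index=[f"ERCC-{i:03d}" for i in range(n)],
        columns=[f"s{j}" for j in range(n_samples)],
    )


class TestSpikeSelection:
    def test_degenerate_correlation_falls_back_to_top_by_fpk(self):
        fpk = proportional_spike_fpk()
        chosen = select_spikein_reference(fpk, top_n=50, subset=10)
        top10 = fpk.mean(axis=1).sort_values(ascending=False).index[:10]
        assert set(chosen) == set(top10)

    def test_shuffled_outlier_rows_never_selected(self):
        fpk = proportional_spike_fpk(n=50)
        outliers = ["ERCC-000", "ERCC-001"]
        for t in outliers:
            # break the cross-sample pattern while keeping magnitude high
            fpk.loc[t] = fpk.loc[t].to_numpy()[::-1] * 10
        chosen = select_spikein_reference(fpk, top_n=50, subset=10)
        assert not set(outliers) & set(chosen)

    def test_exactly_topn_candidates_identity(self):
        fpk = proportional_spike_fpk(n=50)
        assert len(select_spikein_reference(fpk, top_n=50, subset=10)) == 10

    def test_too_few_candidates_rejected(self):
        fpk = proportional_spike_fpk(n=8)
        with pytest.raises(ValueError):
            select_spikein_reference(fpk, top_n=50, subset=10)

    def test_zero_rows_excluded_with_warning(self):
        fpk = proportional_spike_fpk(n=30)
        fpk.iloc[0, 0] = 0.0
        with pytest.warns(UserWarning, match="zero FPK"):
            chosen = select_spikein_reference(fpk, top_n=20, subset=10)
        assert fpk.index[0] not in chosen


class TestNormalization:
    def test_geometric_mean_score(self):
        fpk = pd.DataFrame({"s": [4.0, 9.0]}, index=["a", "b"])
        assert normalization_scores(fpk, ["a", "b"])["s"] == pytest.approx(6.0)

    def test_zero_reference_names_transcript_and_sample(self):
        fpk = pd.DataFrame({"s1": [4.0, 0.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="b.*s1"):
            normalization_scores(fpk, ["a", "b"])

    def test_sample_scaling_cancels(self):
        """Doubling every count in a sample (spike-ins included) leaves its
        normalized column unchanged: the score doubles with the FPK."""
        counts, lengths, flag = simulate.simulate_rnaseq(
            n_genes=400, amplification=1.0, seed=5
        )
        fpk = compute_fpk(counts, lengths)
        ref = select_spikein_reference(fpk.loc[flag], top_n=40, subset=10)
        doubled = counts.copy()
        doubled["low_1"] = doubled["low_1"] * 2
        fpk2 = compute_fpk(doubled, lengths)
        col = fpk.div(normalization_scores(fpk, ref), axis=1)["low_1"]
        col2 = fpk2.div(normalization_scores(fpk2, ref), axis=1)["low_1"]
        assert np.allclose(col, col2, rtol=1e-9)

    def test_global_amplification_recovered_only_with_spikeins(self):
        counts, lengths, flag = simulate.simulate_rnaseq(
            n_genes=1500, amplification=2.0, seed=6
        )
        res = normalize(CountMatrix(counts, lengths, flag))
        genes = res.normalized.loc[~flag]
        low = genes[["low_1", "low_2"]].mean(axis=1)
        high = genes[["high_1", "high_2"]].mean(axis=1)
        ratio = float((high[low > 0] / low[low > 0]).median())
        assert 1.9 <= ratio <= 2.1
        # total-count normalization hides the amplification
        cpm = counts.div(counts.sum(axis=0), axis=1).loc[~flag]
        lowc = cpm[["low_1", "low_2"]].mean(axis=1)
        highc = cpm[["high_1", "high_2"]].mean(axis=1)
        ratio_tc = float((highc[lowc > 0] / lowc[lowc > 0]).median())
        assert abs(ratio_tc - 1.0) < 0.1

    def test_renormalization_is_idempotent(self):
        counts, lengths, flag = simulate.simulate_rnaseq(n_genes=300, seed=7)
        res = normalize(CountMatrix(counts, lengths, flag))
        scores2 = normalization_scores(res.normalized, res.reference_ids)
        assert np.allclose(scores2.to_numpy(), 1.0, atol=1e-9)

    def test_min_spikeins_guard(self):
        counts, lengths, flag = simulate.simulate_rnaseq(n_genes=200, seed=8)
        flag2 = flag.copy()
        flag2[flag2.cumsum() > 10] = False  # keep only 10 spike-ins
        with pytest.raises(ValueError, match="spike-in"):
            normalize(CountMatrix(counts, lengths, flag2))


class TestDifferential:
    def _matrix(self, a_scale=1.0):
        rng = np.random.default_rng(2)
        base = rng.uniform(10, 200, size=50)
        data = {
            "a1": base * a_scale * rng.normal(1, 0.02, 50),
            "a2": base * a_scale * rng.normal(1, 0.02, 50),
            "b1": base * rng.normal(1, 0.02, 50),
            "b2": base * rng.normal(1, 0.02, 50),
        }
        return pd.DataFrame(data, index=[f"g{i}" for i in range(50)])

    def test_identical_groups_fc_one(self):
        m = self._matrix()
        m["a1"], m["a2"] = m["b1"], m["b2"]
        t = differential_table(m, {"a": ["a1", "a2"], "b": ["b1", "b2"]})
        assert np.allclose(t["fold_change"], 1.0)

    def test_six_fold_gene_passes_fc5_and_boundary_excluded(self):
        m = self._matrix()
        m.loc["g0", ["a1", "a2"]] = m.loc["g0", ["b1", "b2"]].to_numpy() * 6.0
        m.loc["g1", ["a1", "a2"]] = m.loc["g1", ["b1", "b2"]].to_numpy() * 4.9
        t = differential_table(m, {"a": ["a1", "a2"], "b": ["b1", "b2"]})
        hits = threshold_fc(t, fc_min=5.0)
        assert "g0" in hits and "g1" not in hits

    def test_q_values_bounded(self):
        t = differential_table(
            self._matrix(1.5), {"a": ["a1", "a2"], "b": ["b1", "b2"]}
        )
        assert t["q_value"].between(0, 1).all()

    def test_single_replicate_missing_p_with_warning(self):
        m = self._matrix()
        with pytest.warns(UserWarning, match="single-replicate"):
            t = differential_table(m, {"a": ["a1"], "b": ["b1", "b2"]})
        assert t["p_value"].isna().all()
        assert np.isfinite(t["fold_change"]).all()


class TestPercentInput:
    def test_identity(self):
        assert percent_input(20.0, 20.0, 1.0) == pytest.approx(100.0)

    def test_hand_value_one_percent_input(self):
        # adjusted input = 20 - log2(100); chip 3 cycles later -> 12.5%
        adj = 20.0 - np.log2(100.0)
        assert percent_input(adj + 3.0, 20.0, 0.01) == pytest.approx(12.5)

    def test_doubling_per_cycle_with_warning(self):
        adj = 20.0 - np.log2(1.0)
        with pytest.warns(UserWarning, match="implausible"):
            assert percent_input(adj - 1.0, 20.0, 1.0) == pytest.approx(200.0)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            percent_input(15.0, 20.0, 0.0)

    @given(delta=st.floats(min_value=0.1, max_value=5.0))
    def test_strictly_decreasing_in_cq_chip(self, delta):
        base = percent_input(16.0, 20.0, 0.1)
        assert percent_input(16.0 + delta, 20.0, 0.1) < base
        assert percent_input(17.0, 20.0, 0.1) == pytest.approx(
            percent_input(16.0, 20.0, 0.1) / 2
        )


def bedgraph(values, chrom="chr1", step=10):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(len(values)) * step,
            "end": (np.arange(len(values)) + 1) * step,
            "value": values,
        }
    )


class TestRegionFC:
    def test_identical_tracks_fc_one(self):
        t = bedgraph([1.0, 2.0, 3.0, 4.0])
        res = region_fold_change([t], [t], ("chr1", 0, 40), [1e6], [1e6])
        assert res["fold_change"] == pytest.approx(1.0)

    def test_scaled_track_recovers_ratio(self):
        a = bedgraph([2.0, 3.0, 1.0, 5.0])
        b = a.copy()
        b["value"] = b["value"] * 1.6
        res = region_fold_change([b], [a], ("chr1", 0, 40), [1e6], [1e6])
        assert res["fold_change"] == pytest.approx(1.6)

    def test_depth_doubling_invariance(self):
        a = bedgraph([2.0, 3.0, 1.0, 5.0])
        a2 = a.copy()
        a2["value"] = a2["value"] * 2
        d1 = region_fold_change([a], [a], ("chr1", 0, 40), [1e6], [1e6])
        d2 = region_fold_change([a2], [a], ("chr1", 0, 40), [2e6], [1e6])
        assert d2["mean_density_a"] == pytest.approx(d1["mean_density_a"])

    def test_partial_overlap_weighted(self):
        a = bedgraph([10.0, 0.0])
        res = region_fold_change([a], [a], ("chr1", 5, 15), [1e6], [1e6])
        # half the region covered at 10 -> density 5 / 10bp
        assert res["mean_density_a"] == pytest.approx(10.0 * 5 / 10 / 1e6 * 1e6)

    def test_zero_denominator_flagged_infinite(self):
        a = bedgraph([1.0, 1.0])
        z = bedgraph([0.0, 0.0])
        with pytest.warns(UserWarning, match="zero denominator"):
            res = region_fold_change([a], [z], ("chr1", 0, 20), [1e6], [1e6])
        assert res["infinite"] and np.isinf(res["fold_change"])
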