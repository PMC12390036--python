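"""Agreement metrics, Wilcoxon signed-rank, Bland-Altman, aggregation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cardioresp import (RRSeriesPair, aggregate_inter, aggregate_intra,
                        bland_altman, mae, mape, overall_metrics, pearson,
                        rmse, wilcoxon_signed_rank)
from cardioresp.evaluation import classify_rho


def _pair(ref, der):
    return RRSeriesPair(np.asarray(ref, float), np.asarray(der, float))


class TestErrorMetrics:
    @pytest.mark.parametrize("ref,der,expected", [
        ([20, 20], [20, 20], 0.0), ([10, 20], [12, 18], 2.0), ([15], [18], 3.0)])
    def test_mae(self, ref, der, expected):
        assert mae(_pair(ref, der)) == pytest.approx(expected)

    @pytest.mark.parametrize("ref,der,expected", [
        ([10, 20], [12, 18], 15.0), ([10, 20], [10, 20], 0.0)])
    def test_mape(self, ref, der, expected):
        assert mape(_pair(ref, der)) == pytest.approx(expected)

    def test_mape_excludes_zero_reference(self):
        assert mape(_pair([0, 10], [1, 11])) == pytest.approx(10.0)

    def test_mape_all_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            mape(_pair([0, 0], [1, 2]))

    @pytest.mark.parametrize("ref,der,expected", [
        ([10, 20], [12, 18], 2.0), ([15], [18], 3.0),
        ([0, 0], [3, 4], np.sqrt(12.5))])
    def test_rmse(self, ref, der, expected):
        assert rmse(_pair(ref, der)) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            _pair([1, 2], [1, 2, 3])

    @given(st.lists(st.tuples(st.floats(0, 60), st.floats(0, 60)),
                    min_size=1, max_size=30))
    def test_mae_never_exceeds_rmse(self, pairs):
        ref, der = zip(*pairs)
        p = _pair(ref, der)
        assert mae(p) <= rmse(p) + 1e-12

    @given(st.lists(st.tuples(st.floats(0, 60), st.floats(0, 60)),
                    min_size=2, max_size=30), st.randoms())
    def test_permutation_invariance(self, pairs, rnd):
        ref, der = map(np.array, zip(*pairs))
        perm = np.array(rnd.sample(range(len(ref)), len(ref)))
        a, b = _pair(ref, der), _pair(ref[perm], der[perm])
        assert mae(a) == pytest.approx(mae(b))
        assert rmse(a) == pytest.approx(rmse(b))
        assert bland_altman(a).bias == pytest.approx(bland_altman(b).bias)


class TestPearson:
    def test_identity_is_strong(self):
        rho, p, band = pearson(_pair([10, 12, 14, 16], [10, 12, 14, 16]))
        assert rho == pytest.approx(1.0)
        assert band == "strong"

    def test_negated_series(self):
        rho, _, _ = pearson(_pair([1, 2, 3], [29, 28, 27]))
        assert rho == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        ref, der = np.array([1.0, 2, 3]), np.array([1.0, 2, 4])
        rho, _, _ = pearson(_pair(ref, der))
        num = np.sum((ref - ref.mean()) * (der - der.mean()))
        den = np.sqrt(np.sum((ref - ref.mean()) ** 2) * np.sum((der - der.mean()) ** 2))
        assert rho == pytest.approx(num / den, abs=1e-12)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson(_pair([5, 5, 5], [1, 2, 3]))

    @pytest.mark.parametrize("rho,band", [
        (0.1, "weak"), (0.3, "moderate"), (0.5, "moderate"),
        (0.7, "moderate"), (0.9, "strong"), (-0.9, "strong")])
    def test_interpretation_bands(self, rho, band):
        assert classify_rho(rho) == band


def _enumerate_wilcoxon_p(d):
    """Full 2^m enumeration of the signed-rank null (mid-ranks for ties)."""
    from scipy.stats import rankdata

    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    dist = [sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([False, True], repeat=d.size)]
    dist = np.array(dist)
    p_le = np.mean(dist <= w_obs + 1e-12)
    p_ge = np.mean(dist >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxon:
    def test_balanced_pair(self):
        _, p = wilcoxon_signed_rank(_pair([10, 12], [11, 11]))  # d = [+1, -1]
        assert p == 1.0

    def test_all_positive_small_sample(self):
        w, p = wilcoxon_signed_rank(_pair([10, 10, 10], [11, 12, 13]))
        assert w == 6.0
        assert p == pytest.approx(0.25)  # 2/8 sign assignments as extreme

    def test_all_zero_differences(self):
        _, p = wilcoxon_signed_rank(_pair([10, 11], [10, 11]))
        assert p == 1.0

    def test_exact_path_matches_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            m = int(rng.integers(2, 11))
            d = np.round(rng.normal(scale=2, size=m), 1)
            ref = np.full(m, 20.0)
            _, p = wilcoxon_signed_rank(_pair(ref, ref + d))
            assert p == pytest.approx(_enumerate_wilcoxon_p(d), abs=1e-12)

    def test_approximate_path_near_scipy(self):
        # tie-free large sample: compare with the scipy normal approximation
        from scipy.stats import wilcoxon as scipy_wilcoxon
        rng = np.random.default_rng(18)
        d = rng.normal(0.5, 1.0, size=40)
        ref = np.full(40, 20.0)
        _, p = wilcoxon_signed_rank(_pair(ref, ref + d))
        p_ref = scipy_wilcoxon(d, correction=True, method="approx").pvalue
        assert p == pytest.approx(p_ref, rel=0.05)


class TestBlandAltman:
    def test_constant_difference(self):
        ba = bland_altman(_pair([20, 21, 22], [19, 20, 21]))
        assert ba.bias == pytest.approx(-1.0)
        assert ba.sd == 0.0
        assert ba.loa_lower == ba.loa_upper == pytest.approx(-1.0)

    def test_hand_example(self):
        ba = bland_altman(_pair([10, 10], [10, 12]))  # d = [0, 2]
        assert ba.bias == pytest.approx(1.0)
        assert ba.sd == pytest.approx(np.sqrt(2))
        assert ba.loa_lower == pytest.approx(1 - 1.96 * np.sqrt(2))
        assert ba.loa_upper == pytest.approx(1 + 1.96 * np.sqrt(2))

    def test_bias_equals_mean_difference(self):
        rng = np.random.default_rng(19)
        ref = rng.uniform(10, 30, 50)
        der = rng.uniform(10, 30, 50)
        ba = bland_altman(_pair(ref, der))
        assert ba.bias == pytest.approx(der.mean() - ref.mean(), abs=1e-12)

    def test_gaussian_coverage(self):
        rng = np.random.default_rng(20)
        d = rng.standard_normal(10_000)
        ba = bland_altman(_pair(np.full(10_000, 20.0), 20.0 + d))
        frac = np.mean((d >= ba.loa_lower) & (d <= ba.loa_upper))
        assert frac == pytest.approx(0.95, abs=0.01)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError, match="2"):
            bland_altman(_pair([20], [21]))


def _toy_table(n_subj=3, n_win=15, seed=21):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subj):
        for w in range(n_win):
            ref = 14 + 2 * s + 0.2 * w + rng.normal(0, 0.5)
            rows.append({"subject": f"s{s}", "window": w, "reference": ref,
                         "r_amp": ref + rng.normal(-0.5, 1.0),
                         "ppg_am": ref + rng.normal(1.0, 2.0)})
    return pd.DataFrame(rows)


class TestAggregation:
    def test_intra_subject_means_and_sds(self):
        table = pd.DataFrame({"subject": ["a", "a"], "window": [0, 1],
                              "reference": [20.0, 22.0], "m": [19.0, 23.0]})
        out = aggregate_intra(table)
        assert out.loc["a", "ref_mean"] == pytest.approx(21.0)
        assert out.loc["a", "ref_sd"] == pytest.approx(np.sqrt(2))
        assert out.loc["a", "m_mean"] == pytest.approx(21.0)
        assert out.loc["a", "m_sd"] == pytest.approx(2 * np.sqrt(2))

    def test_identical_series_wilcoxon_p_one(self):
        table = pd.DataFrame({"subject": ["a"] * 3, "window": range(3),
                              "reference": [20.0, 21, 22], "m": [20.0, 21, 22]})
        assert aggregate_intra(table).loc["a", "m_wilcoxon_p"] == 1.0

    def test_shapes(self):
        table = _toy_table()
        intra, inter = aggregate_intra(table), aggregate_inter(table)
        assert intra.shape[0] == 3 and inter.shape[0] == 15
        for df in (intra, inter):
            for col in ("ref_mean", "r_amp_mean", "r_amp_sd", "r_amp_wilcoxon_p",
                        "ppg_am_mean"):
                assert col in df.columns and df[col].notna().all()

    def test_single_window_subject_skips_wilcoxon(self):
        table = pd.DataFrame({"subject": ["a"], "window": [0],
                              "reference": [20.0], "m": [21.0]})
        assert np.isnan(aggregate_intra(table).loc["a", "m_wilcoxon_p"])


class TestOverallMetrics:
    def test_perfect_agreement(self):
        table = _toy_table()
        table["m"] = table["reference"]
        rep = overall_metrics(table[["subject", "window", "reference", "m"]])["m"]
        assert rep.mae == rep.mape_pct == rep.rmse == 0.0
        assert rep.rho == pytest.approx(1.0)

    def test_constant_offset(self):
        table = _toy_table()
        table["m"] = table["reference"] + 1.0
        rep = overall_metrics(table[["subject", "window", "reference", "m"]])["m"]
        assert rep.mae == pytest.approx(1.0)
        pooled = bland_altman(_pair(table["reference"], table["m"]))
        assert pooled.bias == pytest.approx(1.0)

    def test_matches_two_stage_oracle(self):
        # independent brute-force of the two-stage average
        table = _toy_table(seed=22)
        rep = overall_metrics(table)["r_amp"]
        stages = []
        for key in ("subject", "window"):
            groups = sorted(table[key].unique())
            ref = np.array([table[table[key] == g]["reference"].mean() for g in groups])
            der = np.array([table[table[key] == g]["r_amp"].mean() for g in groups])
            d = der - ref
            stage_mae = np.mean(np.abs(d))
            stage_mape = 100 * np.mean(np.abs(d) / ref)
            stage_rmse = np.sqrt(np.mean(d ** 2))
            num = np.sum((ref - ref.mean()) * (der - der.mean()))
            den = np.sqrt(np.sum((ref - ref.mean()) ** 2)
                          * np.sum((der - der.mean()) ** 2))
            stages.append((stage_mae, stage_mape, stage_rmse, num / den))
        expect = [(a + b) / 2 for a, b in zip(*stages)]
        assert rep.mae == pytest.approx(expect[0], abs=1e-12)
        assert rep.mape_pct == pytest.approx(expect[1], abs=1e-12)
        assert rep.rmse == pytest.approx(expect[2], abs=1e-12)
        assert rep.rho == pytest.approx(expect[3], abs=1e-12)

    def test_missing_cells_rejected(self):
        table = _toy_table()
        table.loc[0, "r_amp"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            overall_metrics(table)
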