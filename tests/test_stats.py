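import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from hdxdiff import (anova_condition_effect, bh_adjust, call_regulated,
                     differential_analysis, effect_size_threshold,
                     successive_exceedance)
from hdxdiff.stats import (ThresholdSpec, _balanced_condition_p,
                           _balanced_condition_p_batch, _typ3_condition_p)

from .conftest import make_rdu_records


class TestEffectSizeThreshold:
    def test_printed_operating_point(self):
        """Mean replicate SD of 0.3925% with the x4 multiplier gives the
        1.57% threshold."""
        rec = make_rdu_records([0.003925] * 10)
        spec = effect_size_threshold(rec)
        assert spec.dispersion == pytest.approx(0.003925)
        assert spec.effect_threshold_percent == pytest.approx(1.57)

    def test_zero_noise_gives_zero_threshold(self):
        spec = effect_size_threshold(make_rdu_records([0.0] * 5))
        assert spec.effect_threshold == 0.0

    def test_scaling_with_dispersion(self):
        spec = effect_size_threshold(make_rdu_records([0.01] * 5))
        assert spec.effect_threshold_percent == pytest.approx(4.0)

    def test_pairwise_mad_estimator_known_ratio(self):
        # for {c-d, c, c+d}: pairwise |diffs| = {d, d, 2d} -> mean 4d/3
        rec = make_rdu_records([0.003] * 8)
        spec = effect_size_threshold(rec, estimator="pairwise_mad")
        assert spec.dispersion == pytest.approx(0.004)
        assert spec.dispersion_sd == pytest.approx(0.003)

    def test_t0_groups_excluded(self):
        rec = pd.concat([make_rdu_records([0.004] * 4, exposure=0.5),
                         make_rdu_records([0.1] * 4, exposure=0.0)])
        spec = effect_size_threshold(rec)
        assert spec.dispersion == pytest.approx(0.004)

    def test_no_replicated_group_is_an_error(self):
        rec = make_rdu_records([0.004]).iloc[:1]
        with pytest.raises(ValueError, match="replicates"):
            effect_size_threshold(rec)


def _two_condition_frame(rng, n_exposures=5, n_rep=3, shift=0.0, sigma=0.001):
    rows = []
    exposures = [0.5, 1.0, 5.0, 10.0, 30.0][:n_exposures]
    base = np.linspace(0.2, 0.6, n_exposures)
    for s, off in (("alone", 0.0), ("complex", shift)):
        for j, t in enumerate(exposures):
            for r in range(n_rep):
                rows.append({"state": s, "exposure": t,
                             "rdu": base[j] + off + rng.normal(0, sigma)})
    return pd.DataFrame(rows)


class TestAnova:
    def test_large_shift_is_overwhelmingly_significant(self):
        rng = np.random.default_rng(1)
        p = anova_condition_effect(_two_condition_frame(rng, shift=0.10))
        assert p < 1e-6

    def test_balanced_design_matches_textbook_sums_of_squares(self):
        """2x2x3 toy table: the condition p equals an independent
        cell-mean sums-of-squares computation to 1e-10."""
        rng = np.random.default_rng(7)
        df = _two_condition_frame(rng, n_exposures=2, shift=0.02, sigma=0.01)
        p = anova_condition_effect(df)

        # independent oracle: classical balanced two-way partition
        y = df.pivot_table(index="state", columns="exposure", values="rdu",
                           aggfunc=list)
        arr = np.array([[y.loc[s, t] for t in y.columns] for s in y.index])
        a, b, n = arr.shape
        grand = arr.mean()
        ss_cond = b * n * ((arr.mean(axis=(1, 2)) - grand) ** 2).sum()
        cell = arr.mean(axis=2)
        ss_err = ((arr - cell[:, :, None]) ** 2).sum()
        f = (ss_cond / (a - 1)) / (ss_err / (a * b * (n - 1)))
        p_oracle = sps.f.sf(f, a - 1, a * b * (n - 1))
        assert p == pytest.approx(p_oracle, abs=1e-10)

    def test_balanced_path_agrees_with_type3_sum_contrast_ols(self):
        rng = np.random.default_rng(3)
        df = _two_condition_frame(rng, shift=0.01, sigma=0.02)
        assert anova_condition_effect(df) == pytest.approx(
            _typ3_condition_p(df), abs=1e-8)

    def test_batch_path_agrees_with_scalar_path(self):
        rng = np.random.default_rng(4)
        arr = rng.normal(0.3, 0.05, size=(20, 2, 5, 3))
        batch = _balanced_condition_p_batch(arr)
        for i in range(20):
            assert batch[i] == pytest.approx(_balanced_condition_p(arr[i]), rel=1e-10)

    def test_null_p_values_are_uniform(self):
        """Both conditions drawn from the same kinetics: raw p ~ U(0,1)."""
        rng = np.random.default_rng(12)
        arr = rng.normal(0.3, 0.004, size=(1000, 2, 5, 3))
        p = _balanced_condition_p_batch(arr)
        frac = np.mean(p <= 0.05)
        assert 0.03 <= frac <= 0.07
        assert sps.kstest(p, "uniform").pvalue > 0.01

    def test_untestable_designs_return_none(self):
        rng = np.random.default_rng(0)
        one_exposure = _two_condition_frame(rng, n_exposures=1)
        assert anova_condition_effect(one_exposure) is None
        single_rep = _two_condition_frame(rng, n_rep=1)
        assert anova_condition_effect(single_rep) is None

    def test_noise_free_data_degenerates_cleanly(self):
        rng = np.random.default_rng(0)
        effect = _two_condition_frame(rng, shift=0.1, sigma=0.0)
        assert anova_condition_effect(effect) == 0.0
        null = _two_condition_frame(rng, shift=0.0, sigma=0.0)
        assert anova_condition_effect(null) == 1.0


def _bh_oracle(p):
    """Hand step-up: p_(i) * m / i with cumulative minimum from the top."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_all_equal_unchanged(self):
        assert bh_adjust([0.04] * 7) == pytest.approx([0.04] * 7)

    def test_out_of_range_is_an_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_nan_passthrough_does_not_count_as_a_test(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        assert out[[0, 2]] == pytest.approx(bh_adjust([0.01, 0.04]))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_step_up_oracle_and_is_monotone(self, p):
        adj = bh_adjust(p)
        assert adj == pytest.approx(_bh_oracle(p), rel=1e-12)
        # corrected values never shrink and preserve the input ordering
        assert np.all((adj >= np.asarray(p) - 1e-15) & (adj <= 1.0))
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)


def _run_oracle(deltas, threshold, k, same_sign=True):
    """Sliding-window brute force."""
    for i in range(len(deltas) - k + 1):
        w = deltas[i:i + k]
        if all(abs(x) > threshold for x in w):
            if not same_sign or all(x > 0 for x in w) or all(x < 0 for x in w):
                return tuple(range(i, i + k))
    return None


class TestSuccessiveExceedance:
    def test_leading_run_found(self):
        d = [0.02, 0.02, 0.02, 0.005, 0.005]
        assert successive_exceedance(d, 0.0157) == (0, 1, 2)

    def test_interrupted_run_is_none(self):
        d = [0.02, 0.005, 0.02, 0.005, 0.02]
        assert successive_exceedance(d, 0.0157) is None

    def test_protection_run_by_absolute_value(self):
        assert successive_exceedance([-0.02, -0.02, -0.02], 0.0157) == (0, 1, 2)

    def test_mixed_sign_window_rejected_unless_configured(self):
        d = [0.02, -0.02, 0.02]
        assert successive_exceedance(d, 0.0157) is None
        assert successive_exceedance(d, 0.0157, require_same_sign=False) == (0, 1, 2)

    def test_too_few_exposures_is_none(self):
        assert successive_exceedance([0.02, 0.02], 0.0157) is None

    @given(st.lists(st.floats(-0.05, 0.05), min_size=0, max_size=8),
           st.floats(0, 0.03), st.integers(1, 4))
    def test_matches_sliding_window_oracle(self, deltas, threshold, k):
        assert successive_exceedance(deltas, threshold, k) == \
            _run_oracle(deltas, threshold, k)


class TestCallRegulated:
    SPEC = ThresholdSpec(alpha=0.01, effect_threshold=0.0157, k_successive=3)

    def test_significant_with_persistent_effect_is_up(self):
        call, run = call_regulated([0.02, 0.02, 0.02, 0.0, 0.0], 0.005, self.SPEC)
        assert call == "up" and run == (0, 1, 2)

    def test_significant_without_persistent_effect_is_not_regulated(self):
        call, _ = call_regulated([0.02, 0.005, 0.02, 0.005, 0.02], 0.005, self.SPEC)
        assert call == "not-regulated"

    def test_persistent_effect_without_significance_is_not_regulated(self):
        call, _ = call_regulated([0.02, 0.02, 0.02, 0.0, 0.0], 0.02, self.SPEC)
        assert call == "not-regulated"

    def test_alpha_cutoff_is_inclusive(self):
        call, _ = call_regulated([-0.02, -0.02, -0.02], 0.01, self.SPEC)
        assert call == "down"


class TestDifferentialAnalysis:
    def test_output_invariant_to_peptide_ordering(self, effect_dataset):
        from hdxdiff import compute_rdu_table
        rdu = compute_rdu_table(effect_dataset.ions)
        spec = effect_size_threshold(rdu)
        a = differential_analysis(rdu, "alone", "complex", spec)
        shuffled = rdu.sample(frac=1.0, random_state=42)
        b = differential_analysis(shuffled, "alone", "complex", spec)
        pd.testing.assert_frame_equal(a, b)

    def test_label_swap_antisymmetry(self, effect_dataset):
        from hdxdiff import compute_rdu_table
        rdu = compute_rdu_table(effect_dataset.ions)
        spec = effect_size_threshold(rdu)
        fwd = differential_analysis(rdu, "alone", "complex", spec)
        rev = differential_analysis(rdu, "complex", "alone", spec)
        delta_cols = [c for c in fwd.columns if c.startswith("delta_")]
        np.testing.assert_allclose(fwd[delta_cols].to_numpy(),
                                   -rev[delta_cols].to_numpy(), atol=1e-12)
        np.testing.assert_allclose(fwd["p_raw"], rev["p_raw"], rtol=1e-9)
        flipped = {"up": "down", "down": "up"}
        assert list(rev["regulated"]) == \
            [flipped.get(c, c) for c in fwd["regulated"]]

    def test_missing_condition_is_an_error(self, effect_dataset):
        from hdxdiff import compute_rdu_table
        rdu = compute_rdu_table(effect_dataset.ions)
        with pytest.raises(ValueError, match="absent"):
            differential_analysis(rdu, "alone", "nonexistent", ThresholdSpec())

    def test_one_condition_peptides_carried_untestable(self, effect_dataset):
        from hdxdiff import PEPTIDE_KEY, compute_rdu_table
        rdu = compute_rdu_table(effect_dataset.ions)
        first = rdu.groupby(PEPTIDE_KEY).ngroup() == 0
        only_ref = rdu[~(first & (rdu["state"] == "complex"))]
        spec = effect_size_threshold(only_ref)
        res = differential_analysis(only_ref, "alone", "complex", spec)
        assert (res["status"] == "one-condition").sum() == 1
        assert res.loc[res["status"] == "one-condition", "regulated"].iloc[0] == \
            "untestable"
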