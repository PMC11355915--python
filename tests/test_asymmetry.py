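"""Residuals, max-normalization, top-decile flags and the overlap partition."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from reva.asymmetry import (
    GROUPS,
    TopDecileFlagger,
    TraitMaxNormalizer,
    align_flags,
    asymmetry_table,
    group_asymmetry,
    normalize_trait,
    overlap,
    signed_residual,
    top_decile_flags,
)
from reva.synthetic import SyntheticConfig, measurements_long, simulate_cohort


class TestSignedResidual:
    def test_symmetry_gives_zero(self):
        assert signed_residual(5.0, 5.0) == 0.0

    def test_sign_convention_is_left_minus_right(self):
        assert signed_residual(7.0, 4.0) == 3.0
        assert signed_residual(4.0, 7.0) == -3.0

    def test_missing_side_propagates(self):
        assert np.isnan(signed_residual(np.nan, 1.0))

    def test_fluctuating_asymmetry_averages_to_zero(self):
        cohort = simulate_cohort(SyntheticConfig(n_subjects=3000, trait_effect_scale=0.0), seed=8)
        d = signed_residual(cohort["axial_length_left"], cohort["axial_length_right"])
        assert abs(np.mean(d)) < 0.02


class TestNormalizeTrait:
    def test_division_by_maximum(self):
        assert normalize_trait([1.0, 2.0, 4.0]).tolist() == [0.25, 0.5, 1.0]

    def test_singleton_maps_to_one(self):
        assert normalize_trait([3.0]).tolist() == [1.0]

    def test_all_zero_guard_warns(self):
        with pytest.warns(UserWarning):
            out = normalize_trait([0.0, 0.0])
        assert out.tolist() == [0.0, 0.0]

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            normalize_trait([-1.0, 2.0])


class TestGroupAsymmetry:
    @staticmethod
    def frame(records):
        return pd.DataFrame(records, columns=["subject_id", "trait", "group", "left", "right",
                                              "signed", "absolute", "normalized"])

    def test_mean_of_constant_group(self):
        df = self.frame([["s1", t, "ophthalmic", 0, 0, 0, 0, 0.5] for t in "abc"])
        assert group_asymmetry(df).loc["s1", "ophthalmic"] == 0.5

    def test_mean_of_extremes(self):
        df = self.frame([["s1", "a", "abpi", 0, 0, 0, 0, 0.0],
                         ["s1", "b", "abpi", 0, 0, 0, 0, 1.0]])
        assert group_asymmetry(df).loc["s1", "abpi"] == 0.5

    def test_result_in_unit_interval_and_missing_group_absent(self):
        cohort = simulate_cohort(SyntheticConfig(n_subjects=80, unilateral_loss_fraction=0.2), seed=3)
        asym = asymmetry_table(measurements_long(cohort))
        means = group_asymmetry(asym)
        assert ((means.dropna() >= 0) & (means.dropna() <= 1)).all().all()
        flagged = cohort.loc[cohort["unilateral_hearing_loss"], "subject_id"]
        assert means.loc[flagged, "audiometry"].isna().all()

    def test_empty_group_rejected(self):
        df = self.frame([["s1", "a", "abpi", 0, 0, 0, 0, 0.2]])
        with pytest.raises(ValueError):
            group_asymmetry(df, group="retina")


class TestTopDecileFlags:
    def test_exactly_two_of_twenty_distinct(self):
        flags = top_decile_flags(np.arange(20, dtype=float))
        assert flags.sum() == 2
        assert flags[-2:].tolist() == [1.0, 1.0]

    def test_all_equal_flags_everyone_with_warning(self):
        with pytest.warns(UserWarning):
            flags = top_decile_flags(np.full(15, 0.4))
        assert flags.sum() == 15

    def test_flags_monotone_in_value(self, rng):
        vals = rng.random(30)
        flags = top_decile_flags(vals)
        idx = int(np.argmax(flags))  # a flagged subject
        raised = vals.copy()
        raised[idx] += 10.0
        assert top_decile_flags(raised)[idx] == 1.0

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            top_decile_flags(np.arange(9, dtype=float))

    def test_missing_values_get_missing_flags(self):
        vals = np.r_[np.arange(12, dtype=float), np.nan]
        flags = top_decile_flags(vals)
        assert np.isnan(flags[-1])


class TestOverlap:
    @staticmethod
    def flags_frame(patterns):
        return pd.DataFrame(patterns, columns=list(GROUPS),
                            index=[f"s{i}" for i in range(len(patterns))])

    def test_two_flags_count_as_multi_asymmetry(self):
        summary = overlap(self.flags_frame([[1, 1, 0, 0]] + [[0, 0, 0, 0]] * 3))
        assert summary.count_by_n[2] == 1
        assert summary.n_multi == 1
        assert summary.multi_asymmetry["s0"]

    def test_all_zero_profile_in_zero_cell(self):
        summary = overlap(self.flags_frame([[0, 0, 0, 0]] * 5))
        assert summary.count_by_n[0] == 5 and summary.n_multi == 0

    def test_venn_partition_matches_brute_force(self, rng):
        patterns = list(product((0, 1), repeat=4))
        counts = rng.integers(0, 5, 16)
        rows = [p for p, c in zip(patterns, counts) for _ in range(c)]
        summary = overlap(self.flags_frame(rows))
        for p, c in zip(patterns, counts):
            assert summary.venn[p] == c
        assert sum(summary.venn.values()) == len(rows)
        assert sum(summary.count_by_n.values()) == len(rows)

    def test_incomplete_profiles_are_dropped(self):
        frame = self.flags_frame([[1, 1, 1, 1], [1, 0, 0, 0]])
        frame.iloc[1, 0] = np.nan
        assert len(overlap(frame).flags) == 1

    def test_non_binary_flags_rejected(self):
        with pytest.raises(ValueError):
            overlap(self.flags_frame([[0, 2, 0, 0]]))

    def test_mismatched_subject_sets_listed(self):
        vectors = {
            "retina": pd.Series([1, 0], index=["s0", "s1"]),
            "ophthalmic": pd.Series([0, 1], index=["s0", "s2"]),
            "abpi": pd.Series([0, 0], index=["s0", "s1"]),
            "audiometry": pd.Series([0, 0], index=["s0", "s1"]),
        }
        with pytest.raises(ValueError, match="s2"):
            align_flags(vectors)


class TestEstimators:
    def test_normalizer_matches_function_and_maxabs_scaler(self, rng):
        from sklearn.preprocessing import MaxAbsScaler

        X = np.abs(rng.normal(size=(40, 3)))
        est = TraitMaxNormalizer().fit(X)
        out = est.transform(X)
        for j in range(3):
            assert np.allclose(out[:, j], normalize_trait(X[:, j]))
        assert np.allclose(out, MaxAbsScaler().fit_transform(X))
        assert out.max(axis=0).tolist() == [1.0, 1.0, 1.0]

    def test_flagger_matches_function(self, rng):
        X = rng.random((50, 2))
        est = TopDecileFlagger(fraction=0.10).fit(X)
        out = est.transform(X)
        for j in range(2):
            assert np.array_equal(out[:, j], top_decile_flags(X[:, j]))

    def test_flagger_parameter_validation(self, rng):
        with pytest.raises(ValueError):
            TopDecileFlagger(fraction=1.5).fit(rng.random((50, 2)))
        with pytest.raises(ValueError):
            TopDecileFlagger().fit(rng.random((5, 2)))

    def test_estimators_clone(self):
        from sklearn.base import clone

        est = TopDecileFlagger(fraction=0.2)
        assert clone(est).get_params() == {"fraction": 0.2}
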