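import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import oracle_select
from mlpcm.data_model import FeatureMatrix
from mlpcm.mrmr import (
    MRMRSetting,
    default_grid,
    discretize,
    enumerate_settings,
    mutual_information,
    select_features,
)


def _fm(values, target):
    values = np.asarray(values, dtype=float)
    names = tuple(f"f{i}" for i in range(values.shape[1]))
    return FeatureMatrix(names, values, np.asarray(target, dtype=float))


class TestDiscretize:
    def test_median_split(self):
        np.testing.assert_array_equal(discretize([1, 2, 3, 4], 2), [0, 0, 1, 1])

    def test_five_equal_bins(self):
        labels = discretize([10, 1, 7, 3, 5, 9, 2, 8, 4, 6], 5)
        assert sorted(np.bincount(labels)) == [2, 2, 2, 2, 2]

    def test_constant_column_warns_all_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            labels = discretize(np.full(10, 3.3), 4)
        assert set(labels) == {0}

    def test_ties_share_a_label(self):
        labels = discretize([1.0, 1.0, 1.0, 2.0, 3.0, 4.0], 3)
        assert len(set(labels[:3])) == 1

    def test_labels_in_range(self):
        rng = np.random.default_rng(5)
        for n_bins in (2, 3, 7):
            labels = discretize(rng.normal(size=101), n_bins)
            assert labels.min() >= 0 and labels.max() <= n_bins - 1

    def test_invalid_bins(self):
        with pytest.raises(ValueError):
            discretize([1.0, 2.0], 1)


class TestMutualInformation:
    def test_identical_two_level_labels(self):
        a = np.array([0, 1] * 50)
        assert mutual_information(a, a) == pytest.approx(np.log(2.0), abs=1e-12)

    def test_independent_labels_near_zero(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 2, 10000)
        b = rng.integers(0, 2, 10000)
        assert mutual_information(a, b) < 0.01

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(11)
        a = rng.integers(0, 4, 500)
        b = 3 - a  # permutation of the label alphabet
        assert mutual_information(a, b) == pytest.approx(
            mutual_information(a, a), abs=1e-12
        )

    @given(st.integers(0, 2**31 - 1))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 4, 80)
        b = rng.integers(0, 3, 80)
        assert mutual_information(a, b) == pytest.approx(
            mutual_information(b, a), abs=1e-12
        )

    def test_bounded_by_entropies(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 3, 400)
        b = (a + rng.integers(0, 2, 400)) % 3
        pa = np.bincount(a) / a.size
        pb = np.bincount(b) / b.size
        ha = -np.sum(pa[pa > 0] * np.log(pa[pa > 0]))
        hb = -np.sum(pb[pb > 0] * np.log(pb[pb > 0]))
        mi = mutual_information(a, b)
        assert 0.0 <= mi <= min(ha, hb) + 1e-12

    def test_matches_sklearn(self):
        from sklearn.metrics import mutual_info_score

        rng = np.random.default_rng(13)
        a = rng.integers(0, 5, 300)
        b = (a // 2 + rng.integers(0, 2, 300)) % 4
        assert mutual_information(a, b) == pytest.approx(
            mutual_info_score(a, b), abs=1e-12
        )

    def test_pseudo_count_smoothing_shrinks_mi(self):
        a = np.array([0, 1] * 20)
        assert mutual_information(a, a, pseudo_samples=True) < mutual_information(a, a)

    def test_coarsening_labels_cannot_raise_mi(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            f = rng.integers(0, 6, 300)
            y = (f + rng.integers(0, 3, 300)) % 6
            merged = y // 2
            assert mutual_information(f, merged) <= mutual_information(f, y) + 1e-12

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mutual_information([0, 1], [0])


class TestSelectFeatures:
    def test_target_clone_ranked_first(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=300)
        cols = [rng.normal(size=300) for _ in range(3)] + [y.copy()] + [
            rng.normal(size=300) for _ in range(2)
        ]
        fm = _fm(np.column_stack(cols), y)
        sel = select_features(fm, 3, MRMRSetting(5, "difference", "forward", False))
        assert sel.ordered_features[0] == "f3"

    def test_forward_full_k_returns_all(self):
        rng = np.random.default_rng(1)
        fm = _fm(rng.normal(size=(100, 5)), rng.normal(size=100))
        sel = select_features(fm, 5, MRMRSetting(3, "difference", "forward", False))
        assert sorted(sel.ordered_features) == [f"f{i}" for i in range(5)]

    def test_backward_full_k_is_identity(self):
        rng = np.random.default_rng(2)
        fm = _fm(rng.normal(size=(100, 5)), rng.normal(size=100))
        sel = select_features(fm, 5, MRMRSetting(3, "difference", "backward", False))
        assert sel.ordered_features == [f"f{i}" for i in range(5)]

    def test_duplicate_column_selected_after_original(self):
        rng = np.random.default_rng(4)
        f1 = rng.normal(size=400)
        f2 = rng.normal(size=400)
        y = f1 + 0.7 * f2 + 0.1 * rng.normal(size=400)
        fm = _fm(np.column_stack([f1, f1.copy(), f2]), y)  # f1 duplicated as f1-col "f1"
        sel = select_features(fm, 3, MRMRSetting(5, "difference", "forward", False))
        # the duplicate's redundancy with the original (~H(f1)) pushes it last
        assert sel.ordered_features[-1] == "f1"
        assert set(sel.ordered_features[:2]) == {"f0", "f2"}

    def test_k_out_of_range(self):
        fm = _fm(np.random.default_rng(0).normal(size=(20, 3)), np.zeros(20))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pytest.raises(ValueError):
                select_features(fm, 0, MRMRSetting())
            with pytest.raises(ValueError):
                select_features(fm, 4, MRMRSetting())

    @pytest.mark.parametrize("direction", ["forward", "backward"])
    @pytest.mark.parametrize("scheme", ["difference", "quotient"])
    def test_matches_bruteforce_oracle(self, direction, scheme):
        rng = np.random.default_rng(hash((direction, scheme)) % 2**31)
        for rep in range(5):
            n = int(rng.integers(50, 301))
            d = int(rng.integers(3, 9))
            X = rng.normal(size=(n, d))
            y = X[:, 0] + rng.normal(size=n)
            fm = _fm(X, y)
            k = int(rng.integers(1, d + 1))
            setting = MRMRSetting(int(rng.choice([3, 5])), scheme, direction, bool(rng.integers(0, 2)))
            sel = select_features(fm, k, setting)
            assert sel.ordered_features == oracle_select(fm, k, setting)


class TestEnumerateSettings:
    def test_product_count(self):
        grid = {"bins": (3, 5), "schemes": ("difference", "quotient"),
                "directions": ("forward",), "pseudo": (False,)}
        assert len(enumerate_settings(grid)) == 4

    def test_default_grid_has_25_settings(self):
        settings = default_grid()
        assert len(settings) == 25
        assert len(set(settings)) == 25

    def test_duplicates_deduplicated(self):
        grid = {"bins": (3, 3, 5), "schemes": ("difference",),
                "directions": ("forward",), "pseudo": (False,)}
        assert len(enumerate_settings(grid)) == 2

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError, match="schemes"):
            enumerate_settings({"bins": (3,), "schemes": (),
                                "directions": ("forward",), "pseudo": (False,)})

    def test_selection_serialization_round_trip(self):
        from mlpcm.mrmr import FeatureSelection

        sel = FeatureSelection(MRMRSetting(5, "quotient", "backward", True), 2,
                               ["a", "b"], [1.5, 0.25])
        back = FeatureSelection.from_json(sel.to_json())
        assert back.setting == sel.setting
        assert back.ordered_features == sel.ordered_features
        assert back.scores == sel.scores
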