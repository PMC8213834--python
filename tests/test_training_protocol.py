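import numpy as np
import pytest

from conftest import permute_targets
from mlpcm.data_model import build_feature_matrix
from mlpcm.mrmr import MRMRSetting, select_features
from mlpcm.neural_net import NetworkConfig, forward
from mlpcm.synthetic import GeneratorParams, generate
from mlpcm.training_protocol import (
    grid_search,
    make_split,
    post_validate,
    residual_tests,
)

DESK_CONFIG = NetworkConfig(n_hidden=10, max_epochs=150)


def _selection(dataset, k=8):
    fm = build_feature_matrix(dataset)
    return select_features(fm, k, MRMRSetting(5, "difference", "forward", False))


class TestMakeSplit:
    def test_exact_fraction_sizes(self, dataset400):
        sub = dataset400.subset(range(100))
        sp = make_split(sub, seed=0)
        assert (len(sp.train), len(sp.val), len(sp.test)) == (60, 15, 25)

    def test_floor_rule_on_awkward_size(self, dataset400):
        sub = dataset400.subset(range(97))
        sp = make_split(sub, seed=0)
        assert len(sp.val) == 14  # floor(0.15 * 97)
        assert len(sp.test) == 24  # floor(0.25 * 97)
        assert len(sp.train) == 59

    def test_partition_and_determinism(self, dataset400):
        a = make_split(dataset400, seed=5)
        b = make_split(dataset400, seed=5)
        np.testing.assert_array_equal(a.train, b.train)
        np.testing.assert_array_equal(a.test, b.test)
        union = np.concatenate([a.train, a.val, a.test])
        assert sorted(union) == list(range(len(dataset400)))

    def test_constraint_satisfied_over_many_seeds(self, dataset400):
        solvents = dataset400.solvent_ids()
        elems = dataset400.element_sets()
        for seed in range(200):
            sp = make_split(dataset400, constrained=True, seed=seed)
            assert sp.constraint_satisfied
            train_solv = set(solvents[sp.train])
            train_elem = set().union(*(elems[i] for i in sp.train))
            holdout = np.concatenate([sp.val, sp.test])
            unseen_solvent = any(solvents[i] not in train_solv for i in holdout)
            unseen_element = any(bool(elems[i] - train_elem) for i in holdout)
            assert unseen_solvent or unseen_element

    def test_unsatisfiable_constraint_warns(self):
        # one solvent, every solute pure hydrocarbon: nothing can be unseen
        ds = generate(
            GeneratorParams(
                n_records=40, n_solvents=1, n_solutes=60, extra_element_rate=0.0
            ),
            0,
        )
        with pytest.warns(UserWarning, match="unseen"):
            sp = make_split(ds, constrained=True, seed=0)
        assert not sp.constraint_satisfied

    def test_too_small_dataset(self, dataset400):
        with pytest.raises(ValueError):
            make_split(dataset400.subset(range(5)), seed=0)


class TestGridSearch:
    def test_run_ledger_length_is_product(self, dataset400, tmp_path):
        sel = _selection(dataset400)
        ledger = tmp_path / "runs.jsonl"
        cands = grid_search(
            dataset400, [sel], [DESK_CONFIG], n_splits=2, n_inits=3,
            master_seed=0, ledger_path=ledger,
        )
        assert len(cands) == 1
        assert len(cands[0].runs) == 6
        assert len(ledger.read_text().strip().splitlines()) == 6

    def test_true_signal_passes_gate(self, dataset400):
        cands = grid_search(
            dataset400, [_selection(dataset400)], [DESK_CONFIG],
            n_splits=2, n_inits=2, master_seed=1,
        )
        assert cands[0].passed_gate
        assert cands[0].gate_mape < 22.0
        assert cands[0].recorded is not None

    def test_permuted_targets_fail_gate(self, dataset400):
        null = permute_targets(dataset400, 123)
        cands = grid_search(
            null, [_selection(null)], [DESK_CONFIG],
            n_splits=2, n_inits=2, master_seed=1,
        )
        assert cands[0].gate_mape > 22.0
        assert cands[0].recorded is None

    def test_empty_grids_rejected(self, dataset400):
        with pytest.raises(ValueError):
            grid_search(dataset400, [], [DESK_CONFIG])


class TestResidualTests:
    def test_identical_samples_t_zero_p_one(self):
        s = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        stats = residual_tests(s, s.copy())
        assert stats.t_stat == pytest.approx(0.0)
        assert stats.t_pvalue == pytest.approx(1.0)
        assert stats.f_stat == pytest.approx(1.0)
        assert stats.passed

    def test_shifted_samples_fail(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 200)
        b = rng.normal(2, 1, 200)
        assert not residual_tests(np.abs(a), np.abs(b) + 2).passed

    def test_variance_rule_optional(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1.0, 300)
        b = rng.normal(0, 2.5, 300)  # same mean, very different spread
        lenient = residual_tests(a, b, require_variance_test=False)
        strict = residual_tests(a, b, require_variance_test=True)
        assert lenient.passed and not strict.passed
        assert strict.f_pvalue < 0.05


class TestPostValidate:
    def test_requires_recorded_weights(self, dataset400):
        cands = grid_search(
            dataset400, [_selection(dataset400)], [DESK_CONFIG],
            n_splits=2, n_inits=2, master_seed=1, gate=0.0,  # nothing passes
        )
        with pytest.raises(ValueError, match="recorded"):
            post_validate(cands[0], dataset400, n_iterations=3, seed=0)

    def test_well_fit_candidate_ensemble_equals_recorded_predictions(self, dataset400):
        """A transferring warm start is evaluated as recorded in every
        iteration, so the ensemble mean equals its predictions exactly."""
        sel = _selection(dataset400)
        cands = grid_search(
            dataset400, [sel], [DESK_CONFIG], n_splits=2, n_inits=2, master_seed=1
        )
        rep = post_validate(cands[0], dataset400, n_iterations=10, seed=7)
        fm = build_feature_matrix(dataset400).select(sel.ordered_features)
        np.testing.assert_allclose(
            rep.ensemble_predictions, forward(cands[0].recorded, fm.values),
            rtol=0, atol=1e-12,
        )

    def test_true_candidate_verdict_true(self, dataset400):
        cands = grid_search(
            dataset400, [_selection(dataset400)], [DESK_CONFIG],
            n_splits=2, n_inits=2, master_seed=1,
        )
        rep = post_validate(cands[0], dataset400, n_iterations=50, seed=3)
        assert rep.pass_count >= 40
        assert rep.verdict
        assert rep.ensemble_summary.mue < 0.6

    def test_permuted_candidate_verdict_false(self, dataset400):
        null = permute_targets(dataset400, 77)
        cands = grid_search(
            null, [_selection(null)], [DESK_CONFIG],
            n_splits=2, n_inits=2, master_seed=1, gate=float("inf"),
        )
        rep = post_validate(cands[0], null, n_iterations=50, seed=3)
        assert rep.pass_count < 40
        assert not rep.verdict

    def test_deterministic_under_master_seed(self, dataset400):
        sel = _selection(dataset400)
        reps = []
        for _ in range(2):
            cands = grid_search(
                dataset400, [sel], [DESK_CONFIG], n_splits=2, n_inits=2, master_seed=9
            )
            reps.append(post_validate(cands[0], dataset400, n_iterations=10, seed=11))
        np.testing.assert_array_equal(
            reps[0].ensemble_predictions, reps[1].ensemble_predictions
        )
        assert reps[0].pass_count == reps[1].pass_count
        assert reps[0].to_json() == reps[1].to_json()

    def test_report_json_fields(self, dataset400):
        cands = grid_search(
            dataset400, [_selection(dataset400)], [DESK_CONFIG],
            n_splits=2, n_inits=2, master_seed=1,
        )
        rep = post_validate(cands[0], dataset400, n_iterations=5, seed=0)
        import json

        payload = json.loads(rep.to_json())
        assert payload["n_iterations"] == 5
        assert len(payload["iterations"]) == 5
        assert {"t_stat", "t_pvalue", "f_stat", "f_pvalue", "passed"} <= set(
            payload["iterations"][0]
        )
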