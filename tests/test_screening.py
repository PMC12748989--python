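"""Batch screening, stopping rules, filtering and accounting identities."""

import numpy as np
import pandas as pd
import pytest

from pepscreen.oracle import synthetic_oracle
from pepscreen.screening import (
    FilterConfig,
    PolicyBundle,
    ScreenResult,
    StopConfig,
    apply_filters,
    first_k_vs_top_k,
    screen_batch,
    screen_library,
)
from pepscreen.sequences import PeptideLibrary


def result_from_rows(rows, stream=None, library_size=None):
    df = pd.DataFrame(rows)
    if "collection_index" not in df.columns and len(df):
        df["collection_index"] = range(len(df))
    return ScreenResult(
        collected=df,
        stream=stream if stream is not None else df.get("mda_pred", pd.Series()).tolist(),
        oracle_calls=len(stream) if stream is not None else len(df),
        library_size=library_size or max(len(df), 1),
        batch_sizes=[library_size or max(len(df), 1)],
        trajectories=1,
        stopped_by_rule=False,
    )


class TestStoppingRuleArithmetic:
    def test_running_mean_rule_fires_at_fourth_item(self):
        """Stream [80, 60, 10, 2] with a minimum of 2 scored: running means
        80, 70, 50, 38 -> stop exactly after the 4th item."""
        stream = [80.0, 60.0, 10.0, 2.0]
        stop_at = None
        for i in range(1, len(stream) + 1):
            if i >= 2 and np.mean(stream[:i]) < 40.0:
                stop_at = i
                break
        assert stop_at == 4

    def test_rule_silent_before_minimum(self):
        stream = [10.0, 5.0]  # mean < 40 but below the minimum count of 3
        fired = any(
            i >= 3 and np.mean(stream[:i]) < 40.0 for i in range(1, len(stream) + 1)
        )
        assert not fired


class TestScreenBatch:
    def test_empty_batch_empty_result(self, trained_tiny):
        report, bundle, oracle = trained_tiny
        res = screen_batch(PeptideLibrary([], name="empty"), bundle, oracle)
        assert len(res.collected) == 0 and res.oracle_calls == 0

    def test_frozen_state_and_unique_scoring(self, trained_tiny, small_library):
        report, bundle, oracle = trained_tiny
        lib, truth, land = small_library
        base = synthetic_oracle(land)
        before = bundle.hotspots.state_hash()
        res = screen_batch(
            lib, bundle, base, StopConfig(max_trajectories=20, max_steps=100),
            rng=np.random.default_rng(4),
        )
        assert bundle.hotspots.state_hash() == before
        assert base.calls_made == res.oracle_calls  # unique peptides only
        assert len(res.collected) <= len(res.stream)
        # everything collected clears the floor
        if len(res.collected):
            assert (res.collected["mda_pred"] >= 40.0).all()

    def test_projector_hash_mismatch_refused(self, trained_tiny, small_library):
        report, bundle, oracle = trained_tiny
        lib, truth, land = small_library
        tampered = PolicyBundle(
            policy=bundle.policy, params=bundle.params, env_config=bundle.env_config,
            projector=bundle.projector, hotspots=bundle.hotspots,
            projector_hash="deadbeefdeadbeef",
        )
        with pytest.raises(RuntimeError, match="hash mismatch"):
            screen_batch(lib, tampered, synthetic_oracle(land))

    def test_oracle_budget_caps_new_trajectories(self, trained_tiny, small_library):
        report, bundle, oracle = trained_tiny
        lib, truth, land = small_library
        base = synthetic_oracle(land)
        res = screen_batch(
            lib, bundle, base,
            StopConfig(max_oracle_calls=30, max_steps=100, max_trajectories=200),
            rng=np.random.default_rng(4),
        )
        # budget can only overshoot by the in-flight trajectory's pickups
        assert res.oracle_calls <= 30 + len(lib)
        assert res.trajectories < 200


class TestScreenLibrary:
    def test_single_batch_equals_screen_batch(self, trained_tiny, small_library):
        report, bundle, oracle = trained_tiny
        lib, truth, land = small_library
        stop = StopConfig(max_trajectories=10, max_steps=80)
        res_lib = screen_library(lib, bundle, synthetic_oracle(land), n_batches=1,
                                 seed=3, stop_config=stop)
        rng = np.random.default_rng(3 + 10_000 + 0)
        order = np.random.default_rng(3).permutation(len(lib))
        batch = lib.subset([int(i) for i in order], name="b")
        res_one = screen_batch(batch, bundle, synthetic_oracle(land), stop, rng=rng)
        assert res_lib.oracle_calls == res_one.oracle_calls
        assert sorted(res_lib.collected["seq"]) == sorted(
            res_one.collected["seq"].drop_duplicates()
        )

    def test_batches_disjoint_and_calls_sum(self, trained_tiny, small_library):
        report, bundle, oracle = trained_tiny
        lib, truth, land = small_library
        base = synthetic_oracle(land)
        stop = StopConfig(max_trajectories=5, max_steps=60)
        res = screen_library(lib, bundle, base, n_batches=4, seed=1, stop_config=stop)
        assert sum(res.batch_sizes) == len(lib)
        assert res.oracle_calls == base.calls_made
        assert res.reduction == pytest.approx(
            100.0 * (1 - res.oracle_calls / len(lib))
        )

    def test_rejects_zero_batches(self, trained_tiny, small_library):
        report, bundle, oracle = trained_tiny
        lib, truth, land = small_library
        with pytest.raises(ValueError):
            screen_library(lib, bundle, synthetic_oracle(land), n_batches=0)


class TestApplyFilters:
    def _rows(self):
        return [
            {"id": "a", "seq": "KLLKA", "mda_pred": 45.0, "pbmc_pred": 10.0, "batch": 0},
            {"id": "b", "seq": "KLLKC", "mda_pred": 45.0, "pbmc_pred": 20.0, "batch": 0},
            {"id": "c", "seq": "KLLKD", "mda_pred": 30.0, "pbmc_pred": 5.0, "batch": 0},
        ]

    def test_default_thresholds_one_survivor(self):
        out = apply_filters(result_from_rows(self._rows()))
        assert out["id"].tolist() == ["a"]

    def test_vacuous_filter_keeps_all(self):
        out = apply_filters(
            result_from_rows(self._rows()),
            filter_config=FilterConfig(mda_min=0.0, pbmc_max=100.0),
        )
        assert len(out) == 3

    def test_boundary_semantics(self):
        rows = [
            {"id": "x", "seq": "KLLKE", "mda_pred": 40.0, "pbmc_pred": 14.999, "batch": 0},
            {"id": "y", "seq": "KLLKF", "mda_pred": 39.999, "pbmc_pred": 0.0, "batch": 0},
            {"id": "z", "seq": "KLLKG", "mda_pred": 100.0, "pbmc_pred": 15.0, "batch": 0},
        ]
        out = apply_filters(result_from_rows(rows))
        # mda >= 40 inclusive, pbmc < 15 strict
        assert out["id"].tolist() == ["x"]

    def test_tightening_mda_never_increases_survivors(self):
        res = result_from_rows(self._rows())
        counts = [
            len(apply_filters(res, filter_config=FilterConfig(mda_min=m, pbmc_max=100.0)))
            for m in (0.0, 20.0, 40.0, 60.0, 100.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_ranked_deterministically(self):
        rows = [
            {"id": "b", "seq": "KLLKA", "mda_pred": 90.0, "pbmc_pred": 5.0, "batch": 0},
            {"id": "a", "seq": "KLLKC", "mda_pred": 90.0, "pbmc_pred": 5.0, "batch": 0},
            {"id": "c", "seq": "KLLKD", "mda_pred": 95.0, "pbmc_pred": 9.0, "batch": 0},
        ]
        out = apply_filters(result_from_rows(rows))
        assert out["id"].tolist() == ["c", "a", "b"]

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(mda_min=120.0)

    def test_classifier_requires_oracle(self):
        with pytest.raises(ValueError, match="classifier"):
            apply_filters(
                result_from_rows(self._rows()),
                filter_config=FilterConfig(use_consensus_classifier=True),
            )


class TestFirstKTopK:
    def test_k_equals_set_size_means_equal(self):
        rows = [
            {"id": f"p{i}", "seq": "KLLKA", "mda_pred": float(v), "pbmc_pred": 0.0,
             "batch": 0}
            for i, v in enumerate([70, 50, 90])
        ]
        fk, tk = first_k_vs_top_k(result_from_rows(rows), 3)
        assert fk == pytest.approx(tk)

    def test_descending_collection_always_equal(self):
        rows = [
            {"id": f"p{i}", "seq": "KLLKA", "mda_pred": float(v), "pbmc_pred": 0.0,
             "batch": 0}
            for i, v in enumerate([90, 80, 70, 60])
        ]
        res = result_from_rows(rows)
        for k in (1, 2, 3, 4):
            fk, tk = first_k_vs_top_k(res, k)
            assert fk == pytest.approx(tk)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            first_k_vs_top_k(result_from_rows([]), 1)
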