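"""Oracle interface, call accounting, fusion training and cross-validation."""

import numpy as np
import pytest

from pepscreen.oracle import (
    CachedOracle,
    FusionModelConfig,
    baseline_mlp,
    crossvalidate,
    synthetic_oracle,
    train_fusion,
)
from pepscreen.sequences import Peptide, PeptideLibrary

FAST = FusionModelConfig(epochs=60, patience=60)


class TestSyntheticOracle:
    def test_call_accounting(self, landscape):
        orc = synthetic_oracle(landscape)
        orc.predict_batch(["KLLKL", "AAAAA", "KKKKK"])
        assert orc.calls_made == 3
        orc.predict(["KLLKL"])
        assert orc.calls_made == 4

    def test_two_oracles_from_same_landscape_agree(self, landscape):
        a, b = synthetic_oracle(landscape), synthetic_oracle(landscape)
        seqs = ["INLKALAALAKKIL", "GGGGG", "KLWKLLKKLLKL"]
        assert a.predict_batch(seqs) == pytest.approx(b.predict_batch(seqs))

    def test_predictions_within_percent_bounds(self, landscape):
        p = synthetic_oracle(landscape).predict(["KKKKKKKKKK", "DDDDD"])
        for pr in p:
            assert 0.0 <= pr.mda_inhibition <= 100.0
            assert 0.0 <= pr.pbmc_inhibition <= 100.0

    def test_cached_oracle_counts_unique(self, landscape):
        base = synthetic_oracle(landscape)
        cache = CachedOracle(base)
        cache.predict_batch(["KLLKL", "KLLKL", "AAAAA"])
        cache.predict_batch(["KLLKL"])
        assert base.calls_made == 2  # unique sequences only
        assert cache.calls_made == 4  # every scoring request
        assert cache.unique_scored == 2


class TestTrainFusion:
    def test_small_dataset_rejected(self):
        lib = PeptideLibrary([Peptide(id="a", seq="KLLKL", labels={"mda": 50.0})])
        with pytest.raises(ValueError, match="too small"):
            train_fusion(lib)

    def test_missing_labels_rejected(self, scaffold_dataset):
        ds, _ = scaffold_dataset
        stripped = PeptideLibrary(
            [Peptide(id=p.id, seq=p.seq) for p in ds], name="unlabeled"
        )
        with pytest.raises(ValueError, match="no regression label"):
            train_fusion(stripped)

    def test_deterministic_predictions(self, scaffold_dataset):
        ds, _ = scaffold_dataset
        orc = train_fusion(ds, FAST)
        a = orc.predict_batch(ds.sequences()[:5])
        b = orc.predict_batch(ds.sequences()[:5])
        assert a == pytest.approx(b)
        assert orc.calls_made == 10

    def test_outputs_clipped(self, scaffold_dataset):
        ds, _ = scaffold_dataset
        orc = train_fusion(ds, FAST)
        preds = orc.predict_batch(["W", "KKKKKKKKKKKKKKK", "DDDDDDDDDDDDDDD"])
        assert np.all(preds >= 0.0) and np.all(preds <= 100.0)

    def test_fit_recovers_signal_on_train(self, scaffold_dataset):
        ds, _ = scaffold_dataset
        orc = train_fusion(ds, FAST)
        y = np.array([p.labels["mda"] for p in ds])
        r = np.corrcoef(y, orc.predict_batch(ds.sequences())[:, 0])[0, 1]
        assert r > 0.8

    def test_classification_head_second_phase(self, scaffold_dataset):
        ds, _ = scaffold_dataset
        med = np.median([p.labels["mda"] for p in ds])
        labeled = PeptideLibrary(
            [
                Peptide(
                    id=p.id, seq=p.seq,
                    labels={**p.labels, "active": float(p.labels["mda"] > med)},
                )
                for p in ds
            ]
        )
        orc = train_fusion(labeled, FAST)
        probs = orc.acp_probability(ds.sequences()[:10])
        assert probs is not None and np.all((probs >= 0) & (probs <= 1))

    def test_checkpoint_roundtrip(self, scaffold_dataset, tmp_path):
        ds, _ = scaffold_dataset
        orc = train_fusion(ds, FAST)
        orc.model.to_json(tmp_path / "m.json")
        from pepscreen.oracle import FusionRegressor

        back = FusionRegressor.from_json(tmp_path / "m.json")
        seqs = ds.sequences()[:5]
        assert back.predict_percent(*back.featurize(seqs)) == pytest.approx(
            orc.predict_batch(seqs)
        )


def _linear_dataset(n=120, noise=0.0, seed=0, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    """Labels are an exactly linear function of net charge."""
    rng = np.random.default_rng(seed)
    from pepscreen import descriptors as desc

    peps = []
    aas = list(alphabet)
    for i in range(n):
        seq = "".join(rng.choice(aas, size=10 if len(aas) > 2 else 12))
        # slope/intercept keep labels inside [0, 100]: clipping would bend
        # the otherwise exactly linear signal
        a, b = (50.0, 8.0) if len(aas) > 2 else (20.0, 6.0)
        y = a + b * desc.net_charge(seq, 7.0, True)
        y += rng.normal(0, noise)
        peps.append(Peptide(id=f"p{i}", seq=seq, labels={"mda": float(np.clip(y, 0, 100))}))
    return PeptideLibrary(peps, name="linear", dedup=True)


class TestCrossvalidate:
    def test_noiseless_linear_signal_recovered(self):
        # charge of a K/A string is a clean linear signal; noiseless labels
        # must be recovered nearly perfectly out of fold
        ds = _linear_dataset(n=250, alphabet="KA")
        cfg = FusionModelConfig(epochs=200, patience=200)
        rep = crossvalidate(ds, cfg, n_folds=5, n_seeds=1)
        assert rep.mean["mda"] > 0.98

    def test_independent_noise_labels_give_null_pearson(self):
        rng = np.random.default_rng(3)
        ds = _linear_dataset()
        shuffled = PeptideLibrary(
            [
                Peptide(id=p.id, seq=p.seq, labels={"mda": float(rng.uniform(0, 100))})
                for p in ds
            ]
        )
        rep = crossvalidate(shuffled, FAST, n_folds=5, n_seeds=1)
        assert abs(rep.mean["mda"]) < 3.0 / np.sqrt(len(ds))

    def test_reproducible_given_seed(self, scaffold_dataset):
        ds, _ = scaffold_dataset
        a = crossvalidate(ds, FAST, n_folds=3, n_seeds=1)
        b = crossvalidate(ds, FAST, n_folds=3, n_seeds=1)
        assert a.per_fold == b.per_fold

    def test_nfolds_exceeding_dataset_rejected(self):
        with pytest.raises(ValueError):
            crossvalidate(_linear_dataset(n=30), FAST, n_folds=40)

    def test_constant_labels_flagged_degenerate(self):
        ds = _linear_dataset(n=40)
        const = PeptideLibrary(
            [Peptide(id=p.id, seq=p.seq, labels={"mda": 50.0}) for p in ds]
        )
        rep = crossvalidate(const, FAST, n_folds=4, n_seeds=1)
        assert rep.degenerate  # zero-variance folds flagged, not crashed


class TestBaselineMLP:
    def test_composition_features_recover_composition_signal(self):
        # charge is a linear function of composition, so AAC+DPC suffices
        ds = _linear_dataset(n=150, alphabet="KA")
        rep = baseline_mlp(ds, "composition", FAST, n_seeds=1)
        assert rep.mean["mda"] > 0.9

    def test_global_panel_beats_mean_predictor(self, scaffold_dataset):
        ds, _ = scaffold_dataset
        rep = baseline_mlp(ds, "global_panel", FAST, n_seeds=1)
        assert rep.mean["mda"] > 0.0

    def test_unknown_family_rejected(self, scaffold_dataset):
        ds, _ = scaffold_dataset
        with pytest.raises(ValueError):
            baseline_mlp(ds, "3d_inductive", FAST, n_seeds=1)


def test_order_sensitive_signal_favors_fusion_over_composition():
    """When activity depends on residue order (hydrophobic moment), the
    CNN branch gives the fusion model an edge over composition alone."""
    rng = np.random.default_rng(7)
    from pepscreen import descriptors as desc

    peps = []
    for i in range(150):
        seq = "".join(rng.permutation(list("LLLLLKKKKA")))
        y = 100.0 * desc.hydrophobic_moment(seq)
        peps.append(Peptide(id=f"p{i}", seq=seq, labels={"mda": float(np.clip(y, 0, 100))}))
    ds = PeptideLibrary(peps, name="order-signal")
    fus = crossvalidate(ds, FAST, n_folds=4, n_seeds=1)
    comp = baseline_mlp(ds, "composition", FAST, n_folds=4, n_seeds=1)
    # composition is identical for every permutation: no recoverable signal
    assert fus.mean["mda"] > comp.mean["mda"]
    assert fus.mean["mda"] > 0.5
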