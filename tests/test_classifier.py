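from dataclasses import replace

import numpy as np
import pytest

from ldmf.classifier import (
    EvalMetrics,
    TrainConfig,
    TrainingSet,
    active_learning_run,
    decision_score,
    draw_random_negatives,
    load_model_bundle,
    loocv,
    save_model_bundle,
    train,
)
from ldmf.io_formats import LdmfError, ProteinRecord, SecondaryStructureTrack
from ldmf.simulator import SimulationConfig, simulate
from ldmf.windows import attach_ss, extract_window

FAST = TrainConfig(seed=0, n_random_negatives=300)


FLANK_LETTERS = np.array(list("GSTNPQDEKR"))  # coil-like, no motif letters


def _toy_window(core, states_core, protein_id, label, rng):
    flank5 = "".join(rng.choice(FLANK_LETTERS, 20))
    flank3 = "".join(rng.choice(FLANK_LETTERS, 20))
    seq = flank5 + core + flank3
    w = extract_window(ProteinRecord(id=protein_id, sequence=seq), 21)
    states = "C" * 20 + states_core + "C" * 20
    return replace(
        attach_ss(w, SecondaryStructureTrack(protein_id, states)), label=label
    )


@pytest.fixture(scope="module")
def toy_set():
    """A cleanly separable set: helical consensus cores vs coil random cores."""
    rng = np.random.default_rng(7)
    letters = np.array(list("ACDEFGHIKNPQRSTWY"))  # no L/M/V in negatives' draw
    pos_cores = ["ELDRLLLELN", "SLDELMASLS", "ALDSLLQELE", "TLDALLSDLE",
                 "ELDKLLQSLN", "NLDELMSALS"]
    positives = tuple(
        _toy_window(c, "H" * 10, f"pos{i}", "positive", rng)
        for i, c in enumerate(pos_cores)
    )
    negatives = tuple(
        _toy_window(
            "".join(rng.choice(letters, 10)), "C" * 10, f"neg{i}", "negative", rng
        )
        for i in range(60)
    )
    return TrainingSet(positives, negatives)


class TestTrain:
    def test_separable_toy_training_accuracy(self, toy_set):
        bundle = train(toy_set, FAST)
        for w in toy_set.positives:
            assert decision_score(bundle, w) > 0
        neg_scores = bundle.decision_function(
            bundle.featurize_windows(list(toy_set.negatives))
        )
        assert (neg_scores < 0).all()

    def test_same_seed_reproduces_bundle(self, toy_set):
        b1 = train(toy_set, FAST)
        b2 = train(toy_set, FAST)
        assert b1.training_hashes == b2.training_hashes
        assert np.array_equal(b1.support_vectors, b2.support_vectors)
        probe = toy_set.positives[0]
        assert decision_score(b1, probe) == decision_score(b2, probe)

    def test_single_class_rejected(self, toy_set):
        with pytest.raises(LdmfError):
            train(TrainingSet(toy_set.positives, ()), FAST)
        with pytest.raises(LdmfError):
            TrainingSet(toy_set.positives[:1], toy_set.negatives)

    def test_class_overlap_rejected(self, toy_set):
        clash = replace(toy_set.positives[0], label="negative")
        with pytest.raises(LdmfError, match="both classes"):
            TrainingSet(toy_set.positives, toy_set.negatives + (clash,))

    def test_doubling_negatives_keeps_positives_positive(self, toy_set):
        """Class weighting must keep the separable positives on the
        positive side as the imbalance grows."""
        rng = np.random.default_rng(11)
        letters = np.array(list("ACDEFGHIKNPQRSTWY"))
        extra = tuple(
            _toy_window(
                "".join(rng.choice(letters, 10)), "C" * 10, f"xneg{i}", "negative", rng
            )
            for i in range(len(toy_set.negatives))
        )
        # jackknife off: the weighting contract is about the fitted margin,
        # which the SVM only guarantees at the training feature locations
        cfg = replace(FAST, jackknife_positive_features=False)
        for ts in (toy_set, TrainingSet(toy_set.positives, toy_set.negatives + extra)):
            bundle = train(ts, cfg)
            for w in toy_set.positives:
                assert decision_score(bundle, w) > 0

    def test_score_invariant_to_window_order(self, toy_set):
        bundle = train(toy_set, FAST)
        windows = list(toy_set.positives) + list(toy_set.negatives[:10])
        fwd = bundle.decision_function(bundle.featurize_windows(windows))
        rev = bundle.decision_function(bundle.featurize_windows(windows[::-1]))
        assert fwd == pytest.approx(rev[::-1])


class TestBundlePersistence:
    def test_round_trip_preserves_scores(self, toy_set, tmp_path):
        bundle = train(toy_set, FAST)
        save_model_bundle(bundle, tmp_path / "bundle")
        loaded = load_model_bundle(tmp_path / "bundle")
        windows = list(toy_set.positives) + list(toy_set.negatives[:5])
        orig = bundle.decision_function(bundle.featurize_windows(windows))
        back = loaded.decision_function(loaded.featurize_windows(windows))
        assert back == pytest.approx(orig, rel=1e-9)

    def test_layout_mismatch_fails_loudly(self, toy_set, tmp_path):
        import json

        bundle = train(toy_set, FAST)
        save_model_bundle(bundle, tmp_path / "bundle")
        manifest = tmp_path / "bundle" / "manifest.json"
        data = json.loads(manifest.read_text())
        data["layout_version"] = "ldmf-v999"
        manifest.write_text(json.dumps(data))
        with pytest.raises(LdmfError, match="layout"):
            load_model_bundle(tmp_path / "bundle")

    def test_replayed_decision_matches_sklearn(self, toy_set):
        """The bundle's hand-rolled RBF expansion must reproduce the
        decision function of an identically fitted sklearn SVC."""
        from sklearn.svm import SVC

        cfg = replace(FAST, jackknife_positive_features=False)
        bundle = train(toy_set, cfg)
        windows = list(toy_set.positives) + list(toy_set.negatives)
        X = bundle.featurize_windows(windows)
        Z = (X - bundle.scaler_mean) / bundle.scaler_scale
        y = np.concatenate(
            [np.ones(len(toy_set.positives)), -np.ones(len(toy_set.negatives))]
        )
        svc = SVC(
            kernel="rbf", C=cfg.C, gamma=cfg.gamma,
            class_weight="balanced", random_state=cfg.seed,
        ).fit(Z, y)
        assert bundle.decision_function(X) == pytest.approx(
            svc.decision_function(Z), rel=1e-9
        )


class TestLoocv:
    def test_sensitivity_arithmetic(self):
        m = EvalMetrics(tp=16, fn=2, tn=1000, fp=0)
        assert m.sensitivity == pytest.approx(16 / 18)
        assert round(m.sensitivity, 4) == 0.8889

    def test_duplicated_positives_fully_recovered(self, toy_set):
        dup = tuple(
            replace(toy_set.positives[0], protein_id=f"dup{i}") for i in range(6)
        )
        ts = TrainingSet(dup, toy_set.negatives)
        m = loocv(ts, FAST)
        assert m.sensitivity == 1.0

    def test_separable_toy_metrics(self, toy_set):
        m = loocv(toy_set, FAST)
        assert m.tp + m.fn == len(toy_set.positives)
        assert m.tn + m.fp == len(toy_set.negatives)
        assert m.specificity >= 0.95
        # accuracy bound when negatives dominate
        n_neg = m.tn + m.fp
        total = n_neg + m.tp + m.fn
        assert m.accuracy >= m.specificity * n_neg / total

    def test_requires_three_positives(self, toy_set):
        ts = TrainingSet(toy_set.positives[:2], toy_set.negatives)
        with pytest.raises(LdmfError):
            loocv(ts, FAST)

    def test_loo_all_scheme_on_tiny_set(self, toy_set):
        ts = TrainingSet(toy_set.positives[:4], toy_set.negatives[:8])
        m = loocv(ts, replace(FAST, loocv_scheme="loo_all"))
        assert m.tp + m.fn == 4
        assert m.tn + m.fp == 8


@pytest.fixture(scope="module")
def world():
    return simulate(
        SimulationConfig(
            seed=301, n_proteins=60, length_range=(150, 250),
            n_implants=10, n_decoys=20,
        )
    )


class TestActiveLearning:
    def test_three_rounds_returned(self, world):
        bundles = active_learning_run(
            world.site_windows("implant"),
            world.proteins,
            world.site_windows("decoy"),
            (),
            replace(FAST, n_rounds=3),
            ss_tracks=world.tracks,
        )
        assert [b.round for b in bundles] == [1, 2, 3]

    def test_empty_decoy_pool_degenerates_with_warning(self, world, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            b1, b2 = active_learning_run(
                world.site_windows("implant"),
                world.proteins,
                (),
                (),
                replace(FAST, n_rounds=2),
                ss_tracks=world.tracks,
            )
        assert any("decoy pool" in m for m in caplog.messages)
        assert b1.training_hashes["negatives"] == b2.training_hashes["negatives"]

    def test_no_validated_hits_keeps_seed_positives(self, world):
        bundles = active_learning_run(
            world.site_windows("implant"),
            world.proteins,
            world.site_windows("decoy"),
            (),
            replace(FAST, n_rounds=3),
            ss_tracks=world.tracks,
        )
        assert (
            bundles[1].training_hashes["positives"]
            == bundles[2].training_hashes["positives"]
        )

    def test_validated_hits_augment_round3(self, world):
        extra = [
            replace(w, label="positive") for w in world.site_windows("decoy")[:2]
        ]
        bundles = active_learning_run(
            world.site_windows("implant"),
            world.proteins,
            world.site_windows("decoy")[2:],
            extra,
            replace(FAST, n_rounds=3),
            ss_tracks=world.tracks,
        )
        assert (
            bundles[1].training_hashes["positives"]
            != bundles[2].training_hashes["positives"]
        )


class TestRandomNegatives:
    def test_excludes_known_sites(self, sim17):
        implants = sim17.site_windows("implant")
        rng = np.random.default_rng(0)
        negs = draw_random_negatives(
            sim17.proteins, 500, rng,
            exclude={w.key for w in implants}, ss_tracks=sim17.tracks,
        )
        assert len(negs) == 500
        assert not ({w.key for w in negs} & {w.key for w in implants})
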