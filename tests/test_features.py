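import math
from dataclasses import replace

import numpy as np
import pytest

from ldmf.features import (
    AA_ALPHABET,
    LAYOUT_VERSION,
    N_FEATURES,
    build_pwm,
    featurize,
    featurize_many,
    physicochemical_profile,
    score_pwm,
)
from ldmf.io_formats import LdmfError, ProteinRecord, SecondaryStructureTrack
from ldmf.windows import attach_ss, extract_window


def _window(core, protein_id="p", flank="G"):
    """A mid-protein window whose core is exactly *core*."""
    seq = flank * 20 + core + flank * 20
    p = ProteinRecord(id=protein_id, sequence=seq)
    return extract_window(p, 21)  # core occupies [20, 30)


def _ss_window(core, states_core="H" * 10, protein_id="p"):
    w = _window(core, protein_id=protein_id)
    states = "C" * 20 + states_core + "C" * 20
    return attach_ss(w, SecondaryStructureTrack(protein_id, states))


UNIFORM_BG = {aa: 1 / 20 for aa in AA_ALPHABET[:-1]}


class TestBuildPwm:
    def test_single_window_zero_pseudocount_is_indicator(self):
        pwm = build_pwm([_window("ELDRLLLELN")], pseudocount=0.0)
        idx = pwm.index
        for j, letter in enumerate("ELDRLLLELN"):
            assert pwm.probs[idx[letter], j] == pytest.approx(1.0)

    def test_laplace_formula(self):
        # two cores differing at position 0: L vs V, pseudocount 1, |A|=21
        pwm = build_pwm(
            [_window("LLDRLLLELN"), _window("VLDRLLLELN")], pseudocount=1.0
        )
        assert pwm.probs[pwm.index["L"], 0] == pytest.approx(2 / 23)
        assert pwm.probs[pwm.index["V"], 0] == pytest.approx(2 / 23)
        assert pwm.probs[pwm.index["A"], 0] == pytest.approx(1 / 23)

    def test_columns_stochastic_for_random_windows(self, rng):
        letters = np.array(list(AA_ALPHABET[:-1]))
        windows = [
            _window("".join(rng.choice(letters, 10))) for _ in range(25)
        ]
        for pc in (0.0, 0.5, 1.0):
            pwm = build_pwm(windows, pseudocount=pc)
            assert np.allclose(pwm.probs.sum(axis=0), 1.0, atol=1e-9)
            if pc > 0:
                assert (pwm.probs > 0).all()

    def test_zero_windows_rejected(self):
        with pytest.raises(LdmfError):
            build_pwm([])


class TestScorePwm:
    def test_own_core_under_uniform_background(self):
        pwm = build_pwm([_window("ELDRLLLELN")], pseudocount=0.0, background=UNIFORM_BG)
        assert score_pwm(pwm, "ELDRLLLELN") == pytest.approx(10 * math.log(20))

    def test_background_samples_score_nonpositive_in_expectation(self, rng):
        """E_bg[log odds] = -sum_j KL(bg || col_j) <= 0."""
        train = [_window(c) for c in ("ELDRLLLELN", "SLDELMASLS", "ALDSLLQELE")]
        pwm = build_pwm(train, pseudocount=1.0, background=UNIFORM_BG)
        letters = np.array(list(AA_ALPHABET[:-1]))
        scores = [
            score_pwm(pwm, "".join(rng.choice(letters, 10))) for _ in range(4000)
        ]
        mean = float(np.mean(scores))
        sem = float(np.std(scores) / math.sqrt(len(scores)))
        assert mean < 4 * sem  # <= 0 up to Monte-Carlo error
        assert mean < 0  # KL of a motif PWM vs background is far from 0

    def test_training_core_is_maximal_for_zero_pseudocount(self, rng):
        pwm = build_pwm([_window("ELDRLLLELN")], pseudocount=0.0, background=UNIFORM_BG)
        best = score_pwm(pwm, "ELDRLLLELN")
        letters = np.array(list(AA_ALPHABET[:-1]))
        for _ in range(500):
            other = "".join(rng.choice(letters, 10))
            assert score_pwm(pwm, other) <= best

    def test_width_mismatch_rejected(self):
        pwm = build_pwm([_window("ELDRLLLELN")])
        with pytest.raises(LdmfError):
            score_pwm(pwm, "ELD")

    def test_finite_scores_with_pads_and_x(self):
        pwm = build_pwm([_window("ELDRLLLELN")], pseudocount=0.0)
        assert math.isfinite(score_pwm(pwm, "-LDRLLLEXN"))


class TestPhysicochemicalProfile:
    def test_homopolymer_blocks(self, tables):
        prof = physicochemical_profile("L" * 10, tables)
        assert prof[:10] == pytest.approx([tables["hydrophobicity"].values["L"]] * 10)
        assert prof[10:20] == pytest.approx([tables["volume"].values["L"]] * 10)

    def test_pad_maps_to_scale_mean(self, tables):
        prof = physicochemical_profile("-LLLLLLLLL", tables)
        assert prof[0] == pytest.approx(tables["hydrophobicity"].mean)

    def test_charge_sign_convention(self, tables):
        acidic = physicochemical_profile("D" * 10, tables)[20:]
        basic = physicochemical_profile("K" * 10, tables)[20:]
        assert (acidic < basic).all()

    def test_missing_table_rejected(self, tables):
        with pytest.raises(LdmfError, match="missing property"):
            physicochemical_profile("L" * 10, {"volume": tables["volume"]})


class TestFeaturize:
    @pytest.fixture()
    def pwms(self):
        from ldmf.classifier import build_model_pwms

        train = [
            _ss_window(c, protein_id=f"t{i}")
            for i, c in enumerate(("ELDRLLLELN", "SLDELMASLS", "ALDSLLQELE"))
        ]
        return build_model_pwms(train), train

    def test_layout(self, pwms, tables):
        model_pwms, train = pwms
        fv = featurize(train[0], model_pwms, tables)
        assert fv.values.shape == (N_FEATURES,)
        assert fv.layout_version == LAYOUT_VERSION
        assert np.all(np.isfinite(fv.values))

    def test_deterministic(self, pwms, tables):
        model_pwms, train = pwms
        a = featurize(train[1], model_pwms, tables).values
        b = featurize(train[1], model_pwms, tables).values
        assert np.array_equal(a, b)

    def test_requires_ss(self, pwms, tables):
        model_pwms, _ = pwms
        with pytest.raises(LdmfError, match="attach_ss"):
            featurize(_window("ELDRLLLELN"), model_pwms, tables)

    def test_vectorized_path_matches_scalar_path(self, pwms, tables, rng):
        model_pwms, train = pwms
        letters = np.array(list(AA_ALPHABET[:-1]))
        windows = train + [
            _ss_window("".join(rng.choice(letters, 10)), protein_id=f"r{i}")
            for i in range(20)
        ]
        X = featurize_many(windows, model_pwms, tables)
        for i, w in enumerate(windows):
            assert X[i] == pytest.approx(featurize(w, model_pwms, tables).values)

    def test_motif_core_outscores_random_cores_on_core_pwm(self, pwms, tables, rng):
        """The sequence-core PWM feature separates consensus-like cores
        from random-composition cores on average."""
        model_pwms, _ = pwms
        letters = np.array(list(AA_ALPHABET[:-1]))
        motif_like = featurize(_ss_window("ELDRLMSELS"), model_pwms, tables).values[0]
        random_scores = [
            featurize(
                _ss_window("".join(rng.choice(letters, 10))), model_pwms, tables
            ).values[0]
            for _ in range(100)
        ]
        assert motif_like > np.mean(random_scores)
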