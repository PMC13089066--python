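import numpy as np
import pandas as pd
import pytest

from slocad.design import (HrfSpec, acompcor, assemble_design,
                           build_event_regressor, build_parametric_modulator,
                           canonical_hrf, motion_24, serial_orthogonalize)

FRAME_TIMES = (np.arange(150) + 0.5) * 2.0


def swe_events(n=20, sync=None, stage=None, coupled=None, spacing=14.0):
    df = pd.DataFrame({"onset": 5.0 + spacing * np.arange(n),
                       "duration": 0.6})
    df["sync_score"] = (sync if sync is not None
                        else 10 + 5 * np.sin(np.arange(n)))
    df["stage"] = (stage if stage is not None
                   else ["N2", "N3"] * (n // 2))
    if coupled is not None:
        df["coupled"] = coupled
    return df


class TestCanonicalHrf:
    def test_starts_at_zero_and_peaks_near_five_seconds(self):
        h = canonical_hrf(dt=0.01)
        assert h[0] == 0.0
        assert np.argmax(h) * 0.01 == pytest.approx(5.0, abs=0.05)

    def test_single_sign_change(self):
        h = canonical_hrf(dt=0.1)
        signs = np.sign(h[np.abs(h) > 1e-10])
        assert (np.diff(signs) != 0).sum() == 1

    def test_matches_reference_spm_shape(self):
        nilearn = pytest.importorskip("nilearn.glm.first_level")
        mine = canonical_hrf(dt=0.1)
        ref = nilearn.spm_hrf(1.0, oversampling=10)
        n = min(len(mine), len(ref))
        r = np.corrcoef(mine[:n], ref[:n])[0, 1]
        assert r > 0.999

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError, match="length"):
            HrfSpec(length=4.0)
        with pytest.raises(ValueError, match="oversampling"):
            HrfSpec(oversampling=0)


class TestEventRegressor:
    def test_empty_event_list_is_zero(self):
        col = build_event_regressor(pd.DataFrame(columns=["onset",
                                                          "duration"]),
                                    FRAME_TIMES)
        assert np.all(col == 0)

    def test_linearity_of_far_separated_events(self):
        e1 = pd.DataFrame({"onset": [20.0], "duration": [0.6]})
        e2 = pd.DataFrame({"onset": [200.0], "duration": [0.6]})
        both = pd.concat([e1, e2], ignore_index=True)
        np.testing.assert_allclose(
            build_event_regressor(both, FRAME_TIMES),
            build_event_regressor(e1, FRAME_TIMES)
            + build_event_regressor(e2, FRAME_TIMES), atol=1e-12)

    def test_zero_duration_event_is_scaled_hrf(self):
        ev = pd.DataFrame({"onset": [40.0], "duration": [0.0]})
        col = build_event_regressor(ev, FRAME_TIMES)
        assert col.max() > 0
        # response peaks ~5 s after the event
        assert FRAME_TIMES[np.argmax(col)] == pytest.approx(45.0, abs=2.0)

    def test_event_beyond_run_rejected(self):
        ev = pd.DataFrame({"onset": [299.9], "duration": [5.0]})
        with pytest.raises(ValueError, match="beyond"):
            build_event_regressor(ev, FRAME_TIMES)


class TestParametricModulator:
    def test_equal_values_center_to_zero(self):
        ev = pd.DataFrame({"onset": [20.0, 100.0], "duration": [0.6, 0.6]})
        col = build_parametric_modulator(ev, [7.0, 7.0], FRAME_TIMES)
        np.testing.assert_allclose(col, 0, atol=1e-12)

    def test_two_event_centering(self):
        ev = pd.DataFrame({"onset": [20.0, 200.0], "duration": [0.6, 0.6]})
        col = build_parametric_modulator(ev, [1.0, 3.0], FRAME_TIMES)
        r1 = build_event_regressor(ev.iloc[[0]], FRAME_TIMES)
        r2 = build_event_regressor(ev.iloc[[1]], FRAME_TIMES)
        np.testing.assert_allclose(col, -1.0 * r1 + 1.0 * r2, atol=1e-12)

    def test_homogeneity(self):
        ev = pd.DataFrame({"onset": [20.0, 150.0], "duration": [0.6, 0.6]})
        a = build_parametric_modulator(ev, [1.0, 4.0], FRAME_TIMES)
        b = build_parametric_modulator(ev, [3.0, 12.0], FRAME_TIMES)
        np.testing.assert_allclose(b, 3 * a, atol=1e-12)

    def test_length_mismatch_rejected(self):
        ev = pd.DataFrame({"onset": [20.0], "duration": [0.6]})
        with pytest.raises(ValueError, match="per event"):
            build_parametric_modulator(ev, [1.0, 2.0], FRAME_TIMES)


class TestSerialOrthogonalize:
    def test_later_columns_orthogonal_to_earlier(self):
        rng = np.random.default_rng(0)
        X = serial_orthogonalize(rng.normal(size=(50, 4)))
        for k in range(1, 4):
            for j in range(k):
                assert abs(X[:, j] @ X[:, k]) < 1e-8

    def test_earlier_columns_unchanged_and_orthogonal_input_preserved(self):
        q, _ = np.linalg.qr(np.random.default_rng(1).normal(size=(30, 3)))
        out = serial_orthogonalize(q)
        np.testing.assert_allclose(out, q, atol=1e-10)

    def test_duplicate_column_becomes_zero_with_warning(self):
        x = np.random.default_rng(2).normal(size=30)
        with pytest.warns(UserWarning, match="zero norm"):
            out = serial_orthogonalize(np.column_stack([x, x]))
        np.testing.assert_allclose(out[:, 1], 0)


class TestMotion24:
    def test_expansion_layout(self):
        rng = np.random.default_rng(0)
        base = np.cumsum(rng.normal(size=(40, 6)), axis=0)
        out = motion_24(base)
        assert out.shape == (40, 24)
        np.testing.assert_allclose(out.iloc[:, :6], base)
        np.testing.assert_allclose(out.iloc[0, 6:12], 0)
        np.testing.assert_allclose(out.iloc[1:, 6:12],
                                   np.diff(base, axis=0))
        np.testing.assert_allclose(out.iloc[:, 12:18], base ** 2)

    def test_constant_and_ramp(self):
        const = motion_24(np.ones((10, 6)))
        assert np.all(const.iloc[:, 6:12] == 0)
        ramp = motion_24(np.tile(np.arange(10.0)[:, None], (1, 6)))
        np.testing.assert_allclose(ramp.iloc[1:, 6], 1.0)

    def test_wrong_width_rejected(self):
        with pytest.raises(ValueError, match="6"):
            motion_24(np.zeros((10, 5)))


class TestAcompcor:
    def test_components_orthogonal_unit_variance(self):
        rng = np.random.default_rng(0)
        comps = acompcor(rng.normal(size=(60, 30)))
        X = comps.to_numpy()
        assert X.shape == (60, 5)
        np.testing.assert_allclose(X.std(axis=0), 1.0)
        gram = X.T @ X
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0,
                                   atol=1e-8)

    def test_dominant_shared_signal_is_first_component(self):
        rng = np.random.default_rng(1)
        t = np.arange(80)
        wave = np.sin(2 * np.pi * t / 25)
        csf = wave[:, None] * rng.uniform(1, 2, 20)[None, :]
        csf += rng.normal(0, 0.05, csf.shape)
        comps = acompcor(csf)
        r = np.corrcoef(comps.iloc[:, 0], wave)[0, 1]
        assert abs(r) > 0.95

    def test_rank_deficient_returns_fewer_with_warning(self):
        rng = np.random.default_rng(2)
        one = rng.normal(size=(40, 1))
        csf = np.tile(one, (1, 8))  # rank 1 after standardization
        with pytest.warns(UserWarning, match="rank"):
            comps = acompcor(csf)
        assert comps.shape[1] < 5


class TestAssembleDesign:
    @pytest.fixture
    def confounds(self):
        from slocad.simulate import generate_confounds
        return generate_confounds(len(FRAME_TIMES), seed=0)

    @pytest.fixture
    def spindles(self):
        return pd.DataFrame({"onset": [30.0, 140.0], "duration": [1.0, 0.8]})

    def test_main_variant_has_32_columns(self, confounds, spindles):
        motion, csf = confounds
        X = assemble_design("main", swe_events(), spindles, motion, csf,
                            FRAME_TIMES)
        assert X.shape[1] == 32  # 1 SWE + 1 spindle + 24 motion + 5 CSF + 1
        assert list(X.columns).count("constant") == 1
        assert X.attrs["condition_columns"] == ["swe"]

    def test_stage_variant_has_two_condition_columns(self, confounds):
        motion, csf = confounds
        X = assemble_design("stage", swe_events(), None, motion, csf,
                            FRAME_TIMES)
        assert X.attrs["condition_columns"] == ["swe_n2", "swe_n3"]
        assert "spindle" not in X.columns

    def test_coupling_syncs_orthogonalization(self, confounds, spindles):
        motion, csf = confounds
        events = swe_events(coupled=[True, False] * 10)
        X = assemble_design("coupling_syncs", events, spindles, motion, csf,
                            FRAME_TIMES)
        syncs = X["swe_by_syncs"].to_numpy()
        assert abs(syncs @ X["swe_by_coupling"].to_numpy()) < 1e-8
        assert abs(syncs @ X["swe"].to_numpy()) < 1e-8

    def test_interaction_reduces_to_stage_when_syncs_constant(self,
                                                              confounds):
        motion, csf = confounds
        events = swe_events(sync=np.full(20, 11.0))
        with pytest.warns(UserWarning, match="zero norm"):
            X = assemble_design("stage_syncs", events, None, motion, csf,
                                FRAME_TIMES)
        np.testing.assert_allclose(X["swe_n2_by_syncs"], 0, atol=1e-10)
        np.testing.assert_allclose(X["swe_n3_by_syncs"], 0, atol=1e-10)

    def test_stage_variant_requires_staged_events(self, confounds):
        motion, csf = confounds
        events = swe_events(stage=[None] * 20)
        with pytest.raises(ValueError, match="staged"):
            assemble_design("stage", events, None, motion, csf, FRAME_TIMES)

    def test_unknown_variant_rejected(self, confounds):
        motion, csf = confounds
        with pytest.raises(ValueError, match="variant"):
            assemble_design("bogus", swe_events(), None, motion, csf,
                            FRAME_TIMES)

    def test_drift_columns_optional(self, confounds):
        motion, csf = confounds
        X = assemble_design("main", swe_events(), None, motion, csf,
                            FRAME_TIMES, drift_order=2)
        assert {"poly_01", "poly_02"} <= set(X.columns)
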