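"""Generator contracts: determinism, trial layout, SNR, drift behaviour."""

import numpy as np
import pytest

from semgcal import GeneratorConfig, generate_database
from semgcal.synthetic import build_templates, load_database, save_database


def _clean_config(**kw):
    """Config with force variability and drift disabled (pure SNR contract)."""
    base = dict(n_sessions=1, n_gestures=2, n_trials=2, drift_scale=0.0,
                trial_gain_cv=0.0, channel_gain_cv=0.0, seed=11)
    base.update(kw)
    return GeneratorConfig(**base)


class TestTrialLayout:
    def test_lengths_and_interval(self):
        db = generate_database(_clean_config())
        rec = db.get(1, 1, 1)
        assert rec.signal.shape == (8, 6000)
        assert rec.active_interval == (0, 3000)

    def test_snr_calibration(self):
        db = generate_database(_clean_config(burst_snr_db=20.0))
        for rec in db:
            lo, hi = rec.active_interval
            act = np.sqrt(np.mean(rec.signal[:, lo:hi] ** 2))
            rest = np.sqrt(np.mean(rec.signal[:, hi:] ** 2))
            assert act / rest == pytest.approx(10.0, rel=0.2)

    def test_energy_ordering_under_drift(self):
        # active RMS > rest RMS whenever burst SNR > 0, drift or not
        db = generate_database(GeneratorConfig(n_sessions=2, n_trials=2,
                                               burst_snr_db=5.0, seed=3))
        for rec in db:
            lo, hi = rec.active_interval
            act = np.sqrt(np.mean(rec.signal[:, lo:hi] ** 2))
            rest = np.sqrt(np.mean(rec.signal[:, hi:] ** 2))
            assert act > rest


class TestDeterminism:
    def test_same_seed_identical(self):
        cfg = GeneratorConfig(n_sessions=2, n_gestures=2, n_trials=2, seed=5)
        db1 = generate_database(cfg)
        db2 = generate_database(cfg)
        assert db1.keys() == db2.keys()
        for key in db1.keys():
            np.testing.assert_array_equal(db1.trials[key].signal, db2.trials[key].signal)

    def test_zero_drift_sessions_exchangeable(self):
        cfg = GeneratorConfig(n_sessions=3, n_gestures=2, n_trials=2,
                              drift_scale=0.0, seed=5)
        db = generate_database(cfg)
        for g in db.gestures:
            for t in (1, 2):
                ref = db.get(1, g, t).signal
                for s in (2, 3):
                    np.testing.assert_array_equal(db.get(s, g, t).signal, ref)

    def test_trial_count(self):
        db = generate_database(GeneratorConfig(n_sessions=7, n_gestures=3,
                                               n_trials=20, active_s=0.5,
                                               rest_s=0.5, seed=1))
        assert len(db) == 7 * 3 * 20


class TestTemplates:
    def test_distinct_gain_vectors(self):
        cfg = GeneratorConfig(n_gestures=5, seed=2)
        templates = build_templates(cfg)
        for i in range(len(templates)):
            for j in range(i + 1, len(templates)):
                assert not np.allclose(templates[i].gains, templates[j].gains)

    def test_gains_positive(self):
        for tpl in build_templates(GeneratorConfig(seed=4)):
            assert np.all(tpl.gains > 0)


def _rms_centroids(db):
    """Per (session, gesture) centroid of per-channel trial RMS features."""
    cents = {}
    for s in db.sessions:
        for g in db.gestures:
            feats = [np.sqrt(np.mean(db.get(s, g, t).signal ** 2, axis=1))
                     for t in range(1, db.config.n_trials + 1)]
            cents[(s, g)] = np.mean(feats, axis=0)
    return cents


def _mean_cross_session_displacement(db):
    cents = _rms_centroids(db)
    dists = []
    for g in db.gestures:
        sessions = db.sessions
        for i, s1 in enumerate(sessions):
            for s2 in sessions[i + 1:]:
                dists.append(np.linalg.norm(cents[(s1, g)] - cents[(s2, g)]))
    return float(np.mean(dists))


class TestDrift:
    N_SEEDS = 20

    def _displacements(self, drift_scale):
        vals = []
        for seed in range(self.N_SEEDS):
            cfg = GeneratorConfig(n_sessions=3, n_gestures=2, n_trials=4,
                                  active_s=1.0, rest_s=1.0,
                                  drift_scale=drift_scale, seed=100 + seed)
            vals.append(_mean_cross_session_displacement(generate_database(cfg)))
        return float(np.mean(vals))

    def test_drift_increases_session_displacement(self):
        assert self._displacements(0.5) > self._displacements(0.0)

    def test_drift_monotonicity(self):
        means = [self._displacements(ds) for ds in (0.0, 0.25, 0.5, 1.0)]
        assert all(a <= b for a, b in zip(means, means[1:]))

    def test_shared_drift_within_session(self):
        db = generate_database(GeneratorConfig(n_sessions=2, n_trials=2, seed=6))
        assert set(db.drifts) == {1, 2}
        for d in db.drifts.values():
            np.testing.assert_allclose(d.mixing.sum(axis=1), 1.0)  # convex rows


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"fs": 500}, {"n_channels": 0}, {"active_s": 0},
        {"drift_scale": -1}, {"rest_noise_rms": 0},
    ])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            GeneratorConfig(**kw)

    def test_channel_mismatch_rejected(self):
        from semgcal.synthetic import _draw_session_drift, generate_trial

        cfg = GeneratorConfig(seed=1)
        tpl = build_templates(GeneratorConfig(n_channels=10, fs=1000, seed=1))[0]
        with pytest.raises(ValueError):
            generate_trial(tpl, cfg, _draw_session_drift(cfg, 1),
                           np.random.default_rng(0))


class TestRoundTrip:
    def test_save_load(self, small_db, tmp_path):
        save_database(small_db, tmp_path / "db")
        loaded = load_database(tmp_path / "db")
        assert loaded.config == small_db.config
        assert loaded.keys() == small_db.keys()
        for key in small_db.keys():
            np.testing.assert_allclose(loaded.trials[key].signal,
                                       small_db.trials[key].signal, rtol=1e-8)
            assert loaded.trials[key].active_interval == small_db.trials[key].active_interval
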