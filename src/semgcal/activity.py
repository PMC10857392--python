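"""Unsupervised EMG activity detection (EAD).

Each frame is summarised by the log short-time energy of three sub-bands
(80-150, 150-300, 300-450 Hz), pooled across channels; a 2-component
Gaussian mixture fitted by EM separates active from resting frames
(the sub-band-energy + GMM recipe long established for voice activity
detection); a 5-frame centred majority vote removes isolated
misclassifications.

The mixture component with the larger mean total log-energy is the active
one, so relabelling components never flips the output.  One GMM is fitted
per recording session (all trials pooled): each session has its own
electrode application and hence its own energy scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
from scipy import signal as sps
from sklearn.mixture import GaussianMixture

from .preprocessing import FrameSet, bandpass_filter, frame_signal

__all__ = [
    "EAD_BANDS",
    "LOG_FLOOR",
    "GmmModel",
    "compute_ead_features",
    "fit_gmm",
    "classify_frames",
    "smooth_labels",
    "extract_active_frames",
    "detect_database",
    "frame_activity_truth",
]

logger = logging.getLogger(__name__)

EAD_BANDS: Tuple[Tuple[float, float], ...] = ((80.0, 150.0), (150.0, 300.0), (300.0, 450.0))
LOG_FLOOR = 1e-12  # squared-amplitude units; keeps log finite on silent frames


def compute_ead_features(frames: FrameSet) -> np.ndarray:
    """Log sub-band energies per frame, pooled over channels -> (n_frames, 3).

    Per band: zero-phase band-pass each channel, take the per-channel mean
    square (squared RMS), sum across channels, and log with a small floor.
    """
    if frames.fs < 2.0 * EAD_BANDS[-1][1]:
        raise ValueError("sampling rate too low: all sub-bands must lie below Nyquist")
    if frames.n_frames == 0:
        return np.empty((0, len(EAD_BANDS)))
    out = np.empty((frames.n_frames, len(EAD_BANDS)))
    for b, (low, high) in enumerate(EAD_BANDS):
        sos = sps.butter(4, [low, high], btype="bandpass", fs=frames.fs, output="sos")
        y = sps.sosfiltfilt(sos, frames.frames, axis=-1)
        energy = np.mean(y**2, axis=-1).sum(axis=-1)  # sum of squared RMS over channels
        out[:, b] = np.log(energy + LOG_FLOOR)
    return out


@dataclass
class GmmModel:
    """Fitted 2-component mixture with its EM log-likelihood trace."""

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    active_component: int
    log_likelihood_trace: List[float]
    converged: bool
    _gm: GaussianMixture

    def posterior_active(self, features: np.ndarray) -> np.ndarray:
        return self._gm.predict_proba(np.asarray(features, dtype=float))[:, self.active_component]


def fit_gmm(
    features: np.ndarray,
    k: int = 2,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> GmmModel:
    """Fit a full-covariance k-component GMM by EM, recording the
    per-iteration mean log-likelihood.

    k-means++-style initialisation from ``seed``; covariance regularisation
    1e-6 * trace/d of the data covariance; converged when the relative
    log-likelihood improvement falls below ``tol``.  The active component
    is the one with the larger mean total energy (sum of the mean vector).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 * k:
        raise ValueError(f"need at least {2 * k} frames to fit a {k}-component mixture")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    reg = max(1e-6 * float(np.var(X, axis=0).mean()), 1e-12)
    gm = GaussianMixture(
        n_components=k, covariance_type="full", reg_covar=reg,
        init_params="k-means++", random_state=seed,
        warm_start=True, max_iter=1, tol=0.0,
    )
    trace: List[float] = []
    converged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-step fits never "converge" internally
        for _ in range(max_iter):
            gm.fit(X)
            ll = float(gm.lower_bound_)
            if trace and abs(ll - trace[-1]) <= tol * abs(trace[-1]):
                trace.append(ll)
                converged = True
                break
            trace.append(ll)
    if not converged:
        logger.warning("GMM EM reached max_iter=%d without converging", max_iter)
    active = int(np.argmax(gm.means_.sum(axis=1)))
    return GmmModel(
        weights=gm.weights_.copy(), means=gm.means_.copy(),
        covariances=gm.covariances_.copy(), active_component=active,
        log_likelihood_trace=trace, converged=converged, _gm=gm,
    )


def classify_frames(model: GmmModel, features: np.ndarray) -> np.ndarray:
    """1 where the active component's posterior is >= 0.5, else 0."""
    features = np.asarray(features, dtype=float)
    if features.shape[0] == 0:
        return np.empty(0, dtype=int)
    return (model.posterior_active(features) >= 0.5).astype(int)


def smooth_labels(labels: np.ndarray, window: int = 5) -> np.ndarray:
    """Centred majority vote over ``window`` frames, clipped at the ends.

    Removes isolated single-frame flips inside long constant runs.  In a
    clipped (even-length) boundary window an exact tie keeps the original
    label.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    half = window // 2
    out = labels.copy()
    for i in range(n):
        seg = labels[max(0, i - half): min(n, i + half + 1)]
        ones = int(seg.sum())
        if 2 * ones > len(seg):
            out[i] = 1
        elif 2 * ones < len(seg):
            out[i] = 0
        # tie: keep original
    return out


def extract_active_frames(frames: FrameSet, labels: np.ndarray) -> FrameSet:
    """Return exactly the frames labelled active, order preserved."""
    labels = np.asarray(labels, dtype=int)
    if len(labels) != frames.n_frames:
        raise ValueError("label length must equal frame count")
    if frames.n_frames and not labels.any():
        logger.warning("no active frames detected in trial %s", frames.meta)
    return frames.subset(labels == 1)


def frame_activity_truth(
    starts: np.ndarray, window: int, interval: Tuple[int, int]
) -> np.ndarray:
    """Ground-truth frame labels: active when >= 50% of the window overlaps
    the trial's active interval."""
    starts = np.asarray(starts)
    lo, hi = interval
    overlap = np.minimum(starts + window, hi) - np.maximum(starts, lo)
    return (overlap >= window / 2.0).astype(int)


def detect_database(
    db,
    window_ms: float = 128.0,
    hop_ms: float = 64.0,
    smoothing_window: int = 5,
    seed: int = 0,
    per_session: bool = True,
    gmm_max_iter: int = 200,
    gmm_tol: float = 1e-4,
) -> Tuple[Dict[Tuple[int, int, int], FrameSet], Dict[Tuple[int, int, int], np.ndarray], Dict[int, GmmModel]]:
    """Run the full EAD stage over a RecordingDatabase.

    Returns (framesets, smoothed labels, fitted GMMs) keyed by
    (session, gesture, trial) / session.  ``per_session=False`` pools all
    sessions into a single mixture.
    """
    framesets: Dict[Tuple[int, int, int], FrameSet] = {}
    feats: Dict[Tuple[int, int, int], np.ndarray] = {}
    for rec in db:
        filtered = bandpass_filter(rec.signal, db.config.fs)
        fset = frame_signal(
            filtered, db.config.fs, window_ms, hop_ms,
            meta={"session": rec.session, "gesture": rec.gesture, "trial": rec.trial},
        )
        key = (rec.session, rec.gesture, rec.trial)
        framesets[key] = fset
        feats[key] = compute_ead_features(fset)

    groups: Dict[int, List[Tuple[int, int, int]]] = {}
    for key in sorted(feats):
        groups.setdefault(key[0] if per_session else 0, []).append(key)

    models: Dict[int, GmmModel] = {}
    labels: Dict[Tuple[int, int, int], np.ndarray] = {}
    for group, keys in groups.items():
        pooled = np.vstack([feats[k] for k in keys])
        model = fit_gmm(pooled, seed=seed, max_iter=gmm_max_iter, tol=gmm_tol)
        models[group] = model
        for k in keys:
            raw = classify_frames(model, feats[k])
            labels[k] = smooth_labels(raw, smoothing_window)
    return framesets, labels, models
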