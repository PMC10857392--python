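"""Hand-crafted frame features for gesture classification.

Per channel, 14 features: sub-band RMS energies (80-150 / 150-300 /
300-450 Hz), RMS, waveform length, mean absolute value, zero crossings,
slope sign changes, AR(4) coefficients with the prediction-error variance,
and the mean amplitude spectrum of the Hann-tapered frame.  Between
channels, all C(C-1)/2 pairwise Pearson correlations.  Total dimension
D = 14*C + C*(C-1)/2: 140 for 8 channels, 287 for 14.

AR(4) coefficients are Yule-Walker estimates from the biased sample
autocorrelation; the "residual" is the order-4 prediction-error variance
r0 - a.r[1:5].  Zero-crossing and slope-sign-change counts use a pure sign
rule by default (deadband eps = 0) — the inputs are already band-passed,
which removes the baseline wander a deadband usually guards against.

Column order is frozen by :class:`FeatureVectorSpec` so serialized
matrices are stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocessing import FrameSet, apply_hanning

__all__ = [
    "INTRA_FEATURE_NAMES",
    "META_COLUMNS",
    "FeatureVectorSpec",
    "compute_intra_channel_features",
    "compute_inter_channel_features",
    "extract_features",
]

logger = logging.getLogger(__name__)

INTRA_FEATURE_NAMES: Tuple[str, ...] = (
    "sbe_80_150", "sbe_150_300", "sbe_300_450",
    "rms", "wl", "mav", "zc", "ssc",
    "ar1", "ar2", "ar3", "ar4", "ar_res",
    "mas",
)

SUB_BANDS: Tuple[Tuple[float, float], ...] = ((80.0, 150.0), (150.0, 300.0), (300.0, 450.0))
AR_ORDER = 4
MIN_FRAME_SAMPLES = 28  # sosfiltfilt edge padding for the 4th-order sub-band filters

META_COLUMNS = ("session", "gesture", "trial", "frame")


@dataclass(frozen=True)
class FeatureVectorSpec:
    """Frozen, versioned feature-column schema for C channels."""

    n_channels: int
    version: str = "1"

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")

    @property
    def intra_names(self) -> List[str]:
        return [
            f"ch{c}_{name}"
            for c in range(1, self.n_channels + 1)
            for name in INTRA_FEATURE_NAMES
        ]

    @property
    def inter_names(self) -> List[str]:
        C = self.n_channels
        return [f"corr_{x}_{y}" for x in range(1, C) for y in range(x + 1, C + 1)]

    @property
    def names(self) -> List[str]:
        return self.intra_names + self.inter_names

    @property
    def n_intra(self) -> int:
        return len(INTRA_FEATURE_NAMES) * self.n_channels

    @property
    def n_inter(self) -> int:
        return self.n_channels * (self.n_channels - 1) // 2

    @property
    def dimension(self) -> int:
        return self.n_intra + self.n_inter

    def schema(self) -> Dict:
        """JSON-serialisable column schema for sidecar files."""
        return {
            "version": self.version,
            "n_channels": self.n_channels,
            "metadata_columns": list(META_COLUMNS),
            "feature_columns": self.names,
        }


def _batched_yule_walker(x: np.ndarray, order: int = AR_ORDER) -> Tuple[np.ndarray, np.ndarray]:
    """Yule-Walker AR fit on the last axis of ``x`` (biased autocorrelation).

    Returns (coefficients (..., order), residual variance (...,)).
    """
    n = x.shape[-1]
    if n < order + 4:
        raise ValueError(f"frame too short for AR({order}): {n} samples")
    r = np.empty(x.shape[:-1] + (order + 1,))
    for k in range(order + 1):
        r[..., k] = np.einsum("...i,...i->...", x[..., : n - k], x[..., k:]) / n
    # Toeplitz system R a = r[1:]
    idx = np.abs(np.subtract.outer(np.arange(order), np.arange(order)))
    R = r[..., idx]
    rhs = r[..., 1:]
    r0 = r[..., 0]
    silent = r0 <= 0
    R = np.where(silent[..., None, None], np.eye(order), R)
    a = np.linalg.solve(R, rhs[..., None])[..., 0]
    a = np.where(silent[..., None], 0.0, a)
    res = np.where(silent, 0.0, r0 - np.einsum("...k,...k->...", a, rhs))
    return a, np.maximum(res, 0.0)


def _intra_features_batch(frames: np.ndarray, fs: float, eps: float = 0.0) -> np.ndarray:
    """Compute the 14 intra-channel features on a (..., W) frame array."""
    x = np.asarray(frames, dtype=float)
    out = np.empty(x.shape[:-1] + (len(INTRA_FEATURE_NAMES),))

    for b, (low, high) in enumerate(SUB_BANDS):
        sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
        y = sps.sosfiltfilt(sos, x, axis=-1)
        out[..., b] = np.sqrt(np.mean(y**2, axis=-1))

    out[..., 3] = np.sqrt(np.mean(x**2, axis=-1))                # RMS
    d = np.diff(x, axis=-1)
    out[..., 4] = np.abs(d).sum(axis=-1)                         # waveform length
    out[..., 5] = np.abs(x).mean(axis=-1)                        # MAV

    prod = x[..., :-1] * x[..., 1:]
    zc = (prod < 0) & (np.abs(d) >= eps)
    out[..., 6] = zc.sum(axis=-1)                                # zero crossings

    d1 = x[..., 1:-1] - x[..., :-2]
    d2 = x[..., 1:-1] - x[..., 2:]
    ssc = (d1 * d2 > 0) & (np.maximum(np.abs(d1), np.abs(d2)) >= eps)
    out[..., 7] = ssc.sum(axis=-1)                               # slope sign changes

    a, res = _batched_yule_walker(x)
    out[..., 8:12] = a
    out[..., 12] = res

    spectrum = np.abs(np.fft.rfft(apply_hanning(x), axis=-1))
    out[..., 13] = spectrum.mean(axis=-1)                        # mean amplitude spectrum
    return out


def compute_intra_channel_features(
    channel_frame: np.ndarray, fs: float, eps: float = 0.0
) -> np.ndarray:
    """14-vector of intra-channel features for a single-channel frame,
    ordered as :data:`INTRA_FEATURE_NAMES`."""
    x = np.asarray(channel_frame, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D single-channel frame")
    if x.size < MIN_FRAME_SAMPLES:
        raise ValueError(
            f"frame too short: {x.size} < {MIN_FRAME_SAMPLES} samples "
            "(zero-phase sub-band filtering needs edge padding)"
        )
    return _intra_features_batch(x[None, :], fs, eps=eps)[0]


def compute_inter_channel_features(frame: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations, pairs ordered x=1..C-1, y=x+1..C.

    A zero-variance channel gets correlation 0 with every partner.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("expected a (channels, samples) frame")
    return _inter_features_batch(frame[None])[0]


def _inter_features_batch(frames: np.ndarray) -> np.ndarray:
    """(F, C, W) -> (F, C*(C-1)/2) Pearson correlations, row-major pairs."""
    x = frames - frames.mean(axis=-1, keepdims=True)
    cov = np.einsum("fcw,fdw->fcd", x, x)
    var = np.einsum("fcw,fcw->fc", x, x)
    denom = np.sqrt(var[:, :, None] * var[:, None, :])
    zero_var = var <= 0
    if np.any(zero_var):
        logger.warning("zero-variance channel(s) in %d frame(s); correlations set to 0",
                       int(zero_var.any(axis=1).sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    corr = np.clip(corr, -1.0, 1.0)
    iu, ju = np.triu_indices(frames.shape[1], k=1)
    return corr[:, iu, ju]


def extract_features(
    active_frames: FrameSet,
    spec: Optional[FeatureVectorSpec] = None,
    eps: float = 0.0,
) -> pd.DataFrame:
    """Feature matrix for the active frames of one trial.

    Row i = per-channel intra features (channel-major) followed by the
    inter-channel correlations; metadata columns carry the frame's
    (session, gesture, trial, frame index) provenance.
    """
    if spec is None:
        spec = FeatureVectorSpec(n_channels=active_frames.n_channels or 2)
    if active_frames.n_frames and spec.n_channels != active_frames.n_channels:
        raise ValueError(
            f"spec expects {spec.n_channels} channels, frames have {active_frames.n_channels}"
        )
    meta = active_frames.meta
    meta_cols: Dict[str, Sequence] = {
        "session": np.full(active_frames.n_frames, meta.get("session", 0)),
        "gesture": np.full(active_frames.n_frames, meta.get("gesture", 0)),
        "trial": np.full(active_frames.n_frames, meta.get("trial", 0)),
        "frame": np.arange(active_frames.n_frames) if active_frames.n_frames else np.empty(0, int),
    }
    if "frame_index" in meta:
        meta_cols["frame"] = np.asarray(meta["frame_index"])
    if active_frames.n_frames == 0:
        data = np.empty((0, spec.dimension))
    else:
        intra = _intra_features_batch(active_frames.frames, active_frames.fs, eps=eps)
        intra = intra.reshape(active_frames.n_frames, -1)
        inter = _inter_features_batch(active_frames.frames)
        data = np.hstack([intra, inter])
    df = pd.DataFrame(data, columns=spec.names)
    for name, col in reversed(list(meta_cols.items())):
        df.insert(0, name, col)
    return df
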