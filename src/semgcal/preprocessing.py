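"""Signal conditioning: zero-phase band-pass filtering, framing, Hann taper.

The whole continuous trial is filtered once (forward-backward Butterworth,
so zero phase), then cut into overlapping frames on a grid that starts at
sample 0: default 128 ms windows with a 64 ms hop.  The Hann taper is only
applied where a spectrum is computed — tapering would bias the amplitude
statistics used as time-domain features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np
from scipy import signal as sps

__all__ = ["FrameSet", "bandpass_filter", "frame_signal", "apply_hanning",
           "save_frameset", "load_frameset"]


@dataclass
class FrameSet:
    """Overlapping fixed-length windows of a (filtered) multichannel signal.

    ``frames`` has shape (n_frames, n_channels, window_samples); ``starts``
    holds the 0-based start sample of each frame (half-open
    [start, start + window) coverage).
    """

    frames: np.ndarray
    starts: np.ndarray
    fs: float
    window_ms: float
    hop_ms: float
    meta: Dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_channels(self) -> int:
        return self.frames.shape[1]

    @property
    def window_samples(self) -> int:
        return self.frames.shape[2]

    def subset(self, index: np.ndarray) -> "FrameSet":
        """Select frames by boolean mask or integer index, order preserved."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(self, frames=self.frames[index], starts=self.starts[index])


def save_frameset(fset: FrameSet, path_prefix) -> None:
    """Write a FrameSet as delimited text plus a JSON sidecar.

    ``<prefix>.csv`` holds the frame tensor flattened to
    (n_frames * n_channels) rows of window samples; ``<prefix>.json``
    holds shape, start indices, timing and provenance.
    """
    import json
    from pathlib import Path

    prefix = Path(path_prefix)
    flat = fset.frames.reshape(-1, fset.frames.shape[-1]) if fset.n_frames else \
        np.empty((0, fset.frames.shape[-1]))
    np.savetxt(prefix.with_suffix(".csv"), flat, delimiter=",", fmt="%.10g")
    sidecar = {
        "shape": list(fset.frames.shape),
        "starts": fset.starts.tolist(),
        "fs": fset.fs,
        "window_ms": fset.window_ms,
        "hop_ms": fset.hop_ms,
        "meta": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                 for k, v in fset.meta.items()},
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_frameset(path_prefix) -> FrameSet:
    """Inverse of :func:`save_frameset`."""
    import json
    from pathlib import Path

    prefix = Path(path_prefix)
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    shape = tuple(sidecar["shape"])
    flat = np.loadtxt(prefix.with_suffix(".csv"), delimiter=",", ndmin=2)
    return FrameSet(
        frames=flat.reshape(shape),
        starts=np.asarray(sidecar["starts"], dtype=int),
        fs=sidecar["fs"],
        window_ms=sidecar["window_ms"],
        hop_ms=sidecar["hop_ms"],
        meta=sidecar["meta"],
    )


def bandpass_filter(
    signal: np.ndarray,
    fs: float,
    low_hz: float = 20.0,
    high_hz: float = 450.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass, applied independently per channel.

    Forward-backward application (``sosfiltfilt``) doubles the effective
    order and cancels the phase response; DC is fully outside the pass
    band.  ``signal`` may be 1-D (samples,) or 2-D (channels, samples).
    """
    if fs <= 2.0 * high_hz:
        raise ValueError(f"fs={fs} too low: need fs > 2*high_hz = {2 * high_hz}")
    if low_hz <= 0 or low_hz >= high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    signal = np.asarray(signal, dtype=float)
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    # sosfiltfilt needs more samples than its edge padding
    padlen = 3 * (2 * sos.shape[0] + 1)
    if signal.shape[-1] <= padlen:
        raise ValueError(
            f"signal too short for zero-phase filtering: {signal.shape[-1]} <= {padlen} samples"
        )
    return sps.sosfiltfilt(sos, signal, axis=-1)


def frame_signal(
    signal: np.ndarray,
    fs: float,
    window_ms: float = 128.0,
    hop_ms: float = 64.0,
    meta: Optional[Dict] = None,
) -> FrameSet:
    """Cut a (channels x samples) signal into overlapping frames.

    Trailing samples that do not fill a whole window are dropped; a signal
    shorter than one window yields an empty FrameSet.
    """
    if window_ms <= 0 or hop_ms <= 0:
        raise ValueError("window_ms and hop_ms must be positive")
    if hop_ms > window_ms:
        raise ValueError("hop_ms must not exceed window_ms")
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    window = int(round(window_ms * fs / 1000.0))
    hop = int(round(hop_ms * fs / 1000.0))
    n = signal.shape[-1]
    if n < window:
        frames = np.empty((0, signal.shape[0], window))
        starts = np.empty(0, dtype=int)
    else:
        n_frames = (n - window) // hop + 1
        starts = np.arange(n_frames) * hop
        view = np.lib.stride_tricks.sliding_window_view(signal, window, axis=-1)
        frames = np.ascontiguousarray(np.swapaxes(view[:, ::hop, :], 0, 1))
        frames = frames[:n_frames]
    return FrameSet(frames=frames, starts=starts, fs=fs,
                    window_ms=window_ms, hop_ms=hop_ms, meta=dict(meta or {}))


def apply_hanning(frame: np.ndarray) -> np.ndarray:
    """Multiply by the symmetric Hann taper of the frame length (last axis)."""
    frame = np.asarray(frame, dtype=float)
    n = frame.shape[-1]
    if n < 2:
        raise ValueError("frame length must be >= 2")
    return frame * sps.windows.hann(n, sym=True)
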