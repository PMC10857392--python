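"""Synthetic multi-session surface-EMG database generator.

Emulates the structure of a cross-session gesture-recognition study: a
subject performs each gesture for ``active_s`` seconds followed by
``rest_s`` seconds of rest, ``n_trials`` times per session, over
``n_sessions`` independent electrode applications.  Because electrodes are
re-applied between sessions, the signal distribution drifts from session to
session; that drift is emulated by per-session multiplicative channel gains
and convex mixing between neighbouring channels.

The signal texture is colored Gaussian noise: an sEMG interference pattern
is well approximated (to second order) by band-limited stochastic noise
whose amplitude is modulated by muscle activation.  Each gesture has a
characteristic per-channel activation gain vector and per-channel spectral
shapes (second-order resonators).  Gestures differ mainly in their spatial
activation pattern, while their spectra stay close to a shared myoelectric
shape — as in real recordings, where every channel sees muscle tissue with
a similar power spectrum and discrimination rests on which muscles are
active.  Trial-to-trial contraction-force variability adds within-gesture
spread, so the synthetic task is not degenerate and cross-session drift is
the dominant error source.

Every trial stores its ground-truth active interval so that the
unsupervised activity detector can be scored; a real recording has no such
labels.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Tuple

import numpy as np
from scipy import signal as sps

__all__ = [
    "GeneratorConfig",
    "GestureTemplate",
    "SessionDrift",
    "TrialRecording",
    "RecordingDatabase",
    "build_templates",
    "generate_trial",
    "generate_database",
    "save_database",
    "load_database",
]

# sub-stream keys so that trial noise never depends on the session index
_TEMPLATE_KEY = 101
_DRIFT_KEY = 202
_TRIAL_KEY = 303


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic recording database.

    Defaults mirror the study layout this package emulates: 8 channels at
    1000 Hz, 3-s active bursts with 3-s rest, 3 gestures, 20 trials per
    gesture per session, 7 sessions.  ``db6like()`` gives the alternative
    14-channel / 2 kHz configuration (7 gestures, 12 trials, 10 sessions).
    """

    n_channels: int = 8
    fs: float = 1000.0
    n_gestures: int = 3
    n_sessions: int = 7
    n_trials: int = 20
    active_s: float = 3.0
    rest_s: float = 3.0
    rest_noise_rms: float = 1.0
    burst_snr_db: float = 20.0
    drift_scale: float = 0.5
    seed: int = 0
    ramp_s: float = 0.1  # raised-cosine on/off ramp of the burst envelope
    trial_gain_cv: float = 0.1    # per-trial contraction-force variability (log-sd)
    channel_gain_cv: float = 0.05  # per-trial per-channel activation jitter (log-sd)

    def __post_init__(self) -> None:
        for name in ("n_channels", "n_gestures", "n_sessions", "n_trials"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.fs < 1000:
            raise ValueError("fs must be >= 1000 Hz so the 20-450 Hz band is representable")
        if self.active_s <= 0 or self.rest_s <= 0:
            raise ValueError("active_s and rest_s must be positive")
        if self.drift_scale < 0:
            raise ValueError("drift_scale must be nonnegative")
        if self.rest_noise_rms <= 0:
            raise ValueError("rest_noise_rms must be positive")
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")

    @property
    def samples_per_trial(self) -> int:
        return int(round((self.active_s + self.rest_s) * self.fs))

    @property
    def active_samples(self) -> int:
        return int(round(self.active_s * self.fs))

    @classmethod
    def db6like(cls, **overrides) -> "GeneratorConfig":
        """14-channel, 2 kHz configuration: 7 gestures, 12 trials, 10 sessions."""
        base = dict(
            n_channels=14, fs=2000.0, n_gestures=7, n_sessions=10,
            n_trials=12, active_s=4.0, rest_s=4.0,
        )
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class GestureTemplate:
    """Per-gesture activation pattern.

    ``gains`` is the nonnegative per-channel activation gain (at least one
    strictly positive; distinct between gestures), and ``coloring`` the
    denominator coefficients of a low-order recursive coloring filter that
    gives the gesture its spectral signature.
    """

    gesture: int
    gains: np.ndarray
    coloring: np.ndarray  # (C, 3) per-channel AR denominators [1, a1, a2]

    def __post_init__(self) -> None:
        if not np.any(self.gains > 0):
            raise ValueError("at least one channel gain must be positive")


@dataclass(frozen=True)
class SessionDrift:
    """Per-session electrode-shift surrogate: channel gains plus mixing."""

    session: int
    gains: np.ndarray        # (C,) multiplicative per-channel gains
    mixing: np.ndarray       # (C, C) row-stochastic convex mixing matrix


@dataclass(frozen=True)
class TrialRecording:
    session: int
    gesture: int
    trial: int
    signal: np.ndarray                 # (C, n_samples)
    active_interval: Tuple[int, int]   # [start, end) in samples


@dataclass
class RecordingDatabase:
    """sessions -> gestures -> trials of multi-channel raw signals."""

    config: GeneratorConfig
    templates: List[GestureTemplate]
    drifts: Dict[int, SessionDrift]
    trials: Dict[Tuple[int, int, int], TrialRecording] = field(default_factory=dict)

    def keys(self) -> List[Tuple[int, int, int]]:
        return sorted(self.trials.keys())

    def __iter__(self) -> Iterator[TrialRecording]:
        for key in self.keys():
            yield self.trials[key]

    def __len__(self) -> int:
        return len(self.trials)

    def get(self, session: int, gesture: int, trial: int) -> TrialRecording:
        return self.trials[(session, gesture, trial)]

    @property
    def sessions(self) -> List[int]:
        return sorted({s for s, _, _ in self.trials})

    @property
    def gestures(self) -> List[int]:
        return sorted({g for _, g, _ in self.trials})


def _bandlimit_sos(fs: float, low: float = 20.0, high: float = 450.0):
    return sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")


def build_templates(config: GeneratorConfig) -> List[GestureTemplate]:
    """Deterministic gesture templates.

    Gains are overlapping spatial bumps centred at gesture-specific
    channels.  Spectral coloring is a per-channel resonator whose centre
    frequency stays near the ~80-150 Hz bulk of the myoelectric spectrum:
    gestures are offset from one another by only a few hertz, so spatial
    pattern — not spectrum — carries most of the gesture information.
    """
    templates = []
    C = config.n_channels
    ch = np.arange(C, dtype=float)
    for g in range(1, config.n_gestures + 1):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, _TEMPLATE_KEY, g]))
        # two bumps with gesture-dependent geometry: activation maps overlap
        # between gestures but are not shifted copies of one another
        center = (g - 0.5) * C / config.n_gestures + rng.uniform(-0.2, 0.2)
        center2 = (center + C / 2.5 + 0.7 * g) % C
        spread2 = C / 6.0 + 0.02 * C * g
        d1 = np.minimum(np.abs(ch - center), C - np.abs(ch - center))
        d2 = np.minimum(np.abs(ch - center2), C - np.abs(ch - center2))
        gains = (0.4 + np.exp(-0.5 * (d1 / (C / 3.0)) ** 2)
                 + 0.5 * np.exp(-0.5 * (d2 / spread2) ** 2))
        gains *= rng.uniform(0.95, 1.05, size=C)
        base_f0 = 110.0 + 12.0 * (g - (config.n_gestures + 1) / 2.0) + rng.uniform(-3.0, 3.0)
        f0 = np.clip(base_f0 + rng.uniform(-15.0, 15.0, size=C), 60.0, 350.0)
        rho = 0.9
        theta = 2.0 * np.pi * f0 / config.fs
        coloring = np.stack(
            [np.ones(C), -2.0 * rho * np.cos(theta), np.full(C, rho**2)], axis=1
        )
        templates.append(GestureTemplate(gesture=g, gains=gains, coloring=coloring))
    return templates


def _draw_session_drift(config: GeneratorConfig, session: int) -> SessionDrift:
    """Electrode-shift surrogate for one session.

    Re-applying electrodes displaces the (circular) array relative to the
    underlying muscles; that is emulated by a fractional circular channel
    shift — each output channel is a convex mix of the two input channels
    it now sits between — plus per-channel lognormal gain changes from
    contact-impedance variation.  Both magnitudes scale with drift_scale;
    at drift_scale = 0 the descriptor is exactly the identity.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _DRIFT_KEY, session]))
    C = config.n_channels
    gains = rng.lognormal(mean=0.0, sigma=0.6 * config.drift_scale, size=C)
    # electrodes are re-applied individually, so each channel shifts by its
    # own amount (in electrode-pitch units)
    delta = rng.normal(0.0, 0.8 * config.drift_scale, size=C)
    mixing = np.zeros((C, C))
    for c in range(C):
        k = int(np.floor(delta[c]))
        f = delta[c] - k
        mixing[c, (c + k) % C] = 1.0 - f
        mixing[c, (c + k + 1) % C] += f
    return SessionDrift(session=session, gains=gains, mixing=mixing)


def _burst_envelope(n_active: int, fs: float, ramp_s: float) -> np.ndarray:
    env = np.ones(n_active)
    r = int(round(ramp_s * fs))
    if 2 * r >= n_active:
        return sps.windows.hann(n_active, sym=True)
    if r > 0:
        t = np.arange(r) / r
        env[:r] = 0.5 * (1.0 - np.cos(np.pi * t))
        env[-r:] = env[:r][::-1]
    return env


def generate_trial(
    template: GestureTemplate,
    config: GeneratorConfig,
    drift: SessionDrift,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, Tuple[int, int]]:
    """Generate one trial: an active burst followed by rest.

    The rest segment is colored Gaussian noise at ``rest_noise_rms``; the
    active segment adds gesture-gain-modulated, band-limited colored noise
    scaled so that the active/rest RMS ratio matches ``burst_snr_db``
    (amplitude dB, i.e. ratio = 10**(snr/20)).  The session drift gains and
    mixing are applied to every sample.
    """
    if len(template.gains) != config.n_channels:
        raise ValueError(
            f"template has {len(template.gains)} channels, config expects {config.n_channels}"
        )
    C = config.n_channels
    n = config.samples_per_trial
    na = config.active_samples
    sos = _bandlimit_sos(config.fs)

    # baseline instrumentation/ambient noise over the whole trial
    rest = sps.sosfiltfilt(sos, rng.standard_normal((C, n)), axis=-1)
    rest_rms = np.sqrt(np.mean(rest**2, axis=-1, keepdims=True))
    rest = rest / rest_rms * config.rest_noise_rms

    # gesture burst: per-channel colored, band-limited, gain- and envelope-modulated
    white = rng.standard_normal((C, na))
    burst = np.empty_like(white)
    for c in range(C):
        burst[c] = sps.lfilter([1.0], template.coloring[c], white[c])
    burst = sps.sosfiltfilt(sos, burst, axis=-1)
    burst *= template.gains[:, None]
    burst *= _burst_envelope(na, config.fs, config.ramp_s)[None, :]

    # scale burst power so aggregate active/rest RMS ratio matches burst_snr_db
    ratio = 10.0 ** (config.burst_snr_db / 20.0)
    p_rest = np.mean(rest**2)
    p_burst = np.mean(burst**2)
    target = max(ratio**2 - 1.0, 0.0) * p_rest
    if p_burst > 0:
        burst *= np.sqrt(target / p_burst)

    # contraction-force variability modulates the calibrated burst level:
    # a per-trial overall factor and per-channel jitter of the spatial pattern
    trial_gain = rng.lognormal(0.0, config.trial_gain_cv)
    channel_gain = rng.lognormal(0.0, config.channel_gain_cv, size=C)
    burst *= trial_gain * channel_gain[:, None]


    sig = rest
    sig[:, :na] += burst
    sig = drift.mixing @ (drift.gains[:, None] * sig)
    return sig, (0, na)


def generate_database(config: GeneratorConfig) -> RecordingDatabase:
    """Generate the full sessions x gestures x trials database.

    Reproducible bit-for-bit from ``config.seed``.  Trial noise streams are
    keyed by (gesture, trial) only, so with ``drift_scale = 0`` every
    session contains identical signals — sessions then differ only through
    their drift descriptor.
    """
    templates = build_templates(config)
    db = RecordingDatabase(config=config, templates=templates, drifts={})
    for s in range(1, config.n_sessions + 1):
        drift = _draw_session_drift(config, s)
        db.drifts[s] = drift
        for template in templates:
            g = template.gesture
            for t in range(1, config.n_trials + 1):
                rng = np.random.default_rng(
                    np.random.SeedSequence([config.seed, _TRIAL_KEY, g, t])
                )
                sig, interval = generate_trial(template, config, drift, rng)
                db.trials[(s, g, t)] = TrialRecording(
                    session=s, gesture=g, trial=t, signal=sig, active_interval=interval
                )
    return db


# ---------------------------------------------------------------------------
# plain-text persistence: one CSV per trial plus a JSON manifest


def _trial_filename(session: int, gesture: int, trial: int) -> str:
    return f"s{session:02d}_g{gesture:02d}_t{trial:02d}.csv"


def save_database(db: RecordingDatabase, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in db:
        fname = _trial_filename(rec.session, rec.gesture, rec.trial)
        header = ",".join(f"ch{c + 1}" for c in range(rec.signal.shape[0]))
        np.savetxt(out / fname, rec.signal.T, delimiter=",", header=header,
                   comments="", fmt="%.10g")
        entries.append({
            "file": fname,
            "session": rec.session,
            "gesture": rec.gesture,
            "trial": rec.trial,
            "active_interval": list(rec.active_interval),
        })
    manifest = {
        "config": dataclasses.asdict(db.config),
        "trials": entries,
        "drifts": {
            str(s): {"gains": d.gains.tolist(), "mixing": d.mixing.tolist()}
            for s, d in db.drifts.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_database(in_dir) -> RecordingDatabase:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    config = GeneratorConfig(**manifest["config"])
    templates = build_templates(config)
    drifts = {
        int(s): SessionDrift(session=int(s), gains=np.asarray(d["gains"]),
                             mixing=np.asarray(d["mixing"]))
        for s, d in manifest["drifts"].items()
    }
    db = RecordingDatabase(config=config, templates=templates, drifts=drifts)
    for entry in manifest["trials"]:
        sig = np.loadtxt(src / entry["file"], delimiter=",", skiprows=1).T
        sig = np.atleast_2d(sig)
        db.trials[(entry["session"], entry["gesture"], entry["trial"])] = TrialRecording(
            session=entry["session"], gesture=entry["gesture"], trial=entry["trial"],
            signal=sig, active_interval=tuple(entry["active_interval"]),
        )
    return db
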