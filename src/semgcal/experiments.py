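"""Study-condition experiments on synthetic databases.

These functions wire the full pipeline into the two headline analyses and
are what the acceptance machinery runs:

* :func:`ead_recovery` — frame-level agreement between the unsupervised
  activity detector and the generator's ground-truth intervals;
* :func:`drift_study` — on drifted databases, the calibration effect
  (updated vs baseline dataset at 5 calibration trials) and the
  training-amount analysis (average-accuracy log-fit slopes for sessions
  vs trials).

Problem sizes are chosen so a replicate finishes in seconds-to-a-minute on
one core: the EAD check uses compact two-session databases, while the
drift study runs the full study layout (7 sessions x 3 gestures x 20
trials) with active frames thinned to a fixed number per trial — frames
within a trial are highly redundant, so thinning changes accuracy little
while keeping the several hundred classifier fits cheap — and the trial
axis of the training grid sampled on an approximately geometric ladder.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import numpy as np

from .activity import detect_database, frame_activity_truth
from .evaluation import (ClassifierSpec, average_accuracy_curves, evaluate_assembly,
                         fit_log_curve, run_training_grid)
from .pipeline import featurize_database
from .protocol import assemble_dataset, make_protocol, training_grid
from .synthetic import GeneratorConfig, generate_database

__all__ = ["ead_recovery", "drift_study", "child_seed"]

GRID_TRIALS = (1, 2, 3, 5, 8, 12, 20)  # geometric ladder over the 1..20 trial axis
FRAMES_PER_TRIAL = 12


def child_seed(seed: int, index: int) -> int:
    """Derive independent per-replicate seeds below 2**31."""
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


def ead_recovery(
    seed: int,
    n_seeds: int = 10,
    burst_snr_db: float = 15.0,
    n_sessions: int = 2,
    n_trials: int = 6,
) -> float:
    """Mean frame-level agreement (%) of EAD with ground-truth activity.

    Averaged over ``n_seeds`` independently generated databases.
    """
    rates = []
    for i in range(n_seeds):
        cfg = GeneratorConfig(
            n_sessions=n_sessions, n_trials=n_trials,
            burst_snr_db=burst_snr_db, seed=child_seed(seed, i),
        )
        db = generate_database(cfg)
        framesets, labels, _ = detect_database(db, seed=cfg.seed)
        agree = total = 0
        for key, fset in framesets.items():
            truth = frame_activity_truth(
                fset.starts, fset.window_samples, db.get(*key).active_interval
            )
            agree += int(np.sum(labels[key] == truth))
            total += len(truth)
        rates.append(100.0 * agree / total)
    return float(np.mean(rates))


def drift_study(
    seed: int,
    n_seeds: int = 10,
    drift_scale: float = 0.5,
    n_calib: int = 5,
    frames_per_trial: int = FRAMES_PER_TRIAL,
    grid_trials: Sequence[int] = GRID_TRIALS,
    classifier: Optional[ClassifierSpec] = None,
) -> Dict[str, float]:
    """Calibration-gain and training-amount analysis on drifted databases.

    Per replicate: generate the study layout (7 sessions, 3 gestures, 20
    trials) with cross-session drift, run detection + feature extraction,
    then (a) score the baseline and updated datasets at ``n_calib``
    calibration trials over the four test sessions, and (b) run the
    training grid (sessions 1..6 x sampled trial counts, tested on session
    7) and fit y = a*ln(x) + b to both average-accuracy marginals.

    Returns means over replicates: baseline/updated accuracy (%), the AA
    log-fit slopes and R^2 for the session and trial axes.
    """
    spec = classifier or ClassifierSpec()
    protocol = make_protocol(preset="study")
    base_accs, upd_accs = [], []
    slopes_s, slopes_t, r2_s, r2_t = [], [], [], []
    for i in range(n_seeds):
        cfg = GeneratorConfig(drift_scale=drift_scale, seed=child_seed(seed, i))
        db = generate_database(cfg)
        features = featurize_database(db, seed=cfg.seed,
                                      max_frames_per_trial=frames_per_trial)
        gestures = db.gestures

        accs = {"baseline": [], "updated": []}
        for test_session in protocol.calib_sessions:
            for variant in ("baseline", "updated"):
                assembly = assemble_dataset(protocol, variant, test_session,
                                            n_calib, gestures)
                accs[variant].append(evaluate_assembly(assembly, features, spec))
        base_accs.append(np.mean(accs["baseline"]))
        upd_accs.append(np.mean(accs["updated"]))

        cells, test_membership = training_grid(
            protocol, range(1, 7), grid_trials, gestures)
        grid = run_training_grid(features, cells, test_membership, spec)
        aa_trials, aa_sessions = average_accuracy_curves(grid)
        fit_t = fit_log_curve(aa_trials.index.to_numpy(), aa_trials.to_numpy())
        fit_s = fit_log_curve(aa_sessions.index.to_numpy(), aa_sessions.to_numpy())
        slopes_t.append(fit_t.slope)
        slopes_s.append(fit_s.slope)
        r2_t.append(fit_t.r_squared)
        r2_s.append(fit_s.r_squared)

    return {
        "baseline_accuracy": float(np.mean(base_accs)),
        "updated_accuracy": float(np.mean(upd_accs)),
        "aa_slope_sessions": float(np.mean(slopes_s)),
        "aa_slope_trials": float(np.mean(slopes_t)),
        "aa_r2_sessions": float(np.mean(r2_s)),
        "aa_r2_trials": float(np.mean(r2_t)),
        "n_seeds": n_seeds,
    }
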