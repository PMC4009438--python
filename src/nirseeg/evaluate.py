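"""Batch evaluation: simulated sessions -> four binary accuracies + decoding.

Mirrors the published report format: each simulated session plays the role
of one subject, scored by stratified cross-validation on four two-class
problems (Left/Right/Forward/Back, each against Stop). EEG problems use the
two C3/C4 mean-peak-amplitude features, NIRS problems the mean HbO/HbR
features. The train/test protocol of the original report is unknown;
seed-controlled stratified k-fold over decision windows is this package's
documented default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import eeg as eeg_mod
from . import fusion, nirs, paradigm
from .classify import cross_validate
from .io import PROBLEM_COLUMNS, AccuracyTable
from .simulate import Recording, SimulationConfig, simulate_session

_EEG_PROBLEMS = {"Left vs Stop": paradigm.TAP_LEFT, "Right vs Stop": paradigm.TAP_RIGHT}
_NIRS_PROBLEMS = {
    "Forward vs Stop": paradigm.MENTAL_COUNTING,
    "Back vs Stop": paradigm.MENTAL_ARITHMETIC,
}


def session_problem_features(
    recording: Recording,
    optics: nirs.OpticsConfig | None = None,
    cfg: fusion.FusionConfig = fusion.FusionConfig(),
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-problem (features, labels) arrays for one session.

    EEG problems: C3/C4 mean peak amplitudes of tap epochs (+1..+11 s) vs
    rest-block windows. NIRS problems: mean HbO/HbR over mental windows
    (onset-lag shifted) vs rest-block windows, from the offline denoising
    chain (MBLL -> Gaussian low-pass -> wavelet).
    """
    optics = optics or nirs.OpticsConfig()
    baselines = fusion.estimate_baselines(recording, optics, cfg)
    eeg_base = {ch: (baselines.eeg_env_mean[ch], baselines.eeg_sig_sd[ch]) for ch in ("C3", "C4")}
    band = eeg_mod.bandpass_beta(recording.eeg, recording.eeg_rate)
    rest_windows = list(paradigm.iter_rest_windows(recording.schedule))

    def eeg_feats(windows):
        eps = eeg_mod.segment_epochs(band, recording.eeg_rate, windows)
        return np.array(
            [eeg_mod.eeg_features(ep, baselines=eeg_base, k=cfg.k, tap_rate=cfg.tap_rate) for ep in eps]
        )

    tap_windows = paradigm.epoch_windows(recording.schedule, "eeg")
    series = nirs.preprocess_nirs(recording.nirs_intensity, recording.nirs_rate, optics)
    # the lag-shifted window of the final mental block overruns the session;
    # clip to the recorded extent
    extent = series.n_samples / series.rate
    mental_windows = [
        paradigm.EpochWindow(w.start, min(w.end, extent), w.label, w.modality)
        for w in paradigm.epoch_windows(recording.schedule, "nirs")
    ]

    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    rest_eeg = eeg_feats(rest_windows)
    for problem, label in _EEG_PROBLEMS.items():
        task = eeg_feats([w for w in tap_windows if w.label == label])
        x = np.vstack([task, rest_eeg])
        y = np.array([problem.split(" vs ")[0]] * len(task) + ["Stop"] * len(rest_eeg))
        out[problem] = (x, y)
    rest_nirs = np.array([nirs.nirs_features(series, w) for w in rest_windows])
    for problem, label in _NIRS_PROBLEMS.items():
        wins = [w for w in mental_windows if w.label == label]
        task = np.array([nirs.nirs_features(series, w) for w in wins])
        x = np.vstack([task, rest_nirs])
        y = np.array([problem.split(" vs ")[0]] * len(task) + ["Stop"] * len(rest_nirs))
        out[problem] = (x, y)
    return out


@dataclass
class EvaluationResult:
    table: AccuracyTable  # one row per session (k-fold CV within session)
    pooled: dict[str, float]  # CV accuracy over all sessions pooled, per problem
    block_accuracies: list[float]  # per-session majority-command accuracy, %
    n_sessions: int

    @property
    def mean_block_accuracy(self) -> float:
        return float(np.mean(self.block_accuracies)) if self.block_accuracies else float("nan")


def session_seed(base_seed: int, index: int) -> int:
    """Per-session seed derived from the run seed (kept below 2**31)."""
    return int((base_seed * 100003 + 7919 * index + 1) % (2**31 - 1))


def evaluate_sessions(
    n_sessions: int = 20,
    sim_cfg: SimulationConfig | None = None,
    seed: int = 0,
    k: int = 5,
    n_samples: int = 5,
    fusion_cfg: fusion.FusionConfig = fusion.FusionConfig(),
    decode: bool = True,
) -> EvaluationResult:
    """Simulate a batch of sessions and score all four binary problems.

    A separate calibration session (its own seed) trains the decoder used
    for per-block command accuracy; classification accuracies come from
    stratified k-fold cross-validation, per session and pooled.
    """
    sim_cfg = sim_cfg or SimulationConfig()
    optics = nirs.OpticsConfig()
    models = None
    if decode:
        calib = simulate_session(
            replace(sim_cfg, seed=session_seed(seed, n_sessions + 1)), n_samples=n_samples
        )
        models = fusion.train_models(calib, optics, fusion_cfg)

    rows = []
    block_acc = []
    pooled_parts: dict[str, list] = {p: [] for p in PROBLEM_COLUMNS}
    for i in range(n_sessions):
        rec = simulate_session(replace(sim_cfg, seed=session_seed(seed, i)), n_samples=n_samples)
        problems = session_problem_features(rec, optics, fusion_cfg)
        row = {}
        for problem, (x, y) in problems.items():
            row[problem] = cross_validate(x, y, k=k, seed=seed + i).accuracy
            pooled_parts[problem].append((x, y))
        rows.append(row)
        if decode and models is not None:
            _, summary = fusion.decode_session(rec, models, fusion_cfg)
            block_acc.append(summary["block_accuracy"])
    pooled = {}
    for problem, parts in pooled_parts.items():
        x = np.vstack([p[0] for p in parts])
        y = np.concatenate([p[1] for p in parts])
        pooled[problem] = cross_validate(x, y, k=k, seed=seed).accuracy
    return EvaluationResult(
        table=AccuracyTable.from_rows(rows),
        pooled=pooled,
        block_accuracies=block_acc,
        n_sessions=n_sessions,
    )
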