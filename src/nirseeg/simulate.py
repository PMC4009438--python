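"""Synthetic multimodal recordings with exported ground truth.

The generator emulates the study conditions of a hybrid NIRS-EEG session:

* EEG (8 channels, 256 Hz, microvolts): pink-noise background; each hand tap
  injects a short transient spike plus a beta-band (12-30 Hz) burst into the
  *contralateral* motor channel (left hand -> C4, right hand -> C3). Left-hand
  taps are stronger than right-hand taps, mirroring the instruction to tap
  harder with the left hand so the two hands are separable by amplitude.
* Prefrontal hemodynamics (12 channels): each mental block drives a smooth
  oxy-hemoglobin rise that starts ``onset_lag`` seconds after the prompt and
  settles back to baseline within ``settle_time`` seconds of block end;
  deoxy-hemoglobin is a scaled negative copy. Arithmetic and counting excite
  distinct spatial weight patterns across the 12 channels so the two mental
  tasks are separable.
* Raw optical intensities (2 wavelengths, 1.81 Hz): the ground-truth
  concentrations are pushed through the modified Beer-Lambert forward model,
  with sinusoidal physiological noise (cardiac, respiratory, Mayer waves) and
  white measurement noise added in the optical-density domain.

All signal shapes here are invented, config-driven plumbing: the real study
recorded human brains and published no amplitude or SNR figures. Defaults are
chosen so the full pipeline behaves like the published system (tap trains
countable on C3/C4, mental blocks separable from rest) and every generator
exports its ground truth for oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from . import montage
from .errors import InvalidArgumentError
from .paradigm import (
    MENTAL_ARITHMETIC,
    MENTAL_COUNTING,
    MENTAL_LABELS,
    TAP_LABELS,
    TAP_LEFT,
    EventSchedule,
    TaskBlock,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Tunable study conditions for the synthetic session."""

    eeg_rate: float = 256.0  # Hz
    nirs_rate: float = 1.81  # Hz
    tap_rate: float = 1.0  # taps per second during a tapping block

    # EEG amplitudes (microvolts); the left hand taps harder than the right
    tap_amp_left: float = 30.0
    tap_amp_right: float = 15.0
    beta_burst_band: tuple[float, float] = (12.0, 30.0)
    burst_freq: float = 21.0  # carrier of the injected beta burst, Hz
    eeg_noise_std: float = 2.0  # pink-noise std, microvolts (0 = noise-free)

    # Hemodynamics (micromolar)
    hbo_peak: float = 5.0
    hbr_peak: float = -1.5
    onset_lag: float = 2.0  # s between prompt and HbO rise
    settle_time: float = 12.0  # s after block end by which HbO has settled (<5% of peak)
    response_rise: float = 4.0  # s from rise onset to plateau

    # Optical-density-domain noise for the NIRS forward model
    cardiac_amp: float = 0.004
    cardiac_freq: float = 1.2  # Hz (aliases through the 1.81 Hz sampling)
    respiratory_amp: float = 0.006
    respiratory_freq: float = 0.3  # Hz
    mayer_amp: float = 0.008
    mayer_freq: float = 0.1  # Hz
    od_noise_std: float = 0.003  # white measurement noise, OD units

    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.eeg_rate, self.nirs_rate, self.tap_rate) <= 0:
            raise InvalidArgumentError("all rates must be > 0")
        if not (self.tap_amp_left > self.tap_amp_right > 0):
            raise InvalidArgumentError(
                "tap amplitudes must satisfy tap_amp_left > tap_amp_right > 0"
            )
        if not (self.hbo_peak > 0 > self.hbr_peak):
            raise InvalidArgumentError("hbo_peak must be > 0 and hbr_peak < 0")

    def noise_free(self) -> "SimulationConfig":
        """Copy of the config with every noise source switched off."""
        return replace(
            self,
            eeg_noise_std=0.0,
            cardiac_amp=0.0,
            respiratory_amp=0.0,
            mayer_amp=0.0,
            od_noise_std=0.0,
        )


#: spatial weight of each mental task over the 12 prefrontal channels.
#: Arithmetic loads on the left half of the strip, counting on the right,
#: giving the two classes distinct (configurable) amplitude patterns.
DEFAULT_TASK_WEIGHTS: Mapping[str, np.ndarray] = {
    MENTAL_ARITHMETIC: np.linspace(1.0, 0.3, montage.N_NIRS_CHANNELS),
    MENTAL_COUNTING: np.linspace(0.3, 1.0, montage.N_NIRS_CHANNELS),
}


def simulate_taps(block: TaskBlock, cfg: SimulationConfig) -> np.ndarray:
    """Tap event times for one tapping block: 1/tap_rate spacing from onset."""
    if block.label not in TAP_LABELS:
        raise InvalidArgumentError(f"block label {block.label!r} is not a tapping block")
    n = int(np.floor(block.duration * cfg.tap_rate + 1e-9))
    return block.onset + np.arange(n) / cfg.tap_rate


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping of white noise."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _tap_waveform(t_rel: np.ndarray, amp: float, cfg: SimulationConfig) -> np.ndarray:
    """Transient spike + beta burst injected at each tap (t_rel = t - tap time)."""
    spike = amp * np.exp(-0.5 * (t_rel / 0.02) ** 2)
    burst = (
        0.6
        * amp
        * np.exp(-0.5 * ((t_rel - 0.08) / 0.06) ** 2)
        * np.cos(2 * np.pi * cfg.burst_freq * (t_rel - 0.08))
    )
    return spike + burst


def simulate_eeg(
    schedule: EventSchedule,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Synthesize the 8-channel EEG matrix plus the ground-truth tap times.

    Returns ``(eeg, tap_events)`` where ``eeg`` has shape [time x 8] in
    microvolts and ``tap_events`` maps 'tap_left'/'tap_right' to event-time
    arrays. Left-hand taps land on C4, right-hand taps on C3 (contralateral
    motor cortex). Deterministic given the config seed.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = int(round(schedule.total_duration * cfg.eeg_rate))
    n_ch = len(montage.EEG_CHANNELS)
    eeg = np.zeros((n, n_ch))
    if cfg.eeg_noise_std > 0:
        for c in range(n_ch):
            eeg[:, c] = cfg.eeg_noise_std * _pink_noise(n, rng)

    contralateral = {TAP_LEFT: montage.EEG_CHANNELS.index("C4")}
    contralateral[TAP_LABELS[1]] = montage.EEG_CHANNELS.index("C3")
    amps = {TAP_LEFT: cfg.tap_amp_left, TAP_LABELS[1]: cfg.tap_amp_right}

    tap_events: dict[str, list[float]] = {lab: [] for lab in TAP_LABELS}
    half_support = 0.4  # s of waveform evaluated around each tap
    for block in schedule.blocks_with_label(*TAP_LABELS):
        events = simulate_taps(block, cfg)
        tap_events[block.label].extend(events.tolist())
        ch = contralateral[block.label]
        for t0 in events:
            i0 = max(0, int((t0 - half_support) * cfg.eeg_rate))
            i1 = min(n, int((t0 + half_support) * cfg.eeg_rate) + 1)
            t_rel = np.arange(i0, i1) / cfg.eeg_rate - t0
            eeg[i0:i1, ch] += _tap_waveform(t_rel, amps[block.label], cfg)
    return eeg, {lab: np.asarray(v) for lab, v in tap_events.items()}


def block_response(times: np.ndarray, block: TaskBlock, cfg: SimulationConfig) -> np.ndarray:
    """Unit-peak HbO response of one mental block evaluated on a time grid.

    The neural drive starts ``onset_lag`` seconds after the prompt (the delay
    at which HbO is observed to begin rising) and stops at block end. The
    response is a smoothstep rise over ``response_rise`` seconds, a plateau
    until block end, then an exponential washout with time constant
    ``settle_time / 3`` (below 5% of peak at ``settle_time`` after block
    end). Because the response peaks before the block ends and only decays
    afterwards, a purely causal detector can in principle separate every
    rest sample from activity.
    """
    t = np.asarray(times, dtype=float)
    start = block.onset + cfg.onset_lag
    rise_end = min(start + cfg.response_rise, block.end)
    rise = np.clip((t - start) / max(rise_end - start, 1e-9), 0.0, 1.0)
    shape = rise * rise * (3.0 - 2.0 * rise)  # smoothstep
    tau = cfg.settle_time / 3.0  # exp(-3) ~ 5% at settle_time after block end
    after = t > block.end
    u_end = np.clip((block.end - start) / max(rise_end - start, 1e-9), 0.0, 1.0)
    end_val = u_end * u_end * (3.0 - 2.0 * u_end)
    out = shape.copy()
    out[after] = end_val * np.exp(-(t[after] - block.end) / tau)
    return out


def simulate_hemodynamics(
    schedule: EventSchedule,
    cfg: SimulationConfig,
    task_weights: Mapping[str, np.ndarray] = DEFAULT_TASK_WEIGHTS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noise-free ground-truth concentration changes at the NIRS rate.

    Returns ``(times, hbo, hbr)`` with shapes [n] and [n x 12] in micromolar.
    Each mental block contributes its rise-plateau-decay response scaled to
    ``hbo_peak`` and by the task's spatial weight vector across the 12
    channels; HbR is a scaled negative copy of HbO.
    """
    rate = cfg.nirs_rate
    n = int(np.floor(schedule.total_duration * rate + 1e-9))
    times = np.arange(n) / rate
    hbo = np.zeros((n, montage.N_NIRS_CHANNELS))
    for block in schedule.blocks_with_label(*MENTAL_LABELS):
        resp = block_response(times, block, cfg) * cfg.hbo_peak
        hbo += np.outer(resp, np.asarray(task_weights[block.label]))
    hbr = hbo * (cfg.hbr_peak / cfg.hbo_peak)
    return times, hbo, hbr


def forward_mbll(
    hbo: np.ndarray,
    hbr: np.ndarray,
    optics,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Raw detected intensities from concentration truth via the MBLL.

    For each channel and wavelength the optical-density change is
    ``dA = (a_HbO * dcHbO + a_HbR * dcHbR) * l * d(lambda)``; physiological
    sinusoids (cardiac, respiratory, Mayer) and white noise are added in the
    dA domain, and the emitted intensity is
    ``I_out = I_in * exp(-A0 - dA_total)``. Output shape [time x channels x 2].
    """
    from .nirs import OpticsConfig  # local import to avoid a cycle

    if not isinstance(optics, OpticsConfig):
        raise InvalidArgumentError("optics must be an OpticsConfig")
    optics.check_invertible()
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    n, n_ch = hbo.shape
    t = np.arange(n) / cfg.nirs_rate
    ext = optics.extinction  # rows: wavelengths, cols: (HbO, HbR)
    intensity = np.empty((n, n_ch, 2))
    for w in range(2):
        path = optics.l * optics.d[w]
        d_a = (ext[w, 0] * hbo + ext[w, 1] * hbr) * path
        for c in range(n_ch):
            noise = np.zeros(n)
            for amp, freq in (
                (cfg.cardiac_amp, cfg.cardiac_freq),
                (cfg.respiratory_amp, cfg.respiratory_freq),
                (cfg.mayer_amp, cfg.mayer_freq),
            ):
                if amp > 0:
                    noise += amp * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
            if cfg.od_noise_std > 0:
                noise += cfg.od_noise_std * rng.standard_normal(n)
            intensity[:, c, w] = optics.i_in[w] * np.exp(-optics.a0[w] - d_a[:, c] - noise)
    return intensity


@dataclass
class Recording:
    """Time-aligned synthetic session: EEG, raw NIRS intensities and truth."""

    eeg: np.ndarray  # [time x 8] microvolts
    eeg_rate: float
    nirs_intensity: np.ndarray  # [time x 12 x 2] arbitrary units
    nirs_rate: float
    schedule: EventSchedule
    wavelengths: tuple[float, float] = montage.WAVELENGTHS_NM
    eeg_channels: tuple[str, ...] = montage.EEG_CHANNELS
    tap_events: dict[str, np.ndarray] = field(default_factory=dict)
    truth_hbo: np.ndarray | None = None  # [time x 12] micromolar
    truth_hbr: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.eeg.shape[1] != len(montage.EEG_CHANNELS):
            raise InvalidArgumentError(
                f"EEG must have {len(montage.EEG_CHANNELS)} channels, got {self.eeg.shape[1]}"
            )
        if self.nirs_intensity.shape[1:] != (montage.N_NIRS_CHANNELS, 2):
            raise InvalidArgumentError(
                "NIRS intensity must have shape [time x 12 x 2], got "
                f"{self.nirs_intensity.shape}"
            )
        if np.any(self.nirs_intensity <= 0):
            raise InvalidArgumentError("all NIRS intensities must be > 0")

    @property
    def duration(self) -> float:
        return self.schedule.total_duration


def simulate_session(
    cfg: SimulationConfig,
    schedule: EventSchedule | None = None,
    optics=None,
    n_samples: int = 5,
) -> Recording:
    """Generate one full synthetic session (EEG + NIRS + ground truth)."""
    from . import paradigm
    from .nirs import OpticsConfig

    if schedule is None:
        schedule = paradigm.build_session(n_samples)
    if optics is None:
        optics = OpticsConfig()
    rng = np.random.default_rng(cfg.seed)
    eeg, taps = simulate_eeg(schedule, cfg, rng)
    _, hbo, hbr = simulate_hemodynamics(schedule, cfg)
    intensity = forward_mbll(hbo, hbr, optics, cfg, rng)
    return Recording(
        eeg=eeg,
        eeg_rate=cfg.eeg_rate,
        nirs_intensity=intensity,
        nirs_rate=cfg.nirs_rate,
        schedule=schedule,
        tap_events=taps,
        truth_hbo=hbo,
        truth_hbr=hbr,
        seed=cfg.seed,
    )
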