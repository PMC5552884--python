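"""Synthetic cohorts for the confidence-weighted group-decision pipeline.

The generator emulates a rapid visual-search session: 8 blocks of 40 trials
with exactly 25% target prevalence per block, a shared stimulus sequence
across participants, correctness sampled per participant, log-normal
response times that are slower on incorrect trials, and continuous EEG
consisting of background noise plus a biphasic ERP template injected at
stimulus onset and around the response, attenuated on incorrect trials.

Reported confidence (0-100 in steps of 10) tracks correctness when members
are isolated; in the communication condition it is decoupled from
correctness, ERP correct/incorrect differences shrink, and a second
response is produced in which the less confident pair member may conform to
the partner's decision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .channels import EARLOBES, default_channel_names
from .exceptions import ConfigurationError
from .preprocess import ContinuousRecording, EventMarker

logger = logging.getLogger(__name__)

#: Default ERP injection sites (central/parietal midline).
DEFAULT_ERP_CHANNELS: tuple[str, ...] = ("Cz", "CPz", "Pz", "POz", "Oz")


@dataclass(frozen=True)
class RTParams:
    """Log-normal response-time parameters: median (s) and log-scale sigma."""

    median: float
    sigma: float

    def draw(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
        return rng.lognormal(mean=np.log(self.median), sigma=self.sigma, size=size)


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-generation parameters.

    Defaults reproduce the experimental design this pipeline targets:
    8 blocks x 40 trials, 25% targets per block, 64-channel EEG at 2048 Hz,
    an individual error rate around 20% with participant-to-participant
    spread, and incorrect trials that are slower and carry attenuated ERPs.
    """

    n_participants: int = 10
    n_blocks: int = 8
    trials_per_block: int = 40
    target_fraction: float = 0.25
    sampling_rate: float = 2048.0
    n_channels: int = 64
    error_rate: float | Sequence[float] = 0.2
    error_rate_sd: float = 0.08
    rt_correct: RTParams = RTParams(median=0.6, sigma=0.25)
    rt_incorrect: RTParams = RTParams(median=1.0, sigma=0.30)
    erp_amplitude: float = 8.0  # microvolts, template peak
    erp_attenuation_incorrect: float = 0.5
    erp_channels: tuple[str, ...] = DEFAULT_ERP_CHANNELS
    noise_sigma: float = 10.0  # microvolts
    noise_kind: str = "white"  # "white" or "pink"
    communication_mode: bool = False
    communication_erp_shrink: float = 0.4  # fraction of the correct/incorrect
    # ERP difference retained under communication
    communication_amplitude_scale: float = 0.7
    conformity_probability: float = 0.5
    confidence_noise: float = 15.0  # SD on the 0-100 scale
    trial_duration_s: float = 4.0
    stimulus_offset_s: float = 1.3  # stimulus onset within each trial slot
    max_rt_s: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if not 0.0 <= self.target_fraction <= 1.0:
            raise ConfigurationError("target_fraction must lie in [0, 1]")
        n_targets = self.target_fraction * self.trials_per_block
        if abs(n_targets - round(n_targets)) > 1e-9:
            raise ConfigurationError(
                "target_fraction x trials_per_block must be an integer "
                f"(got {n_targets})"
            )
        rates = np.atleast_1d(np.asarray(self.error_rate, dtype=float))
        if np.any((rates < 0) | (rates > 1)):
            raise ConfigurationError("error_rate must lie in [0, 1]")
        if not isinstance(self.error_rate, (int, float)) and len(rates) != self.n_participants:
            raise ConfigurationError("error_rate sequence must have n_participants entries")
        if not 0.0 < self.erp_attenuation_incorrect <= 1.0:
            raise ConfigurationError("erp_attenuation_incorrect must lie in (0, 1]")
        if self.communication_mode and self.n_participants % 2:
            raise ConfigurationError("communication_mode requires an even n_participants")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def targets_per_block(self) -> int:
        return int(round(self.target_fraction * self.trials_per_block))


@dataclass
class SimulatedSession:
    """One participant's synthetic recording plus the behavioural table.

    ``trials`` columns: participant, block, trial, is_target, decision,
    correct, rt, reported_confidence, second_response, stimulus_onset_s,
    response_s, erp_amplitude (the injected ground-truth amplitude).
    """

    participant_id: int
    recording: ContinuousRecording
    trials: pd.DataFrame
    config: SimulationConfig = field(repr=False, default=None)


def _participant_rng(config: SimulationConfig, participant_id: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, 1000 + participant_id]))


def shared_stimulus_sequence(config: SimulationConfig) -> np.ndarray:
    """Boolean target sequence shared by every participant of a cohort.

    Each block holds exactly ``targets_per_block`` targets in a seeded
    random order, mirroring a design where one display sequence is shown to
    all participants.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    blocks = []
    for _ in range(config.n_blocks):
        block = np.zeros(config.trials_per_block, dtype=bool)
        block[: config.targets_per_block] = True
        rng.shuffle(block)
        blocks.append(block)
    return np.concatenate(blocks)


def _participant_error_rates(config: SimulationConfig) -> np.ndarray:
    """Per-participant error rates: explicit sequence, or seeded spread."""
    if not isinstance(config.error_rate, (int, float)):
        return np.asarray(config.error_rate, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rates = rng.normal(float(config.error_rate), config.error_rate_sd, config.n_participants)
    return np.clip(rates, 0.0, 0.95) if config.error_rate_sd > 0 else np.full(
        config.n_participants, float(config.error_rate)
    )


def _erp_template(fs: float, amplitude: float) -> tuple[np.ndarray, np.ndarray]:
    """Biphasic stimulus-locked and response-locked waveforms.

    Stimulus-locked: positive deflection peaking ~350 ms after onset with a
    later negative rebound.  Response-locked: a deflection centred ~100 ms
    before the response.  Returned as (waveform, sample offsets relative to
    the event).
    """
    t = np.arange(0.0, 0.9, 1.0 / fs)
    wave = amplitude * (
        np.exp(-0.5 * ((t - 0.35) / 0.08) ** 2)
        - 0.6 * np.exp(-0.5 * ((t - 0.60) / 0.12) ** 2)
    )
    offsets = np.arange(wave.size)
    tr = np.arange(-0.45, 0.35, 1.0 / fs)
    wave_r = amplitude * (
        np.exp(-0.5 * ((tr + 0.10) / 0.10) ** 2)
        - 0.5 * np.exp(-0.5 * ((tr - 0.15) / 0.12) ** 2)
    )
    offsets_r = np.round(tr * fs).astype(int)
    return (wave, offsets), (wave_r, offsets_r)  # type: ignore[return-value]


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Approximate 1/f noise via spectral shaping of white noise, unit SD."""
    n = shape[1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
    scale[0] = 0.0
    pink = np.fft.irfft(spec * scale, n=n, axis=1)
    return pink / pink.std(axis=1, keepdims=True)


def simulate_trials(
    config: SimulationConfig,
    participant_id: int,
    stimulus_sequence: np.ndarray | None = None,
    error_rate: float | None = None,
) -> pd.DataFrame:
    """Generate the behavioural table for one participant (no EEG).

    Correctness is Bernoulli(1 - error rate) per trial; RTs are log-normal
    with the incorrect-trial distribution shifted slower, resampled (and
    counted in the log) if they exceed the per-trial response window;
    reported confidence is a noisy monotone function of correctness when
    communication is off and correctness-independent when on.
    """
    if stimulus_sequence is None:
        stimulus_sequence = shared_stimulus_sequence(config)
    if error_rate is None:
        error_rate = float(_participant_error_rates(config)[participant_id])
    rng = _participant_rng(config, participant_id)
    n = config.n_trials
    is_target = np.asarray(stimulus_sequence, dtype=bool)
    if is_target.size != n:
        raise ConfigurationError("stimulus sequence length must equal n_trials")

    correct = rng.random(n) >= error_rate
    truth = np.where(is_target, 1, -1)
    decision = np.where(correct, truth, -truth)

    rts = np.empty(n)
    n_resampled = 0
    for i in range(n):
        params = config.rt_correct if correct[i] else config.rt_incorrect
        rt = float(params.draw(rng))
        while rt >= config.max_rt_s:
            rt = float(params.draw(rng))
            n_resampled += 1
        rts[i] = rt
    if n_resampled:
        logger.info(
            "participant %d: resampled %d RT draw(s) exceeding %.1f s",
            participant_id, n_resampled, config.max_rt_s,
        )

    if config.communication_mode:
        latent = 60.0 + rng.normal(0.0, config.confidence_noise, n)
    else:
        latent = np.where(correct, 80.0, 40.0) + rng.normal(0.0, config.confidence_noise, n)
    reported = np.clip(np.round(latent / 10.0) * 10.0, 0.0, 100.0)

    onset = config.stimulus_offset_s + config.trial_duration_s * np.arange(n)
    return pd.DataFrame(
        {
            "participant": participant_id,
            "block": np.repeat(np.arange(config.n_blocks), config.trials_per_block),
            "trial": np.arange(n),
            "is_target": is_target,
            "decision": decision,
            "correct": correct,
            "rt": rts,
            "reported_confidence": reported,
            "second_response": decision,  # overwritten in communication cohorts
            "stimulus_onset_s": onset,
            "response_s": onset + rts,
        }
    )


def _synthesize_eeg(
    config: SimulationConfig, trials: pd.DataFrame, rng: np.random.Generator
) -> ContinuousRecording:
    fs = config.sampling_rate
    scalp = default_channel_names(config.n_channels)
    names = scalp + list(EARLOBES)
    n_samples = int(round(config.n_trials * config.trial_duration_s * fs))
    if config.noise_kind == "pink":
        data = config.noise_sigma * _pink_noise(rng, (len(names), n_samples))
    else:
        data = config.noise_sigma * rng.standard_normal((len(names), n_samples))

    erp_idx = [scalp.index(ch) for ch in config.erp_channels if ch in scalp]
    if not erp_idx:
        erp_idx = [len(scalp) // 2]
    (wave_s, off_s), (wave_r, off_r) = _erp_template(fs, 1.0)

    att = config.erp_attenuation_incorrect
    amp_scale = 1.0
    if config.communication_mode:
        # communication shrinks the correct/incorrect ERP difference and the
        # overall amplitude
        att = 1.0 - (1.0 - att) * config.communication_erp_shrink
        amp_scale = config.communication_amplitude_scale

    amplitudes = np.empty(len(trials))
    events: list[EventMarker] = []
    for row in trials.itertuples():
        a = config.erp_amplitude * amp_scale * (1.0 if row.correct else att)
        amplitudes[row.trial] = a
        s0 = int(round(row.stimulus_onset_s * fs))
        r0 = int(round(row.response_s * fs))
        events.append(EventMarker("stimulus_onset", s0, row.trial))
        events.append(EventMarker("response", r0, row.trial))
        for wave, off, e0 in ((wave_s, off_s, s0), (wave_r, off_r, r0)):
            lo, hi = e0 + off[0], e0 + off[-1] + 1
            if lo < 0 or hi > n_samples:
                continue
            for ci in erp_idx:
                data[ci, lo:hi] += a * wave
    trials["erp_amplitude"] = amplitudes
    return ContinuousRecording(data=data, channel_names=names, sampling_rate=fs, events=events)


def simulate_session(
    config: SimulationConfig,
    participant_id: int = 0,
    stimulus_sequence: np.ndarray | None = None,
    error_rate: float | None = None,
) -> SimulatedSession:
    """Generate one participant's session: behavioural table plus EEG."""
    trials = simulate_trials(config, participant_id, stimulus_sequence, error_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2000 + participant_id]))
    recording = _synthesize_eeg(config, trials, rng)
    return SimulatedSession(
        participant_id=participant_id, recording=recording, trials=trials, config=config
    )


def _apply_communication(
    a: pd.DataFrame, b: pd.DataFrame, rng: np.random.Generator, p_conform: float
) -> None:
    """Second responses for a communicating pair.

    On disagreement the less confident member (ties broken by slower RT,
    then participant order) conforms to the partner with probability
    ``p_conform``; agreements are simply restated.
    """
    second_a = a["decision"].to_numpy().copy()
    second_b = b["decision"].to_numpy().copy()
    disagree = second_a != second_b
    for i in np.flatnonzero(disagree):
        ca, cb = a["reported_confidence"].iat[i], b["reported_confidence"].iat[i]
        if ca < cb or (ca == cb and a["rt"].iat[i] >= b["rt"].iat[i]):
            weaker, other = second_a, second_b
        else:
            weaker, other = second_b, second_a
        if rng.random() < p_conform:
            weaker[i] = other[i]
    a["second_response"] = second_a
    b["second_response"] = second_b


def simulate_cohort(config: SimulationConfig) -> list[SimulatedSession]:
    """Generate a cohort sharing one stimulus sequence.

    With communication on, participants are paired in index order
    ``(0,1), (2,3), ...`` and second responses are produced via the
    conformity rule.
    """
    sequence = shared_stimulus_sequence(config)
    rates = _participant_error_rates(config)
    sessions = [
        simulate_session(config, p, sequence, float(rates[p]))
        for p in range(config.n_participants)
    ]
    if config.communication_mode:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
        for a, b in zip(sessions[::2], sessions[1::2]):
            _apply_communication(a.trials, b.trials, rng, config.conformity_probability)
    return sessions
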