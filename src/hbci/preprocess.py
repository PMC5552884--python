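"""EEG conditioning: re-referencing, filtering, ocular correction, epoching.

The chain mirrors a standard rapid-decision ERP pipeline: earlobe-average
re-referencing, a long linear-phase FIR band-pass (0.15-40 Hz), regression
removal of ocular activity against the mean of the Fp1-F1 and Fp2-F2
derivations, extraction of 1900 ms stimulus-locked and response-locked
epochs, and per-epoch conditioning (linear detrend, 14/16 Hz equiripple
low-pass, trim to the central 1500 ms, decimation to 32 Hz) yielding exactly
48 samples per channel.

All filters are applied forward with symmetric (odd-length, linear-phase)
kernels and ``mode='same'`` convolution, so the net group delay is zero and
event latencies are preserved.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import signal as sps

from .channels import EARLOBES, OCULAR_CHANNELS
from .exceptions import ChannelSetError, InputError

logger = logging.getLogger(__name__)

#: Output sampling rate of conditioned epochs, Hz.
EPOCH_RATE = 32
#: Samples per channel in a conditioned epoch (1.5 s at 32 Hz).
EPOCH_SAMPLES = 48
#: Raw epoch duration, seconds.
RAW_EPOCH_S = 1.9
#: Pre-event offsets for the two lock types, seconds.
PRE_STIMULUS_S = 0.2
PRE_RESPONSE_S = 1.2
#: Band-pass defaults.
BANDPASS_LOW_HZ = 0.15
BANDPASS_HIGH_HZ = 40.0
BANDPASS_TAPS_2048 = 14677
#: Epoch low-pass band edges (equiripple design).
LOWPASS_PASS_HZ = 14.0
LOWPASS_STOP_HZ = 16.0

Lock = Literal["stimulus", "response"]


@dataclass(frozen=True)
class EventMarker:
    """A stimulus-onset or response marker at a sample index."""

    kind: Literal["stimulus_onset", "response"]
    sample_index: int
    trial_index: int


@dataclass
class ContinuousRecording:
    """Multichannel EEG in microvolts with 10-20 channel names and events.

    ``data`` is ``(n_channels, n_samples)``; ``events`` carry sample-exact
    stimulus-onset and response markers per trial.
    """

    data: np.ndarray
    channel_names: list[str]
    sampling_rate: float
    events: list[EventMarker] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InputError("data must be (n_channels, n_samples)")
        if len(self.channel_names) != self.data.shape[0]:
            raise InputError("channel_names length must match data rows")
        if self.sampling_rate <= 0:
            raise InputError("sampling_rate must be positive")
        n = self.data.shape[1]
        for ev in self.events:
            if not 0 <= ev.sample_index < n:
                raise InputError(
                    f"event at sample {ev.sample_index} outside recording of {n} samples"
                )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise ChannelSetError(f"channel {name!r} not in recording") from None

    def drop_channels(self, names: Iterable[str]) -> "ContinuousRecording":
        drop = set(names)
        keep = [i for i, ch in enumerate(self.channel_names) if ch not in drop]
        return replace(
            self,
            data=self.data[keep],
            channel_names=[self.channel_names[i] for i in keep],
            events=list(self.events),
        )


@dataclass
class ProcessedEpoch:
    """A conditioned epoch: ``(n_channels, 48)`` at 32 Hz, microvolts."""

    data: np.ndarray
    lock: Lock
    trial_index: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != EPOCH_SAMPLES:
            raise InputError(
                f"epoch must be (n_channels, {EPOCH_SAMPLES}); got {self.data.shape}"
            )


@dataclass
class EpochSet:
    """Conditioned stimulus- and response-locked epochs for one session."""

    stimulus: np.ndarray  # (n_trials, n_channels, 48)
    response: np.ndarray  # (n_trials, n_channels, 48)
    trial_indices: np.ndarray  # original trial indices of retained trials
    channel_names: list[str]
    excluded: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Referencing and artefact removal
# ---------------------------------------------------------------------------

def rereference_earlobes(
    rec: ContinuousRecording, earlobes: Sequence[str] = EARLOBES
) -> ContinuousRecording:
    """Subtract the mean of the two earlobe channels from every channel.

    The earlobe channels remain in the output (identically zero after the
    first pass, which makes the operation idempotent); drop them with
    :meth:`ContinuousRecording.drop_channels` before feature extraction.
    """
    idx = [rec.channel_index(ch) for ch in earlobes]
    ref = rec.data[idx].mean(axis=0)
    data = rec.data - ref
    data[idx] = 0.0  # reference channels carry no signal of their own now
    return replace(rec, data=data, events=list(rec.events))


def remove_ocular(
    rec: ContinuousRecording, proxy_channels: Sequence[str] = OCULAR_CHANNELS
) -> ContinuousRecording:
    """Regress the ocular proxy out of every channel.

    The proxy is the average of the Fp1-F1 and Fp2-F2 bipolar derivations;
    each channel has its least-squares projection onto the (mean-centred)
    proxy subtracted, leaving every channel uncorrelated with it.
    """
    fp1, f1, fp2, f2 = (rec.channel_index(ch) for ch in proxy_channels)
    o = 0.5 * ((rec.data[fp1] - rec.data[f1]) + (rec.data[fp2] - rec.data[f2]))
    oc = o - o.mean()
    var_o = float(oc @ oc)
    if var_o == 0.0:
        logger.warning("ocular proxy has zero variance; recording returned unchanged")
        return replace(rec, data=rec.data.copy(), events=list(rec.events))
    beta = (rec.data - rec.data.mean(axis=1, keepdims=True)) @ oc / var_o
    return replace(rec, data=rec.data - np.outer(beta, oc), events=list(rec.events))


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def default_bandpass_taps(sampling_rate: float) -> int:
    """Tap count for the band-pass FIR: 14677 at 2048 Hz, scaled pro rata.

    Scaling with the sampling rate keeps the transition width in hertz
    constant across rates; the count is forced odd for exact linear phase.
    """
    n = int(round(BANDPASS_TAPS_2048 * sampling_rate / 2048.0))
    return n | 1


def _apply_fir(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    # symmetric odd-length kernel + 'same' convolution = zero net group delay
    return sps.fftconvolve(data, taps[None, :], mode="same", axes=-1)


def bandpass_filter(
    rec: ContinuousRecording,
    low: float = BANDPASS_LOW_HZ,
    high: float = BANDPASS_HIGH_HZ,
    n_taps: int | None = None,
) -> ContinuousRecording:
    """Linear-phase FIR band-pass, zero net group delay.

    Signals shorter than the kernel are implicitly zero-padded by the
    ``same``-mode convolution.
    """
    fs = rec.sampling_rate
    if fs <= 2 * high:
        raise InputError(f"sampling rate {fs} Hz too low for a {high} Hz band edge")
    if n_taps is None:
        n_taps = default_bandpass_taps(fs)
    if n_taps % 2 == 0:
        raise InputError("n_taps must be odd for a zero-delay linear-phase filter")
    # difference of two unit-DC-gain low-passes: exact null at DC, so drift
    # and offsets are fully rejected even though the 0.15 Hz edge is narrow
    taps = sps.firwin(n_taps, high, fs=fs) - sps.firwin(n_taps, low, fs=fs)
    return replace(rec, data=_apply_fir(rec.data, taps), events=list(rec.events))


@lru_cache(maxsize=8)
def _remez_lowpass_taps(fs: float, pass_hz: float, stop_hz: float) -> np.ndarray:
    """Equiripple low-pass (Remez exchange), >=40 dB stop-band, odd length."""
    atten_db = 48.0  # design margin so the achieved stop band clears 40 dB
    delta_f = (stop_hz - pass_hz) / fs
    n = int(math.ceil((atten_db - 13.0) / (14.6 * delta_f))) | 1  # fred harris
    return sps.remez(n, [0.0, pass_hz, stop_hz, fs / 2.0], [1.0, 0.0], fs=fs)


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------

def raw_epoch_samples(sampling_rate: float) -> int:
    """Samples in a raw 1900 ms epoch (ceil: 3892 at 2048 Hz)."""
    return int(math.ceil(RAW_EPOCH_S * sampling_rate))


def extract_epochs(rec: ContinuousRecording) -> "RawEpochs":
    """Cut raw 1900 ms stimulus- and response-locked windows per trial.

    Stimulus-locked windows span [-200, +1700) ms around stimulus onset;
    response-locked windows span [-1200, +700) ms around the response.
    Trials whose windows cross a recording edge, or that lack a response
    marker, are excluded and logged.
    """
    fs = rec.sampling_rate
    n_ep = raw_epoch_samples(fs)
    pre_stim = int(round(PRE_STIMULUS_S * fs))
    pre_resp = int(round(PRE_RESPONSE_S * fs))
    stim_at: dict[int, int] = {}
    resp_at: dict[int, int] = {}
    for ev in rec.events:
        at = stim_at if ev.kind == "stimulus_onset" else resp_at
        if ev.trial_index in at:
            raise InputError(f"duplicate {ev.kind} marker for trial {ev.trial_index}")
        at[ev.trial_index] = ev.sample_index

    stim_list, resp_list, kept, excluded = [], [], [], []
    for trial in sorted(stim_at):
        starts = []
        if trial in resp_at:
            if resp_at[trial] < stim_at[trial]:
                raise InputError(f"response precedes stimulus in trial {trial}")
            starts = [stim_at[trial] - pre_stim, resp_at[trial] - pre_resp]
        if not starts or any(s < 0 or s + n_ep > rec.n_samples for s in starts):
            excluded.append(trial)
            continue
        stim_list.append(rec.data[:, starts[0] : starts[0] + n_ep])
        resp_list.append(rec.data[:, starts[1] : starts[1] + n_ep])
        kept.append(trial)
    if excluded:
        logger.info("extract_epochs: excluded %d trial(s): %s", len(excluded), excluded)
    shape = (0, rec.data.shape[0], n_ep)
    return RawEpochs(
        stimulus=np.stack(stim_list) if stim_list else np.empty(shape),
        response=np.stack(resp_list) if resp_list else np.empty(shape),
        trial_indices=np.asarray(kept, dtype=int),
        sampling_rate=fs,
        channel_names=list(rec.channel_names),
        excluded=excluded,
    )


@dataclass
class RawEpochs:
    """Raw (acquisition-rate) epochs for one session, both lock types."""

    stimulus: np.ndarray  # (n_trials, n_channels, n_raw_samples)
    response: np.ndarray
    trial_indices: np.ndarray
    sampling_rate: float
    channel_names: list[str]
    excluded: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Epoch conditioning
# ---------------------------------------------------------------------------

def condition_epochs(
    epochs: np.ndarray,
    sampling_rate: float,
    pass_hz: float = LOWPASS_PASS_HZ,
    stop_hz: float = LOWPASS_STOP_HZ,
) -> np.ndarray:
    """Detrend, low-pass, trim to 1500 ms and decimate to 32 Hz.

    ``epochs`` is ``(..., n_channels, n_raw_samples)``; the result has
    exactly :data:`EPOCH_SAMPLES` samples on the last axis.  The sampling
    rate must be an integer multiple of 32 Hz and large enough that the raw
    epoch contains the central 1500 ms.
    """
    fs = sampling_rate
    decim = fs / EPOCH_RATE
    if decim != int(decim) or decim < 1:
        raise InputError(f"sampling rate {fs} must be an integer multiple of {EPOCH_RATE} Hz")
    decim = int(decim)
    core = EPOCH_SAMPLES * decim  # 1500 ms
    n_in = epochs.shape[-1]
    if n_in < core:
        raise InputError(f"epoch of {n_in} samples too short for {core}-sample core")
    x = sps.detrend(np.asarray(epochs, dtype=float), axis=-1, type="linear")
    if decim > 1:
        taps = _remez_lowpass_taps(fs, pass_hz, stop_hz)
        flat = x.reshape(-1, n_in)
        flat = sps.fftconvolve(flat, taps[None, :], mode="same", axes=-1)
        x = flat.reshape(x.shape)
    left = (n_in - core) // 2
    x = x[..., left : left + core]
    return x[..., ::decim]


def condition_epoch(
    epoch: np.ndarray,
    sampling_rate: float,
    lock: Lock = "stimulus",
    trial_index: int = 0,
) -> ProcessedEpoch:
    """Condition a single raw ``(n_channels, n_samples)`` epoch."""
    data = condition_epochs(np.asarray(epoch, dtype=float)[None], sampling_rate)[0]
    return ProcessedEpoch(data=data, lock=lock, trial_index=trial_index)


# ---------------------------------------------------------------------------
# Full per-session chain
# ---------------------------------------------------------------------------

def preprocess_recording(
    rec: ContinuousRecording,
    bandpass: tuple[float, float] = (BANDPASS_LOW_HZ, BANDPASS_HIGH_HZ),
    n_taps: int | None = None,
    ocular: bool = True,
    earlobes: Sequence[str] = EARLOBES,
) -> EpochSet:
    """Run the full chain: re-reference, band-pass, ocular removal, epoch, condition."""
    rec = rereference_earlobes(rec, earlobes)
    rec = rec.drop_channels(earlobes)
    rec = bandpass_filter(rec, bandpass[0], bandpass[1], n_taps)
    if ocular:
        rec = remove_ocular(rec)
    raw = extract_epochs(rec)
    return EpochSet(
        stimulus=condition_epochs(raw.stimulus, raw.sampling_rate),
        response=condition_epochs(raw.response, raw.sampling_rate),
        trial_indices=raw.trial_indices,
        channel_names=raw.channel_names,
        excluded=raw.excluded,
    )
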