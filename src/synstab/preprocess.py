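"""EMG preprocessing: rectification, zero-phase low-pass filtering,
experiment-wide amplitude normalization, and perturbation-window extraction.

The chain turns raw multichannel surface EMG recorded around a support-surface
perturbation into the non-negative m x t activation matrix that is fed to the
synergy factorization.  Defaults mirror a typical automatic-posture-response
protocol: 1 kHz sampling, 32 Hz envelope cutoff, and a 160 ms analysis window
opening 40 ms after the perturbation trigger (the average EMG response
latency).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "EMGRecording",
    "ActivationMatrix",
    "DegenerateChannelError",
    "rectify",
    "lowpass",
    "normalize_emg",
    "extract_window",
    "DEFAULT_CUTOFF_HZ",
    "DEFAULT_FILTER_ORDER",
    "DEFAULT_LATENCY_MS",
    "DEFAULT_WINDOW_MS",
]

DEFAULT_CUTOFF_HZ = 32.0
DEFAULT_FILTER_ORDER = 4
DEFAULT_LATENCY_MS = 40.0
DEFAULT_WINDOW_MS = 160.0


class DegenerateChannelError(ValueError):
    """A muscle channel is identically zero where a positive amplitude is required."""


@dataclass(frozen=True)
class EMGRecording:
    """Multichannel EMG for one trial.

    Parameters
    ----------
    samples
        ``(channels, time)`` array.  Raw EMG may be signed; after
        rectification all entries are non-negative.
    rate
        Sampling frequency in Hz.
    muscles
        Ordered channel labels, one per row of ``samples``.
    trigger_time
        Perturbation onset in seconds from the start of the recording,
        or ``None`` if the trial carries no trigger.
    """

    samples: np.ndarray
    rate: float
    muscles: tuple[str, ...]
    trigger_time: float | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        if samples.shape[0] < 1 or samples.shape[1] < 2:
            raise ValueError("need at least 1 channel and 2 samples")
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")
        muscles = tuple(self.muscles)
        if len(muscles) != samples.shape[0]:
            raise ValueError("one muscle label per channel is required")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "muscles", muscles)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.rate


@dataclass(frozen=True)
class ActivationMatrix:
    """Non-negative m x t activation matrix M extracted from one trial.

    ``window`` records ``(start_ms, duration_ms)`` relative to the trigger so
    downstream reports can state exactly which slice of the response was
    analyzed.
    """

    values: np.ndarray
    rate: float
    muscles: tuple[str, ...] = field(default=())
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D (muscles x time) array")
        if np.any(values < 0):
            raise ValueError("activation matrix entries must be non-negative")
        muscles = tuple(self.muscles) if self.muscles else tuple(
            f"ch{i}" for i in range(values.shape[0])
        )
        if len(muscles) != values.shape[0]:
            raise ValueError("one muscle label per row is required")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "muscles", muscles)

    @property
    def m(self) -> int:
        """Number of muscles."""
        return self.values.shape[0]

    @property
    def t(self) -> int:
        """Number of time samples."""
        return self.values.shape[1]


def rectify(rec: EMGRecording) -> EMGRecording:
    """Full-wave rectify: replace every sample by its absolute value."""
    return replace(rec, samples=np.abs(rec.samples))


def lowpass(
    rec: EMGRecording,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
) -> EMGRecording:
    """Zero-phase Butterworth low-pass of every channel.

    The filter is applied forward and backward (``filtfilt``) so the envelope
    is not delayed relative to the perturbation trigger; response-latency
    bookkeeping stays valid.

    Raises
    ------
    ValueError
        If ``cutoff_hz`` is not strictly between 0 and the Nyquist frequency.
    """
    nyquist = rec.rate / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist} Hz)"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=rec.rate, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=1)
    return replace(rec, samples=filtered)


def normalize_emg(
    recs: list[EMGRecording], mode: str = "max"
) -> list[EMGRecording]:
    """Divide each muscle by its experiment-wide reference amplitude.

    All recordings must share the same muscle ordering.  With the default
    ``mode="max"`` the reference is the muscle's maximum processed amplitude
    over all supplied trials, so the per-muscle maximum over the set equals 1
    and all entries lie in [0, 1].  ``mode="mean-of-maxima"`` instead uses the
    mean across trials of the per-trial maxima (entries may then exceed 1 on
    the strongest trial).

    Raises
    ------
    DegenerateChannelError
        If some muscle is identically zero in every supplied recording.
    """
    if not recs:
        raise ValueError("need at least one recording")
    muscles = recs[0].muscles
    for rec in recs[1:]:
        if rec.muscles != muscles:
            raise ValueError("all recordings must share the same muscle ordering")
    per_trial_maxima = np.array([np.max(rec.samples, axis=1) for rec in recs])
    if mode == "max":
        maxima = per_trial_maxima.max(axis=0)
    elif mode == "mean-of-maxima":
        maxima = per_trial_maxima.mean(axis=0)
    else:
        raise ValueError(f"unknown normalization mode: {mode!r}")
    dead = np.flatnonzero(maxima <= 0)
    if dead.size:
        names = ", ".join(muscles[i] for i in dead)
        raise DegenerateChannelError(
            f"muscle(s) identically zero across the experiment: {names}"
        )
    return [replace(rec, samples=rec.samples / maxima[:, None]) for rec in recs]


def extract_window(
    rec: EMGRecording,
    latency_ms: float = DEFAULT_LATENCY_MS,
    duration_ms: float = DEFAULT_WINDOW_MS,
) -> ActivationMatrix:
    """Cut the post-perturbation analysis window into an activation matrix.

    The window starts ``latency_ms`` after the trigger and spans
    ``duration_ms``; samples are taken from the half-open interval
    ``[start, start + t)`` with ``t = round(duration_ms * rate / 1000)``.

    Raises
    ------
    ValueError
        If the recording has no trigger or the window falls outside it.
    """
    if rec.trigger_time is None:
        raise ValueError("recording has no trigger_time; cannot place the window")
    start = int(round((rec.trigger_time + latency_ms / 1000.0) * rec.rate))
    t = int(round(duration_ms * rec.rate / 1000.0))
    if start < 0 or start + t > rec.n_samples or t < 1:
        raise ValueError(
            f"window [{start}, {start + t}) exceeds recording of "
            f"{rec.n_samples} samples"
        )
    values = rec.samples[:, start : start + t]
    if np.any(values < 0):
        warnings.warn(
            "negative samples in analysis window; was the recording rectified?",
            stacklevel=2,
        )
        values = np.clip(values, 0.0, None)
    return ActivationMatrix(
        values=values,
        rate=rec.rate,
        muscles=rec.muscles,
        window=(latency_ms, duration_ms),
    )
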