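"""Epoching, filtering, artifact-trial rejection and channel exclusion.

The preprocessing contract mirrors a standard MEG task pipeline: continuous
multichannel recordings are epoched around stimulus onsets into fixed-length
trials (default window -0.5 to +4 s), low-pass filtered below 250 Hz with a
zero-phase 4th-order Butterworth filter, screened for high-amplitude artifact
trials, and stripped of known-bad sensors.

Conventions: sample indexing is 0-based; segment intervals are half-open
``[start, end)`` in seconds relative to stimulus onset; trial time axes start
at ``t0`` (default -0.5 s).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

#: Default stage boundaries (seconds relative to stimulus onset, half-open).
DEFAULT_SEGMENTS: dict[str, tuple[float, float]] = {
    "pre": (-0.5, 0.0),
    "perception": (0.0, 1.0),
    "preparation": (1.0, 2.0),
    "production": (2.0, 4.0),
}

STAGES = tuple(DEFAULT_SEGMENTS)


@dataclass
class Recording:
    """A continuous multichannel recording with stimulus events.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Sensor time series (arbitrary units for synthetic data).
    fs : float
        Sampling rate in Hz.
    channel_ids : list of str
        Unique sensor identifiers, one per row of ``signal``.
    events : list of (int, int)
        ``(sample_index, class_label)`` stimulus onsets.
    """

    signal: np.ndarray
    fs: float
    channel_ids: list[str]
    events: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel_ids must be unique")
        if self.signal.shape[0] != len(self.channel_ids):
            raise ValueError("signal rows must match channel_ids")
        n = self.signal.shape[1]
        for s, _ in self.events:
            if not 0 <= s < n:
                raise ValueError(f"event sample {s} outside recording")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass
class Trial:
    """One epoched multichannel trial.

    ``segments`` maps stage name to a half-open ``[start, end)`` interval in
    seconds relative to stimulus onset; together the stages tile
    ``[t0, t0 + duration)``.  ``provenance`` is either
    ``{"kind": "original"}`` or
    ``{"kind": "augmented", "parent": <trial_id>, "shift_ms": <float>}``.
    """

    signal: np.ndarray
    fs: float
    label: int
    subject: int = 0
    t0: float = -0.5
    segments: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SEGMENTS)
    )
    provenance: dict = field(default_factory=lambda: {"kind": "original"})
    trial_id: str = ""
    channel_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("trial signal must be 2-D (channels x samples)")
        if not self.channel_ids:
            self.channel_ids = [f"ch{i:03d}" for i in range(self.signal.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def time_to_sample(self, t: float) -> int:
        """Sample index of time ``t`` (seconds relative to stimulus onset)."""
        return int(round((t - self.t0) * self.fs))

    def segment_slice(self, segment: str | tuple[float, float]) -> slice:
        """Half-open sample slice of a named stage or ``(start, end)`` pair."""
        if isinstance(segment, str):
            if segment not in self.segments:
                raise KeyError(
                    f"unknown segment {segment!r}; have {sorted(self.segments)}"
                )
            start, end = self.segments[segment]
        else:
            start, end = segment
        i0 = max(self.time_to_sample(start), 0)
        i1 = min(self.time_to_sample(end), self.n_samples)
        if i1 <= i0:
            raise ValueError(f"segment {segment!r} is empty within this trial")
        return slice(i0, i1)

    def segment_signal(self, segment: str | tuple[float, float]) -> np.ndarray:
        return self.signal[:, self.segment_slice(segment)]


def epoch_trials(
    rec: Recording,
    window: tuple[float, float] = (-0.5, 4.0),
    segments: dict[str, tuple[float, float]] | None = None,
    subject: int = 0,
) -> tuple[list[Trial], list[dict]]:
    """Cut one fixed-length trial per stimulus event.

    Events whose window falls outside the recording are skipped and logged
    (returned as the second element) rather than raising.

    Returns
    -------
    trials : list of Trial
    skipped : list of dict
        One entry per skipped event: ``{"event_sample", "label", "reason"}``.
    """
    t_start, t_end = window
    if t_end <= t_start:
        raise ValueError("window end must exceed window start")
    n_win = int(round((t_end - t_start) * rec.fs))
    segments = dict(DEFAULT_SEGMENTS) if segments is None else dict(segments)

    trials: list[Trial] = []
    skipped: list[dict] = []
    for k, (onset, label) in enumerate(rec.events):
        i0 = onset + int(round(t_start * rec.fs))
        i1 = i0 + n_win
        if i0 < 0 or i1 > rec.n_samples:
            skipped.append(
                {"event_sample": onset, "label": label, "reason": "window out of bounds"}
            )
            continue
        trials.append(
            Trial(
                signal=rec.signal[:, i0:i1].copy(),
                fs=rec.fs,
                label=label,
                subject=subject,
                t0=t_start,
                segments=dict(segments),
                trial_id=f"s{subject}_t{k:04d}",
                channel_ids=list(rec.channel_ids),
            )
        )
    return trials, skipped


def lowpass_filter(
    x: np.ndarray, fs: float, cutoff: float = 250.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth low-pass of a (channels x samples) array.

    Applied forward-backward (``sosfiltfilt``) so segment boundaries are not
    shifted by filter latency; the effective magnitude response is the squared
    single-pass response.
    """
    if cutoff >= fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist ({fs / 2} Hz)")
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def filter_trials(trials: list[Trial], cutoff: float = 250.0, order: int = 4) -> list[Trial]:
    """Return new trials with each signal low-pass filtered."""
    out = []
    for tr in trials:
        tr2 = copy.copy(tr)
        tr2.signal = lowpass_filter(tr.signal, tr.fs, cutoff=cutoff, order=order)
        out.append(tr2)
    return out


def robust_peak_threshold(trials: list[Trial], n_mads: float = 6.0) -> np.ndarray:
    """Per-channel peak threshold as ``n_mads`` robust SDs (1.4826 x MAD).

    Stands in for the visual artifact screening of a human reviewer when no
    absolute sensor units are available.
    """
    stacked = np.concatenate([t.signal for t in trials], axis=1)
    med = np.median(stacked, axis=1, keepdims=True)
    mad = np.median(np.abs(stacked - med), axis=1)
    return n_mads * 1.4826 * mad


def reject_trials(
    trials: list[Trial],
    peak_threshold: float | np.ndarray | None = None,
    flat_threshold: float = 0.0,
) -> tuple[list[Trial], pd.DataFrame]:
    """Drop trials with excessive peaks or flat channels.

    A trial is removed iff any channel's peak absolute amplitude exceeds
    ``peak_threshold`` (scalar or per-channel vector; default 6 robust SDs
    estimated from the data) or any channel's peak-to-peak range falls below
    ``flat_threshold``.  Surviving trials are returned unmodified
    (bit-identical).  The log has columns (trial_id, reason, channel, value).
    """
    if flat_threshold < 0:
        raise ValueError("flat_threshold must be >= 0")
    if peak_threshold is None:
        peak_threshold = robust_peak_threshold(trials) if trials else np.inf
    thr = np.asarray(peak_threshold, dtype=float)

    kept: list[Trial] = []
    rows: list[dict] = []
    for tr in trials:
        peaks = np.max(np.abs(tr.signal), axis=1)
        ptp = np.ptp(tr.signal, axis=1)
        bad_peak = np.nonzero(peaks > thr)[0] if np.ndim(thr) else np.nonzero(peaks > float(thr))[0]
        bad_flat = np.nonzero(ptp < flat_threshold)[0]
        if bad_peak.size:
            c = int(bad_peak[np.argmax(peaks[bad_peak])])
            rows.append(
                {"trial_id": tr.trial_id, "reason": "peak", "channel": tr.channel_ids[c],
                 "value": float(peaks[c])}
            )
        elif bad_flat.size:
            c = int(bad_flat[0])
            rows.append(
                {"trial_id": tr.trial_id, "reason": "flat", "channel": tr.channel_ids[c],
                 "value": float(ptp[c])}
            )
        else:
            kept.append(tr)
    log = pd.DataFrame(rows, columns=["trial_id", "reason", "channel", "value"])
    return kept, log


def exclude_channels(obj, bad_ids: list[str]):
    """Remove sensors by id from a Recording, a Trial, or a list of trials.

    Preserves the ordering of the remaining channels; raises on unknown ids.
    """
    if isinstance(obj, list):
        return [exclude_channels(t, bad_ids) for t in obj]
    ids = obj.channel_ids
    unknown = [b for b in bad_ids if b not in ids]
    if unknown:
        raise ValueError(f"unknown channel ids: {unknown}")
    keep = [i for i, c in enumerate(ids) if c not in set(bad_ids)]
    out = copy.copy(obj)
    out.signal = obj.signal[keep, :].copy()
    out.channel_ids = [ids[i] for i in keep]
    return out
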