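"""Synthetic MEG-like phrase experiments.

Generates labeled multichannel trials with the statistical structure a
phrase-decoding analysis assumes: a delayed-reading trial layout
(pre-stimulus rest, perception, preparation, production), class-specific
band-limited oscillatory signatures concentrated on sensor subsets, 1/f
background noise, optional blink/cardiac-like artifacts, and reaction-time
jitter of the production onset.

The model deliberately abstracts the physics: channels are indices with no
geometry, noise has unit SD per channel, and class signal is a sum of
amplitude-modulated sinusoidal carriers (Hann on/offsets) whose per-channel
amplitudes are expressed in noise-SD units.  A stage's signal-to-noise ratio
is then simply the multichannel RMS of the injected signal within that stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import DEFAULT_SEGMENTS, Trial
from .wavelets import NOMINAL_RANGES_HZ

STAGE_ORDER = ("pre", "perception", "preparation", "production")


@dataclass
class SynthConfig:
    """Study-level configuration for the synthetic experiment.

    Defaults emulate the recording conditions the analysis targets: 1 kHz
    sampling, 196 gradiometer-like channels, five phrase classes, trials
    -0.5 to +4 s around stimulus onset, and a stage SNR ordering
    production > preparation > perception with silent pre-stimulus rest.
    """

    n_subjects: int = 1
    n_trials_per_class: int = 50
    n_classes: int = 5
    n_channels: int = 196
    fs: float = 1000.0
    segment_durations: dict[str, float] = field(
        default_factory=lambda: {
            "pre": 0.5, "perception": 1.0, "preparation": 1.0, "production": 2.0,
        }
    )
    stage_snr: dict[str, float] = field(
        default_factory=lambda: {
            "pre": 0.0, "perception": 0.5, "preparation": 0.8, "production": 1.2,
        }
    )
    noise_exponent: float = 1.0
    noise_sd: float = 1.0  # 0 disables noise; SNR semantics assume 1
    artifact_rate: float = 0.0
    reaction_jitter_mean: float = 0.25
    reaction_jitter_sd: float = 0.1
    carryover_gain: float = 0.0
    edge_ramp_frac: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_subjects", "n_trials_per_class", "n_classes", "n_channels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if any(d <= 0 for d in self.segment_durations.values()):
            raise ValueError("segment durations must be positive")
        if any(v < 0 for v in self.stage_snr.values()):
            raise ValueError("stage_snr values must be >= 0")
        if not 0 <= self.noise_exponent <= 2:
            raise ValueError("noise_exponent must lie in [0, 2]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.carryover_gain <= 1:
            raise ValueError("carryover_gain must lie in [0, 1]")
        if not 0 <= self.edge_ramp_frac < 0.5:
            raise ValueError("edge_ramp_frac must lie in [0, 0.5)")

    @property
    def trial_duration(self) -> float:
        return sum(self.segment_durations.values())

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_duration * self.fs))

    def segments(self) -> dict[str, tuple[float, float]]:
        """Stage intervals in seconds relative to stimulus onset."""
        t = -self.segment_durations["pre"]
        out = {}
        for stage in STAGE_ORDER:
            d = self.segment_durations[stage]
            out[stage] = (t, t + d)
            t += d
        return out


@dataclass
class ClassSignature:
    """Spatio-spectral content of one phrase class.

    ``components`` maps a band label to ``(carrier_hz, amplitudes)`` where
    ``amplitudes`` is a per-channel vector in noise-SD units.  ``stage_gains``
    multiplies the config's per-stage SNR (default 1 for every stage), letting
    individual classes modulate their strength per stage.
    """

    class_id: int
    components: dict[str, tuple[float, np.ndarray]]
    stage_gains: dict[str, float] = field(default_factory=dict)

    def validate(self, n_channels: int, fs: float) -> None:
        for band, (f, amps) in self.components.items():
            if band not in NOMINAL_RANGES_HZ:
                raise ValueError(f"unknown band {band!r}")
            lo, hi = NOMINAL_RANGES_HZ[band]
            if not lo < f < hi:
                raise ValueError(
                    f"carrier {f} Hz not strictly inside {band} band ({lo}-{hi} Hz)"
                )
            if f >= fs / 2:
                raise ValueError(f"carrier {f} Hz >= Nyquist ({fs / 2} Hz)")
            if np.asarray(amps).shape != (n_channels,):
                raise ValueError("amplitude vector length must equal n_channels")

    def gain(self, stage: str) -> float:
        return self.stage_gains.get(stage, 1.0)


def make_random_signatures(
    config: SynthConfig,
    n_active_channels: int = 6,
    bands: tuple[str, ...] = ("theta", "alpha", "beta", "gamma", "high_gamma"),
    rng: np.random.Generator | None = None,
) -> list[ClassSignature]:
    """Draw one distinct signature per class, normalized to unit SNR.

    Each class activates two bands on a random sparse channel subset; the
    joint waveform is scaled so its multichannel RMS (over all channels, flat
    envelope) is 1.  With unit-SD noise, a stage gain of ``g`` then realizes
    a within-stage SNR of ``g``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    sigs = []
    for k in range(config.n_classes):
        chosen = [bands[k % len(bands)], bands[(k + 2) % len(bands)]]
        comps: dict[str, tuple[float, np.ndarray]] = {}
        raw_power = 0.0
        for band in dict.fromkeys(chosen):
            lo, hi = NOMINAL_RANGES_HZ[band]
            f = float(rng.uniform(lo + 0.15 * (hi - lo), hi - 0.15 * (hi - lo)))
            amps = np.zeros(config.n_channels)
            idx = rng.choice(config.n_channels, size=min(n_active_channels, config.n_channels),
                             replace=False)
            amps[idx] = rng.uniform(0.5, 1.0, size=idx.size)
            comps[band] = (f, amps)
            raw_power += float(np.sum(amps**2)) / 2.0
        # multichannel RMS = sqrt(sum_c a_c^2 / 2 / C); rescale to 1
        scale = 1.0 / math.sqrt(raw_power / config.n_channels)
        comps = {b: (f, a * scale) for b, (f, a) in comps.items()}
        sigs.append(ClassSignature(class_id=k, components=comps))
    return sigs


def background_noise(
    n_channels: int,
    n_samples: int,
    fs: float,
    exponent: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Mutually independent channels of 1/f^exponent noise, unit SD each.

    Shaped in the frequency domain: white Gaussian spectra are multiplied by
    ``f^(-exponent/2)`` (DC term reuses the first nonzero frequency's weight
    to avoid a divergent mean) and inverse-transformed.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if not 0 <= exponent <= 2:
        raise ValueError("exponent must lie in [0, 2]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    weights = np.empty_like(freqs)
    weights[1:] = freqs[1:] ** (-exponent / 2.0)
    weights[0] = weights[1]
    spec = (rng.standard_normal((n_channels, freqs.size))
            + 1j * rng.standard_normal((n_channels, freqs.size))) * weights
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    x -= x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _stage_envelope(n: int, ramp_frac: float) -> np.ndarray:
    """Flat envelope with Hann on/offsets covering ``ramp_frac`` of each end."""
    env = np.ones(n)
    r = int(round(ramp_frac * n))
    if r > 0:
        ramp = np.hanning(2 * r)[:r]
        env[:r] = ramp
        env[-r:] = ramp[::-1]
    return env


def _render_signature(
    sig: ClassSignature,
    config: SynthConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Class signal for one trial (channels x samples), before noise."""
    n = config.n_samples
    fs = config.fs
    out = np.zeros((config.n_channels, n))
    segs = config.segments()
    t0 = segs["pre"][0]

    jitter = 0.0
    if config.reaction_jitter_sd > 0 or config.reaction_jitter_mean > 0:
        jitter = float(np.clip(
            rng.normal(config.reaction_jitter_mean, config.reaction_jitter_sd), 0.0, 0.5))

    for stage in STAGE_ORDER:
        snr = config.stage_snr.get(stage, 0.0) * sig.gain(stage)
        if stage == "pre":
            snr = config.carryover_gain * config.stage_snr.get("production", 0.0) * sig.gain("production")
        if snr <= 0:
            continue
        start_s, end_s = segs[stage]
        if stage == "production":
            start_s = min(start_s + jitter, end_s - 1.0 / fs)
        i0 = int(round((start_s - t0) * fs))
        i1 = int(round((end_s - t0) * fs))
        m = i1 - i0
        env = _stage_envelope(m, config.edge_ramp_frac)
        t = np.arange(m) / fs
        for band, (f, amps) in sig.components.items():
            phase = rng.uniform(0, 2 * np.pi)
            wave = np.sin(2 * np.pi * f * t + phase) * env
            out[:, i0:i1] += snr * amps[:, None] * wave[None, :]
    return out


def generate_dataset(
    config: SynthConfig,
    signatures: list[ClassSignature] | None = None,
) -> list[Trial]:
    """Generate the full labeled synthetic experiment.

    Returns ``n_subjects * n_classes * n_trials_per_class`` trials, each with
    pseudo-randomized (per subject) label order, class-dependent oscillations
    only in stages with positive gain, and pre-stimulus class content only via
    ``carryover_gain``.  Fully deterministic under ``config.seed``.
    """
    config.validate()
    if signatures is None:
        signatures = make_random_signatures(config)
    if len(signatures) != config.n_classes:
        raise ValueError(
            f"need {config.n_classes} signatures, got {len(signatures)}")
    for sig in signatures:
        sig.validate(config.n_channels, config.fs)
    by_class = {s.class_id: s for s in signatures}

    rng = np.random.default_rng(config.seed)
    segs = config.segments()
    channel_ids = [f"ch{i:03d}" for i in range(config.n_channels)]
    trials: list[Trial] = []
    for subj in range(config.n_subjects):
        labels = np.repeat(np.arange(config.n_classes), config.n_trials_per_class)
        rng.shuffle(labels)
        for k, lab in enumerate(labels):
            noise = background_noise(
                config.n_channels, config.n_samples, config.fs,
                exponent=config.noise_exponent, rng=rng)
            x = config.noise_sd * noise + _render_signature(by_class[int(lab)], config, rng)
            trials.append(Trial(
                signal=x, fs=config.fs, label=int(lab), subject=subj,
                t0=segs["pre"][0], segments=dict(segs),
                trial_id=f"s{subj}_t{k:04d}", channel_ids=list(channel_ids)))
    if config.artifact_rate > 0:
        trials, _ = inject_artifacts(trials, config.artifact_rate, rng=rng)
    return trials


ARTIFACT_KINDS = ("blink", "cardiac")


def inject_artifacts(
    trials: list[Trial],
    artifact_rate: float,
    kinds: tuple[str, ...] = ARTIFACT_KINDS,
    rng: np.random.Generator | int | None = None,
    blink_amplitude: tuple[float, float] = (10.0, 20.0),
    cardiac_amplitude: float = 3.0,
) -> tuple[list[Trial], pd.DataFrame]:
    """Superimpose ocular/cardiac-like artifacts on a Poisson schedule.

    Blink artifacts are single low-frequency (<4 Hz) high-amplitude Hann
    transients on a frontal-like channel subset (first fifth of channels);
    cardiac events are quasi-periodic ~1 Hz pulse trains spanning the trial.
    The log records (trial_id, time_s, kind, peak).
    """
    if artifact_rate < 0:
        raise ValueError("artifact_rate must be >= 0")
    unknown = [k for k in kinds if k not in ARTIFACT_KINDS]
    if unknown:
        raise ValueError(f"unknown artifact kinds: {unknown}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    rows: list[dict] = []
    out: list[Trial] = []
    for tr in trials:
        x = tr.signal.copy()
        n_events = int(rng.poisson(artifact_rate)) if artifact_rate > 0 else 0
        n_front = max(1, tr.n_channels // 5)
        for _ in range(n_events):
            kind = kinds[int(rng.integers(len(kinds)))]
            if kind == "blink":
                width = int(0.35 * tr.fs)  # ~2.9 Hz dominant: inside <4 Hz
                center = int(rng.integers(width, tr.n_samples - width))
                amp = float(rng.uniform(*blink_amplitude))
                pulse = amp * np.hanning(2 * width)
                decay = np.exp(-np.arange(n_front) / max(n_front / 2, 1))
                x[:n_front, center - width:center + width] += decay[:, None] * pulse[None, :]
                t_ev = tr.t0 + center / tr.fs
                peak = amp
            else:
                period = float(rng.uniform(0.8, 1.2))
                width = int(0.04 * tr.fs)
                pulse = cardiac_amplitude * np.hanning(2 * width)
                phase0 = float(rng.uniform(0, period))
                t_beat = phase0
                while t_beat * tr.fs + 2 * width < tr.n_samples:
                    i0 = int(t_beat * tr.fs)
                    x[:, i0:i0 + 2 * width] += pulse[None, : x.shape[1] - i0]
                    t_beat += period
                t_ev = tr.t0 + phase0
                peak = cardiac_amplitude
            rows.append({"trial_id": tr.trial_id, "time_s": float(t_ev),
                         "kind": kind, "peak": peak})
        tr2 = Trial(signal=x, fs=tr.fs, label=tr.label, subject=tr.subject,
                    t0=tr.t0, segments=dict(tr.segments),
                    provenance=dict(tr.provenance), trial_id=tr.trial_id,
                    channel_ids=list(tr.channel_ids))
        out.append(tr2)
    log = pd.DataFrame(rows, columns=["trial_id", "time_s", "kind", "peak"])
    return out, log
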