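"""Discrete-wavelet denoising, band decomposition, and RMS feature screening.

A 7-level db4 discrete wavelet transform splits a 1 kHz signal into detail
components d1..d7 and approximation a7.  d1 (250-500 Hz) and d2 (125-250 Hz)
are discarded as noise; the remaining reconstructions map onto the
conventional neural oscillation bands:

    d3 -> high-gamma (62-125 Hz)     d6 -> alpha (8-16 Hz)
    d4 -> gamma      (31-58 Hz)      d7 -> theta (4-8 Hz)
    d5 -> beta       (16-30 Hz)      a7 -> delta (0.1-4 Hz)

The printed band edges are the labels used throughout; the realized
reconstructions are dyadic (e.g. gamma is 31.25-62.5 Hz), since a dyadic
filter bank cannot carve a 58-62 Hz notch.  The denoised composite is the
sum of the six kept bands.

RMS of each (channel, band) pair within an analysis stage is the baseline
decoder's feature; ``screen_features`` ranks candidate statistics by the
fraction of dimensions separating the classes (one-way ANOVA then Tukey HSD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import stats

from .preprocess import Trial

#: Kept bands in feature order, lowest frequency first.
BAND_ORDER: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma", "high_gamma")

#: Printed nominal ranges (Hz) of the kept bands.
NOMINAL_RANGES_HZ: dict[str, tuple[float, float]] = {
    "delta": (0.1, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 16.0),
    "beta": (16.0, 30.0),
    "gamma": (31.0, 58.0),
    "high_gamma": (62.0, 125.0),
}

#: Wavelet-level name for each kept band at fs=1000, levels=7.
_BAND_COMPONENT = {
    "delta": "a7", "theta": "d7", "alpha": "d6",
    "beta": "d5", "gamma": "d4", "high_gamma": "d3",
}


@dataclass
class BandSet:
    """Six band-limited versions of a trial's channels plus their sum.

    ``bands`` maps band label to a (channels x samples) signal sharing the
    source trial's shape; ``denoised`` is their exact sum (the <125 Hz
    reconstruction with d1/d2 removed).
    """

    bands: dict[str, np.ndarray]
    denoised: np.ndarray
    fs: float
    trial_ref: Trial | None = None
    nominal_ranges_hz: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(NOMINAL_RANGES_HZ)
    )


@dataclass
class FeatureVector:
    """Channel-major concatenation of per-band statistics for one trial.

    For channel ``c`` the six entries ``values[6c:6c+6]`` follow
    ``BAND_ORDER`` (delta..high_gamma); with 196 channels the vector has
    1176 entries.
    """

    values: np.ndarray
    feature_name: str = "rms"
    trial_ref: Trial | None = None

    def __len__(self) -> int:
        return self.values.size


def _min_length(wavelet: str, levels: int) -> int:
    flen = pywt.Wavelet(wavelet).dec_len
    return (flen - 1) * 2**levels


def dwt_components(
    x: np.ndarray, wavelet: str = "db4", levels: int = 7
) -> dict[str, np.ndarray]:
    """Full-length reconstructions of every component d1..d{levels}, a{levels}.

    Each component is reconstructed by zeroing all other coefficient arrays
    and inverting, so the components sum to the input (up to float error).
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if pywt.dwt_max_level(n, wavelet) < levels:
        raise ValueError(
            f"signal too short for {levels}-level {wavelet} DWT: "
            f"need >= {_min_length(wavelet, levels)} samples, got {n}"
        )
    coeffs = pywt.wavedec(x, wavelet, level=levels, mode="symmetric", axis=-1)
    names = [f"a{levels}"] + [f"d{levels - i + 1}" for i in range(1, levels + 1)]
    out: dict[str, np.ndarray] = {}
    for i, name in enumerate(names):
        kept = [c if j == i else np.zeros_like(c) for j, c in enumerate(coeffs)]
        rec = pywt.waverec(kept, wavelet, mode="symmetric", axis=-1)
        out[name] = rec[..., :n]
    return out


def dwt_bands(
    trial_signal: np.ndarray | Trial,
    fs: float = 1000.0,
    wavelet: str = "db4",
    levels: int = 7,
) -> BandSet:
    """Decompose a trial into the six kept oscillation bands.

    ``trial_signal`` may be a (channels x samples) array or a Trial.  The two
    finest details (>125 Hz at 1 kHz) are dropped; ``denoised`` is the sum of
    the six stored bands.
    """
    trial_ref = None
    if isinstance(trial_signal, Trial):
        trial_ref = trial_signal
        fs = trial_signal.fs
        x = trial_signal.signal
    else:
        x = np.asarray(trial_signal, dtype=float)
    comps = dwt_components(np.atleast_2d(x), wavelet=wavelet, levels=levels)
    bands = {band: comps[_BAND_COMPONENT[band]] for band in BAND_ORDER}
    denoised = np.sum([bands[b] for b in BAND_ORDER], axis=0)
    return BandSet(bands=bands, denoised=denoised, fs=fs, trial_ref=trial_ref)


def rms_features(
    bandset: BandSet, segment: str | tuple[float, float] | slice
) -> FeatureVector:
    """Per-(channel, band) RMS over an analysis stage.

    ``segment`` is a stage name or ``(start, end)`` seconds pair resolved
    through the band set's source trial, or an explicit sample slice.
    """
    if isinstance(segment, slice):
        sl = segment
    else:
        if bandset.trial_ref is None:
            raise ValueError("named/timed segments need a trial_ref on the BandSet")
        sl = bandset.trial_ref.segment_slice(segment)
    if sl.stop is not None and sl.start is not None and sl.stop <= sl.start:
        raise ValueError("empty segment")
    per_band = []
    for band in BAND_ORDER:
        seg = bandset.bands[band][:, sl]
        if seg.shape[1] == 0:
            raise ValueError("empty segment")
        per_band.append(np.sqrt(np.mean(seg**2, axis=1)))
    mat = np.stack(per_band, axis=1)  # channels x bands
    return FeatureVector(values=mat.reshape(-1), feature_name="rms",
                         trial_ref=bandset.trial_ref)


# ---------------------------------------------------------------------------
# candidate statistics for feature screening

def _windowed_energy(x: np.ndarray, n_windows: int = 4) -> np.ndarray:
    parts = np.array_split(x, n_windows, axis=-1)
    return np.concatenate([np.sum(p**2, axis=-1, keepdims=True) for p in parts], axis=-1)


CANDIDATE_STATS = {
    "rms": lambda x: np.sqrt(np.mean(x**2, axis=-1)),
    "mean": lambda x: np.mean(x, axis=-1),
    "median": lambda x: np.median(x, axis=-1),
    "sd": lambda x: np.std(x, axis=-1),
    "quartiles": lambda x: np.percentile(x, [25, 50, 75], axis=-1).T.reshape(x.shape[0], -1) if x.ndim == 2 else np.percentile(x, [25, 50, 75], axis=-1),
    "tertiles": lambda x: np.percentile(x, [100 / 3, 200 / 3], axis=-1).T.reshape(x.shape[0], -1) if x.ndim == 2 else np.percentile(x, [100 / 3, 200 / 3], axis=-1),
    "energy": lambda x: np.sum(x**2, axis=-1),
    "windowed_energy": _windowed_energy,
}


def candidate_feature_tables(
    bandsets: list[BandSet],
    segment: str | tuple[float, float],
    stats_names: tuple[str, ...] = tuple(CANDIDATE_STATS),
) -> dict[str, np.ndarray]:
    """Build (n_trials x dim) tables of each candidate statistic.

    The cross-correlation-matrix candidate is intentionally not offered: its
    dimension grows quadratically in channels and it was screened out of the
    baseline feature set on that ground.
    """
    tables: dict[str, list[np.ndarray]] = {s: [] for s in stats_names}
    for bs in bandsets:
        sl = bs.trial_ref.segment_slice(segment)
        for s in stats_names:
            fn = CANDIDATE_STATS[s]
            rows = [np.atleast_1d(fn(bs.bands[band][:, sl])) for band in BAND_ORDER]
            mat = np.stack([r.reshape(bs.denoised.shape[0], -1) for r in rows], axis=1)
            tables[s].append(mat.reshape(-1))
    return {s: np.asarray(v) for s, v in tables.items()}


def screen_features(
    tables: dict[str, np.ndarray],
    labels: np.ndarray,
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Rank candidate feature types by class separability.

    For each candidate, every dimension gets a one-way ANOVA across classes;
    the ranking statistic is the fraction of (non-degenerate) dimensions with
    ANOVA p < ``alpha``.  Dimensions passing ANOVA additionally get Tukey HSD
    pairwise tests, reported as the count confirmed by at least one pairwise
    difference at ``alpha``.  Zero-variance dimensions are flagged and
    excluded from the fraction.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need >= 2 classes to screen features")
    for c in classes:
        if np.sum(labels == c) < 3:
            raise ValueError("need >= 3 trials per class")

    rows = []
    for name, mat in tables.items():
        mat = np.asarray(mat, dtype=float)
        n_sig = 0
        n_tukey = 0
        n_degenerate = 0
        for j in range(mat.shape[1]):
            groups = [mat[labels == c, j] for c in classes]
            if all(np.ptp(g) == 0 for g in groups) or np.ptp(mat[:, j]) == 0:
                n_degenerate += 1
                continue
            f, p = stats.f_oneway(*groups)
            if np.isnan(p) or p >= alpha:
                continue
            n_sig += 1
            tk = stats.tukey_hsd(*groups)
            if np.any(tk.pvalue[np.triu_indices(classes.size, 1)] < alpha):
                n_tukey += 1
        n_valid = mat.shape[1] - n_degenerate
        rows.append({
            "feature": name,
            "dim": mat.shape[1],
            "n_degenerate": n_degenerate,
            "n_significant": n_sig,
            "n_tukey_confirmed": n_tukey,
            "frac_significant": n_sig / n_valid if n_valid else np.nan,
        })
    report = pd.DataFrame(rows).sort_values(
        "frac_significant", ascending=False, ignore_index=True)
    return report
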