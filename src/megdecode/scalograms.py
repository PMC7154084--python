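"""Morlet scalograms, per-sensor rasters, spatial tiling, shift augmentation.

The continuous wavelet transform of the denoised (<125 Hz) signal with a
complex Morlet wavelet (omega0 = 6 equivalent, i.e. ``cmor2.0-0.9549`` in
PyWavelets' bandwidth-center parametrization) yields an energy matrix over
log-spaced center frequencies.  Per-sensor energy matrices are rendered to
small RGB rasters (log scale, per-image min-max normalization, fixed
perceptually-uniform colormap) and either used one image per sensor, or tiled
into a single rows x cols composite (default 14 x 14, holding 196 sensors) so
one image encodes whole-head spatial-spectral-temporal structure.

Time-shift augmentation re-windows each trial at small positive offsets
(default 100 and 200 ms, emulating reaction-time variability) and records
parent provenance so data splits can keep a trial and its shifted copies
together.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
import pywt
from PIL import Image

from .preprocess import Trial

DEFAULT_WAVELET = "cmor2.0-0.9549"  # complex Morlet, omega0 = 6 equivalent


@dataclass
class Scalogram:
    """CWT coefficient energy over (frequency x time) for one channel."""

    energy: np.ndarray
    freqs_hz: np.ndarray  # descending
    times_s: np.ndarray
    channel_id: str = ""
    trial_ref: Trial | None = None
    wavelet: str = DEFAULT_WAVELET

    def coi_efolding_s(self) -> np.ndarray:
        """Cone-of-influence half-width per frequency (e-folding time).

        For a Morlet wavelet with angular center frequency omega0, the
        Gaussian envelope's SD at frequency f is omega0 / (2 pi f); edge
        effects matter within sqrt(2) SDs of either end.
        """
        # cmor(B=2, C): envelope exp(-t^2/2), carrier 2*pi*C -> omega0 = 2*pi*C
        omega0 = 2 * math.pi * pywt.ContinuousWavelet(self.wavelet).center_frequency
        return math.sqrt(2.0) * omega0 / (2 * math.pi * self.freqs_hz)


@dataclass
class TiledImage:
    """Composite raster with one scalogram tile per sensor in a fixed grid."""

    raster: np.ndarray  # H x W x 3, float in [0, 1]
    grid: tuple[int, int]
    tile_map: list[tuple[str, tuple[int, int]]]
    tile_size: tuple[int, int]
    render_params: dict = field(default_factory=dict)

    def extract_tile(self, sensor_id: str) -> np.ndarray:
        """Bit-exact recovery of the tile placed for ``sensor_id``."""
        lookup = dict(self.tile_map)
        if sensor_id not in lookup:
            raise KeyError(f"sensor {sensor_id!r} not in tile map")
        r, c = lookup[sensor_id]
        h, w = self.tile_size
        return self.raster[r * h:(r + 1) * h, c * w:(c + 1) * w, :]


def cwt_scalogram(
    x: np.ndarray,
    fs: float,
    freq_range: tuple[float, float] = (0.5, 125.0),
    n_freqs: int = 64,
    wavelet: str = DEFAULT_WAVELET,
    channel_id: str = "",
    trial_ref: Trial | None = None,
) -> Scalogram:
    """Morlet CWT energy of one channel over log-spaced frequencies.

    ``x`` is expected to be the denoised (<125 Hz) signal.  Energy is the
    squared magnitude of the complex coefficients; frequencies run from high
    to low so the raster reads like a spectrogram.
    """
    lo, hi = freq_range
    if hi >= fs / 2:
        raise ValueError(f"upper frequency {hi} Hz must be below Nyquist ({fs / 2})")
    if not 0 < lo < hi:
        raise ValueError("freq_range must satisfy 0 < low < high")
    x = np.asarray(x, dtype=float).ravel()
    freqs = np.logspace(math.log10(hi), math.log10(lo), n_freqs)  # descending
    fc = pywt.ContinuousWavelet(wavelet).center_frequency
    scales = fc * fs / freqs
    coef, _ = pywt.cwt(x, scales, wavelet, sampling_period=1.0 / fs, method="fft")
    energy = np.abs(coef) ** 2
    times = np.arange(x.size) / fs
    return Scalogram(energy=energy, freqs_hz=freqs, times_s=times,
                     channel_id=channel_id, trial_ref=trial_ref, wavelet=wavelet)


def _colormap(name: str):
    from matplotlib import colormaps
    return colormaps[name]


def render_scalogram(
    s: Scalogram | np.ndarray,
    target_size: tuple[int, int],
    cmap: str = "viridis",
    eps: float = 1e-12,
) -> np.ndarray:
    """Render an energy matrix to a float RGB raster in [0, 1].

    log10(energy + eps) is min-max normalized per image (constant images map
    to the colormap floor), passed through a fixed perceptually-uniform
    colormap, and bilinearly resized to ``target_size`` (H, W).
    """
    h, w = target_size
    if h < 8 or w < 8:
        raise ValueError("target size must be at least 8 x 8")
    energy = s.energy if isinstance(s, Scalogram) else np.asarray(s, dtype=float)
    z = np.log10(energy + eps)
    zmin, zmax = z.min(), z.max()
    z = (z - zmin) / (zmax - zmin) if zmax > zmin else np.zeros_like(z)
    # resize the scalar field first, then colormap: keeps ridge geometry
    # independent of colormap curvature under interpolation
    img = Image.fromarray(z.astype(np.float32), mode="F")
    z_rs = np.asarray(img.resize((w, h), Image.BILINEAR), dtype=float)
    rgb = _colormap(cmap)(np.clip(z_rs, 0.0, 1.0))[..., :3]
    return rgb.astype(np.float64)


def tile_scalograms(
    rasters: dict[str, np.ndarray],
    grid: tuple[int, int] = (14, 14),
    order: list[str] | None = None,
    render_params: dict | None = None,
) -> TiledImage:
    """Place per-sensor rasters row-major into a rows x cols composite.

    ``order`` fixes the sensor->cell assignment (default: ascending sensor
    id); unused cells stay black.  The tile map is recorded so any tile can
    be recovered bit-exactly.
    """
    rows, cols = grid
    order = sorted(rasters) if order is None else list(order)
    if len(set(order)) != len(order):
        raise ValueError("duplicate sensor in tile order")
    missing = [s for s in order if s not in rasters]
    if missing:
        raise ValueError(f"no raster for sensors: {missing}")
    if len(order) > rows * cols:
        raise ValueError(f"{len(order)} sensors exceed {rows}x{cols} grid")
    shapes = {rasters[s].shape for s in order}
    if len(shapes) != 1:
        raise ValueError("all tiles must share one shape")
    h, w, _ = shapes.pop()

    raster = np.zeros((rows * h, cols * w, 3))
    tile_map: list[tuple[str, tuple[int, int]]] = []
    for i, sensor in enumerate(order):
        r, c = divmod(i, cols)
        raster[r * h:(r + 1) * h, c * w:(c + 1) * w, :] = rasters[sensor]
        tile_map.append((sensor, (r, c)))
    return TiledImage(raster=raster, grid=grid, tile_map=tile_map,
                      tile_size=(h, w), render_params=dict(render_params or {}))


def augment_shift(
    trials: list[Trial],
    shifts_ms: tuple[float, ...] = (100.0, 200.0),
    recording: np.ndarray | None = None,
) -> list[Trial]:
    """Originals plus one positively time-shifted copy per shift.

    A shift of +s ms re-windows the trial s ms later: the child's samples are
    the parent's from index ``s*fs/1000`` on.  When the source recording is
    not available the vacated tail is zero-padded (and this is recorded in
    provenance).  Labels and segment maps are copied; provenance points at
    the parent so split hygiene can be enforced downstream.
    """
    out: list[Trial] = list(trials)
    for tr in trials:
        for shift in shifts_ms:
            k = int(round(shift * tr.fs / 1000.0))
            if k < 0:
                raise ValueError("shifts must be non-negative")
            child = copy.copy(tr)
            x = np.zeros_like(tr.signal)
            if k < tr.n_samples:
                x[:, : tr.n_samples - k] = tr.signal[:, k:]
            child.signal = x
            child.segments = dict(tr.segments)
            child.provenance = {
                "kind": "augmented", "parent": tr.trial_id,
                "shift_ms": float(shift), "tail": "zero-padded",
            }
            child.trial_id = f"{tr.trial_id}_sh{int(shift)}"
            child.channel_ids = list(tr.channel_ids)
            out.append(child)
    return out
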