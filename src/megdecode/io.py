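"""Dataset container, sidecar manifests, table/report/image writers.

A dataset is stored as one ``signals.npy`` stack (n_trials x channels x
samples, float32) plus a ``manifest.json`` sidecar carrying the sampling
rate, channel ids and per-trial metadata (label, subject, t0, segment map,
provenance).  Feature tables and logs go to TSV; scalogram rasters to PNG
with a JSON sidecar; evaluation reports to JSON/Markdown.  Trials can also
be exported to an in-memory ``mne.EpochsArray`` for inspection with standard
neurophysiology tooling.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import Trial
from .scalograms import TiledImage
from .wavelets import BAND_ORDER, FeatureVector


def save_dataset(trials: list[Trial], path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    signals = np.stack([t.signal for t in trials]).astype(np.float32)
    np.save(path / "signals.npy", signals)
    manifest = {
        "fs": trials[0].fs,
        "channel_ids": trials[0].channel_ids,
        "trials": [
            {
                "trial_id": t.trial_id, "label": int(t.label),
                "subject": int(t.subject), "t0": t.t0,
                "segments": {k: list(v) for k, v in t.segments.items()},
                "provenance": t.provenance,
            }
            for t in trials
        ],
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_dataset(path: str | Path) -> list[Trial]:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    signals = np.load(path / "signals.npy")
    trials = []
    for sig, meta in zip(signals, manifest["trials"]):
        trials.append(Trial(
            signal=np.asarray(sig, dtype=float), fs=manifest["fs"],
            label=meta["label"], subject=meta["subject"], t0=meta["t0"],
            segments={k: tuple(v) for k, v in meta["segments"].items()},
            provenance=meta["provenance"], trial_id=meta["trial_id"],
            channel_ids=list(manifest["channel_ids"])))
    return trials


def feature_table(
    vectors: list[FeatureVector], channel_ids: list[str]
) -> pd.DataFrame:
    """Feature vectors as a DataFrame with (channel, band) column names."""
    cols = [f"{c}:{b}" for c in channel_ids for b in BAND_ORDER]
    mat = np.stack([v.values for v in vectors])
    return pd.DataFrame(mat, columns=cols)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def save_tiled_image(tiled: TiledImage, path: str | Path) -> None:
    """PNG raster plus a JSON sidecar with the tile map and render params."""
    from PIL import Image

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.clip(tiled.raster * 255.0, 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)
    sidecar = {
        "grid": list(tiled.grid),
        "tile_size": list(tiled.tile_size),
        "tile_map": [[s, list(rc)] for s, rc in tiled.tile_map],
        "render_params": tiled.render_params,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def to_mne_epochs(trials: list[Trial]):
    """Export trials as an ``mne.EpochsArray`` (misc channels, event=label)."""
    import mne

    info = mne.create_info(trials[0].channel_ids, trials[0].fs, ch_types="misc")
    data = np.stack([t.signal for t in trials])
    events = np.column_stack([
        np.arange(len(trials)) * trials[0].n_samples,
        np.zeros(len(trials), dtype=int),
        np.asarray([t.label + 1 for t in trials]),
    ]).astype(int)
    return mne.EpochsArray(data, info, events=events, tmin=trials[0].t0,
                           verbose="error")
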