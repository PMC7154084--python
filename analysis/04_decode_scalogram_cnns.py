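"""Scalogram decoding: whole-head tiled images + small CNN (SST route).

Builds one Morlet-scalogram tile per sensor per trial (denoised signal,
4x decimated), tiles them into a single square composite, triples the
training material with +100/+200 ms time-shift augmentation (children follow
their parents' split), and trains the small CNN (Adam 1e-4, head x20,
minibatch 64, gradient clipping, validation patience 6).  Also saves one
example tiled image with its sensor map sidecar.  Reports land under
results/cnn/.
"""

from pathlib import Path

from megdecode import evaluate, io, scalograms, wavelets

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    trials = io.load_dataset(OUT / "dataset_clean")
    (OUT / "cnn").mkdir(parents=True, exist_ok=True)

    # example composite image for the first trial
    tr = trials[0]
    bs = wavelets.dwt_bands(tr)
    seg = bs.denoised[:, tr.segment_slice("production")][:, ::4]
    rasters = {cid: scalograms.render_scalogram(
        scalograms.cwt_scalogram(seg[i], tr.fs / 4, freq_range=(0.5, 124),
                                 n_freqs=32), (16, 16))
        for i, cid in enumerate(tr.channel_ids)}
    tiled = scalograms.tile_scalograms(rasters, grid=(5, 5),
                                       render_params={"scale": "log10",
                                                      "colormap": "viridis"})
    io.save_tiled_image(tiled, OUT / "cnn" / "example_tiled.png")

    rep = evaluate.run_pipeline(trials, "production", "sst_cnn", seed=seed,
                                lowpass=False, n_repeats=3)
    (OUT / "cnn" / "sst_production.json").write_text(rep.to_json())
    print(rep.to_markdown())


if __name__ == "__main__":
    main()
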