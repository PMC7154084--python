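"""Baseline decoding: per-(channel, band) RMS features + shallow ANN.

Runs the 256-hidden-node sigmoid ANN (SGD, lr 0.01, early stopping) on all
four analysis stages with three stratified 70/15/15 splits each, and reports
mean +/- SD average per-class accuracy, the exact binomial chance level, and
one-vs-rest AUCs.  Reports land under results/ann/.
"""

import json
from pathlib import Path

from megdecode import evaluate, io

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    trials = io.load_dataset(OUT / "dataset_clean")
    (OUT / "ann").mkdir(parents=True, exist_ok=True)
    summary = {}
    for stage in ("pre", "perception", "preparation", "production"):
        rep = evaluate.run_pipeline(trials, stage, "ann", seed=seed,
                                    lowpass=False)
        (OUT / "ann" / f"{stage}.json").write_text(rep.to_json())
        print(rep.to_markdown(), "\n")
        summary[stage] = rep.mean_accuracy
    (OUT / "ann" / "summary.json").write_text(json.dumps(summary, indent=1))
    print("stage ordering (accuracy %):",
          {k: round(v, 1) for k, v in summary.items()})


if __name__ == "__main__":
    main()
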