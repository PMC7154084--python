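"""Compare decoders and stages: t-tests, chance level, summary table.

Collects the per-repeat accuracies written by the decoding drivers, tests
the ANN-vs-SST-CNN difference (paired two-tail t) and each method against
the exact binomial chance level (one-sample one-tail t, with Holm-adjusted
p-values reported alongside), and writes results/summary.md.
"""

import json
from pathlib import Path

import numpy as np

from megdecode import evaluate

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ann = json.loads((OUT / "ann" / "production.json").read_text())
    sst = json.loads((OUT / "cnn" / "sst_production.json").read_text())
    a, b = np.asarray(ann["accuracies"]), np.asarray(sst["accuracies"])
    chance = ann["chance_level_pct"]

    pair = evaluate.compare_methods(b, a)
    vs_chance = [evaluate.compare_methods(x, chance=chance) for x in (a, b)]
    holm = evaluate.holm_correct([t["p"] for t in vs_chance])

    lines = [
        "# Phrase decoding summary (production stage)", "",
        f"- ANN:     {a.mean():.2f} +/- {a.std(ddof=1):.2f} %",
        f"- SST-CNN: {b.mean():.2f} +/- {b.std(ddof=1):.2f} %",
        f"- chance level (alpha=0.05, n={ann['n_test_per_repeat']}): {chance:.2f} %",
        f"- SST-CNN vs ANN (paired 2-tail): t={pair['t']:.3f}, p={pair['p']:.3g}",
        f"- ANN vs chance (1-tail): p={vs_chance[0]['p']:.3g} "
        f"(Holm {holm[0]:.3g})",
        f"- SST-CNN vs chance (1-tail): p={vs_chance[1]['p']:.3g} "
        f"(Holm {holm[1]:.3g})",
    ]
    (OUT / "summary.md").write_text("\n".join(lines) + "\n")
    print("\n".join(lines))


if __name__ == "__main__":
    main()
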