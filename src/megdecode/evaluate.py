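"""Splits, metrics, chance level, significance tests, and the full pipeline.

Evaluation follows a subject-dependent protocol: stratified 70/15/15
train/validation/test splits repeated over 3 random assignments, accuracy
summarized as mean +/- SD across repeats, confusion matrices accumulated
over test sets, one-vs-rest ROC AUCs, an exact-binomial chance level, and
paired / one-sample t-tests for method and chance comparisons.  Augmented
trials always inherit their parent's split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from . import decoders, scalograms, wavelets
from .preprocess import Trial, filter_trials, reject_trials

SPLITS = ("train", "val", "test")


@dataclass
class SplitPlan:
    """Trial-to-split assignment for each repeat.

    ``assignment[trial_id][repeat]`` is one of ``train``/``val``/``test``.
    """

    ratios: tuple[float, float, float]
    n_repeats: int
    seed: int
    assignment: dict[str, list[str]]

    def split_of(self, repeat: int) -> dict[str, str]:
        return {tid: reps[repeat] for tid, reps in self.assignment.items()}

    def ids_in(self, repeat: int, split: str) -> list[str]:
        return [tid for tid, reps in self.assignment.items() if reps[repeat] == split]


def _stratified_counts(n: int, ratios: tuple[float, float, float]) -> tuple[int, int, int]:
    """Largest-remainder rounding of n into three parts."""
    raw = [n * r for r in ratios]
    base = [int(np.floor(v)) for v in raw]
    rem = n - sum(base)
    order = np.argsort([b - v for b, v in zip(base, raw)])  # most-negative first
    for i in range(rem):
        base[order[i]] += 1
    return tuple(base)  # type: ignore[return-value]


def split_data(
    trial_ids: list[str],
    labels: np.ndarray,
    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15),
    n_repeats: int = 3,
    seed: int = 0,
    parents: dict[str, str] | None = None,
) -> SplitPlan:
    """Stratified train/val/test assignment, repeated ``n_repeats`` times.

    ``parents`` maps augmented trial ids to their parent's id; children are
    assigned wherever their parent lands.  Deterministic under ``seed``.
    Classes with fewer than 3 trials trigger a warning entry (they cannot
    populate all three splits) but are still assigned.
    """
    if not np.isclose(sum(ratios), 1.0):
        raise ValueError("split ratios must sum to 1")
    labels = np.asarray(labels)
    parents = parents or {}
    originals = [t for t in trial_ids if t not in parents]
    lab_of = dict(zip(trial_ids, labels))
    classes = sorted(set(int(lab_of[t]) for t in originals))

    import warnings
    for c in classes:
        if sum(1 for t in originals if lab_of[t] == c) < 3:
            warnings.warn(f"class {c} has < 3 trials; cannot stratify across splits")

    rng = np.random.default_rng(seed)
    assignment: dict[str, list[str]] = {t: [] for t in trial_ids}
    for _ in range(n_repeats):
        for c in classes:
            ids_c = [t for t in originals if int(lab_of[t]) == c]
            perm = rng.permutation(len(ids_c))
            n_tr, n_va, n_te = _stratified_counts(len(ids_c), ratios)
            tags = ["train"] * n_tr + ["val"] * n_va + ["test"] * n_te
            for pos, tag in zip(perm, tags):
                assignment[ids_c[pos]].append(tag)
        for child, parent in parents.items():
            assignment[child].append(assignment[parent][-1])
    return SplitPlan(ratios=ratios, n_repeats=n_repeats, seed=seed,
                     assignment=assignment)


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # K x K, rows = true, cols = predicted
    class_labels: list[int]

    @property
    def overall_accuracy(self) -> float:
        return 100.0 * np.trace(self.counts) / self.counts.sum()

    @property
    def per_class_accuracy(self) -> np.ndarray:
        rowsum = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * np.diag(self.counts) / rowsum

    @property
    def average_accuracy(self) -> float:
        """Mean of per-class accuracies (the headline metric).

        Classes with no test rows are excluded from the mean.
        """
        return float(np.nanmean(self.per_class_accuracy))


def confusion_and_accuracy(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int
) -> ConfusionMatrix:
    """Tally a K x K confusion matrix (rows true, columns predicted)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("label arrays must have equal length")
    if (y_true.min() < 0 or y_true.max() >= n_classes
            or y_pred.min() < 0 or y_pred.max() >= n_classes):
        raise ValueError(f"labels must lie in 0..{n_classes - 1}")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts=counts, class_labels=list(range(n_classes)))


def roc_auc_ovr(
    scores: np.ndarray, y_true: np.ndarray
) -> tuple[np.ndarray, float, list[int]]:
    """One-vs-rest ROC AUC per class plus the macro average.

    ``scores`` is (n x K) per-class probabilities (or monotone scores).
    Classes absent from the truth get NaN and are listed in the returned
    flag list; the macro average spans the defined classes.
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true, dtype=int)
    K = scores.shape[1]
    aucs = np.full(K, np.nan)
    undefined = []
    for k in range(K):
        pos = y_true == k
        if pos.all() or not pos.any():
            undefined.append(k)
            continue
        aucs[k] = roc_auc_score(pos.astype(int), scores[:, k])
    macro = float(np.nanmean(aucs)) if np.any(~np.isnan(aucs)) else float("nan")
    return aucs, macro, undefined


def chance_level(n_trials: int, n_classes: int, alpha: float = 0.05) -> float:
    """Exact binomial chance-level accuracy threshold, in percent.

    The smallest accuracy a = k/n such that a random classifier (success
    rate 1/K) reaches at least k correct with probability <= alpha.  When no
    achievable count satisfies the bound (tiny n), returns 100%.
    """
    if n_trials < 1 or n_classes < 2:
        raise ValueError("need n_trials >= 1 and n_classes >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    p = 1.0 / n_classes
    # P(X >= k) = sf(k - 1); find the smallest qualifying k
    ks = np.arange(n_trials + 1)
    tail = stats.binom.sf(ks - 1, n_trials, p)
    ok = np.nonzero(tail <= alpha)[0]
    k = int(ok[0]) if ok.size else n_trials
    return 100.0 * k / n_trials


def binomial_chance_interval(
    n_trials: int, n_classes: int, conf: float = 0.95
) -> tuple[float, float]:
    """Central accuracy interval (percent) of a chance classifier."""
    p = 1.0 / n_classes
    lo = stats.binom.ppf((1 - conf) / 2, n_trials, p)
    hi = stats.binom.ppf(1 - (1 - conf) / 2, n_trials, p)
    return 100.0 * lo / n_trials, 100.0 * hi / n_trials


def compare_methods(
    acc_a: np.ndarray,
    acc_b: np.ndarray | None = None,
    chance: float | None = None,
) -> dict:
    """Paired two-tail t-test between methods, or one-tail test vs chance.

    Exactly one of ``acc_b`` / ``chance`` must be given.  Zero-variance,
    zero-mean-difference inputs report p = 1 with a flag instead of NaN.
    """
    a = np.asarray(acc_a, dtype=float)
    if (acc_b is None) == (chance is None):
        raise ValueError("give exactly one of acc_b or chance")
    if acc_b is not None:
        b = np.asarray(acc_b, dtype=float)
        if a.shape != b.shape or a.size < 2:
            raise ValueError("paired arrays must share length >= 2")
        d = a - b
        if np.allclose(d.std(), 0) and np.allclose(d.mean(), 0):
            return {"test": "paired-2tail", "t": 0.0, "p": 1.0, "df": a.size - 1,
                    "flag": "degenerate: zero variance and zero mean difference"}
        t, p = stats.ttest_rel(a, b)
        return {"test": "paired-2tail", "t": float(t), "p": float(p), "df": a.size - 1}
    if a.size < 2:
        raise ValueError("need >= 2 accuracies for the one-sample test")
    if np.allclose(a.std(), 0):
        if np.allclose(a.mean(), chance):
            return {"test": "1sample-1tail", "t": 0.0, "p": 1.0, "df": a.size - 1,
                    "flag": "degenerate: zero variance at the chance level"}
        # all repeats identical but off chance: direction decides the tail
        return {"test": "1sample-1tail",
                "t": float(np.inf if a.mean() > chance else -np.inf),
                "p": 0.0 if a.mean() > chance else 1.0, "df": a.size - 1,
                "flag": "degenerate: zero variance"}
    t, p = stats.ttest_1samp(a, chance, alternative="greater")
    return {"test": "1sample-1tail", "t": float(t), "p": float(p), "df": a.size - 1}


def holm_correct(pvals: list[float]) -> list[float]:
    """Holm step-down adjusted p-values (reported alongside raw ones)."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvals[i])
        adj[i] = min(running, 1.0)
    return adj.tolist()


# ---------------------------------------------------------------------------
# full pipeline

@dataclass
class EvalReport:
    """Per-(stage, method) decoding results."""

    stage: str
    method: str
    accuracies: list[float]            # average per-class accuracy, per repeat
    mean_accuracy: float
    sd_accuracy: float
    confusion: np.ndarray              # summed over repeats
    per_class_accuracy: list[float]
    aucs: list[float]
    macro_auc: float
    chance_level_pct: float
    n_test_per_repeat: int
    t_vs_chance: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = asdict(self)
        d["confusion"] = self.confusion.tolist()
        return json.dumps(d, indent=2)

    def to_markdown(self) -> str:
        lines = [
            f"## {self.method} / {self.stage}",
            "",
            f"- accuracy: {self.mean_accuracy:.2f} +/- {self.sd_accuracy:.2f} % "
            f"({len(self.accuracies)} repeats)",
            f"- chance level (alpha=0.05): {self.chance_level_pct:.2f} %",
            f"- macro one-vs-rest AUC: {self.macro_auc:.3f}",
            f"- t vs chance: t={self.t_vs_chance.get('t', float('nan')):.3f}, "
            f"p={self.t_vs_chance.get('p', float('nan')):.2e}",
        ]
        return "\n".join(lines)


METHODS = ("ann", "st_cnn", "sst_cnn")


def _square_grid(n_sensors: int) -> tuple[int, int]:
    side = int(np.ceil(np.sqrt(n_sensors)))
    return side, side


def _decimate(x: np.ndarray, factor: int) -> np.ndarray:
    """Plain subsampling; valid because input is already band-limited."""
    return x[..., ::factor] if factor > 1 else x


def _trial_feature_matrix(trials: list[Trial], stage: str) -> np.ndarray:
    rows = []
    for tr in trials:
        bs = wavelets.dwt_bands(tr)
        rows.append(wavelets.rms_features(bs, stage).values)
    return np.asarray(rows)


def _trial_tiled_images(
    trials: list[Trial], stage: str, tile_px: int, n_freqs: int,
    decim: int, grid: tuple[int, int] | None,
) -> np.ndarray:
    imgs = []
    for tr in trials:
        bs = wavelets.dwt_bands(tr)
        seg = bs.denoised[:, tr.segment_slice(stage)]
        seg = _decimate(seg, decim)
        fs = tr.fs / decim
        rasters = {}
        for c, cid in enumerate(tr.channel_ids):
            sg = scalograms.cwt_scalogram(seg[c], fs, freq_range=(0.5, min(125.0, fs / 2 - 1)),
                                          n_freqs=n_freqs, channel_id=cid)
            rasters[cid] = scalograms.render_scalogram(sg, (tile_px, tile_px))
        g = grid or _square_grid(len(rasters))
        tiled = scalograms.tile_scalograms(rasters, grid=g, order=list(tr.channel_ids))
        imgs.append(tiled.raster)
    return np.asarray(imgs)


def _trial_sensor_images(
    trials: list[Trial], stage: str, img_px: int, n_freqs: int, decim: int,
) -> np.ndarray:
    """(n_trials, n_sensors, H, W, 3) per-sensor scalogram images."""
    out = []
    for tr in trials:
        bs = wavelets.dwt_bands(tr)
        seg = bs.denoised[:, tr.segment_slice(stage)]
        seg = _decimate(seg, decim)
        fs = tr.fs / decim
        per_sensor = []
        for c in range(tr.n_channels):
            sg = scalograms.cwt_scalogram(seg[c], fs,
                                          freq_range=(0.5, min(125.0, fs / 2 - 1)),
                                          n_freqs=n_freqs)
            per_sensor.append(scalograms.render_scalogram(sg, (img_px, img_px)))
        out.append(np.asarray(per_sensor))
    return np.asarray(out)


def run_pipeline(
    trials: list[Trial],
    stage: str,
    method: str,
    n_classes: int = 5,
    seed: int = 0,
    n_repeats: int = 3,
    lowpass: bool = True,
    reject: bool = False,
    augment: bool | None = None,
    shifts_ms: tuple[float, ...] = (100.0, 200.0),
    tile_px: int = 8,
    img_px: int = 32,
    n_freqs: int = 32,
    decim: int = 4,
    ann_cfg: decoders.AnnConfig | None = None,
    cnn_cfg: decoders.CnnConfig | None = None,
) -> EvalReport:
    """Preprocess, featurize, decode and score one (stage, method) cell.

    ``method`` is one of ``ann`` (RMS features + shallow ANN), ``st_cnn``
    (per-sensor scalogram CNN with cross-entropy aggregation) or ``sst_cnn``
    (tiled whole-head scalogram CNN with time-shift augmentation).  Scalogram
    features are computed on the 4x-decimated denoised signal (content is
    <125 Hz, so 250 Hz sampling is lossless in band).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; valid: {METHODS}")
    if not trials:
        raise ValueError("empty dataset")
    if stage not in trials[0].segments:
        raise ValueError(
            f"unknown stage {stage!r}; valid: {sorted(trials[0].segments)}")

    if lowpass:
        trials = filter_trials(trials)
    if reject:
        trials, _ = reject_trials(trials)

    if augment is None:
        augment = method == "sst_cnn"
    parents: dict[str, str] = {}
    if augment:
        trials = scalograms.augment_shift(trials, shifts_ms=shifts_ms)
        parents = {t.trial_id: t.provenance["parent"] for t in trials
                   if t.provenance.get("kind") == "augmented"}

    ids = [t.trial_id for t in trials]
    labels = np.asarray([t.label for t in trials])
    plan = split_data(ids, labels, n_repeats=n_repeats, seed=seed, parents=parents)
    by_id = {t.trial_id: t for t in trials}

    # features once, reused across repeats
    if method == "ann":
        X = _trial_feature_matrix(trials, stage)
    elif method == "sst_cnn":
        X = _trial_tiled_images(trials, stage, tile_px=tile_px,
                                n_freqs=n_freqs, decim=decim, grid=None)
    else:
        X = _trial_sensor_images(trials, stage, img_px=img_px,
                                 n_freqs=n_freqs, decim=decim)
    idx_of = {tid: i for i, tid in enumerate(ids)}

    accs, all_true, all_pred, all_scores = [], [], [], []
    for rep in range(plan.n_repeats):
        split_of = plan.split_of(rep)
        tr_ids = plan.ids_in(rep, "train")
        va_ids = plan.ids_in(rep, "val")
        te_ids = [tid for tid in plan.ids_in(rep, "test")
                  if by_id[tid].provenance.get("kind") != "augmented"]
        ytr = labels[[idx_of[t] for t in tr_ids]]
        yva = labels[[idx_of[t] for t in va_ids]]
        yte = labels[[idx_of[t] for t in te_ids]]

        if method == "ann":
            cfg = ann_cfg or decoders.AnnConfig(
                input_dim=X.shape[1], output_classes=n_classes, seed=seed + rep)
            model = decoders.train_ann(
                X[[idx_of[t] for t in tr_ids]], ytr,
                X[[idx_of[t] for t in va_ids]], yva, cfg)
            scores = model.predict_proba(X[[idx_of[t] for t in te_ids]])
            preds = scores.argmax(axis=1)
        elif method == "sst_cnn":
            cfg = cnn_cfg or decoders.CnnConfig(
                input_size=tuple(X.shape[1:]), output_classes=n_classes,
                seed=seed + rep)
            prov = [dict(by_id[t].provenance, id=t) for t in tr_ids + va_ids]
            model = decoders.train_cnn(
                X[[idx_of[t] for t in tr_ids]], ytr,
                X[[idx_of[t] for t in va_ids]], yva, cfg,
                provenance=prov, split_of=split_of)
            scores = model.predict_proba(X[[idx_of[t] for t in te_ids]])
            preds = scores.argmax(axis=1)
        else:  # st_cnn: pool sensor images as samples, aggregate per trial
            n_sensors = X.shape[1]
            img_shape = X.shape[2:]
            Xtr = X[[idx_of[t] for t in tr_ids]].reshape(-1, *img_shape)
            Xva = X[[idx_of[t] for t in va_ids]].reshape(-1, *img_shape)
            cfg = cnn_cfg or decoders.CnnConfig(
                input_size=tuple(img_shape), output_classes=n_classes,
                seed=seed + rep)
            model = decoders.train_cnn(
                Xtr, np.repeat(ytr, n_sensors), Xva, np.repeat(yva, n_sensors), cfg)
            preds, scores = [], []
            for tid in te_ids:
                p_sensors = model.predict_proba(X[idx_of[tid]])
                pred, sc, _ = decoders.aggregate_trial(p_sensors)
                preds.append(pred)
                # convert mean -log p scores to a probability-like vector
                w = np.exp(-sc)
                scores.append(w / w.sum())
            preds = np.asarray(preds)
            scores = np.asarray(scores)

        cm = confusion_and_accuracy(yte, preds, n_classes)
        accs.append(cm.average_accuracy)
        all_true.append(yte)
        all_pred.append(preds)
        all_scores.append(scores)

    y_true = np.concatenate(all_true)
    y_pred = np.concatenate(all_pred)
    score_mat = np.concatenate(all_scores, axis=0)
    cm = confusion_and_accuracy(y_true, y_pred, n_classes)
    aucs, macro, _ = roc_auc_ovr(score_mat, y_true)
    n_test = len(all_true[0])
    chance = chance_level(n_test, n_classes)
    t_res = compare_methods(np.asarray(accs), chance=chance) if len(accs) >= 2 else {}

    return EvalReport(
        stage=stage, method=method,
        accuracies=[float(a) for a in accs],
        mean_accuracy=float(np.mean(accs)), sd_accuracy=float(np.std(accs, ddof=1))
        if len(accs) > 1 else 0.0,
        confusion=cm.counts, per_class_accuracy=cm.per_class_accuracy.tolist(),
        aucs=aucs.tolist(), macro_auc=macro, chance_level_pct=chance,
        n_test_per_repeat=n_test, t_vs_chance=t_res,
        params={"seed": seed, "n_repeats": n_repeats, "augment": bool(augment),
                "decim": decim, "n_freqs": n_freqs})
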