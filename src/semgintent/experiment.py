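"""Training/evaluation protocol: trial-level five-fold splits, the AdamW
training loop with plateau scheduling and early stopping, Table-style
classification metrics, and the prediction-time (Plabel) sweep.

The modelling surface follows the Model/Results convention: a
:class:`MotionIntentModel` is built from featurized windows and ``fit()``
returns a :class:`MotionIntentResults` carrying the trained network, the
loss history and evaluation helpers.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .config import IFIAConfig, ModelConfig, TrainConfig, WindowingConfig
from .fusion import build_variant
from .network import IntentNetwork, count_parameters
from .nn import AdamW, ReduceLROnPlateau, averaged_probs_cross_entropy, softmax_cross_entropy
from .preprocessing import batch_features, preprocess_trial, segment_windows
from .synthetic import SignalTrial

N_CLASSES = 17


# --------------------------------------------------------------------------
# features

@dataclass
class FeatureSet:
    """Featurized windows: scalograms, spectra, labels and provenance."""

    tfmap: np.ndarray           # (N, 30, W, 8) float32
    spectrum: np.ndarray        # (N, W/2+1, 8) float32
    labels: np.ndarray          # (N,) int, 1..17
    trial_ids: np.ndarray       # (N,) str
    starts: np.ndarray          # (N,) int, window start ms
    subject_ids: np.ndarray     # (N,) str

    def __len__(self) -> int:
        return self.labels.shape[0]

    def subset(self, mask: np.ndarray) -> "FeatureSet":
        return FeatureSet(
            self.tfmap[mask], self.spectrum[mask], self.labels[mask],
            self.trial_ids[mask], self.starts[mask], self.subject_ids[mask],
        )

    def for_trials(self, trial_ids: Iterable[str]) -> "FeatureSet":
        wanted = set(trial_ids)
        return self.subset(np.array([t in wanted for t in self.trial_ids]))

    def window_keys(self) -> set[tuple[str, int]]:
        return set(zip(self.trial_ids.tolist(), self.starts.tolist()))


class TransformCache:
    """Memoizes per-(trial, start) transforms so a Plabel sweep only pays
    the CWT/FFT cost once (raw window content does not depend on Plabel)."""

    def __init__(self) -> None:
        self._store: dict[tuple[str, int], tuple[np.ndarray, np.ndarray]] = {}

    def get(self, key):
        return self._store.get(key)

    def put(self, key, tf, sp):
        self._store[key] = (tf, sp)


def featurize_trials(
    trials: Sequence[SignalTrial],
    wcfg: WindowingConfig,
    cache: TransformCache | None = None,
    preprocessed: bool = False,
) -> FeatureSet:
    """Condition trials, segment them and compute per-window transforms."""
    tf_list, sp_list = [], []
    labels, tids, starts, sids = [], [], [], []
    for trial in trials:
        cooked = trial if preprocessed else preprocess_trial(trial)
        windows, _ = segment_windows(cooked, wcfg)
        fresh = [w for w in windows
                 if cache is None or cache.get((w.trial_id, w.window_start_ms)) is None]
        if fresh:
            tf_new, sp_new, _ = batch_features(fresh, fs=trial.fs)
            if cache is not None:
                for i, w in enumerate(fresh):
                    cache.put((w.trial_id, w.window_start_ms), tf_new[i], sp_new[i])
        fresh_pos = {(w.trial_id, w.window_start_ms): i for i, w in enumerate(fresh)}
        for w in windows:
            key = (w.trial_id, w.window_start_ms)
            if cache is not None and key not in fresh_pos:
                tf_w, sp_w = cache.get(key)
            else:
                tf_w, sp_w = tf_new[fresh_pos[key]], sp_new[fresh_pos[key]]
            tf_list.append(tf_w)
            sp_list.append(sp_w)
            labels.append(w.label)
            tids.append(w.trial_id)
            starts.append(w.window_start_ms)
            sids.append(w.subject_id)
    if not labels:
        raise ValueError("no windows survived segmentation")
    return FeatureSet(
        tfmap=np.stack(tf_list),
        spectrum=np.stack(sp_list),
        labels=np.array(labels, dtype=np.int64),
        trial_ids=np.array(tids),
        starts=np.array(starts, dtype=np.int64),
        subject_ids=np.array(sids),
    )


# --------------------------------------------------------------------------
# splits

@dataclass(frozen=True)
class FoldSplit:
    fold: int
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]


def kfold_split(trials: Sequence[SignalTrial], k: int = 5, seed: int = 0
                ) -> list[FoldSplit]:
    """Trial-level five-fold rotation with a nested 7:1:2 train/val/test.

    Splits are computed within subject: per subject the shuffled trials form
    k non-overlapping groups; in fold f the f-th group is the test set and
    one of the remaining trials (rotating with f) is the validation trial.
    With 10 trials per subject this realizes exactly 7 train / 1 val /
    2 test.
    """
    by_subject: dict[str, list[str]] = {}
    for t in trials:
        by_subject.setdefault(t.subject_id, []).append(t.trial_id)
    for sid, ids in by_subject.items():
        if len(ids) < 2 * k:
            raise ValueError(
                f"subject {sid} has {len(ids)} trials; at least {2 * k} are "
                "needed to realize the 7:1:2 trial-level split"
            )
    folds: list[FoldSplit] = []
    for f in range(k):
        train: list[str] = []
        val: list[str] = []
        test: list[str] = []
        for sid in sorted(by_subject):
            ids = np.array(by_subject[sid])
            sid_hash = zlib.crc32(sid.encode()) % 2**31
            perm = ids[np.random.default_rng([seed, sid_hash]).permutation(len(ids))]
            groups = np.array_split(perm, k)
            test.extend(groups[f].tolist())
            remaining = np.concatenate([g for i, g in enumerate(groups) if i != f])
            n_val = max(1, round(len(ids) / 10))
            val_pos = [(f * n_val + j) % len(remaining) for j in range(n_val)]
            val.extend(remaining[val_pos].tolist())
            train.extend(np.delete(remaining, val_pos).tolist())
        folds.append(FoldSplit(f, tuple(train), tuple(val), tuple(test)))
    return folds


def assert_no_leakage(train: FeatureSet, val: FeatureSet, test: FeatureSet) -> None:
    """Hash-based guard: no (trial_id, window_start) may cross the split."""
    tr, va, te = train.window_keys(), val.window_keys(), test.window_keys()
    if tr & te or va & te or tr & va:
        raise AssertionError("window leakage across train/val/test splits")


# --------------------------------------------------------------------------
# metrics

@dataclass
class FoldResult:
    """Per-fold evaluation: accuracy / macro precision / recall / F1 in
    percent and the 17x17 confusion matrix (rows true, columns predicted)."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: np.ndarray
    n_test: int
    fold: int = -1
    plabel_ms: int | None = None
    variant: str | None = None
    history: dict = field(default_factory=dict)
    predictions: "pandas.DataFrame | None" = None  # window id, true, predicted, probs

    def to_dict(self) -> dict:
        return {
            "fold": self.fold,
            "variant": self.variant,
            "plabel_ms": self.plabel_ms,
            "n_test": self.n_test,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "confusion": self.confusion.tolist(),
            "history": self.history,
        }


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray,
                     n_classes: int = N_CLASSES) -> np.ndarray:
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true - 1, y_pred - 1), 1)
    return cm


def metrics_from_confusion(cm: np.ndarray) -> dict[str, float]:
    """Accuracy plus macro precision/recall/F1 (percent), macro-averaged
    over the classes present in the test labels (row support > 0)."""
    total = cm.sum()
    if total == 0:
        raise ValueError("empty test set")
    accuracy = float(np.trace(cm) / total)
    support = cm.sum(axis=1)
    predicted = cm.sum(axis=0)
    present = support > 0
    diag = np.diag(cm).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(predicted > 0, diag / np.maximum(predicted, 1), 0.0)
        rec = np.where(present, diag / np.maximum(support, 1), 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / np.maximum(prec + rec, 1e-300), 0.0)
    return {
        "accuracy": 100.0 * accuracy,
        "precision": 100.0 * float(prec[present].mean()),
        "recall": 100.0 * float(rec[present].mean()),
        "f1": 100.0 * float(f1[present].mean()),
    }


def _onehot(labels: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    return np.eye(n_classes, dtype=np.float32)[labels - 1]


def _loss_and_grads(out, y1h):
    if isinstance(out, tuple):
        loss, da, db = averaged_probs_cross_entropy(out[0], out[1], y1h)
        return loss, (da, db)
    return softmax_cross_entropy(out, y1h)


def _batched_loss(model: IntentNetwork, fs: FeatureSet, batch: int = 128) -> float:
    total, n = 0.0, len(fs)
    y1h = _onehot(fs.labels, model.cfg.n_classes)
    for i0 in range(0, n, batch):
        out = model.forward(fs.tfmap[i0:i0 + batch], fs.spectrum[i0:i0 + batch],
                            train=False)
        loss, _ = _loss_and_grads(out, y1h[i0:i0 + batch])
        total += loss * min(batch, n - i0)
    return total / n


def calibrate_batchnorm(model: IntentNetwork, fs: FeatureSet,
                        batch: int = 128, max_windows: int = 768) -> None:
    """Precise batch-norm recalibration: replace every BN layer's running
    statistics with exact aggregate statistics over (a capped prefix of) the
    training set.  With only a few mini-batches per epoch the exponential
    moving average lags far behind the fast-moving activations of a deep
    stack, which would wreck evaluation-mode predictions."""
    from .nn.layers import BatchNorm, Dropout

    bns = [m for _, m in model.named_modules() if isinstance(m, BatchNorm)]
    drops = [m for _, m in model.named_modules() if isinstance(m, Dropout)]
    saved = [d.p for d in drops]
    for d in drops:
        d.p = 0.0
    for bn in bns:
        bn.start_calibration()
    n = min(len(fs), max_windows)
    for i0 in range(0, n, batch):
        model.forward(fs.tfmap[i0:i0 + batch], fs.spectrum[i0:i0 + batch],
                      train=True)
    for bn in bns:
        bn.finish_calibration()
    for d, p in zip(drops, saved):
        d.p = p


def train_model(model: IntentNetwork, train: FeatureSet, val: FeatureSet,
                tcfg: TrainConfig) -> dict:
    """Mini-batch AdamW loop with ReduceLROnPlateau on the validation loss,
    early stopping, and best-validation weight restoration.  Fully seeded:
    data order and dropout derive from ``tcfg.seed``."""
    if len(train) == 0 or len(val) == 0:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng([tcfg.seed, 0x5EED])
    model.set_rng(np.random.default_rng([tcfg.seed, 0xD409]))
    opt = AdamW(model.parameters(), lr=tcfg.lr, betas=tcfg.betas,
                weight_decay=tcfg.weight_decay)
    sched = ReduceLROnPlateau(opt, factor=tcfg.scheduler_factor,
                              patience=tcfg.scheduler_patience)
    y1h = _onehot(train.labels, model.cfg.n_classes)
    history = {"train_loss": [], "val_loss": [], "lr": []}
    best_val, best_epoch, best_state = np.inf, 0, model.state_dict()
    for epoch in range(1, tcfg.epochs + 1):
        perm = rng.permutation(len(train))
        epoch_loss, n_batches = 0.0, 0
        for i0 in range(0, len(train), tcfg.batch_size):
            idx = perm[i0:i0 + tcfg.batch_size]
            out = model.forward(train.tfmap[idx], train.spectrum[idx], train=True)
            loss, grads = _loss_and_grads(out, y1h[idx])
            opt.zero_grad()
            model.backward(grads)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        calibrate_batchnorm(model, train)
        val_loss = _batched_loss(model, val)
        sched.step(val_loss)
        history["train_loss"].append(epoch_loss / max(n_batches, 1))
        history["val_loss"].append(val_loss)
        history["lr"].append(opt.lr)
        if val_loss < best_val:
            best_val, best_epoch, best_state = val_loss, epoch, model.state_dict()
        if epoch - best_epoch >= tcfg.early_stop_patience:
            break
    model.load_state_dict(best_state)
    history["best_epoch"] = best_epoch
    history["best_val_loss"] = float(best_val)
    return history


def evaluate(model: IntentNetwork, test: FeatureSet, batch: int = 128) -> FoldResult:
    """Confusion matrix and Table-style metrics on a test set."""
    if len(test) == 0:
        raise ValueError("empty test set")
    import pandas as pd

    probs_all = []
    for i0 in range(0, len(test), batch):
        probs_all.append(model.predict_proba(test.tfmap[i0:i0 + batch],
                                             test.spectrum[i0:i0 + batch]))
    probs = np.concatenate(probs_all)
    y_pred = probs.argmax(axis=1) + 1
    cm = confusion_matrix(test.labels, y_pred, n_classes=model.cfg.n_classes)
    m = metrics_from_confusion(cm)
    preds = pd.DataFrame({
        "window_id": [f"{t}:{s}" for t, s in zip(test.trial_ids, test.starts)],
        "true": test.labels,
        "predicted": y_pred,
    })
    for i in range(model.cfg.n_classes):
        preds[f"p{i + 1}"] = probs[:, i]
    return FoldResult(
        accuracy=m["accuracy"], precision=m["precision"], recall=m["recall"],
        f1=m["f1"], confusion=cm, n_test=len(test), predictions=preds,
    )


# --------------------------------------------------------------------------
# Model / Results surface

class MotionIntentModel:
    """Motion-intent classifier bound to featurized training/validation data.

    Parameters
    ----------
    train, val : FeatureSet
        Featurized windows for optimization and for scheduler/early-stop
        monitoring.  They must not share any (trial, window) pair.
    variant : str
        Fusion variant name (see :data:`semgintent.config.FUSION_VARIANTS`).
    """

    def __init__(self, train: FeatureSet, val: FeatureSet,
                 variant: str = "baseline",
                 model_config: ModelConfig | None = None,
                 ifia_config: IFIAConfig | None = None):
        self.train_set = train
        self.val_set = val
        self.variant = variant
        self.model_config = model_config or ModelConfig()
        self.ifia_config = ifia_config or IFIAConfig()
        if train.window_keys() & val.window_keys():
            raise ValueError("train and validation sets share windows")

    @classmethod
    def from_trials(cls, train_trials, val_trials, wcfg: WindowingConfig,
                    variant: str = "baseline", cache: TransformCache | None = None,
                    **kw) -> "MotionIntentModel":
        return cls(featurize_trials(train_trials, wcfg, cache),
                   featurize_trials(val_trials, wcfg, cache), variant, **kw)

    def build_network(self, seed: int = 0) -> IntentNetwork:
        return build_variant(self.variant, self.model_config, self.ifia_config,
                             seed=seed)

    def fit(self, train_config: TrainConfig | None = None) -> "MotionIntentResults":
        tcfg = train_config or TrainConfig()
        network = self.build_network(seed=tcfg.seed)
        history = train_model(network, self.train_set, self.val_set, tcfg)
        return MotionIntentResults(self, network, history, tcfg)


class MotionIntentResults:
    """Fitted-model container: trained network, loss history, diagnostics."""

    def __init__(self, model: MotionIntentModel, network: IntentNetwork,
                 history: dict, train_config: TrainConfig):
        self.model = model
        self.network = network
        self.history = history
        self.train_config = train_config

    @property
    def n_parameters(self) -> int:
        return count_parameters(self.network)

    def predict_proba(self, fs: FeatureSet) -> np.ndarray:
        return self.network.predict_proba(fs.tfmap, fs.spectrum)

    def predict(self, fs: FeatureSet) -> np.ndarray:
        return self.predict_proba(fs).argmax(axis=1) + 1

    def evaluate(self, fs: FeatureSet) -> FoldResult:
        res = evaluate(self.network, fs)
        res.variant = self.model.variant
        res.history = {k: v for k, v in self.history.items()}
        return res

    def summary(self) -> str:
        h = self.history
        lines = [
            "Motion-intent classification results",
            "=" * 52,
            f"{'fusion variant':<28}{self.model.variant:>24}",
            f"{'trainable parameters':<28}{self.n_parameters:>24,}",
            f"{'train windows':<28}{len(self.model.train_set):>24}",
            f"{'validation windows':<28}{len(self.model.val_set):>24}",
            f"{'epochs run':<28}{len(h['train_loss']):>24}",
            f"{'best epoch':<28}{h['best_epoch']:>24}",
            f"{'best validation loss':<28}{h['best_val_loss']:>24.4f}",
            f"{'final learning rate':<28}{h['lr'][-1]:>24.6f}",
            "=" * 52,
        ]
        return "\n".join(lines)


# --------------------------------------------------------------------------
# protocol drivers

def run_fold(
    features: FeatureSet,
    split: FoldSplit,
    variant: str = "baseline",
    tcfg: TrainConfig | None = None,
    model_config: ModelConfig | None = None,
    ifia_config: IFIAConfig | None = None,
) -> FoldResult:
    """Train and evaluate one fold from pre-featurized windows.

    Useful when several variants share one featurization: the (large)
    scalogram tensor is computed and held once instead of per variant."""
    train = features.for_trials(split.train_ids)
    val = features.for_trials(split.val_ids)
    test = features.for_trials(split.test_ids)
    assert_no_leakage(train, val, test)
    model = MotionIntentModel(train, val, variant,
                              model_config=model_config,
                              ifia_config=ifia_config)
    res = model.fit(tcfg or TrainConfig()).evaluate(test)
    res.fold = split.fold
    return res


def run_cross_validation(
    trials: Sequence[SignalTrial],
    wcfg: WindowingConfig,
    variant: str = "baseline",
    tcfg: TrainConfig | None = None,
    model_config: ModelConfig | None = None,
    ifia_config: IFIAConfig | None = None,
    k: int = 5,
    folds: Sequence[int] | None = None,
    cache: TransformCache | None = None,
    split_seed: int = 0,
) -> list[FoldResult]:
    """Five-fold trial-level protocol: featurize once, then train and
    evaluate the requested folds for one fusion variant."""
    cooked = [preprocess_trial(t) for t in trials]
    features = featurize_trials(cooked, wcfg, cache, preprocessed=True)
    splits = kfold_split(trials, k=k, seed=split_seed)
    if folds is not None:
        splits = [s for s in splits if s.fold in set(folds)]
    results = []
    for split in splits:
        res = run_fold(features, split, variant, tcfg,
                       model_config=model_config, ifia_config=ifia_config)
        res.plabel_ms = wcfg.plabel_ms
        results.append(res)
    return results


def plabel_sweep(
    trials: Sequence[SignalTrial],
    wcfg: WindowingConfig,
    plabels: Sequence[int] = (100, 200, 300, 400, 500),
    variant: str = "baseline",
    tcfg: TrainConfig | None = None,
    folds: Sequence[int] | None = (0,),
    **kw,
) -> dict[int, list[FoldResult]]:
    """Re-run the protocol per prediction time; raw windows are identical
    across Plabels (only labels shift), so transforms are shared."""
    if any(p < 0 for p in plabels):
        raise ValueError("plabels must be nonnegative")
    cache = TransformCache()
    out: dict[int, list[FoldResult]] = {}
    for p in plabels:
        wp = dataclasses.replace(wcfg, plabel_ms=p)
        out[p] = run_cross_validation(trials, wp, variant=variant, tcfg=tcfg,
                                      folds=folds, cache=cache, **kw)
    return out


def summarize_results(results: Mapping[str, Sequence[FoldResult]]) -> "pandas.DataFrame":
    """Aggregate FoldResults into a mean +- std table (per key and overall)."""
    import pandas as pd

    rows = []
    for key, folds_ in results.items():
        for r in folds_:
            rows.append({"group": key, "fold": r.fold, "accuracy": r.accuracy,
                         "precision": r.precision, "recall": r.recall, "f1": r.f1})
    df = pd.DataFrame(rows)
    agg = df.groupby("group")[["accuracy", "precision", "recall", "f1"]].agg(
        ["mean", "std"]
    )
    overall = df[["accuracy", "precision", "recall", "f1"]].agg(["mean", "std"])
    agg.loc["Mean"] = overall.T.stack()
    return agg
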