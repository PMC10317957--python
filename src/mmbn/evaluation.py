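"""Cross-validation harness, classification metrics and ablation experiments.

The standard protocol is stratified ten-fold cross-validation: per fold, 90%
of the windows train the model (10% of that as validation for best-epoch
selection) and the held-out 10% is scored. Seizure is the positive class,
so sensitivity is the seizure true-positive rate and specificity the normal
true-negative rate, both reported in percent.

Caveat: window-wise splitting matches the usual sample bookkeeping, but when
windows overlap in time, adjacent train/test windows share samples and leak
information. With the non-overlapping synthetic windows used in the tests
this does not arise; for real overlapping-window data, group windows by
recording (``groups`` argument) to get an honest estimate.

Ablations mirror the usual design questions: how many frequency bands to
split into (none / 2 / 4 / 8), one band at a time, and attention on or off.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .amcnn import AMCNN, ModelConfig, TrainConfig, build_model, train
from .network import MultilayerNetwork, build_mmbn, spearman_matrix, threshold_layer, LayerNetwork
from .nn import DTYPE

__all__ = [
    "EvalReport",
    "ExperimentSpec",
    "metrics_from_counts",
    "crossvalidate",
    "ablation_inputs",
    "run_ablation",
]


@dataclass
class EvalReport:
    """Confusion counts and derived metrics, per fold and aggregated.

    ``folds`` has one row per fold; ``aggregate`` is computed from the
    summed confusion counts (equivalently: each window is tested exactly
    once, so the aggregate is the whole-dataset confusion matrix).
    """

    folds: pd.DataFrame
    aggregate: dict

    @property
    def accuracy(self) -> float:
        return self.aggregate["accuracy"]

    @property
    def sensitivity(self) -> float:
        return self.aggregate["sensitivity"]

    @property
    def specificity(self) -> float:
        return self.aggregate["specificity"]

    def summary(self) -> str:
        a = self.aggregate
        lines = [
            f"folds: {len(self.folds)}",
            f"confusion: TP={a['TP']} TN={a['TN']} FP={a['FP']} FN={a['FN']}",
            f"accuracy:    {a['accuracy']:.2f}%",
            "sensitivity: " + (f"{a['sensitivity']:.2f}%" if a["sensitivity"] is not None else "undefined"),
            "specificity: " + (f"{a['specificity']:.2f}%" if a["specificity"] is not None else "undefined"),
        ]
        return "\n".join(lines)


def metrics_from_counts(TP: int, TN: int, FP: int, FN: int) -> dict:
    """Accuracy / sensitivity / specificity (in %) from confusion counts.

    Seizure is the positive class. A metric whose denominator is zero (e.g.
    sensitivity with no positive windows) is reported as None.
    """
    counts = dict(TP=TP, TN=TN, FP=FP, FN=FN)
    if min(counts.values()) < 0:
        raise ValueError("confusion counts must be nonnegative")
    total = TP + TN + FP + FN
    if total == 0:
        raise ValueError("empty confusion matrix")
    counts["accuracy"] = 100.0 * (TP + TN) / total
    counts["sensitivity"] = 100.0 * TP / (TP + FN) if TP + FN else None
    counts["specificity"] = 100.0 * TN / (TN + FP) if TN + FP else None
    return counts


def _counts(y_true: np.ndarray, y_pred: np.ndarray) -> tuple:
    TP = int(np.sum((y_true == 1) & (y_pred == 1)))
    TN = int(np.sum((y_true == 0) & (y_pred == 0)))
    FP = int(np.sum((y_true == 0) & (y_pred == 1)))
    FN = int(np.sum((y_true == 1) & (y_pred == 0)))
    return TP, TN, FP, FN


def crossvalidate(
    X: np.ndarray,
    y: np.ndarray,
    model_builder=None,
    train_config: TrainConfig | None = None,
    folds: int = 10,
    groups: np.ndarray | None = None,
) -> EvalReport:
    """Stratified k-fold cross-validation of the AM-CNN.

    Parameters
    ----------
    X : (n, N, N, n_branches) stacked MMBN layers
    y : (n,) binary labels
    model_builder : callable giving a fresh model per fold
        (default: AM-CNN with ``n_branches`` matching X). A stub returning
        an object with ``predict_proba`` and no ``train`` support must also
        provide a no-op fit path — anything accepted by
        :func:`mmbn.amcnn.train` works.
    groups : optional per-window recording ids; when given, folds are
        grouped so windows of one recording never straddle train and test.
    """
    from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

    X = np.asarray(X, dtype=DTYPE)
    y = np.asarray(y, dtype=int)
    if len(X) < folds:
        raise ValueError("dataset smaller than fold count")
    cfg = train_config or TrainConfig()
    if model_builder is None:
        model_builder = lambda: build_model(  # noqa: E731
            ModelConfig(n_channels=X.shape[1], n_branches=X.shape[3], seed=cfg.seed)
        )
    if groups is None:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cfg.seed % 2**31)
        split = splitter.split(X, y)
    else:
        splitter = StratifiedGroupKFold(n_splits=folds, shuffle=True, random_state=cfg.seed % 2**31)
        split = splitter.split(X, y, groups=groups)

    rows = []
    for fold, (tr, te) in enumerate(split):
        if len(np.unique(y[tr])) < 2:
            raise ValueError(
                f"fold {fold}: training split lacks a class; use stratification or change the seed"
            )
        model = model_builder()
        if hasattr(model, "params"):  # trainable AM-CNN vs test stub
            train(model, (X[tr], y[tr]), replace(cfg, seed=cfg.seed + fold))
        y_pred = model.predict_proba(X[te]).argmax(axis=1)
        TP, TN, FP, FN = _counts(y[te], y_pred)
        rows.append(dict(fold=fold, **metrics_from_counts(TP, TN, FP, FN)))
    df = pd.DataFrame(rows)
    agg = metrics_from_counts(
        int(df["TP"].sum()), int(df["TN"].sum()), int(df["FP"].sum()), int(df["FN"].sum())
    )
    return EvalReport(folds=df, aggregate=agg)


@dataclass
class ExperimentSpec:
    """One ablation cell: input variant x attention on/off.

    ``input_mode``: 'all_8_bands', 'single_band' (with ``band``),
    'two_bands' (0-32 / 32-64 Hz via the level-2 tree), 'four_bands'
    (16-Hz bands via the level-3 tree) or 'no_split' (Spearman network of
    the raw unsplit signals, one branch).
    """

    input_mode: str = "all_8_bands"
    band: int = 0
    attention: bool = True
    folds: int = 10

    _LEVELS = {"all_8_bands": 4, "two_bands": 2, "four_bands": 3}

    def __post_init__(self):
        if self.input_mode not in (*self._LEVELS, "single_band", "no_split"):
            raise ValueError(f"unknown input_mode {self.input_mode!r}")


def ablation_inputs(windows: list, spec: ExperimentSpec, fs: float = 256.0, **mmbn_kwargs):
    """Build the (X, y) model input for one ablation variant from raw windows."""
    y = np.array([w.label for w in windows], dtype=int)
    if spec.input_mode == "no_split":
        layers = []
        for w in windows:
            raw = LayerNetwork(weights=spearman_matrix(w.data), band_index=0)
            layers.append(threshold_layer(raw, **{k: v for k, v in mmbn_kwargs.items() if k in ("keep_fraction", "by_magnitude")}))
        X = np.stack([lay.weights for lay in layers])[..., None]
        return X.astype(DTYPE), y
    level = spec._LEVELS.get(spec.input_mode, 4)
    nets = [build_mmbn(w, fs=fs, level=level, **mmbn_kwargs) for w in windows]
    X = np.stack([net.as_array().transpose(1, 2, 0) for net in nets]).astype(DTYPE)
    if spec.input_mode == "single_band":
        if not 0 <= spec.band < X.shape[3]:
            raise ValueError(f"band {spec.band} outside 0..{X.shape[3] - 1}")
        X = X[..., spec.band : spec.band + 1]
    return X, y


def run_ablation(
    specs: list,
    windows: list,
    fs: float = 256.0,
    train_config: TrainConfig | None = None,
    model_seed: int = 0,
    **mmbn_kwargs,
) -> pd.DataFrame:
    """Cross-validate each experiment variant; one result row per spec."""
    cfg = train_config or TrainConfig()
    rows = []
    for spec in specs:
        X, y = ablation_inputs(windows, spec, fs=fs, **mmbn_kwargs)
        builder = lambda: build_model(  # noqa: E731
            ModelConfig(
                n_channels=X.shape[1], n_branches=X.shape[3], attention=spec.attention, seed=model_seed
            )
        )
        report = crossvalidate(X, y, model_builder=builder, train_config=cfg, folds=spec.folds)
        rows.append(
            {
                "input_mode": spec.input_mode,
                "band": spec.band if spec.input_mode == "single_band" else None,
                "attention": spec.attention,
                "n_branches": X.shape[3],
                "accuracy": report.accuracy,
                "sensitivity": report.sensitivity,
                "specificity": report.specificity,
            }
        )
    return pd.DataFrame(rows)
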