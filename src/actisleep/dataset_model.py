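"""Epoch dataset assembly and random-forest sleep-stage models.

``epoch_align`` merges one subject's 24 Hz record with the 30-s PSG epoch
grid: HRV features from the cleaned RR series, per-axis activity counts,
and raw-channel summaries (mean green/IR count per epoch), one row per
epoch with its stage label. Tables from several subjects are concatenated
into a single pooled dataset.

Four model variants are defined by a :class:`FeatureConfig`: feature family
(HRV vs acceleration counts) crossed with inclusion of the raw PPG
summaries, in multiclass (five-stage) or binary (wake/sleep) mode. The
classifier is a random forest (500 trees, entropy criterion, sqrt feature
subsampling) with entropy-based impurity feature importances; a small
deterministic comparison harness covers the usual alternative classifiers.

The default train/validation split is an epoch-level stratified random
split of the pooled table, which treats epochs as exchangeable rows; a
whole-subject hold-out split is available as the methodologically stricter
alternative (epochs within a subject are strongly dependent, so the
epoch-level split is optimistic about generalisation to new subjects).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from . import activity_counts, evaluation, hrv_features, rr_preprocess
from .synthetic import EPOCH_S, STAGES, RawRecord

logger = logging.getLogger("actisleep")

DEFAULT_SEED = 20230109
DEFAULT_N_TREES = 500

RAW_COLUMNS = ["green_mean", "ir_mean"]
COUNT_COLUMNS = ["counts_x", "counts_y", "counts_z", "vm"]
KEY_COLUMNS = ["subject_id", "epoch_index", "stage", "n_beats", "flag"]


@dataclass(frozen=True)
class FeatureConfig:
    """Which feature family a model sees.

    feature_family: "hrv" (HRV-derived variables) or "acceleration"
    (activity counts); include_raw adds the per-epoch mean green/IR PPG
    summaries; mode selects five-stage multiclass or binary wake/sleep.
    """

    feature_family: str = "hrv"
    include_raw: bool = True
    mode: str = "multiclass"

    def __post_init__(self) -> None:
        if self.feature_family not in ("hrv", "acceleration"):
            raise ValueError(f"unknown feature_family {self.feature_family!r}")
        if self.mode not in ("multiclass", "binary"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def feature_columns(self) -> list[str]:
        cols = (
            list(hrv_features.FEATURE_COLUMNS)
            if self.feature_family == "hrv"
            else list(COUNT_COLUMNS)
        )
        if self.include_raw:
            cols += RAW_COLUMNS
        return cols

    @property
    def label_column(self) -> str:
        return "stage" if self.mode == "multiclass" else "label"


#: The four model variants compared in the study design.
STANDARD_CONFIGS = {
    "hrv+raw": FeatureConfig("hrv", True),
    "hrv": FeatureConfig("hrv", False),
    "accel+raw": FeatureConfig("acceleration", True),
    "accel": FeatureConfig("acceleration", False),
}


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to reproduce it."""

    model: object
    feature_names: list[str]
    config: FeatureConfig
    seed: int
    n_dropped: int = 0

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return self.model.predict(table[self.feature_names].to_numpy())


def epoch_align(
    record: RawRecord,
    hypnogram: list[str],
    freq_window_s: float = hrv_features.DEFAULT_FREQ_WINDOW_S,
) -> pd.DataFrame:
    """One subject's epoch feature table aligned to the PSG epoch grid.

    Epoch i covers [i*30, (i+1)*30) seconds (half-open). Epochs beyond
    either the record or the hypnogram are dropped with a warning; zero
    overlap is an error.
    """
    n_epochs = min(record.n_epochs, len(hypnogram))
    if n_epochs == 0:
        raise ValueError("record and hypnogram share no complete epoch")
    if n_epochs < max(record.n_epochs, len(hypnogram)):
        logger.warning(
            "truncating to %d epochs (record has %d, hypnogram %d)",
            n_epochs, record.n_epochs, len(hypnogram),
        )
    rr = rr_preprocess.clean_rr(record.rr, times=record.t)
    hrv = hrv_features.extract_features_table(rr, n_epochs, freq_window_s=freq_window_s)
    stream = activity_counts.AccelStream(record.t, record.ax, record.ay, record.az)
    counts = activity_counts.counts_per_epoch(stream, n_epochs)
    spe = int(EPOCH_S * len(record.t) / record.duration_s)  # samples per epoch
    n_full = n_epochs * spe
    raw = pd.DataFrame(
        {
            "epoch_index": np.arange(n_epochs),
            "green_mean": record.green[:n_full].reshape(n_epochs, spe).mean(axis=1),
            "ir_mean": record.ir[:n_full].reshape(n_epochs, spe).mean(axis=1),
        }
    )
    out = hrv.merge(counts, on="epoch_index").merge(raw, on="epoch_index")
    out.insert(0, "subject_id", record.subject_id)
    out["stage"] = list(hypnogram[:n_epochs])
    return out


def build_dataset(
    cohort: list[tuple[RawRecord, list[str]]],
    freq_window_s: float = hrv_features.DEFAULT_FREQ_WINDOW_S,
) -> pd.DataFrame:
    """Pool several subjects' aligned epoch tables into one dataset."""
    tables = [epoch_align(rec, hyp, freq_window_s=freq_window_s) for rec, hyp in cohort]
    df = pd.concat(tables, ignore_index=True)
    if df.duplicated(subset=["subject_id", "epoch_index"]).any():
        raise ValueError("duplicated (subject, epoch) keys")
    return df


def relabel_binary(table: pd.DataFrame) -> pd.DataFrame:
    """Add a binary ``label`` column: wake -> 0, any sleep stage -> 1."""
    unknown = sorted(set(table["stage"]) - set(STAGES))
    if unknown:
        raise ValueError(f"unknown stage label(s): {unknown}")
    out = table.copy()
    out["label"] = (out["stage"] != "W").astype(int)
    return out


def split(
    table: pd.DataFrame,
    strategy: str = "epoch",
    fraction: float = 0.2,
    seed: int = DEFAULT_SEED,
    label_column: str = "stage",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition the table into (train, valid).

    strategy "epoch": label-stratified random split over rows, ``fraction``
    in the validation part. strategy "subject": round(fraction * n_subjects)
    whole subjects held out.
    """
    if len(table) < 2:
        raise ValueError("need >= 2 rows to split")
    if strategy == "epoch":
        train, valid = train_test_split(
            table,
            test_size=fraction,
            random_state=seed % (2**32),
            stratify=table[label_column],
        )
        if set(valid[label_column]) - set(train[label_column]):
            raise ValueError("a label is absent from the training part")
        return train, valid
    if strategy == "subject":
        subjects = sorted(table["subject_id"].unique())
        n_valid = max(1, round(fraction * len(subjects)))
        rng = np.random.default_rng(seed)
        held_out = set(rng.choice(subjects, size=n_valid, replace=False))
        mask = table["subject_id"].isin(held_out)
        return table[~mask], table[mask]
    raise ValueError(f"unknown split strategy {strategy!r}")


def _model_matrix(table: pd.DataFrame, config: FeatureConfig) -> tuple[pd.DataFrame, list[str]]:
    """Select feature columns, dropping all-NaN columns (e.g. VLF on short
    spectral windows) and rows with any remaining missing value."""
    cols = [c for c in config.feature_columns if not table[c].isna().all()]
    clean = table.dropna(subset=cols)
    return clean, cols


def train_rf(
    train: pd.DataFrame,
    config: FeatureConfig,
    n_estimators: int = DEFAULT_N_TREES,
    seed: int = DEFAULT_SEED,
) -> TrainedModel:
    """Fit the random forest (entropy criterion, sqrt-feature splits)."""
    clean, cols = _model_matrix(train, config)
    n_dropped = len(train) - len(clean)
    if n_dropped:
        logger.info("dropped %d epochs with missing features", n_dropped)
    y = clean[config.label_column].to_numpy()
    if config.mode == "multiclass" and len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    rf = RandomForestClassifier(
        n_estimators=n_estimators,
        criterion="entropy",
        max_features="sqrt",
        random_state=seed % (2**32),
        n_jobs=1,
    )
    rf.fit(clean[cols].to_numpy(), y)
    return TrainedModel(rf, cols, config, seed, n_dropped)


def feature_importance(m: TrainedModel) -> list[tuple[str, float]]:
    """Impurity (information-gain) importances, descending; they sum to 1."""
    imp = m.model.feature_importances_
    order = np.argsort(imp)[::-1]
    return [(m.feature_names[i], float(imp[i])) for i in order]


def evaluate_model(m: TrainedModel, valid: pd.DataFrame) -> dict:
    """Confusion matrix and metric set of a fitted model on held-out rows."""
    clean, _ = _model_matrix(valid, m.config)
    y_true = clean[m.config.label_column].to_numpy()
    y_pred = m.predict(clean)
    order = (
        evaluation.MULTICLASS_LABEL_ORDER
        if m.config.mode == "multiclass"
        else evaluation.BINARY_LABEL_ORDER
    )
    cm = evaluation.confusion(y_true, y_pred, label_order=order)
    out = evaluation.metrics(cm)
    out["confusion_matrix"] = cm
    out["n_valid"] = len(clean)
    return out


def run_config(
    table: pd.DataFrame,
    config: FeatureConfig,
    strategy: str = "epoch",
    fraction: float = 0.2,
    seed: int = DEFAULT_SEED,
    n_estimators: int = DEFAULT_N_TREES,
) -> dict:
    """Split, fit and evaluate one feature configuration end to end."""
    work = relabel_binary(table) if config.mode == "binary" else table
    train, valid = split(work, strategy=strategy, fraction=fraction, seed=seed,
                         label_column=config.label_column)
    model = train_rf(train, config, n_estimators=n_estimators, seed=seed)
    result = evaluate_model(model, valid)
    result["model"] = model
    return result


_ALGORITHMS = {
    "Random Forest Classifier": lambda seed: RandomForestClassifier(
        n_estimators=DEFAULT_N_TREES, criterion="entropy", max_features="sqrt",
        random_state=seed, n_jobs=1),
    "Extra Trees Classifier": lambda seed: ExtraTreesClassifier(
        n_estimators=DEFAULT_N_TREES, criterion="entropy", max_features="sqrt",
        random_state=seed, n_jobs=1),
    "Gradient Boosting Classifier": lambda seed: GradientBoostingClassifier(
        random_state=seed),
    "Decision Tree Classifier": lambda seed: DecisionTreeClassifier(random_state=seed),
    "K Neighbors Classifier": lambda seed: KNeighborsClassifier(),
    "Linear Discriminant Analysis": lambda seed: LinearDiscriminantAnalysis(),
    "Logistic Regression": lambda seed: LogisticRegression(max_iter=1000),
    "Naive Bayes": lambda seed: GaussianNB(),
}


def compare_algorithms(
    train: pd.DataFrame,
    valid: pd.DataFrame,
    config: FeatureConfig | None = None,
    algorithms: list[str] | None = None,
    seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """Deterministic comparison harness over standard classifiers.

    Returns one row per algorithm with Accuracy / AUC (one-vs-rest macro) /
    Recall / Prec. / F1 / Kappa / MCC on the validation rows.
    """
    config = FeatureConfig() if config is None else config
    if algorithms is None:
        algorithms = list(_ALGORITHMS)
    unknown = set(algorithms) - set(_ALGORITHMS)
    if unknown:
        raise ValueError(f"unknown algorithm(s): {sorted(unknown)}")
    tr, cols = _model_matrix(train, config)
    va, _ = _model_matrix(valid, config)
    X_tr, y_tr = tr[cols].to_numpy(), tr[config.label_column].to_numpy()
    X_va, y_va = va[cols].to_numpy(), va[config.label_column].to_numpy()
    order = (
        evaluation.MULTICLASS_LABEL_ORDER
        if config.mode == "multiclass"
        else evaluation.BINARY_LABEL_ORDER
    )
    rows = []
    for name in algorithms:
        clf = _ALGORITHMS[name](seed % (2**32))
        clf.fit(X_tr, y_tr)
        y_pred = clf.predict(X_va)
        m = evaluation.metrics(evaluation.confusion(y_va, y_pred, label_order=order))
        if hasattr(clf, "predict_proba"):
            proba = clf.predict_proba(X_va)
            if proba.shape[1] == 2:
                auc = roc_auc_score(y_va, proba[:, 1])
            else:
                auc = roc_auc_score(y_va, proba, multi_class="ovr", average="macro")
        else:
            auc = np.nan
        rows.append(
            {
                "Model": name,
                "Accuracy": m["accuracy"],
                "AUC": auc,
                "Recall": m["macro_recall"],
                "Prec.": m["macro_precision"],
                "F1": m["macro_f1"],
                "Kappa": m["kappa"],
                "MCC": m["mcc"],
            }
        )
    return pd.DataFrame(rows)
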