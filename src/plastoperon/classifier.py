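"""Bootstrap random-forest classification of adjacent gene pairs.

Pairs are modelled separately for two schemas: the CDS group (both members
protein-coding, with codon-usage and hydropathy features available) and
the mixed group (any pair involving a tRNA or rRNA).  For each group an
ensemble of forests is trained over repeated random 70/30
train/cross-validation splits; the headline metric is the mean held-out
accuracy over rounds, and genome-wide predictions take the majority vote
of the ensemble (vote fraction reported as a 0..1 operon score).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.pipeline import Pipeline

logger = logging.getLogger("plastoperon")

META_COLUMNS = ("genome_id", "gene5", "gene3", "pair_group", "label")

VOTE_THRESHOLD = 0.5  # score >= threshold -> operon pair; ties resolve to 1


@dataclass
class LabeledDataset:
    """Feature matrix plus binary labels for one pair group."""

    features: pd.DataFrame  # numeric feature columns only, indexed by pair_id
    labels: pd.Series  # 1 = operon pair
    group: str

    def __post_init__(self) -> None:
        if not self.features.index.equals(self.labels.index):
            self.labels = self.labels.reindex(self.features.index)
        if self.labels.isna().any():
            raise ValueError("every feature vector needs a label")
        self.labels = self.labels.astype(int)

    @classmethod
    def from_table(
        cls, table: pd.DataFrame, labels: Mapping[str, int] | pd.Series, group: str
    ) -> "LabeledDataset":
        """Build from a feature table (as produced by ``features.feature_table``).

        Keeps only rows of ``group`` and drops metadata and all-missing
        columns (the CDS-only columns vanish for the mixed group rather
        than being zero-filled).
        """
        sub = table[table["pair_group"] == group]
        feats = sub.drop(columns=[c for c in META_COLUMNS if c in sub.columns])
        feats = feats.select_dtypes(include=[np.number])
        feats = feats.dropna(axis=1, how="all")
        lab = pd.Series(labels).reindex(feats.index)
        return cls(features=feats, labels=lab, group=group)

    def __len__(self) -> int:
        return len(self.features)


@dataclass
class EnsembleModel:
    group: str
    members: list[Pipeline]
    selected_features: list[str]
    seeds: list[int]
    cv_accuracies: list[float]
    trees: int
    train_frac: float

    @property
    def mean_cv_accuracy(self) -> float:
        return float(np.mean(self.cv_accuracies))

    def __post_init__(self) -> None:
        if not (len(self.members) == len(self.seeds) == len(self.cv_accuracies)):
            raise ValueError("members, seeds and cv_accuracies must align")


@dataclass(frozen=True)
class PairPrediction:
    pair_id: str
    score: float
    label: int


def accuracy(tp: int, tn: int, n: int) -> float:
    """(TP + TN) / N — fraction of pairs classified correctly."""
    if n <= 0:
        raise ValueError("n must be positive")
    if tp + tn > n:
        raise ValueError("tp + tn cannot exceed n")
    return (tp + tn) / n


def _make_forest(trees: int, seed: int) -> Pipeline:
    return Pipeline(
        [
            (
                "impute",
                SimpleImputer(strategy="median", keep_empty_features=True),
            ),
            (
                "forest",
                RandomForestClassifier(
                    n_estimators=trees, random_state=seed, n_jobs=1
                ),
            ),
        ]
    )


def _split(
    n: int, train_frac: float, rng: np.random.Generator, y: np.ndarray, stratify: bool
) -> tuple[np.ndarray, np.ndarray]:
    if stratify:
        train_idx: list[int] = []
        for cls in np.unique(y):
            members = np.flatnonzero(y == cls)
            rng.shuffle(members)
            k = max(1, int(round(train_frac * len(members))))
            train_idx.extend(members[:k])
        train = np.sort(np.asarray(train_idx))
    else:
        perm = rng.permutation(n)
        train = np.sort(perm[: int(round(train_frac * n))])
    test = np.setdiff1d(np.arange(n), train)
    return train, test


def train_bootstrap(
    data: LabeledDataset,
    rounds: int = 10,
    train_frac: float = 0.7,
    trees: int = 1000,
    seed: int | None = None,
    stratify: bool = False,
    eval_labels: pd.Series | None = None,
) -> EnsembleModel:
    """Train the bootstrap forest ensemble.

    Each round draws a fresh random 70/30 split (simple random, not
    stratified, by default), fits a forest on the train part and records
    accuracy on the held-out 30%.  ``eval_labels`` lets held-out accuracy
    be scored against a different label vector than the one trained on
    (used by the label-error robustness test).  All randomness flows from
    ``seed`` via per-round seeds recorded in the model.
    """
    if len(data) < 20:
        raise ValueError("need at least 20 labeled pairs")
    y = data.labels.to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    X = data.features.to_numpy(dtype=float)
    y_eval = y if eval_labels is None else eval_labels.reindex(data.features.index).to_numpy()
    root = np.random.default_rng(seed)
    round_seeds = [int(s) for s in root.integers(0, 2**31 - 1, size=rounds)]
    members, accs = [], []
    for rseed in round_seeds:
        rng = np.random.default_rng(rseed)
        for _ in range(100):  # redraw if the train part is single-class
            train, test = _split(len(y), train_frac, rng, y, stratify)
            if len(np.unique(y[train])) == 2 and len(test) > 0:
                break
        model = _make_forest(trees, rseed)
        model.fit(X[train], y[train])
        pred = model.predict(X[test])
        accs.append(float(np.mean(pred == y_eval[test])))
        members.append(model)
    return EnsembleModel(
        group=data.group,
        members=members,
        selected_features=list(data.features.columns),
        seeds=round_seeds,
        cv_accuracies=accs,
        trees=trees,
        train_frac=train_frac,
    )


def _mean_importances(model: EnsembleModel) -> np.ndarray:
    return np.mean(
        [m.named_steps["forest"].feature_importances_ for m in model.members], axis=0
    )


def backward_elimination(
    data: LabeledDataset,
    rounds_per_iter: int = 10,
    drop_per_iter: int = 1,
    trees: int = 1000,
    seed: int | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Wrapped backward feature elimination.

    Iterates: evaluate the current feature set by mean cross-validation
    accuracy over bootstrap rounds, then remove the feature(s) with the
    lowest mean impurity importance.  Constant (zero-variance) features
    are dropped up front with a warning.  The returned selection is the
    smallest feature set whose mean accuracy lies within one standard
    deviation of the best observed mean — a deterministic stand-in for a
    by-eye choice from the accuracy trace, which is returned in full so a
    human can override it.
    """
    feats = data.features.copy()
    constant = [c for c in feats.columns if feats[c].nunique(dropna=True) <= 1]
    if constant:
        logger.warning("dropping constant features first: %s", constant)
        feats = feats.drop(columns=constant)
    if feats.shape[1] < 2:
        raise ValueError("need at least 2 non-constant features")
    root = np.random.default_rng(seed)
    trace_rows = []
    current = list(feats.columns)
    while True:
        subset = LabeledDataset(feats[current], data.labels, data.group)
        model = train_bootstrap(
            subset,
            rounds=rounds_per_iter,
            trees=trees,
            seed=int(root.integers(0, 2**31 - 1)),
        )
        trace_rows.append(
            {
                "n_features": len(current),
                "mean_accuracy": model.mean_cv_accuracy,
                "sd_accuracy": float(np.std(model.cv_accuracies)),
                "features": ",".join(current),
            }
        )
        if len(current) <= drop_per_iter:
            break
        importances = _mean_importances(model)
        order = np.argsort(importances)
        drop = {current[i] for i in order[:drop_per_iter]}
        current = [c for c in current if c not in drop]
    trace = pd.DataFrame(trace_rows)
    best_i = int(trace["mean_accuracy"].idxmax())
    threshold = trace.loc[best_i, "mean_accuracy"] - trace.loc[best_i, "sd_accuracy"]
    eligible = trace[trace["mean_accuracy"] >= threshold]
    chosen = eligible.loc[eligible["n_features"].idxmin()]
    selected = chosen["features"].split(",")
    return selected, trace


def error_robustness(
    data: LabeledDataset,
    max_errors: int = 19,
    error_type: str = "type_I",
    rounds: int = 10,
    trees: int = 1000,
    seed: int | None = None,
) -> list[tuple[int, float]]:
    """Accuracy degradation under injected label errors.

    For each error count 0..max, flips that many labels in a fresh copy
    (type I: 0 -> 1 false positives; type II: 1 -> 0 false negatives),
    retrains the bootstrap ensemble on the corrupted labels, and records
    mean held-out accuracy scored against the ORIGINAL labels.  The
    zero-error point runs ``train_bootstrap`` with ``seed`` itself, so it
    reproduces the uncorrupted headline accuracy exactly.
    """
    if error_type not in ("type_I", "type_II"):
        raise ValueError("error_type must be 'type_I' or 'type_II'")
    source_class = 0 if error_type == "type_I" else 1
    candidates = data.labels.index[data.labels == source_class]
    if max_errors > len(candidates):
        raise ValueError(
            f"cannot inject {max_errors} errors: only {len(candidates)} "
            f"labels of class {source_class}"
        )
    root = np.random.default_rng(seed)
    curve = []
    for k in range(max_errors + 1):
        flip = root.choice(candidates, size=k, replace=False)
        corrupted = data.labels.copy()
        corrupted.loc[flip] = 1 - source_class
        run_seed = int(root.integers(0, 2**31 - 1))
        if k == 0:
            model = train_bootstrap(data, rounds=rounds, trees=trees, seed=seed)
        else:
            corrupted_data = LabeledDataset(data.features, corrupted, data.group)
            model = train_bootstrap(
                corrupted_data,
                rounds=rounds,
                trees=trees,
                seed=run_seed,
                eval_labels=data.labels,
            )
        curve.append((k, model.mean_cv_accuracy))
    return curve


def predict_majority(
    models: Mapping[str, EnsembleModel],
    vectors: pd.DataFrame,
    max_missing_frac: float = 0.5,
) -> list[PairPrediction]:
    """Majority vote of the ensemble, routed by pair group.

    score = fraction of members voting operon; label 1 when score >= 0.5
    (a 5/10 tie resolves to operon).  Rows missing more than half of the
    model's features are skipped with a logged reason.
    """
    predictions: list[PairPrediction] = []
    for group, model in models.items():
        sub = vectors[vectors["pair_group"] == group]
        if sub.empty:
            continue
        unknown = [
            c
            for c in model.selected_features
            if c not in sub.columns
        ]
        if unknown:
            raise ValueError(f"feature schema mismatch; missing columns: {unknown}")
        X_df = sub.reindex(columns=model.selected_features)
        missing_frac = X_df.isna().mean(axis=1)
        usable = missing_frac <= max_missing_frac
        for pair_id in sub.index[~usable]:
            logger.warning(
                "%s: %d%% of features missing; no label assigned",
                pair_id,
                int(100 * missing_frac[pair_id]),
            )
        X = X_df[usable].to_numpy(dtype=float)
        if len(X) == 0:
            continue
        votes = np.mean([m.predict(X) for m in model.members], axis=0)
        for pair_id, score in zip(X_df[usable].index, votes):
            predictions.append(
                PairPrediction(
                    pair_id=pair_id,
                    score=float(score),
                    label=int(score >= VOTE_THRESHOLD),
                )
            )
    return predictions


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_model(model: EnsembleModel, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    joblib.dump(model.members, directory / f"{model.group}_members.joblib")
    meta = {
        "group": model.group,
        "selected_features": model.selected_features,
        "seeds": model.seeds,
        "cv_accuracies": model.cv_accuracies,
        "trees": model.trees,
        "train_frac": model.train_frac,
    }
    with open(directory / f"{model.group}_meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    return directory


def load_model(directory: str | Path, group: str) -> EnsembleModel:
    directory = Path(directory)
    with open(directory / f"{group}_meta.json") as fh:
        meta = json.load(fh)
    members = joblib.load(directory / f"{group}_members.joblib")
    return EnsembleModel(members=members, **meta)


def write_predictions(
    predictions: Sequence[PairPrediction], table: pd.DataFrame, path: str | Path
) -> None:
    """Predictions as TSV (pair_id, gene5, gene3, score, label)."""
    rows = []
    for p in predictions:
        meta = table.loc[p.pair_id]
        rows.append(
            {
                "pair_id": p.pair_id,
                "gene5": meta["gene5"],
                "gene3": meta["gene3"],
                "score": p.score,
                "label": p.label,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
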