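"""Leave-one-out cross-validated classification of case vs control samples.

Four small-cohort models with fixed, untuned hyperparameters: logistic
regression, a decision tree splitting on entropy, a 30-tree random forest,
and a support-vector classifier with probability output.  Each sample is
scored by a model trained on the other n-1 samples; the held-out
probability is thresholded to a predicted label (conventional thresholds:
0.63 logistic, 0 decision tree, 0.23 random forest, 0.2 or 0.24 SVC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

DEFAULT_THRESHOLDS = {
    "logistic": 0.63,
    "decision_tree": 0.0,
    "random_forest": 0.23,
    "svc": 0.2,
    "svc_mfr": 0.24,
}


@dataclass(frozen=True)
class ModelSpec:
    kind: str                      # logistic | decision_tree | random_forest | svc
    threshold: float | None = None
    hyperparameters: dict = field(default_factory=dict)

    def resolved_threshold(self) -> float:
        if self.threshold is not None:
            return self.threshold
        return DEFAULT_THRESHOLDS[self.kind]


@dataclass
class LoocvResult:
    spec: ModelSpec
    table: pd.DataFrame        # sample_id, score, predicted, true, scored
    models: list               # fitted estimator per fold (None if unscored)

    @property
    def accuracy(self) -> float:
        ok = self.table[self.table["scored"]]
        return float((ok["predicted"] == ok["true"]).mean())


def _build_model(spec: ModelSpec, seed: int):
    hp = dict(spec.hyperparameters)
    if spec.kind == "logistic":
        return LogisticRegression(max_iter=1000, **hp)
    if spec.kind == "decision_tree":
        hp.setdefault("criterion", "entropy")
        return DecisionTreeClassifier(random_state=seed, **hp)
    if spec.kind == "random_forest":
        hp.setdefault("n_estimators", 30)
        return RandomForestClassifier(random_state=seed, **hp)
    if spec.kind.startswith("svc"):
        return SVC(probability=True, random_state=seed, **hp)
    raise ValueError(f"unknown model kind {spec.kind!r}")


def loocv_predict(features: pd.DataFrame, labels: pd.DataFrame,
                  spec: ModelSpec, seed: int = 0) -> LoocvResult:
    """Leave-one-out prediction of group membership.

    ``features`` is a sample-by-feature matrix indexed by sample_id;
    ``labels`` maps sample_id to group (case = positive class).  A fold
    whose training set contains a single class is flagged unscored.
    """
    if features.isna().any().any():
        raise ValueError("features contain missing values")
    if len(features) < 3:
        raise ValueError("need at least three samples")
    y = labels.set_index("sample_id").loc[features.index, "group"]
    y = (y == "case").astype(int).to_numpy()
    X = features.to_numpy(dtype=float)
    thr = spec.resolved_threshold()

    rows, models = [], []
    for i, sample in enumerate(features.index):
        mask = np.arange(len(y)) != i
        if len(np.unique(y[mask])) < 2:
            rows.append((sample, np.nan, None, bool(y[i]), False))
            models.append(None)
            continue
        model = _build_model(spec, seed)
        model.fit(X[mask], y[mask])
        prob = float(model.predict_proba(X[i:i + 1])[0, 1])
        rows.append((sample, prob, prob > thr, bool(y[i]), True))
        models.append(model)
    table = pd.DataFrame(
        rows, columns=["sample_id", "score", "predicted", "true", "scored"])
    return LoocvResult(spec, table, models)


def concordance(results: list[LoocvResult]) -> pd.DataFrame:
    """Per-sample agreement of predicted labels across models.

    Returns a frame with one row per sample, one column per model kind, and
    an ``agree`` flag; the overall concordance fraction is
    ``out["agree"].mean()``.
    """
    if len(results) < 2:
        raise ValueError("need at least two model results")
    base = results[0].table["sample_id"]
    out = pd.DataFrame({"sample_id": base})
    for res in results:
        if not res.table["sample_id"].equals(base):
            raise ValueError("results cover different samples")
        out[res.spec.kind] = res.table["predicted"].to_numpy()
    preds = out.drop(columns="sample_id")
    out["agree"] = preds.nunique(axis=1) == 1
    return out
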