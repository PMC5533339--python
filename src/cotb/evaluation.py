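"""Evaluation battery for essentiality rankings.

Given a ranking (``protein``/``score``/``rank`` DataFrame as produced by
:func:`cotb.model.score_and_rank`) and a ground-truth essential set, this
module computes top-k true-positive counts, the six confusion-derived
statistics at a top-fraction cutoff, precision-recall and jackknife curve
series, overlap rates between rankings, and stratified cross-validated AUC
of the forest on a labelled feature matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .config import Config
from .model import FEATURE_COLUMNS

__all__ = [
    "ConfusionCounts",
    "SixMeasures",
    "top_k_counts",
    "six_measures",
    "pr_curve",
    "jackknife_curve",
    "overlap_rate",
    "cross_validated_auc",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class SixMeasures:
    """Sensitivity, specificity, predictive values, F-measure and accuracy.

    ``degenerate`` flags any statistic whose denominator was zero; such
    statistics are reported as 0 so batch tables stay numeric.
    """

    counts: ConfusionCounts
    sn: float
    sp: float
    ppv: float
    npv: float
    f_measure: float
    acc: float
    degenerate: bool


def _ranked_proteins(ranking: pd.DataFrame) -> list[str]:
    return ranking.sort_values("rank")["protein"].to_list()


def top_k_counts(
    ranking: pd.DataFrame, essential: set[str], ks: list[int]
) -> list[tuple[int, int]]:
    """(k, TP(k)) for each requested cutoff; TP(k) = |top-k ∩ essential|."""
    ordered = _ranked_proteins(ranking)
    out = []
    for k in ks:
        if k > len(ordered):
            raise ValueError(f"k={k} exceeds ranking size {len(ordered)}")
        out.append((k, sum(1 for v in ordered[:k] if v in essential)))
    return out


def _safe_ratio(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def six_measures(
    ranking: pd.DataFrame, essential: set[str], top_fraction: float = 0.20
) -> SixMeasures:
    """Confusion statistics with the top ceil(top_fraction·|V|) proteins
    called positive."""
    if not (0.0 < top_fraction < 1.0):
        raise ValueError("top_fraction must lie strictly between 0 and 1")
    ordered = _ranked_proteins(ranking)
    cut = math.ceil(top_fraction * len(ordered))
    positive = set(ordered[:cut])
    tp = sum(1 for v in positive if v in essential)
    fp = len(positive) - tp
    fn = sum(1 for v in ordered[cut:] if v in essential)
    tn = len(ordered) - cut - fn
    counts = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    sn, d1 = _safe_ratio(tp, tp + fn)
    sp, d2 = _safe_ratio(tn, tn + fp)
    ppv, d3 = _safe_ratio(tp, tp + fp)
    npv, d4 = _safe_ratio(tn, tn + fn)
    f, d5 = _safe_ratio(2.0 * sn * ppv, sn + ppv)
    acc, d6 = _safe_ratio(tp + tn, counts.total)
    return SixMeasures(
        counts=counts, sn=sn, sp=sp, ppv=ppv, npv=npv, f_measure=f, acc=acc,
        degenerate=any([d1, d2, d3, d4, d5, d6]),
    )


def jackknife_curve(ranking: pd.DataFrame, essential: set[str]) -> pd.DataFrame:
    """Cumulative true-essential count versus rank: one (n, y) row per rank."""
    ordered = _ranked_proteins(ranking)
    hits = np.cumsum([1 if v in essential else 0 for v in ordered])
    return pd.DataFrame({"n": np.arange(1, len(ordered) + 1), "cumulative_tp": hits})


def pr_curve(ranking: pd.DataFrame, essential: set[str]) -> pd.DataFrame:
    """Precision(n) = TP(n)/n and Recall(n) = TP(n)/P for n = 1..|ranking|."""
    ordered = _ranked_proteins(ranking)
    p = sum(1 for v in ordered if v in essential)
    if p == 0:
        raise ValueError("precision-recall curve undefined: no essential protein in ranking")
    hits = np.cumsum([1 if v in essential else 0 for v in ordered])
    n = np.arange(1, len(ordered) + 1)
    return pd.DataFrame({"n": n, "recall": hits / p, "precision": hits / n})


def overlap_rate(top_a: list[str], top_b: list[str]) -> float:
    """Percentage overlap of two equal-length top-k ID lists."""
    if len(top_a) != len(top_b):
        raise ValueError("overlap_rate requires equal-length top-k lists")
    if not top_a:
        raise ValueError("overlap_rate undefined for k=0")
    return 100.0 * len(set(top_a) & set(top_b)) / len(top_a)


def cross_validated_auc(
    features: pd.DataFrame, cfg: Config | None = None, folds: int = 10
) -> float:
    """Mean held-out ROC AUC of the forest over stratified seeded folds."""
    cfg = cfg or Config()
    if "label" not in features.columns:
        raise ValueError("feature matrix needs a label column for cross-validation")
    if len(features) < folds:
        raise ValueError(f"{len(features)} rows cannot be split into {folds} folds")
    x = features[FEATURE_COLUMNS].to_numpy()
    y = features["label"].to_numpy()
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cfg.rf_seed)
    aucs = []
    for train_idx, test_idx in splitter.split(x, y):
        if len(set(y[train_idx].tolist())) < 2 or len(set(y[test_idx].tolist())) < 2:
            raise ValueError("a stratified fold lost one of the classes")
        clf = RandomForestClassifier(
            n_estimators=cfg.rf_trees,
            max_features="sqrt",
            random_state=cfg.rf_seed,
            n_jobs=1,
        )
        clf.fit(x[train_idx], y[train_idx])
        class_index = list(clf.classes_).index(1)
        scores = clf.predict_proba(x[test_idx])[:, class_index]
        aucs.append(roc_auc_score(y[test_idx], scores))
    return float(np.mean(aucs))
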