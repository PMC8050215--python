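"""Comparison analyses around the decoding pipeline.

Three controls give the decoding numbers their meaning:

* **Empirical chance** — because the final selection is the best of four
  candidates, its accuracy is optimistically biased even on pure noise.  The
  estimator destroys the feature–label relationship (independent column
  permutation), re-runs the *identical* pipeline, and takes the per-fold
  maximum of the four hold-out accuracies, so real and chance performance
  share the same degrees of freedom and can be compared directly.
* **Bias baseline** — predicts each choice from the training-set preference
  for one expression over the other within the same emotion pair, using the
  same folding.  If feature-based decoding beats this baseline, the features
  carry information beyond emotion-content preferences.
* **Emotion decoding** — 4-class decoding of expression from single-image
  features, either with free ensemble selection or with the top-n features
  transferred from the behavioural analysis (n matched per fold), to ask
  whether the behaviourally relevant features are the emotion-defining ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score

from .selection import (
    DecodingResult,
    FoldPlan,
    SelectionConfig,
    default_estimator,
    run_participant,
)
from .synth import EXPRESSIONS

__all__ = [
    "ChanceEstimate",
    "BiasBaseline",
    "EmotionDecodingResult",
    "empirical_chance",
    "shuffle_features",
    "bias_baseline",
    "emotion_decoding",
]

logger = logging.getLogger("gazedecode.evaluation")


@dataclass
class ChanceEstimate:
    """Per-fold max-of-four accuracy on shuffled data; the empirical chance."""

    per_fold: np.ndarray
    shuffle_mode: str = "columns"

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_fold))


@dataclass
class BiasBaseline:
    """Emotion-pair bias decoding: per-pair training biases and accuracies."""

    per_pair: pd.DataFrame      # pair_a, pair_b, bias, accuracy, n_test
    per_fold: np.ndarray        # accuracy over all different-pair test trials

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.per_fold))


@dataclass
class EmotionDecodingResult:
    """4-class expression decoding (chance 0.25)."""

    mode: str                       # "free_selection" | "transferred_top_n"
    per_fold_accuracy: np.ndarray
    n_features_per_fold: np.ndarray
    foldplan: FoldPlan
    result: DecodingResult = None   # populated in free_selection mode

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.per_fold_accuracy))


# ---------------------------------------------------------------------------
# empirical chance
# ---------------------------------------------------------------------------

def shuffle_features(X, seed: int = 0, mode: str = "columns") -> np.ndarray:
    """Destroy the feature–label relationship.

    ``columns`` (canonical): permute every feature column independently
    across trials — marginal distributions are preserved, class linkage and
    within-trial coupling are destroyed.  ``rows``: permute whole trials
    (feature rows) against the label vector, preserving within-trial
    feature coupling.
    """
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    if mode == "columns":
        out = np.empty_like(X)
        for j in range(X.shape[1]):
            out[:, j] = X[rng.permutation(X.shape[0]), j]
        return out
    if mode == "rows":
        return X[rng.permutation(X.shape[0])]
    raise ValueError(f"unknown shuffle mode {mode!r}")


def empirical_chance(X, y, config: SelectionConfig = None, seed: int = 0,
                     foldplan: FoldPlan = None, mode: str = "columns",
                     reference: DecodingResult = None) -> ChanceEstimate:
    """Empirical chance with the same selection optimism as the real pipeline.

    Shuffles the features, re-runs the entire four-candidate pipeline (same
    config, same folding if given) and takes the per-fold maximum of the
    four hold-out accuracies — which is exactly the final-model accuracy, as
    the final selection is the argmax.

    With ``reference`` set, the four candidate sets of the reference run are
    reused and only refit on shuffled data (cheap smoke-test mode; NOT the
    canonical estimator, since it skips re-selection and therefore has fewer
    degrees of freedom).
    """
    cfg = config or SelectionConfig()
    y = np.asarray(y)
    ss = np.random.SeedSequence(seed)
    s_shuffle, s_run = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2)]
    Xs = shuffle_features(X, seed=s_shuffle, mode=mode)

    if reference is not None:
        logger.warning("fixed-selection chance mode: reusing reference "
                       "selections (non-canonical)")
        plan = foldplan or reference.foldplan
        accs = []
        for f, fr in enumerate(reference.fold_results):
            pool, hold = plan.split(f)
            fold_accs = []
            for feats in fr.sets.values():
                est = default_estimator(y[pool], C=cfg.svm_C)
                est.fit(Xs[np.ix_(pool, feats)], y[pool])
                fold_accs.append(accuracy_score(
                    y[hold], est.predict(Xs[np.ix_(hold, feats)])))
            accs.append(max(fold_accs))
        return ChanceEstimate(per_fold=np.array(accs), shuffle_mode=mode)

    result = run_participant(Xs, y, config=cfg, seed=s_run, foldplan=foldplan)
    return ChanceEstimate(per_fold=result.per_fold_accuracy, shuffle_mode=mode)


# ---------------------------------------------------------------------------
# bias baseline
# ---------------------------------------------------------------------------

def _canonical_order(classes) -> list:
    known = [e for e in EXPRESSIONS if e in classes]
    return known + sorted(c for c in classes if c not in EXPRESSIONS)


def bias_baseline(trials: pd.DataFrame, labels, foldplan: FoldPlan) -> BiasBaseline:
    """Predict choices from training-set emotion-content preferences.

    For every fold and unordered different-expression pair {A, B} (A earlier
    in canonical order), the bias is the training proportion of trials in
    which expression A was chosen; test trials of that pair are predicted as
    "the side showing the majority expression" (exact 0.5 tie → A).  Pairs
    absent from a training fold are skipped with a log message.
    """
    y = np.asarray(labels)
    chosen = np.where(y == 1, trials["right_class"].to_numpy(),
                      trials["left_class"].to_numpy())
    classes = set(trials["left_class"]) | set(trials["right_class"])
    order = _canonical_order(classes)
    rank = {c: i for i, c in enumerate(order)}

    lc = trials["left_class"].to_numpy()
    rc = trials["right_class"].to_numpy()
    different = lc != rc
    pair_a = np.where([rank[l] <= rank[r] for l, r in zip(lc, rc)], lc, rc)
    pair_b = np.where([rank[l] <= rank[r] for l, r in zip(lc, rc)], rc, lc)

    pair_rows = {}
    fold_acc = []
    for f in range(foldplan.n_folds):
        pool, hold = foldplan.split(f)
        pool = pool[different[pool]]
        hold = hold[different[hold]]
        correct_fold, n_fold = 0, 0
        for a, b in {(pa, pb) for pa, pb in zip(pair_a[different], pair_b[different])}:
            tr_mask = (pair_a[pool] == a) & (pair_b[pool] == b)
            te_mask = (pair_a[hold] == a) & (pair_b[hold] == b)
            te = hold[te_mask]
            if not tr_mask.any():
                logger.warning("pair (%s, %s) absent from training fold %d; "
                               "skipping %d test trials", a, b, f, len(te))
                continue
            if len(te) == 0:
                continue
            bias = float(np.mean(chosen[pool[tr_mask]] == a))
            majority = a if bias >= 0.5 else b      # tie -> canonical earlier
            pred = np.where(rc[te] == majority, 1, 0)
            correct = int(np.sum(pred == y[te]))
            correct_fold += correct
            n_fold += len(te)
            row = pair_rows.setdefault((a, b), {"bias": [], "correct": 0, "n": 0})
            row["bias"].append(bias)
            row["correct"] += correct
            row["n"] += len(te)
        fold_acc.append(correct_fold / n_fold if n_fold else np.nan)

    per_pair = pd.DataFrame(
        [(a, b, float(np.mean(v["bias"])), v["correct"] / v["n"], v["n"])
         for (a, b), v in sorted(pair_rows.items(),
                                 key=lambda kv: (rank[kv[0][0]], rank[kv[0][1]]))],
        columns=["pair_a", "pair_b", "bias", "accuracy", "n_test"])
    return BiasBaseline(per_pair=per_pair, per_fold=np.array(fold_acc))


# ---------------------------------------------------------------------------
# emotion decoding
# ---------------------------------------------------------------------------

def emotion_decoding(X_images, class_labels, mode: str = "free_selection",
                     reference: EmotionDecodingResult = None,
                     behavioural_weights=None, seed: int = 0,
                     config: SelectionConfig = None) -> EmotionDecodingResult:
    """Decode expression class from single-image features.

    ``free_selection`` runs the full ensemble selection pipeline with a
    one-vs-one linear SVM over stratified image folds.  ``transferred_top_n``
    instead takes, per fold, the top-n features by behavioural relevance
    weights (from the eye-movement decoding analysis), with n equal to the
    reference free-selection run's per-fold selection size and the identical
    folding — measuring whether behaviourally relevant features carry the
    emotion content.
    """
    cfg = config or SelectionConfig()
    X = np.asarray(X_images, dtype=float)
    y = np.asarray(class_labels)

    if mode == "free_selection":
        result = run_participant(X, y, config=cfg, seed=seed,
                                 feature_kind="emotion")
        n_per_fold = np.array([len(fr.final) for fr in result.fold_results])
        return EmotionDecodingResult(mode=mode,
                                     per_fold_accuracy=result.per_fold_accuracy,
                                     n_features_per_fold=n_per_fold,
                                     foldplan=result.foldplan, result=result)

    if mode == "transferred_top_n":
        if reference is None:
            raise ValueError("transferred mode requires the free-selection "
                             "reference run")
        if behavioural_weights is None:
            raise ValueError("transferred mode requires behavioural relevance "
                             "weights")
        w = np.asarray(getattr(behavioural_weights, "weights",
                               behavioural_weights), dtype=float)
        if len(w) != X.shape[1]:
            raise ValueError("weights do not match the image feature space")
        order = np.argsort(-w, kind="stable")
        plan = reference.foldplan
        accs, ns = [], []
        for f in range(plan.n_folds):
            pool, hold = plan.split(f)
            n_f = int(reference.n_features_per_fold[f])
            feats = order[:n_f]
            est = default_estimator(y[pool], C=cfg.svm_C)
            est.fit(X[np.ix_(pool, feats)], y[pool])
            accs.append(accuracy_score(y[hold],
                                       est.predict(X[np.ix_(hold, feats)])))
            ns.append(n_f)
        return EmotionDecodingResult(mode=mode,
                                     per_fold_accuracy=np.array(accs),
                                     n_features_per_fold=np.array(ns),
                                     foldplan=plan)

    raise ValueError(f"unknown mode {mode!r}")
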