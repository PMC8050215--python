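"""Ensemble feature selection and decoding of two-alternative choices.

The decoding question: given right-minus-left feature differences of two
simultaneously shown faces, predict which side received the initial eye
movement.  Because the informative features are sparse and unknown, selection
proceeds per cross-validation fold through four competing candidate sets of a
common size M:

* **filter** — the top-M features by chi-squared (Kruskal–Wallis) ranking;
* **wrapper** — a stepwise-additive linear-SVM search seeded by that ranking,
  with a pruning checkpoint at 25% of the budget;
* **random** — M features drawn at random (fallback);
* **pseudo-random** — M features drawn from those untouched by filter and
  wrapper (fallback, disjoint by construction).

Each candidate trains a linear SVM on the 7 training partitions and is scored
on the held-out partition; the final selection is the argmax.  The budget M
is the smallest number of top-ranked features holding 10% of the total
chi-squared mass, so cleanly separable data yields small selections.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import accuracy_score, f1_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC

__all__ = [
    "SelectionConfig",
    "FoldPlan",
    "RankedFeatures",
    "SelectionBudget",
    "CandidateSelections",
    "DecodingResult",
    "make_folds",
    "balanced_split",
    "rank_features_kw",
    "selection_budget",
    "wrapper_selection",
    "assemble_candidates",
    "run_participant",
]

logger = logging.getLogger("gazedecode.selection")

CANDIDATE_ORDER = ("filter", "wrapper", "random", "pseudo_random")


@dataclass(frozen=True)
class SelectionConfig:
    """Tunable knobs of the selection pipeline.

    ``subsample_size`` is the number of candidate features the wrapper tests
    per iteration (default ``max(10, ceil(0.05 · n_features))``);
    ``max_budget`` optionally caps M to bound runtime on large problems.
    """

    n_folds: int = 8
    mass_fraction: float = 0.10
    subsample_size: int = None
    svm_C: float = 1.0
    prune_fraction: float = 0.25
    max_budget: int = None


@dataclass
class FoldPlan:
    """Stratified, temporally interleaved fold assignment per trial."""

    n_folds: int
    assignment: np.ndarray

    def split(self, fold: int):
        hold = self.assignment == fold
        return np.flatnonzero(~hold), np.flatnonzero(hold)


@dataclass
class RankedFeatures:
    scores: np.ndarray   # per-feature Kruskal–Wallis H (chi-squared scale)
    order: np.ndarray    # descending permutation, ties broken by lower index


@dataclass
class SelectionBudget:
    M: int
    mass_fraction: float = 0.10


@dataclass
class CandidateSelections:
    """Per-fold outcome: the four candidate sets, their hold-out accuracies,
    the winner, and the all-features reference model."""

    sets: dict
    accuracies: dict
    final_kind: str
    budget: SelectionBudget
    full_accuracy: float
    predictions: np.ndarray        # final model's predictions on the hold-out

    @property
    def final(self) -> np.ndarray:
        return self.sets[self.final_kind]

    @property
    def final_accuracy(self) -> float:
        return self.accuracies[self.final_kind]


@dataclass
class DecodingResult:
    """Aggregate of all folds of one synthetic participant/run."""

    fold_results: list
    foldplan: FoldPlan
    predictions: pd.DataFrame      # trial, fold, y_true, y_pred
    n_features: int = 0
    feature_kind: str = ""

    @property
    def mean_fs_accuracy(self) -> float:
        return float(np.mean([fr.final_accuracy for fr in self.fold_results]))

    @property
    def mean_full_accuracy(self) -> float:
        return float(np.mean([fr.full_accuracy for fr in self.fold_results]))

    @property
    def per_fold_accuracy(self) -> np.ndarray:
        return np.array([fr.final_accuracy for fr in self.fold_results])

    @property
    def selection_counts(self) -> dict:
        counts = {k: 0 for k in CANDIDATE_ORDER}
        for fr in self.fold_results:
            counts[fr.final_kind] += 1
        return counts

    @property
    def selected_union(self) -> np.ndarray:
        """Union of the final selections over folds."""
        return np.unique(np.concatenate([fr.final for fr in self.fold_results]))

    def save(self, outdir) -> None:
        """Write per-fold selections/accuracies as JSON and the per-trial
        predictions as a tidy CSV."""
        import json
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        folds = []
        for f, fr in enumerate(self.fold_results):
            folds.append({
                "fold": f,
                "budget_M": fr.budget.M,
                "final_kind": fr.final_kind,
                "full_accuracy": fr.full_accuracy,
                "accuracies": {k: float(v) for k, v in fr.accuracies.items()},
                "selections": {k: np.asarray(v).tolist()
                               for k, v in fr.sets.items()},
            })
        summary = {
            "feature_kind": self.feature_kind,
            "n_features": self.n_features,
            "mean_fs_accuracy": self.mean_fs_accuracy,
            "mean_full_accuracy": self.mean_full_accuracy,
            "selection_counts": self.selection_counts,
            "folds": folds,
        }
        (out / "decoding_result.json").write_text(json.dumps(summary, indent=2))
        self.predictions.to_csv(out / "predictions.csv", index=False)


# ---------------------------------------------------------------------------
# folding and splitting
# ---------------------------------------------------------------------------

def make_folds(labels, n_folds: int = 8, seed: int = 0) -> FoldPlan:
    """Stratified folds with trials interleaved across the session.

    Within each class, trials in temporal order are processed in blocks of
    ``n_folds``; each block scatters one trial into each fold (randomly
    permuted per block), so every fold samples the whole session and per-fold
    class counts differ by at most one.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes to stratify")
    if counts.min() < n_folds:
        raise ValueError(
            f"class with only {counts.min()} trials cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(y), dtype=int)
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        for start in range(0, len(idx), n_folds):
            block = idx[start:start + n_folds]
            assignment[block] = rng.permutation(n_folds)[: len(block)]
    return FoldPlan(n_folds, assignment)


def balanced_split(labels, seed=0):
    """Class-balanced ~50% train set; the remainder is the validation set.

    Per-class train count = ``min(pool_size // (2 · n_classes), minority)``.
    For a balanced binary pool this is half the data, equally from each
    class.  Errors if any class is absent or the validation set is empty.
    """
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present in the pool")
    per_class = min(len(y) // (2 * len(classes)), counts.min())
    if per_class < 1:
        raise ValueError("a class is exhausted; cannot build a balanced train set")
    train = []
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        train.append(rng.choice(idx, size=per_class, replace=False))
    train = np.sort(np.concatenate(train))
    val = np.setdiff1d(np.arange(len(y)), train)
    if len(val) == 0:
        raise ValueError("validation set is empty")
    return train, val


# ---------------------------------------------------------------------------
# ranking and budget
# ---------------------------------------------------------------------------

def rank_features_kw(X, y) -> RankedFeatures:
    """Per-feature Kruskal–Wallis H statistic (chi-squared scale).

    Midrank-based with tie correction; a feature whose values are all tied
    scores 0.  Vectorized over features; supports 2+ groups.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if counts.min() < 2:
        raise ValueError("need at least two trials per class")
    N = len(y)
    ranks = rankdata(X, axis=0)
    ssq = np.zeros(X.shape[1])
    for cls, n_g in zip(classes, counts):
        rbar = ranks[y == cls].mean(axis=0)
        ssq += n_g * (rbar - (N + 1) / 2.0) ** 2
    H = 12.0 / (N * (N + 1)) * ssq

    # tie correction only where ties exist (features are typically continuous)
    Xs = np.sort(X, axis=0)
    tied_cols = np.flatnonzero((np.diff(Xs, axis=0) == 0).any(axis=0))
    correction = np.ones(X.shape[1])
    for j in tied_cols:
        _, t = np.unique(Xs[:, j], return_counts=True)
        correction[j] = 1.0 - np.sum(t**3 - t) / float(N**3 - N)
    scores = np.where(correction > 0, H / np.where(correction > 0, correction, 1.0), 0.0)
    order = np.argsort(-scores, kind="stable")
    return RankedFeatures(scores=scores, order=order)


def selection_budget(scores, mass_fraction: float = 0.10,
                     max_budget: int = None) -> SelectionBudget:
    """Smallest M whose top-M ranked scores hold ``mass_fraction`` of the total.

    Strong separability (a few very large chi-squared scores) therefore
    yields a small feature budget.
    """
    scores = np.asarray(scores, dtype=float)
    total = scores.sum()
    if total <= 0:
        raise ValueError("all scores are zero; budget undefined")
    order = np.argsort(-scores, kind="stable")
    csum = np.cumsum(scores[order])
    M = int(np.searchsorted(csum, mass_fraction * total - 1e-12) + 1)
    M = min(M, len(scores))
    if max_budget is not None:
        M = min(M, max_budget)
    return SelectionBudget(M=max(M, 1), mass_fraction=mass_fraction)


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

def _is_binary(y) -> bool:
    return len(np.unique(y)) <= 2


def default_estimator(y, C: float = 1.0):
    """Standardized linear SVM: LinearSVC for binary labels, one-vs-one
    SVC(linear) for multi-class (ties broken by aggregate decision values)."""
    if _is_binary(y):
        clf = LinearSVC(C=C, dual="auto", max_iter=5000)
    else:
        clf = SVC(kernel="linear", C=C)
    return make_pipeline(StandardScaler(), clf)


def validation_score(y_true, y_pred) -> float:
    """Wrapper validation metric: F1 (positive class = 1) for binary labels,
    macro-F1 for multi-class."""
    if _is_binary(y_true):
        return f1_score(y_true, y_pred, pos_label=1, zero_division=0)
    return f1_score(y_true, y_pred, average="macro", zero_division=0)


def _fit_and_score(X, y, train_idx, val_idx, feats, C, scorer):
    """Train on the train split, score on validation; None on degenerate fits."""
    feats = np.asarray(feats, dtype=int)
    if feats.size == 0:
        return None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est = default_estimator(y[train_idx], C=C)
            est.fit(X[np.ix_(train_idx, feats)], y[train_idx])
            pred = est.predict(X[np.ix_(val_idx, feats)])
    except Exception as exc:  # degenerate split / singular fit
        logger.warning("SVM training failed on candidate %s: %s", feats, exc)
        return None
    return scorer(y[val_idx], pred)


# ---------------------------------------------------------------------------
# wrapper selection
# ---------------------------------------------------------------------------

def wrapper_selection(X, y, budget: SelectionBudget, ranking: RankedFeatures,
                      seed: int = 0, config: SelectionConfig = None) -> np.ndarray:
    """Stepwise-additive SVM wrapper over a priority-ordered search space.

    Each iteration draws a fresh class-balanced train/validation split,
    evaluates the top-S unselected features by current priority (each added
    to the selected set, one linear SVM per candidate) and includes the
    candidate with the best validation F1.  Priorities start at the
    chi-squared scores scaled to [0, 1] and are replaced by observed
    validation F1 once a feature has been tested, so the search stays in
    the informative region of the ranking while the F1 updates reorder
    candidates within it by multivariate value.  When 25% of the budget has
    been included, each included feature is dropped in turn if the
    selection scores at least as well without it.  The loop ends at M
    inclusions or feature exhaustion.
    """
    cfg = config or SelectionConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[1]
    M = budget.M
    if M < 1:
        raise ValueError("budget must allow at least one feature")
    S = cfg.subsample_size or max(10, math.ceil(0.05 * n))
    rng = np.random.default_rng(seed)

    top = ranking.scores.max()
    priority = ranking.scores / top if top > 0 else np.zeros(n)
    available = np.ones(n, dtype=bool)
    selected: list[int] = []
    prune_at = max(1, math.ceil(cfg.prune_fraction * M))
    pruned = False

    while len(selected) < M and available.any():
        tr, va = balanced_split(y, rng)
        cand_order = np.argsort(-priority, kind="stable")
        cands = [int(i) for i in cand_order if available[i]][:S]
        best_score, best_c = -np.inf, None
        for ci in cands:
            score = _fit_and_score(X, y, tr, va, selected + [ci], cfg.svm_C,
                                   validation_score)
            if score is None:
                continue
            priority[ci] = score
            if score > best_score:
                best_score, best_c = score, ci
        if best_c is None:
            logger.warning("no candidate could be evaluated; stopping wrapper")
            break
        selected.append(best_c)
        available[best_c] = False
        logger.debug("wrapper included feature %d (F1=%.3f, %d/%d)",
                     best_c, best_score, len(selected), M)

        if not pruned and len(selected) >= prune_at:
            pruned = True
            tr, va = balanced_split(y, rng)
            i = 0
            while i < len(selected) and len(selected) > 1:
                base = _fit_and_score(X, y, tr, va, selected, cfg.svm_C,
                                      validation_score)
                without = _fit_and_score(
                    X, y, tr, va, selected[:i] + selected[i + 1:], cfg.svm_C,
                    validation_score)
                if base is not None and without is not None and without >= base:
                    logger.debug("pruning feature %d (F1 %.3f -> %.3f)",
                                 selected[i], base, without)
                    selected.pop(i)
                else:
                    i += 1
    return np.array(selected, dtype=int)


# ---------------------------------------------------------------------------
# candidate assembly and the per-participant run
# ---------------------------------------------------------------------------

def assemble_candidates(X_pool, y_pool, X_hold, y_hold,
                        budget: SelectionBudget, ranking: RankedFeatures,
                        seed: int = 0, config: SelectionConfig = None) -> CandidateSelections:
    """Build the four size-M candidate sets and pick the hold-out winner.

    Each candidate trains a standardized linear SVM on the whole training
    pool and is scored by accuracy on the held-out partition; the final
    selection is the most accurate (ties resolved in the fixed order
    filter > wrapper > random > pseudo-random).  A model on all features is
    trained for reference.
    """
    cfg = config or SelectionConfig()
    X_pool = np.asarray(X_pool, dtype=float)
    X_hold = np.asarray(X_hold, dtype=float)
    y_pool = np.asarray(y_pool)
    y_hold = np.asarray(y_hold)
    n = X_pool.shape[1]
    M = budget.M
    if M > n:
        raise ValueError(f"budget M={M} exceeds {n} features")
    ss = np.random.SeedSequence(seed)
    s_wrap, s_rand, s_pseudo = [int(c.generate_state(1)[0] % (2**31))
                                for c in ss.spawn(3)]

    sets = {}
    sets["filter"] = ranking.order[:M].copy()
    sets["wrapper"] = wrapper_selection(X_pool, y_pool, budget, ranking,
                                        seed=s_wrap, config=cfg)
    rng = np.random.default_rng(s_rand)
    sets["random"] = np.sort(rng.choice(n, size=M, replace=False))

    used = np.union1d(sets["filter"], sets["wrapper"])
    remaining = np.setdiff1d(np.arange(n), used)
    rng = np.random.default_rng(s_pseudo)
    if len(remaining) >= M:
        sets["pseudo_random"] = np.sort(rng.choice(remaining, size=M, replace=False))
    else:
        logger.warning("only %d features outside filter/wrapper; padding "
                       "pseudo-random selection", len(remaining))
        pad = rng.choice(used, size=M - len(remaining), replace=False)
        sets["pseudo_random"] = np.sort(np.concatenate([remaining, pad]))

    accuracies, preds = {}, {}
    for kind in CANDIDATE_ORDER:
        feats = np.asarray(sets[kind], dtype=int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est = default_estimator(y_pool, C=cfg.svm_C)
            est.fit(X_pool[:, feats], y_pool)
            p = est.predict(X_hold[:, feats])
        preds[kind] = p
        accuracies[kind] = accuracy_score(y_hold, p)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est = default_estimator(y_pool, C=cfg.svm_C)
        est.fit(X_pool, y_pool)
        full_accuracy = accuracy_score(y_hold, est.predict(X_hold))

    final_kind = max(CANDIDATE_ORDER, key=lambda k: (accuracies[k],
                                                     -CANDIDATE_ORDER.index(k)))
    logger.info("final selection: %s (acc=%.3f, M=%d)", final_kind,
                accuracies[final_kind], M)
    return CandidateSelections(sets=sets, accuracies=accuracies,
                               final_kind=final_kind, budget=budget,
                               full_accuracy=full_accuracy,
                               predictions=preds[final_kind])


def run_participant(X, y, config: SelectionConfig = None, seed: int = 0,
                    foldplan: FoldPlan = None, feature_kind: str = "") -> DecodingResult:
    """Run the full eightfold selection-and-decoding pipeline on one session.

    For every fold: rank features on the 7 training partitions, derive the
    budget, assemble the four candidates, record the hold-out winner.  If all
    chi-squared scores are zero (fully uninformative features), the budget
    falls back to ``ceil(mass_fraction · n_features)`` — the equal-scores
    value — so the pipeline still produces chance-level output.
    """
    cfg = config or SelectionConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(cfg.n_folds + 1)]
    if foldplan is None:
        foldplan = make_folds(y, cfg.n_folds, seed=seeds[0])

    fold_results = []
    pred_rows = []
    for f in range(cfg.n_folds):
        pool, hold = foldplan.split(f)
        ranking = rank_features_kw(X[pool], y[pool])
        if ranking.scores.sum() > 0:
            budget = selection_budget(ranking.scores, cfg.mass_fraction,
                                      cfg.max_budget)
        else:
            M = min(X.shape[1], math.ceil(cfg.mass_fraction * X.shape[1]))
            if cfg.max_budget is not None:
                M = min(M, cfg.max_budget)
            budget = SelectionBudget(M=M, mass_fraction=cfg.mass_fraction)
        cs = assemble_candidates(X[pool], y[pool], X[hold], y[hold], budget,
                                 ranking, seed=seeds[f + 1], config=cfg)
        fold_results.append(cs)
        for t, yt, yp in zip(hold, y[hold], cs.predictions):
            pred_rows.append((int(t), f, yt, yp))

    predictions = pd.DataFrame(pred_rows, columns=["trial", "fold", "y_true",
                                                   "y_pred"]).sort_values("trial")
    return DecodingResult(fold_results=fold_results, foldplan=foldplan,
                          predictions=predictions.reset_index(drop=True),
                          n_features=X.shape[1], feature_kind=feature_kind)
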