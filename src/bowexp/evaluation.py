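"""Per-class F1, macro-F1, the learning-curve protocol, ALC, and the paired
sign-flip (Fisher randomization) significance test.

The learning-curve harness is seed-paired by design: two methods evaluated
under the same :class:`~bowexp.corpus.SplitPlan` see identical train/test
partitions and identical nested subsamples in every run, so per-run score
differences are meaningful paired statistics.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .corpus import Corpus, SplitPlan, nested_subsample, stratified_split
from .embeddings import EmbeddingTable
from .models import ClassifierConfig, train

__all__ = [
    "ConfusionCounts",
    "LearningCurve",
    "f1",
    "macro_f1",
    "run_learning_curve",
    "run_learning_curves",
    "alc",
    "fisher_randomization_test",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0


def f1(counts: ConfusionCounts) -> float:
    """2*TP / (2*TP + FP + FN); 0 when the denominator vanishes."""
    den = 2 * counts.tp + counts.fp + counts.fn
    return 2 * counts.tp / den if den else 0.0


def confusion_counts(y_true: Sequence[str], y_pred: Sequence[str], cls: str) -> ConfusionCounts:
    """One-vs-rest confusion counts for a single class."""
    tp = fp = fn = tn = 0
    for t, p in zip(y_true, y_pred):
        if p == cls:
            tp += t == cls
            fp += t != cls
        else:
            fn += t == cls
            tn += t != cls
    return ConfusionCounts(tp, fp, fn, tn)


def macro_f1(y_true: Sequence[str], y_pred: Sequence[str], classes: Iterable[str]) -> float:
    """Unweighted mean of per-class F1 over exactly ``classes``.

    A class in ``classes`` that never occurs in ``y_true`` still contributes
    its F1 (0 unless it was falsely predicted, in which case still 0), giving
    rare classes equal voice.
    """
    classes = list(classes)
    if not classes:
        raise ValueError("classes must be non-empty")
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    return float(np.mean([f1(confusion_counts(y_true, y_pred, c)) for c in classes]))


@dataclass(frozen=True)
class LearningCurve:
    """Macro-F1 scores indexed by (run, training proportion)."""

    proportions: tuple[float, ...]
    scores: np.ndarray  # shape (n_runs, n_proportions)
    class_scope: str = "all"
    split_fingerprints: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=np.float64)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 2 or scores.shape[1] != len(self.proportions):
            raise ValueError("scores must be (n_runs, n_proportions)")
        if np.any(scores < 0) or np.any(scores > 1):
            raise ValueError("macro-F1 scores must lie in [0, 1]")

    @property
    def n_runs(self) -> int:
        return self.scores.shape[0]

    def mean_curve(self) -> np.ndarray:
        return self.scores.mean(axis=0)

    def to_dataframe(self, method: str = "") -> pd.DataFrame:
        rows = [
            {"method": method, "scope": self.class_scope, "run": r,
             "proportion": p, "macro_f1": self.scores[r, j]}
            for r in range(self.n_runs)
            for j, p in enumerate(self.proportions)
        ]
        return pd.DataFrame(rows)


def _derived_seed(master: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=master, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def run_splits(corpus: Corpus, plan: SplitPlan):
    """Yield (run, train_subsets, test, fingerprint) for each run of the plan.

    The splits depend only on the corpus and the plan, never on the method
    being evaluated — this is what makes cross-method comparisons paired.
    """
    for r in range(plan.n_runs):
        split_seed = _derived_seed(plan.seed, r, 0)
        sub_seed = _derived_seed(plan.seed, r, 1)
        train_side, test_side = stratified_split(corpus, plan.test_fraction, split_seed)
        subsets = nested_subsample(train_side, plan.proportions, sub_seed)
        fp = hashlib.sha256(
            ("|".join(sorted(d.id for d in test_side))).encode()
        ).hexdigest()[:16]
        yield r, subsets, test_side, fp


def _resolve_scope(corpus: Corpus, class_scope: str | Iterable[str]) -> tuple[list[str], str]:
    if isinstance(class_scope, str):
        if class_scope != "all":
            raise ValueError(f"unknown scope name {class_scope!r}")
        return list(corpus.classes), "all"
    wanted = set(class_scope)
    unknown = wanted - set(corpus.classes)
    if unknown:
        raise ValueError(f"scope classes not in corpus: {sorted(unknown)}")
    return [c for c in corpus.classes if c in wanted], "custom"


def run_learning_curves(
    corpus: Corpus,
    config: ClassifierConfig,
    plan: SplitPlan,
    scopes: dict[str, str | Iterable[str]],
    embeddings: Optional[EmbeddingTable] = None,
    trainer: Optional[Callable] = None,
) -> dict[str, LearningCurve]:
    """Learning curves for one method scored under several class scopes.

    Per run: a fresh stratified split, nested subsamples of the training side
    at the plan's proportions, a model trained per subset, and macro-F1 of its
    predictions on the *full* test side — once per scope.  A restricted scope
    (e.g. the rare classes) restricts only the classes averaged in macro-F1,
    never the training data, so each model is trained once however many
    scopes are scored.
    """
    resolved = {name: _resolve_scope(corpus, sc) for name, sc in scopes.items()}
    fit = trainer or (lambda sub, seed: train(sub, config, seed=seed, embeddings=embeddings))
    scores = {name: np.zeros((plan.n_runs, len(plan.proportions))) for name in scopes}
    fingerprints = []
    for r, subsets, test_side, fp in run_splits(corpus, plan):
        fingerprints.append(fp)
        y_true = [d.label for d in test_side]
        model_seed = _derived_seed(plan.seed, r, 2)
        for j, subset in enumerate(subsets):
            model = fit(subset, model_seed)
            y_pred = model.predict(list(test_side))
            for name, (scope, _) in resolved.items():
                scores[name][r, j] = macro_f1(y_true, y_pred, scope)
    return {
        name: LearningCurve(tuple(plan.proportions), scores[name],
                            resolved[name][1], tuple(fingerprints))
        for name in scopes
    }


def run_learning_curve(
    corpus: Corpus,
    config: ClassifierConfig,
    plan: SplitPlan,
    class_scope: str | Iterable[str] = "all",
    embeddings: Optional[EmbeddingTable] = None,
    trainer: Optional[Callable] = None,
) -> LearningCurve:
    """Average-of-runs learning curve for one method (single class scope)."""
    return run_learning_curves(
        corpus, config, plan, {"scope": class_scope}, embeddings, trainer
    )["scope"]


def alc(curve: LearningCurve, rule: str = "mean") -> float:
    """Area under the learning curve: a scalar summary across training sizes.

    ``mean`` (default) averages macro-F1 uniformly over the proportion grid
    per run, then over runs — the normalized rectangle rule on an equally
    spaced grid.  ``trapezoid`` integrates over the proportion axis and
    normalizes by its range.
    """
    if rule == "mean":
        return float(curve.scores.mean())
    if rule == "trapezoid":
        ps = np.asarray(curve.proportions)
        per_run = np.trapezoid(curve.scores, ps, axis=1) / (ps[-1] - ps[0])
        return float(per_run.mean())
    raise ValueError(f"unknown ALC rule {rule!r}")


def fisher_randomization_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    n_perm: int = 10_000,
    seed: int = 0,
    method: str = "auto",
) -> float:
    """One-sided paired sign-flip test of mean(a - b) > 0.

    Under the null that the two methods are exchangeable within a pair, each
    paired difference keeps its magnitude with a random sign.  For up to 20
    pairs all 2^n sign assignments are enumerated exactly and
    p = #{null >= observed} / 2^n; beyond that, ``n_perm`` random sign
    vectors are sampled and p = (#{null >= observed} + 1) / (n_perm + 1).
    ``method`` forces one route ("exact" / "sample") instead of "auto".
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least two paired scores")
    if method not in ("auto", "exact", "sample"):
        raise ValueError(f"unknown method {method!r}")
    d = a - b
    observed = d.mean()
    tol = 1e-12
    n = d.size
    if method == "exact" and n > 20:
        raise ValueError("exact enumeration limited to 20 pairs")
    if method == "exact" or (method == "auto" and n <= 20):
        total = 1 << n
        count = 0
        chunk = 1 << 16
        for start in range(0, total, chunk):
            idx = np.arange(start, min(start + chunk, total), dtype=np.uint64)
            # bit j of idx decides the sign of pair j
            signs = 1.0 - 2.0 * ((idx[:, None] >> np.arange(n, dtype=np.uint64)) & 1)
            null = (signs * d).mean(axis=1)
            count += int(np.sum(null >= observed - tol))
        return count / total
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    null = (signs * d).mean(axis=1)
    return (int(np.sum(null >= observed - tol)) + 1) / (n_perm + 1)
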