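"""Evaluation protocol: average precision under subject-grouped k-fold CV.

Classifiers here emit a ranking score per examination (higher = more
glaucomatous); the quality of that ranking is summarized by average
precision (AP), the precision-weighted sum of recall increments over
descending score thresholds, with tied scores entering the confusion counts
together.  AP = 1 means every EG field is ranked above every control field.

Because subjects contribute several longitudinal fields (often from both
eyes), folds are built on *subjects*: all examinations of one subject land
in exactly one test fold, so no subject ever appears on both sides of a
split.  Neural methods are trained several times per fold with distinct
seeds to expose initialization variance; index baselines are deterministic
and scored once per fold.  Aggregates are the median and (sample) standard
deviation over all cumulated AP entries per method.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace as dc_replace
from typing import Optional, Sequence

import numpy as np

from .indices import fit_md_slv_fusion, index_scores
from .io import TestPattern, VisualFieldRecord
from .models import ModelSpec, labels_of, predict_records, train_model

METHODS = ("MD", "sLV", "MD+sLV", "NN", "CNN")
NEURAL_METHODS = ("NN", "CNN")


@dataclass(frozen=True)
class FoldSplit:
    fold_id: int
    train_subjects: frozenset
    test_subjects: frozenset

    def __post_init__(self) -> None:
        if self.train_subjects & self.test_subjects:
            raise ValueError("train and test subject sets overlap")


# ---------------------------------------------------------------------------
# ranking metrics


def _validate_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equally long")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary (0/1)")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return scores, labels.astype(int)


def average_precision(scores, labels) -> float:
    """Step-wise AP: sum of (R_k - R_{k-1}) * P_k over descending unique
    score thresholds, ties grouped.  1.0 for a perfect ranking."""
    scores, labels = _validate_scores_labels(scores, labels)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # group tied scores: confusion counts only change at unique thresholds
    boundary = np.flatnonzero(np.diff(s) != 0)
    cut = np.concatenate([boundary, [s.size - 1]])
    tp = np.cumsum(y)[cut]
    n_pred = cut + 1
    n_pos = labels.sum()
    precision = tp / n_pred
    recall = tp / n_pos
    recall_prev = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - recall_prev) * precision))


def ap_product_integral(scores, labels) -> float:
    """Secondary AP variant: the integral of PPV(t) * TPR(t) over the
    classification threshold t, taken literally.

    Scores are min-max rescaled to [0, 1] so the threshold domain is the
    unit interval; PPV and TPR are piece-wise constant in t (predict EG iff
    score >= t) and the integral is computed exactly.  PPV is defined as 0
    where nothing is predicted positive.  This is *not* the standard AP;
    :func:`average_precision` is the primary metric.
    """
    scores, labels = _validate_scores_labels(scores, labels)
    lo, hi = scores.min(), scores.max()
    s = np.zeros_like(scores) if hi == lo else (scores - lo) / (hi - lo)
    knots = np.unique(np.concatenate([[0.0, 1.0], s]))
    total = 0.0
    n_pos = labels.sum()
    for a, b in zip(knots[:-1], knots[1:]):
        t = 0.5 * (a + b)  # PPV, TPR constant on (a, b)
        pred = s >= t
        n_pred = pred.sum()
        tp = int((labels[pred] == 1).sum())
        ppv = tp / n_pred if n_pred else 0.0
        tpr = tp / n_pos
        total += ppv * tpr * (b - a)
    return float(total)


def f1_cutoff(scores, labels) -> float:
    """Threshold maximizing PPV*TPR/(PPV+TPR) (a monotone rescaling of F1).

    Candidates are the observed unique scores with the rule
    ``predict EG iff score >= threshold``; the smallest maximizing threshold
    is returned.
    """
    scores, labels = _validate_scores_labels(scores, labels)
    n_pos = labels.sum()
    best_t, best_obj = None, -1.0
    for t in np.unique(scores):
        pred = scores >= t
        tp = int((labels[pred] == 1).sum())
        ppv = tp / pred.sum()
        tpr = tp / n_pos
        obj = 0.0 if (ppv + tpr) == 0 else ppv * tpr / (ppv + tpr)
        if obj > best_obj + 1e-15 or (best_t is None):
            best_obj, best_t = obj, float(t)
        # ties keep the earlier (smaller) threshold
    return best_t


# ---------------------------------------------------------------------------
# folds


def make_folds(records: Sequence[VisualFieldRecord], k: int = 10, seed: int = 0) -> list[FoldSplit]:
    """Partition subjects (with all their examinations) into k folds.

    Subjects are shuffled with the seed (within their class, when labels are
    available) and dealt round-robin, so fold subject counts differ by at
    most one and the class mix stays close to the cohort's — important at
    small cohort sizes, where an unstratified shuffle can produce test folds
    containing a single class, on which AP is undefined.
    """
    subjects = sorted({rec.subject_id for rec in records})
    if len(subjects) < k:
        raise ValueError(f"{len(subjects)} subjects cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    group_of = {rec.subject_id: rec.group for rec in records}
    by_group: dict = {}
    for sid in subjects:
        by_group.setdefault(group_of[sid] or "", []).append(sid)
    shuffled = []
    for key in sorted(by_group):
        block = by_group[key]
        shuffled.extend(np.array(block)[rng.permutation(len(block))])
    shuffled = [str(s) for s in shuffled]
    folds = []
    for fold_id in range(1, k + 1):
        test = frozenset(shuffled[fold_id - 1 :: k])
        train = frozenset(subjects) - test
        folds.append(FoldSplit(fold_id=fold_id, train_subjects=train, test_subjects=test))
    return folds


# ---------------------------------------------------------------------------
# cross-validation report


@dataclass
class CVReport:
    """Per-(method, fold, repeat) AP entries with median/std aggregation."""

    entries: list[dict] = field(default_factory=list)
    k: int = 0
    repeats: int = 0
    seed: int = 0

    def add(self, method: str, fold: int, repeat: int, ap: float) -> None:
        self.entries.append({"method": method, "fold": fold, "repeat": repeat, "ap": float(ap)})

    def scores(self, method: str) -> np.ndarray:
        return np.array([e["ap"] for e in self.entries if e["method"] == method])

    def aggregate(self) -> dict[str, dict]:
        out = {}
        for method in dict.fromkeys(e["method"] for e in self.entries):
            aps = self.scores(method)
            out[method] = {
                "median": float(np.median(aps)),
                "std": float(np.std(aps, ddof=1)) if aps.size > 1 else 0.0,
                "n": int(aps.size),
            }
        return out

    def to_json(self, path=None) -> str:
        payload = {
            "k": self.k,
            "repeats": self.repeats,
            "seed": self.seed,
            "methods": {
                m: {"entries": [e for e in self.entries if e["method"] == m], **agg}
                for m, agg in self.aggregate().items()
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _validation_split(
    train_records: list[VisualFieldRecord], rng: np.random.Generator, fraction: float = 0.1
) -> tuple[list[VisualFieldRecord], list[VisualFieldRecord]]:
    """Hold out ~10% of training subjects, group-aware (per class), keeping
    both classes in the inner training split."""
    by_class: dict[int, list] = {0: [], 1: []}
    for sid in sorted({r.subject_id for r in train_records}):
        label = next(1 if r.group == "EG" else 0 for r in train_records if r.subject_id == sid)
        by_class[label].append(sid)
    val_subjects = set()
    for label, sids in by_class.items():
        if len(sids) < 2:
            continue  # keep the lone subject of a class in the training split
        n_val = max(1, math.ceil(fraction * len(sids)))
        n_val = min(n_val, len(sids) - 1)
        picked = rng.choice(len(sids), size=n_val, replace=False)
        val_subjects.update(sids[i] for i in picked)
    if not val_subjects:
        raise ValueError("could not carve out a validation split (too few subjects)")
    inner = [r for r in train_records if r.subject_id not in val_subjects]
    val = [r for r in train_records if r.subject_id in val_subjects]
    return inner, val


def run_cv(
    records: Sequence[VisualFieldRecord],
    pattern: TestPattern,
    methods: Sequence[str] = METHODS,
    k: int = 10,
    repeats: int = 5,
    seed: int = 0,
    model_spec: Optional[ModelSpec] = None,
) -> CVReport:
    """Subject-grouped k-fold cross-validation of the requested methods.

    Index baselines (MD, sLV, MD+sLV) are deterministic and contribute one
    AP entry per fold; neural methods (NN, CNN) are trained ``repeats``
    times per fold with distinct seeds, each training using an internal
    subject-grouped validation split of the training fold for checkpoint
    selection.  Subject disjointness is asserted for every fold.

    ``model_spec`` carries shared neural hyperparameters (epochs, batch
    size, ...); its ``kind`` and ``seed`` are overridden per method/repeat.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}; choose from {METHODS}")
    records = list(records)
    labels_of(records)  # validates that every record is labeled
    base_spec = model_spec if model_spec is not None else ModelSpec()
    folds = make_folds(records, k=k, seed=seed)
    report = CVReport(k=k, repeats=repeats, seed=seed)
    for fold in folds:
        train_recs = [r for r in records if r.subject_id in fold.train_subjects]
        test_recs = [r for r in records if r.subject_id in fold.test_subjects]
        leaked = {r.subject_id for r in train_recs} & {r.subject_id for r in test_recs}
        if leaked:
            raise AssertionError(f"subject leakage in fold {fold.fold_id}: {sorted(leaked)}")
        y_test = labels_of(test_recs)
        index_methods = [m for m in methods if m not in NEURAL_METHODS]
        if index_methods:
            fusion = fit_md_slv_fusion(train_recs, pattern) if "MD+sLV" in methods else None
            scores = index_scores(test_recs, pattern, fusion=fusion)
            for m in index_methods:
                report.add(m, fold.fold_id, 0, average_precision(scores[m], y_test))
        for m in (m for m in methods if m in NEURAL_METHODS):
            for repeat in range(1, repeats + 1):
                # independent, reproducible seed per (fold, repeat, method)
                sub_seed = (seed * 1_000_003 + fold.fold_id * 1009 + repeat * 97
                            + (1 if m == "CNN" else 2)) % (2**31)
                split_rng = np.random.default_rng(sub_seed)
                inner, val = _validation_split(train_recs, split_rng)
                spec = dc_replace(base_spec, kind=m, seed=sub_seed)
                trained = train_model(spec, inner, val, pattern)
                test_scores = predict_records(trained, test_recs, pattern)
                report.add(m, fold.fold_id, repeat, average_precision(test_scores, y_test))
    return report
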