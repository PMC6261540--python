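"""Classical perimetric global indices: mean defect (MD) and sLV.

MD is the negated arithmetic mean of the sensitivity deviations, so that a
field with loss has positive MD.  sLV (square root of loss variance) is the
sample standard deviation of the deviations and measures field
inhomogeneity; focal scotomas raise it while uniform depression does not.
Blind-spot locations are excluded before either index is computed.

Both indices double as baseline classifiers (higher = more glaucomatous);
``index_scores`` also exposes their combination MD+sLV, either as a logistic
fusion fitted on labeled training records or as a label-free rank-sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

from .io import TestPattern, VisualFieldRecord


@dataclass(frozen=True)
class GlobalIndices:
    md: float
    slv: float
    r_bar: float


def mean_defect(r) -> float:
    """MD = -(1/L) * sum(r_l): positive when sensitivity is lost."""
    r = np.asarray(r, dtype=float)
    if r.size == 0:
        raise ValueError("mean_defect needs at least one deviation")
    if not np.all(np.isfinite(r)):
        raise ValueError("deviations must be finite")
    return float(-np.mean(r))


def slv(r) -> float:
    """Sample standard deviation of the deviations (L-1 denominator)."""
    r = np.asarray(r, dtype=float)
    if r.size < 2:
        raise ValueError("slv needs at least two deviations")
    if not np.all(np.isfinite(r)):
        raise ValueError("deviations must be finite")
    return float(np.std(r, ddof=1))


def global_indices(record: VisualFieldRecord, pattern: TestPattern) -> GlobalIndices:
    """MD and sLV of one examination, blind-spot locations excluded."""
    r = record.usable_deviations(pattern)
    return GlobalIndices(md=mean_defect(r), slv=slv(r), r_bar=float(np.mean(r)))


def index_features(records: Sequence[VisualFieldRecord], pattern: TestPattern) -> np.ndarray:
    """(n, 2) array of [MD, sLV] per record."""
    out = np.empty((len(records), 2))
    for i, rec in enumerate(records):
        gi = global_indices(rec, pattern)
        out[i, 0] = gi.md
        out[i, 1] = gi.slv
    return out


def fit_md_slv_fusion(
    train_records: Sequence[VisualFieldRecord], pattern: TestPattern
) -> LogisticRegression:
    """Fit the logistic MD+sLV fusion on labeled training records.

    The combined score is the fitted probability of the EG class given the
    two indices.  Requires both classes present.
    """
    feats = index_features(train_records, pattern)
    labels = np.array([1 if r.group == "EG" else 0 for r in train_records])
    if labels.min() == labels.max():
        raise ValueError("MD+sLV fusion needs both classes in the training records")
    model = LogisticRegression(max_iter=1000)
    model.fit(feats, labels)
    return model


def index_scores(
    records: Sequence[VisualFieldRecord],
    pattern: TestPattern,
    fusion: Optional[LogisticRegression] = None,
) -> dict[str, np.ndarray]:
    """Per-record scores of the three index baselines.

    Returns ``{"MD": ..., "sLV": ..., "MD+sLV": ...}``; higher scores mean
    more glaucomatous.  MD and sLV are the raw index values.  For MD+sLV,
    pass a fusion fitted with :func:`fit_md_slv_fusion` (trainable variant);
    without one, the label-free fallback scores each record by the sum of
    its MD rank and sLV rank within ``records`` (average ranks on ties).
    """
    feats = index_features(records, pattern)
    md_scores = feats[:, 0]
    slv_scores = feats[:, 1]
    if fusion is not None:
        combined = fusion.predict_proba(feats)[:, 1]
    else:
        combined = rankdata(md_scores) + rankdata(slv_scores)
    return {"MD": md_scores, "sLV": slv_scores, "MD+sLV": combined}
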