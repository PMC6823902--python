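"""Performance assessment: PR-AUC, ROC-AUC, per-class error rates, OOB
reporting and ratio-preserving test downsampling.

ROC-AUC is the usual rank statistic (equivalent to the Mann-Whitney
probability of concordance).  PR-AUC uses the continuous Davis-Goadrich
interpolation between operating points: between two confusion states the
number of false positives is interpolated linearly in the number of true
positives, which makes precision a smooth (non-linear) function of recall
with a closed-form segment integral.  This matches the convention of the
PRROC family of tools rather than step-wise average precision; on
well-separated score distributions the two agree closely, and since there
is no universal random baseline for PR-AUC it is always contrasted against
a model's own alternatives.

Confusion counts use threshold 0.5 (forest majority vote); the bound-class
error FN/(TP+FN) is the false negative rate, the unbound-class error
FP/(TN+FP) the false positive rate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .exceptions import DataError


@dataclass
class ScoredSet:
    """Scores with binary truth and a provenance tag (``oob`` or ``test``)."""

    scores: np.ndarray
    y: np.ndarray
    provenance: str = "test"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float).ravel()
        self.y = np.asarray(self.y).astype(int).ravel()
        if self.scores.size != self.y.size:
            raise DataError("scores and truth have different lengths")


def _validate(y_true, scores) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y_true).astype(int).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    if y.size != s.size:
        raise DataError("scores and truth have different lengths")
    return y, s


def roc_auc(y_true, scores) -> float:
    """Area under the ROC curve (rank/Mann-Whitney statistic)."""
    y, s = _validate(y_true, scores)
    if np.unique(y).size < 2:
        raise DataError("ROC-AUC undefined: a single class in the truth vector")
    return float(roc_auc_score(y, s))


def _operating_points(y: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = np.cumsum(y_sorted == 1)
    fp = np.cumsum(y_sorted == 0)
    # keep the last index of every tied-score block
    last = np.flatnonzero(np.diff(s_sorted) != 0)
    idx = np.concatenate([last, [s_sorted.size - 1]])
    return tp[idx].astype(float), fp[idx].astype(float)


def pr_auc(y_true, scores) -> float:
    """Area under the precision-recall curve, Davis-Goadrich interpolation.

    Between consecutive operating points (TP_a, FP_a) and (TP_b, FP_b) the
    false positives grow linearly in the true positives, so precision along
    the segment is TP / (c*TP + d) with c = 1 + slope and d = FP_a -
    slope*TP_a, and the recall integral has the closed form
    (TP_b - TP_a)/c - d/c^2 * ln((TP_b + FP_b)/(TP_a + FP_a)).
    """
    y, s = _validate(y_true, scores)
    n_pos = int((y == 1).sum())
    if n_pos == 0:
        raise DataError("PR-AUC undefined: no positives in the truth vector")
    tps, fps = _operating_points(y, s)
    area = 0.0
    a, fa = 0.0, 0.0
    for b, fb in zip(tps, fps):
        if b > a:
            slope = (fb - fa) / (b - a)
            c = 1.0 + slope
            d = fa - slope * a
            if abs(d) < 1e-12:
                area += (b - a) / c
            else:
                area += (b - a) / c - (d / c**2) * math.log((b + fb) / (a + fa))
        a, fa = b, fb
    return area / n_pos


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise DataError(f"negative confusion count {name}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(y_true, scores, threshold: float = 0.5) -> ConfusionCounts:
    y, s = _validate(y_true, scores)
    pred = (s > threshold).astype(int)
    return ConfusionCounts(tp=int(((pred == 1) & (y == 1)).sum()),
                           fp=int(((pred == 1) & (y == 0)).sum()),
                           tn=int(((pred == 0) & (y == 0)).sum()),
                           fn=int(((pred == 0) & (y == 1)).sum()))


def class_error_rates(c: ConfusionCounts) -> tuple[float, float]:
    """(FNR, FPR): bound-class error FN/(TP+FN) and unbound-class error FP/(TN+FP)."""
    if c.tp + c.fn == 0:
        raise DataError("FNR undefined: no bound samples")
    if c.tn + c.fp == 0:
        raise DataError("FPR undefined: no unbound samples")
    return c.fn / (c.tp + c.fn), c.fp / (c.tn + c.fp)


def downsample_preserving_ratio(y_true, scores, n_max: int = 100_000, *,
                                seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Stratified downsample to ``n_max`` keeping the bound:unbound ratio.

    Identity when n <= n_max.  Class quotas use largest-remainder rounding
    so the total hits ``n_max`` exactly, with at least one sample per
    present class; sampling is without replacement.
    """
    y, s = _validate(y_true, scores)
    n = y.size
    if n <= n_max:
        return y, s
    rng = np.random.default_rng(seed)
    classes = [1, 0]
    counts = {c: int((y == c).sum()) for c in classes}
    quotas = {c: n_max * counts[c] / n for c in classes}
    base = {c: int(math.floor(quotas[c])) for c in classes}
    short = n_max - sum(base.values())
    for c in sorted(classes, key=lambda c: quotas[c] - base[c], reverse=True):
        if short <= 0:
            break
        base[c] += 1
        short -= 1
    for c in classes:
        if counts[c] > 0 and base[c] == 0:
            base[c] = 1
            other = [k for k in classes if k != c][0]
            base[other] -= 1
    keep = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        take = min(base[c], idx.size)
        if take > 0:
            keep.append(rng.choice(idx, size=take, replace=False))
    sel = np.sort(np.concatenate(keep))
    return y[sel], s[sel]


def evaluate_run(y_true, scores, provenance: str = "test", setup: str | None = None,
                 downsample: int | None = None, seed: int | None = None,
                 path: str | Path | None = None) -> dict:
    """Full metrics report for one model run.

    Computes PR-AUC, ROC-AUC, FNR/FPR at threshold 0.5 and class counts;
    optionally downsamples first (ratio-preserving, needs ``seed``).  The
    report is returned as a dict and, if ``path`` is given, written as
    ``<path>.json`` and ``<path>.tsv``.
    """
    y, s = _validate(y_true, scores)
    if downsample is not None:
        if seed is None:
            raise DataError("downsampling requires a seed")
        y, s = downsample_preserving_ratio(y, s, n_max=downsample, seed=seed)
    c = confusion_counts(y, s)
    fnr, fpr = class_error_rates(c)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    report = {
        "provenance": provenance,
        "setup": setup,
        "n": int(y.size),
        "n_bound": n_pos,
        "n_unbound": n_neg,
        "balanced": n_pos == n_neg,
        "pr_auc": pr_auc(y, s),
        "roc_auc": roc_auc(y, s),
        "fnr": fnr,
        "fpr": fpr,
        "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
    }
    if path is not None:
        base = Path(path)
        base.parent.mkdir(parents=True, exist_ok=True)
        with open(base.with_suffix(".json"), "w") as fh:
            json.dump(report, fh, indent=2)
        pd.DataFrame([report]).to_csv(base.with_suffix(".tsv"), sep="\t", index=False)
    return report


def read_report(path: str | Path) -> dict:
    base = Path(path)
    if base.suffix != ".json":
        base = base.with_suffix(".json")
    with open(base) as fh:
        return json.load(fh)
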