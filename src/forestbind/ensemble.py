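"""Two-step random-forest ensemble for cross-tissue binding prediction.

Training for a target TF with tissues 1..m proceeds in two steps:

1. A full random forest ``RF_i`` is fitted per tissue on all features.  The
   feature space is then shrunk to the union of the top ``t`` features of
   every ``RF_i``, ranked by Gini importance, and reduced forests ``RF'_i``
   are refitted on the union.
2. Every ``RF'_i`` scores every training row of every tissue, yielding an
   ``n x m`` matrix of bound-probabilities.  An ensemble forest ``RF_E`` is
   fitted on those m columns against the concatenated labels.  At prediction
   time a new row is scored by all ``RF'_i`` and the resulting m-vector is
   fed to ``RF_E``.

With a single training tissue the reduced forest ``RF'_1`` itself is the
final model.  Class balance (1:1 bound/unbound) is assumed in the training
rows and the per-class cap (default 30,000) is re-applied to the
concatenated ensemble rows.

Estimators follow scikit-learn conventions (``fit``/``predict_proba``,
``get_params``, fitted attributes with a trailing underscore) and compose
with sklearn tooling; the module-level functions are thin wrappers.
"""

from __future__ import annotations

import itertools
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier

from .exceptions import DataError

N_TREES = 4500
TOP_T = 20
CLASS_CAP = 30_000


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X)
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])


def _seed_stream(random_state: int | None, n: int) -> list[int]:
    """Deterministic per-forest seeds below 2**31."""
    base = 0 if random_state is None else int(random_state)
    return [int(s) for s in
            np.random.SeedSequence(base).generate_state(n, dtype=np.uint32) % (2**31)]


class TissueForestClassifier(ClassifierMixin, BaseEstimator):
    """Random-forest binding classifier for one tissue.

    A thin layer over :class:`sklearn.ensemble.RandomForestClassifier` that
    records out-of-bag bound-probabilities, the OOB misclassification rate at
    threshold 0.5, Gini (mean-decrease-impurity) feature importances, and a
    deterministic top-``t`` feature ranking with lexicographic tie-breaks.
    """

    def __init__(self, n_estimators: int = N_TREES, max_features="sqrt",
                 min_samples_leaf: int = 1, random_state: int | None = None):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state

    def fit(self, X, y) -> "TissueForestClassifier":
        frame = _as_frame(X)
        y = np.asarray(y).astype(int).ravel()
        if len(frame) != len(y):
            raise DataError("X and y have different lengths")
        classes = np.unique(y)
        if classes.size < 2:
            raise DataError("training labels contain a single class")
        if frame.isna().to_numpy().any():
            raise DataError("feature matrix contains missing values")
        forest = RandomForestClassifier(
            n_estimators=self.n_estimators, max_features=self.max_features,
            min_samples_leaf=self.min_samples_leaf,
            bootstrap=True, oob_score=True, random_state=self.random_state)
        forest.fit(frame.to_numpy(), y)
        self.forest_ = forest
        self.classes_ = forest.classes_
        self.feature_names_ = list(map(str, frame.columns))
        self.n_features_in_ = len(self.feature_names_)
        self.importances_ = pd.Series(forest.feature_importances_,
                                      index=self.feature_names_)
        pos = int(np.flatnonzero(forest.classes_ == 1)[0])
        oob = forest.oob_decision_function_[:, pos]
        self.oob_proba_ = np.nan_to_num(oob, nan=0.5)
        self.oob_error_ = float(np.mean((self.oob_proba_ > 0.5).astype(int) != y))
        return self

    def _align(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names_ if c not in X.columns]
            if missing:
                raise DataError(f"missing feature columns: {missing}")
            return X[self.feature_names_].to_numpy()
        X = np.asarray(X)
        if X.shape[1] != self.n_features_in_:
            raise DataError(f"expected {self.n_features_in_} features, got {X.shape[1]}")
        return X

    def predict_proba(self, X) -> np.ndarray:
        return self.forest_.predict_proba(self._align(X))

    def positive_proba(self, X) -> np.ndarray:
        """Probability of the bound class, as a 1-d vector."""
        pos = int(np.flatnonzero(self.classes_ == 1)[0])
        return self.predict_proba(X)[:, pos]

    def predict(self, X) -> np.ndarray:
        return (self.positive_proba(X) > 0.5).astype(int)

    def top_features(self, t: int = TOP_T) -> list[str]:
        """The ``t`` largest-importance features; ties broken by name."""
        if t <= 0:
            raise ValueError("t must be positive")
        if t > len(self.feature_names_):
            raise ValueError(f"t={t} exceeds the {len(self.feature_names_)} features")
        ranked = sorted(self.importances_.items(), key=lambda kv: (-kv[1], kv[0]))
        return [name for name, _ in ranked[:t]]


class EnsembleBindingClassifier(ClassifierMixin, BaseEstimator):
    """The full two-step cross-tissue ensemble.

    ``fit(X, y, tissues=...)`` takes the row-concatenated training bins of
    all tissues; ``tissues`` assigns each row to its training tissue.  With a
    single tissue (or ``tissues=None``) the model degenerates to the
    single-tissue path: the reduced forest is the final model.

    Parameters
    ----------
    n_estimators : trees per forest (full, reduced and ensemble forests).
    t : per-tissue top-feature count for the Gini-guided reduction.
    cap : per-class row cap re-applied to the concatenated ensemble matrix.
    use_oob_inputs : if True, a tissue's own rows enter the ensemble matrix
        with out-of-bag instead of in-sample probabilities (off by default;
        the in-sample variant is the reference behaviour).
    """

    def __init__(self, n_estimators: int = N_TREES, t: int = TOP_T,
                 cap: int = CLASS_CAP, max_features="sqrt",
                 use_oob_inputs: bool = False, random_state: int | None = None):
        self.n_estimators = n_estimators
        self.t = t
        self.cap = cap
        self.max_features = max_features
        self.use_oob_inputs = use_oob_inputs
        self.random_state = random_state

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y, tissues=None) -> "EnsembleBindingClassifier":
        frame = _as_frame(X)
        y = np.asarray(y).astype(int).ravel()
        if tissues is None:
            tissues = np.array(["tissue1"] * len(frame))
        tissues = np.asarray(tissues)
        if not (len(frame) == len(y) == len(tissues)):
            raise DataError("X, y and tissues must have equal lengths")
        order = list(pd.unique(tissues))
        seeds = _seed_stream(self.random_state, 3 * len(order) + 2)
        t_eff = min(self.t, frame.shape[1])

        self.tissues_ = order
        self.tissue_forests_: dict[str, TissueForestClassifier] = {}
        self.top_features_: dict[str, list[str]] = {}
        rows_by_tissue = {}
        for i, tissue in enumerate(order):
            sel = tissues == tissue
            rows_by_tissue[tissue] = sel
            forest = TissueForestClassifier(
                n_estimators=self.n_estimators, max_features=self.max_features,
                random_state=seeds[i]).fit(frame[sel], y[sel])
            self.tissue_forests_[tissue] = forest
            self.top_features_[tissue] = forest.top_features(t_eff)

        self.feature_union_ = feature_union(self.tissue_forests_.values(),
                                            self.top_features_)
        self.reduced_forests_: dict[str, TissueForestClassifier] = {}
        for i, tissue in enumerate(order):
            sel = rows_by_tissue[tissue]
            self.reduced_forests_[tissue] = TissueForestClassifier(
                n_estimators=self.n_estimators, max_features=self.max_features,
                random_state=seeds[len(order) + i]
            ).fit(frame.loc[sel, self.feature_union_], y[sel])

        self.classes_ = np.array([0, 1])
        if len(order) == 1:
            self.ensemble_forest_ = None
            only = self.reduced_forests_[order[0]]
            self.oob_error_ = only.oob_error_
            self.oob_proba_ = only.oob_proba_
            self.oob_y_ = y[rows_by_tissue[order[0]]]
            return self

        # step 2: cross-tissue prediction matrix and the ensemble forest
        blocks, labels = [], []
        for tissue in order:
            sel = rows_by_tissue[tissue]
            sub = frame.loc[sel, self.feature_union_]
            cols = {}
            for src in order:
                rf = self.reduced_forests_[src]
                if src == tissue and self.use_oob_inputs:
                    cols[f"pred_{src}"] = rf.oob_proba_
                else:
                    cols[f"pred_{src}"] = rf.positive_proba(sub)
            blocks.append(pd.DataFrame(cols))
            labels.append(y[sel])
        te = pd.concat(blocks, ignore_index=True)
        ye = np.concatenate(labels)
        te, ye = _cap_per_class(te, ye, self.cap, seeds[-2])
        # The meta-forest sees near-binary probability columns; a modest leaf
        # size keeps its vote fractions smooth enough to rank test rows
        # instead of collapsing them onto a handful of tied scores.
        self.ensemble_forest_ = TissueForestClassifier(
            n_estimators=self.n_estimators, min_samples_leaf=5,
            random_state=seeds[-1]).fit(te, ye)
        self.ensemble_matrix_ = te
        self.oob_error_ = self.ensemble_forest_.oob_error_
        self.oob_proba_ = self.ensemble_forest_.oob_proba_
        self.oob_y_ = ye
        return self

    # -- prediction -------------------------------------------------------

    def ensemble_inputs(self, X) -> pd.DataFrame:
        """The m probability columns produced by the reduced tissue forests."""
        frame = _as_frame(X)
        missing = [c for c in self.feature_union_ if c not in frame.columns]
        if missing:
            raise DataError(f"missing feature-union columns: {missing}")
        sub = frame[self.feature_union_]
        return pd.DataFrame({f"pred_{t}": self.reduced_forests_[t].positive_proba(sub)
                             for t in self.tissues_})

    def positive_proba(self, X) -> np.ndarray:
        if self.ensemble_forest_ is None:
            frame = _as_frame(X)
            missing = [c for c in self.feature_union_ if c not in frame.columns]
            if missing:
                raise DataError(f"missing feature-union columns: {missing}")
            return self.reduced_forests_[self.tissues_[0]].positive_proba(
                frame[self.feature_union_])
        return self.ensemble_forest_.positive_proba(self.ensemble_inputs(X))

    def predict_proba(self, X) -> np.ndarray:
        p = self.positive_proba(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.positive_proba(X) > 0.5).astype(int)


def _cap_per_class(te: pd.DataFrame, y: np.ndarray, cap: int,
                   seed: int) -> tuple[pd.DataFrame, np.ndarray]:
    rng = np.random.default_rng(seed)
    keep = []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if idx.size > cap:
            idx = np.sort(rng.choice(idx, size=cap, replace=False))
        keep.append(idx)
    sel = np.sort(np.concatenate(keep))
    if sel.size == len(y):
        return te, y
    return te.iloc[sel].reset_index(drop=True), y[sel]


def feature_union(forests, top_lists: Mapping[str, Sequence[str]]) -> list[str]:
    """Union of per-tissue top features, ordered by descending maximum
    importance across tissues (ties by name) for a stable column order."""
    best: dict[str, float] = {}
    for forest, names in zip(forests, top_lists.values()):
        for name in names:
            imp = float(forest.importances_[name])
            best[name] = max(best.get(name, -np.inf), imp)
    return [n for n, _ in sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))]


# ---------------------------------------------------------------------------
# Thin functional wrappers and experiment drivers

def stack_tissue_data(tissue_data: Mapping[str, tuple[pd.DataFrame, np.ndarray]]
                      ) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Concatenate per-tissue (X, y) pairs into (X, y, tissues) arrays."""
    frames, ys, tags = [], [], []
    for tissue, (X, y) in tissue_data.items():
        frames.append(_as_frame(X))
        ys.append(np.asarray(y).astype(int).ravel())
        tags.append(np.array([tissue] * len(X)))
    return (pd.concat(frames, ignore_index=False), np.concatenate(ys),
            np.concatenate(tags))


def fit_forest(X, y, n_trees: int = N_TREES, seed: int | None = None
               ) -> TissueForestClassifier:
    return TissueForestClassifier(n_estimators=n_trees, random_state=seed).fit(X, y)


def top_features(forest: TissueForestClassifier, t: int = TOP_T) -> list[str]:
    return forest.top_features(t)


def reduce_and_refit(tissue_data: Mapping[str, tuple[pd.DataFrame, np.ndarray]],
                     forests: Mapping[str, TissueForestClassifier], t: int = TOP_T,
                     seed: int | None = None
                     ) -> tuple[list[str], dict[str, TissueForestClassifier]]:
    """Compute the top-``t`` union over all tissue forests and refit each
    tissue's forest on exactly the union columns of its own rows."""
    tops = {tissue: forests[tissue].top_features(t) for tissue in tissue_data}
    union = feature_union([forests[t_] for t_ in tissue_data], tops)
    seeds = _seed_stream(seed, len(tissue_data))
    reduced = {}
    for s, (tissue, (X, y)) in zip(seeds, tissue_data.items()):
        reduced[tissue] = TissueForestClassifier(
            n_estimators=next(iter(forests.values())).n_estimators,
            random_state=s).fit(_as_frame(X)[union], y)
    return union, reduced


def build_ensemble_matrix(reduced: Mapping[str, TissueForestClassifier],
                          tissue_data: Mapping[str, tuple[pd.DataFrame, np.ndarray]],
                          ) -> tuple[pd.DataFrame, np.ndarray]:
    """Cross-tissue prediction matrix T'_E and the concatenated labels.

    Column j holds the bound-probability of tissue j's reduced forest for
    every training row of every tissue (its own tissue's rows included,
    in-sample).  No tissue-identity column is added.
    """
    names = list(reduced)
    blocks, labels = [], []
    for tissue, (X, y) in tissue_data.items():
        frame = _as_frame(X)
        cols = {f"pred_{src}": reduced[src].positive_proba(frame) for src in names}
        blocks.append(pd.DataFrame(cols))
        labels.append(np.asarray(y).astype(int).ravel())
    return pd.concat(blocks, ignore_index=True), np.concatenate(labels)


def fit_ensemble(te: pd.DataFrame, y, n_trees: int = N_TREES,
                 seed: int | None = None) -> TissueForestClassifier:
    if te.shape[1] < 2:
        raise DataError("ensemble forest needs >= 2 tissue prediction columns; "
                        "use the reduced tissue forest directly for one tissue")
    return TissueForestClassifier(n_estimators=n_trees, min_samples_leaf=5,
                                  random_state=seed).fit(te, y)


def pooled_baseline(tissue_data: Mapping[str, tuple[pd.DataFrame, np.ndarray]],
                    t: int = TOP_T, n_trees: int = N_TREES,
                    seed: int | None = None) -> TissueForestClassifier:
    """Baseline: one forest on the row-concatenation of all tissues' reduced
    matrices (data pooling instead of ensembling)."""
    seeds = _seed_stream(seed, len(tissue_data) + 2)
    forests = {tissue: TissueForestClassifier(n_estimators=n_trees, random_state=s)
               .fit(X, y)
               for s, (tissue, (X, y)) in zip(seeds, tissue_data.items())}
    t_eff = min(t, next(iter(forests.values())).n_features_in_)
    tops = {tissue: forests[tissue].top_features(t_eff) for tissue in tissue_data}
    union = feature_union([forests[t_] for t_ in tissue_data], tops)
    X_all = pd.concat([_as_frame(X)[union] for X, _ in tissue_data.values()],
                      ignore_index=True)
    y_all = np.concatenate([np.asarray(y).astype(int).ravel()
                            for _, y in tissue_data.values()])
    return TissueForestClassifier(n_estimators=n_trees,
                                  random_state=seeds[-1]).fit(X_all, y_all)


def averaging_baseline(reduced: Mapping[str, TissueForestClassifier], X
                       ) -> np.ndarray:
    """Baseline: arithmetic mean of the tissue forests' bound-probabilities."""
    frame = _as_frame(X)
    probs = [rf.positive_proba(frame[rf.feature_names_]) for rf in reduced.values()]
    return np.mean(probs, axis=0)


def tissue_subset_experiment(tissue_data: Mapping[str, tuple[pd.DataFrame, np.ndarray]],
                             t: int = TOP_T, n_trees: int = N_TREES,
                             seed: int | None = None, max_tissues: int = 8,
                             allow_large: bool = False) -> pd.DataFrame:
    """Train the two-step model on every non-empty tissue subset.

    Returns one row per subset with its size and OOB misclassification
    error (the ensemble forest's OOB error; for singleton subsets the
    reduced tissue forest's).  The per-size mean reveals how accuracy
    scales with the number of training tissues.
    """
    names = list(tissue_data)
    m = len(names)
    if m < 2:
        raise DataError("subset experiment needs >= 2 tissues")
    if m > max_tissues and not allow_large:
        raise DataError(f"{m} tissues means {2**m - 1} subsets; "
                        f"pass allow_large=True to proceed")
    records = []
    counter = 0
    for size in range(1, m + 1):
        for combo in itertools.combinations(names, size):
            X, y, tags = stack_tissue_data({k: tissue_data[k] for k in combo})
            model = EnsembleBindingClassifier(
                n_estimators=n_trees, t=t,
                random_state=None if seed is None else seed + counter)
            model.fit(X, y, tissues=tags)
            records.append({"subset": "+".join(combo), "size": size,
                            "oob_error": model.oob_error_})
            counter += 1
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Model persistence

def save_model(model, path) -> None:
    joblib.dump({"format": "forestbind-model", "version": 1, "model": model}, path)


def load_model(path):
    bundle = joblib.load(path)
    if not isinstance(bundle, dict) or bundle.get("format") != "forestbind-model":
        raise DataError(f"{path}: not a forestbind model bundle")
    return bundle["model"]
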