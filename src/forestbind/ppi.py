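"""Gini-weighted protein-protein-interaction score for selected predictors.

Given an interaction probability matrix R (not symmetric: R[i,j] is the
probability that protein i interacts with protein j) and a predictor set P
selected for a target TF t with Gini importances GI(p), the score is

    S(t, P) = -ln( sum_{p in P} (R[p,t] + R[t,p]) * GI(p) / (2 |P|) ).

Smaller scores mean the selected predictors are more likely to interact
with the target.  A zero argument is floored at 1e-12 before the log.  The
random baseline re-scores ``n_draws`` uniformly drawn predictor sets of the
same size, reusing the observed Gini weights in rank order, so the
comparison is about set membership rather than weighting.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError, SymbolLookupError

SCORE_FLOOR = 1e-12

_VERSION_SUFFIX = re.compile(r"[._-](?:V?\d+|[A-D])$", re.IGNORECASE)


def normalize_symbol(symbol: str) -> str:
    """Case-fold and strip motif-version decorations before matrix lookup."""
    s = symbol.strip().upper()
    s = s.split("(")[0].strip()
    prev = None
    while prev != s:
        prev = s
        s = _VERSION_SUFFIX.sub("", s)
    return s


def read_interaction_matrix(path: str | Path) -> pd.DataFrame:
    """Square TSV with header symbols; values validated to lie in [0, 1]."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return validate_interaction_matrix(frame)


def validate_interaction_matrix(frame: pd.DataFrame) -> pd.DataFrame:
    if frame.shape[0] != frame.shape[1]:
        raise DataError(f"interaction matrix is not square: {frame.shape}")
    if list(frame.index) != list(frame.columns):
        raise DataError("interaction matrix row and column symbols differ")
    values = frame.to_numpy(float)
    if not np.all(np.isfinite(values)) or values.min() < 0 or values.max() > 1:
        raise DataError("interaction probabilities must be finite and in [0, 1]")
    return frame


def _symbol_map(matrix: pd.DataFrame) -> dict[str, str]:
    out: dict[str, str] = {}
    for sym in matrix.index:
        out.setdefault(normalize_symbol(str(sym)), str(sym))
    return out


def _resolve(matrix: pd.DataFrame, symbols: Sequence[str]) -> list[str]:
    table = _symbol_map(matrix)
    resolved, unknown = [], []
    for sym in symbols:
        key = normalize_symbol(sym)
        if key in table:
            resolved.append(table[key])
        else:
            unknown.append(sym)
    if unknown:
        raise SymbolLookupError(f"symbols not in interaction matrix: {unknown}")
    return resolved


def ppi_score(matrix: pd.DataFrame, target: str, predictors: Mapping[str, float],
              floor: float = SCORE_FLOOR) -> float:
    """The interaction score S(t, P); smaller means more likely interaction."""
    if len(predictors) < 1:
        raise DataError("predictor set must contain at least one symbol")
    t_sym = _resolve(matrix, [target])[0]
    p_syms = _resolve(matrix, list(predictors))
    total = 0.0
    for p_sym, weight in zip(p_syms, predictors.values()):
        total += (float(matrix.at[p_sym, t_sym]) + float(matrix.at[t_sym, p_sym])) * weight
    arg = total / (2.0 * len(predictors))
    return float(-np.log(max(arg, floor)))


def random_baseline(matrix: pd.DataFrame, target: str, size: int,
                    weights: Sequence[float], n_draws: int = 100, *,
                    seed: int) -> tuple[float, float]:
    """Mean and sd of the score over random predictor sets of ``size``.

    Sets are drawn uniformly without replacement from the matrix symbols
    excluding the target; the observed weights are assigned to the drawn
    members in rank order.
    """
    t_sym = _resolve(matrix, [target])[0]
    candidates = [s for s in matrix.index.astype(str) if s != t_sym]
    if size > len(candidates):
        raise DataError(f"requested subset size {size} exceeds the "
                        f"{len(candidates)} candidate symbols")
    weights = list(weights)
    if len(weights) != size:
        raise DataError(f"need {size} weights, got {len(weights)}")
    rng = np.random.default_rng(seed)
    scores = np.empty(n_draws)
    for i in range(n_draws):
        drawn = rng.choice(candidates, size=size, replace=False)
        scores[i] = ppi_score(matrix, t_sym, dict(zip(drawn, weights)))
    return float(scores.mean()), float(scores.std())


def _is_accessibility_feature(name: str) -> bool:
    return name.startswith("dnase")


def score_model_features(model, matrix: pd.DataFrame, target: str,
                         n_draws: int = 100, *, seed: int) -> dict:
    """Eq.-style interaction report for every tissue forest of a fitted model.

    The predictor set of a tissue is its top motif features (accessibility
    features are not proteins and are excluded) restricted to symbols
    resolvable in the matrix; unresolvable symbols are reported verbatim as
    dropped.  Each set is scored and compared against the random baseline.
    """
    table = _symbol_map(matrix)
    per_tissue: dict[str, dict] = {}
    top_lists = getattr(model, "top_features_", None)
    forests = getattr(model, "tissue_forests_", None)
    if top_lists is None or forests is None:
        # single fitted forest
        forests = {"model": model}
        top_lists = {"model": model.top_features(min(20, model.n_features_in_))}
    for i, (tissue, names) in enumerate(top_lists.items()):
        forest = forests[tissue]
        motif_names = [n for n in names if not _is_accessibility_feature(n)]
        kept, dropped = [], []
        for n in motif_names:
            if normalize_symbol(n) in table:
                kept.append(n)
            else:
                dropped.append(n)
        if not kept:
            raise DataError(f"tissue {tissue!r}: empty predictor set after "
                            f"matching symbols to the interaction matrix")
        weights = [float(forest.importances_[n]) for n in kept]
        predictors = dict(zip(kept, weights))
        observed = ppi_score(matrix, target, predictors)
        ranked = sorted(weights, reverse=True)
        mean, sd = random_baseline(matrix, target, len(kept), ranked,
                                   n_draws=n_draws, seed=seed + i)
        per_tissue[tissue] = {
            "observed_score": observed,
            "random_mean": mean,
            "random_sd": sd,
            "predictors": kept,
            "dropped_symbols": dropped,
            "n_draws": n_draws,
        }
    return {"target": target, "per_tissue": per_tissue}
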