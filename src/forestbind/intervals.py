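"""Genome binning, challenge-style label tables, and balanced training sets.

Predictions are made in fixed-width bins (default 200 bp) on a sliding
lattice (default step 50 bp), so consecutive bins overlap by
``bin_size - step`` bp.  Labels per bin and tissue are B (bound), U
(unbound) or A (ambiguous); ambiguous bins are excluded from both training
and evaluation.  Coordinates are 0-based half-open (BED convention)
throughout; label files use a ``chrom/start/stop`` header like the
challenge tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DataError

BIN_SIZE = 200
STEP = 50
LABELS = ("B", "U", "A")

#: Chromosomes reserved for testing; never used for model training.
HELD_OUT_CHROMS = frozenset({"chr1", "chr8", "chr21"})


def make_bins(chrom_sizes: Mapping[str, int], bin_size: int = BIN_SIZE,
              step: int = STEP) -> pd.DataFrame:
    """Tile each chromosome with bins of ``bin_size`` at starts 0, step, 2*step, ...

    Trailing windows that would exceed the chromosome are dropped, so every
    bin has equal width; a chromosome shorter than ``bin_size`` yields no
    bins.  Returns a frame with columns chrom/start/end sorted by
    (chrom, start).
    """
    if bin_size <= 0 or step <= 0:
        raise ConfigError("bin_size and step must be positive")
    if bin_size % step != 0:
        raise ConfigError("bin_size must be a multiple of step")
    parts = []
    for chrom in sorted(chrom_sizes):
        length = int(chrom_sizes[chrom])
        if length <= 0:
            raise ConfigError(f"chromosome {chrom!r} has non-positive length")
        if length < bin_size:
            continue
        n = (length - bin_size) // step + 1
        starts = np.arange(n, dtype=np.int64) * step
        parts.append(pd.DataFrame({"chrom": chrom, "start": starts,
                                   "end": starts + bin_size}))
    if not parts:
        return pd.DataFrame({"chrom": pd.Series(dtype=str),
                             "start": pd.Series(dtype=np.int64),
                             "end": pd.Series(dtype=np.int64)})
    return pd.concat(parts, ignore_index=True)


def _canonical(table: pd.DataFrame) -> pd.DataFrame:
    cols = {c.lower(): c for c in table.columns}
    ren = {}
    for want in ("chrom", "start"):
        if want in cols and cols[want] != want:
            ren[cols[want]] = want
    if "stop" in cols:
        ren[cols["stop"]] = "end"
    elif "end" in cols and cols["end"] != "end":
        ren[cols["end"]] = "end"
    return table.rename(columns=ren)


def tissue_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ("chrom", "start", "end")]


def read_labels(path: str | Path, bins: pd.DataFrame | None = None,
                strict: bool = True) -> pd.DataFrame:
    """Read a challenge-style label table (chrom, start, stop, one column per tissue).

    If ``bins`` is given, the result is aligned to the bin order; file rows
    whose coordinates do not match a bin raise :class:`DataError` in strict
    mode and are skipped otherwise.
    """
    table = _canonical(pd.read_csv(path, sep="\t"))
    for col in ("chrom", "start", "end"):
        if col not in table.columns:
            raise DataError(f"label table lacks column {col!r}")
    try:
        table["start"] = table["start"].astype(np.int64)
        table["end"] = table["end"].astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise DataError("malformed coordinates in label table") from exc
    tissues = tissue_columns(table)
    if not tissues:
        raise DataError("label table has no tissue columns")
    for t in tissues:
        bad = ~table[t].isin(LABELS)
        if bad.any():
            sym = table.loc[bad, t].iloc[0]
            raise DataError(f"unknown label symbol {sym!r} in tissue column {t!r}")
    table = table.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    if table.duplicated(["chrom", "start", "end"]).any():
        raise DataError("duplicate bins in label table")
    if bins is not None:
        key = pd.MultiIndex.from_frame(bins[["chrom", "start", "end"]])
        row_key = pd.MultiIndex.from_frame(table[["chrom", "start", "end"]])
        matched = row_key.isin(key)
        if strict and not matched.all():
            first = table.loc[~matched, ["chrom", "start", "end"]].iloc[0]
            raise DataError(
                f"label row {first.chrom}:{first.start}-{first.end} does not match a bin")
        table = table[matched]
        # align to bin order
        table = (bins[["chrom", "start", "end"]]
                 .merge(table, on=["chrom", "start", "end"], how="inner"))
    return table.reset_index(drop=True)


def write_labels(table: pd.DataFrame, path: str | Path) -> None:
    out = table.rename(columns={"end": "stop"})
    out.to_csv(path, sep="\t", index=False)


def exclude_held_out(table: pd.DataFrame,
                     chroms: Iterable[str] = HELD_OUT_CHROMS) -> pd.DataFrame:
    """Training view: drop all bins on the held-out chromosomes."""
    chroms = set(chroms)
    return table[~table["chrom"].isin(chroms)].reset_index(drop=True)


def select_chromosomes(table: pd.DataFrame, chroms: Iterable[str]) -> pd.DataFrame:
    """Complementary selector: only bins on the given chromosomes (test view)."""
    chroms = set(chroms)
    return table[table["chrom"].isin(chroms)].reset_index(drop=True)


@dataclass
class TrainingSet:
    """Balanced, A-free selection of bins for one tissue.

    ``indices`` are positional row indices into the label table the set was
    drawn from; ``y`` is 1 for bound, 0 for unbound.
    """

    indices: np.ndarray
    y: np.ndarray
    tissue: str
    seed: int

    def __len__(self) -> int:
        return len(self.indices)


def balance_sample(table: pd.DataFrame, tissue: str, cap: int = 30_000, *,
                   seed: int) -> TrainingSet:
    """Draw an exactly balanced bound/unbound sample for one tissue.

    Positives are capped at ``cap`` (the per-class training limit), negatives
    are matched 1:1, both without replacement.  If there are fewer unbound
    than (capped) bound bins, positives are downsampled to keep the balance
    exact.  Ambiguous bins are never sampled.
    """
    if tissue not in table.columns:
        raise DataError(f"tissue {tissue!r} not in label table")
    labels = table[tissue].to_numpy()
    bound = np.flatnonzero(labels == "B")
    unbound = np.flatnonzero(labels == "U")
    if bound.size == 0 or unbound.size == 0:
        raise DataError(
            f"tissue {tissue!r}: need at least one bound and one unbound bin "
            f"(got {bound.size} B, {unbound.size} U)")
    n_pos = min(bound.size, cap)
    n_pos = min(n_pos, unbound.size)
    rng = np.random.default_rng(seed)
    pos = rng.choice(bound, size=n_pos, replace=False)
    neg = rng.choice(unbound, size=n_pos, replace=False)
    idx = np.concatenate([pos, neg])
    y = np.concatenate([np.ones(n_pos, dtype=np.int8), np.zeros(n_pos, dtype=np.int8)])
    order = np.argsort(idx, kind="stable")
    return TrainingSet(indices=idx[order], y=y[order], tissue=tissue, seed=seed)
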