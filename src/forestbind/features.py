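"""Feature matrices for the two accessibility annotation setups.

Setup "peak": TF affinities and the median DNase signal are computed once
per merged accessibility peak (DHS); every bin inherits the row of the peak
it overlaps most via a left-outer join, and bins overlapping no peak get
all-zero rows.  This restricts the effective search space to accessible
regions.

Setup "bin": TF affinities are computed on each bin's own sequence, and the
accessibility features are the per-bin mean coverage (median across
replicates) for the bin itself and for its non-overlapping left/right
neighbor windows at +/- bin_size.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import CoordinateError, DataError
from .motifs import PSEM, _fetch_chrom, affinities_for_intervals

PEAK_SIGNAL_COLUMN = "dnase_median"
BIN_SIGNAL_COLUMNS = ("dnase_bin", "dnase_left", "dnase_right")


# ---------------------------------------------------------------------------
# BED I/O and interval arithmetic

def read_bed(path: str | Path) -> pd.DataFrame:
    rows = pd.read_csv(path, sep="\t", header=None, comment="#")
    frame = rows.iloc[:, :3].set_axis(["chrom", "start", "end"], axis=1)
    frame["start"] = frame["start"].astype(np.int64)
    frame["end"] = frame["end"].astype(np.int64)
    return frame


def write_bed(frame: pd.DataFrame, path: str | Path) -> None:
    frame[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def merge_peaks(peak_beds: Iterable) -> pd.DataFrame:
    """Union of all input intervals with bedtools-merge semantics.

    Overlapping *and book-ended* (touching) intervals are merged; unsorted
    input is sorted internally.  Inputs may be data frames or BED paths.
    """
    frames = []
    for item in peak_beds:
        if isinstance(item, (str, Path)):
            frames.append(read_bed(item))
        else:
            frames.append(item[["chrom", "start", "end"]])
    if not frames:
        return pd.DataFrame({"chrom": pd.Series(dtype=str),
                             "start": pd.Series(dtype=np.int64),
                             "end": pd.Series(dtype=np.int64)})
    allp = (pd.concat(frames, ignore_index=True)
            .sort_values(["chrom", "start", "end"], kind="stable"))
    out_chrom: list[str] = []
    out_start: list[int] = []
    out_end: list[int] = []
    for chrom, grp in allp.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:  # overlap or book-ended
                cur_e = max(cur_e, int(e))
            else:
                out_chrom.append(chrom)
                out_start.append(cur_s)
                out_end.append(cur_e)
                cur_s, cur_e = int(s), int(e)
        out_chrom.append(chrom)
        out_start.append(cur_s)
        out_end.append(cur_e)
    return pd.DataFrame({"chrom": out_chrom,
                         "start": np.array(out_start, dtype=np.int64),
                         "end": np.array(out_end, dtype=np.int64)})


# ---------------------------------------------------------------------------
# Signal tracks

class SignalTrack:
    """Step-function genomic signal with bedGraph semantics.

    Uncovered bases read as 0.  If ``chrom_sizes`` is provided, queries
    beyond a chromosome raise :class:`CoordinateError`.
    """

    def __init__(self, frame: pd.DataFrame, chrom_sizes: dict[str, int] | None = None):
        frame = frame[["chrom", "start", "end", "value"]].sort_values(
            ["chrom", "start"], kind="stable")
        self.chrom_sizes = dict(chrom_sizes) if chrom_sizes else None
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, grp in frame.groupby("chrom", sort=False):
            self._data[str(chrom)] = (grp["start"].to_numpy(np.int64),
                                      grp["end"].to_numpy(np.int64),
                                      grp["value"].to_numpy(float))
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_bedgraph(cls, path: str | Path,
                      chrom_sizes: dict[str, int] | None = None) -> "SignalTrack":
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as fh:
            frame = pd.read_csv(fh, sep="\t", header=None, comment="#",
                                names=["chrom", "start", "end", "value"])
        return cls(frame, chrom_sizes)

    def _check_bounds(self, chrom: str, start: int, end: int) -> None:
        if start < 0 or start > end:
            raise CoordinateError(f"bad interval {chrom}:{start}-{end}")
        if self.chrom_sizes is not None:
            if chrom not in self.chrom_sizes:
                raise CoordinateError(f"unknown chromosome {chrom!r}")
            if end > self.chrom_sizes[chrom]:
                raise CoordinateError(
                    f"interval {chrom}:{start}-{end} beyond chromosome bounds")

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base signal values over [start, end)."""
        self._check_bounds(chrom, start, end)
        arr = np.zeros(end - start)
        data = self._data.get(chrom)
        if data is None:
            return arr
        starts, ends, vals = data
        i0 = int(np.searchsorted(ends, start, side="right"))
        i1 = int(np.searchsorted(starts, end, side="left"))
        for i in range(i0, i1):
            a = max(int(starts[i]), start)
            b = min(int(ends[i]), end)
            if b > a:
                arr[a - start:b - start] = vals[i]
        return arr

    def mean(self, chrom: str, start: int, end: int) -> float:
        v = self.values(chrom, start, end)
        return float(v.mean()) if v.size else 0.0

    def median(self, chrom: str, start: int, end: int) -> float:
        v = self.values(chrom, start, end)
        return float(np.median(v)) if v.size else 0.0


class BigWigTrack:
    """Read-only signal access backed by a bigWig file (requires pyBigWig)."""

    def __init__(self, path: str | Path):
        import pyBigWig

        self._bw = pyBigWig.open(str(path))
        self.chrom_sizes = dict(self._bw.chroms())

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        if chrom not in self.chrom_sizes:
            raise CoordinateError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > self.chrom_sizes[chrom]:
            raise CoordinateError(f"interval {chrom}:{start}-{end} beyond chromosome bounds")
        vals = np.asarray(self._bw.values(chrom, start, end), dtype=float)
        return np.nan_to_num(vals, nan=0.0)

    def mean(self, chrom: str, start: int, end: int) -> float:
        v = self.values(chrom, start, end)
        return float(v.mean()) if v.size else 0.0

    def median(self, chrom: str, start: int, end: int) -> float:
        v = self.values(chrom, start, end)
        return float(np.median(v)) if v.size else 0.0


def average_tracks(tracks: Sequence[SignalTrack]) -> SignalTrack:
    """Average replicate tracks defined on an identical interval grid."""
    if len(tracks) == 1:
        return tracks[0]
    base = tracks[0].frame[["chrom", "start", "end"]]
    acc = tracks[0].frame["value"].to_numpy(float).copy()
    for tr in tracks[1:]:
        if not tr.frame[["chrom", "start", "end"]].reset_index(drop=True).equals(
                base.reset_index(drop=True)):
            raise DataError("replicate tracks must share the same interval grid")
        acc += tr.frame["value"].to_numpy(float)
    out = base.copy()
    out["value"] = acc / len(tracks)
    return SignalTrack(out, tracks[0].chrom_sizes)


def median_signal(intervals: pd.DataFrame, track) -> np.ndarray:
    """Per-interval median of the per-base signal (even count: mean of central pair)."""
    meds = np.zeros(len(intervals))
    for i, (chrom, start, end) in enumerate(
            zip(intervals["chrom"], intervals["start"], intervals["end"])):
        meds[i] = track.median(str(chrom), int(start), int(end))
    return meds


# ---------------------------------------------------------------------------
# Feature matrices

def _bin_index(bins: pd.DataFrame) -> pd.MultiIndex:
    return pd.MultiIndex.from_frame(bins[["chrom", "start", "end"]])


def _best_peak_per_bin(bins: pd.DataFrame, peaks: pd.DataFrame) -> np.ndarray:
    """Index of the overlapping peak with the largest overlap (ties: leftmost); -1 if none."""
    assign = np.full(len(bins), -1, dtype=np.int64)
    peak_rows = {c: g for c, g in peaks.groupby("chrom", sort=False)}
    for chrom, grp in bins.groupby("chrom", sort=False):
        pg = peak_rows.get(chrom)
        if pg is None:
            continue
        p_start = pg["start"].to_numpy()
        p_end = pg["end"].to_numpy()
        p_idx = pg.index.to_numpy()
        b_start = grp["start"].to_numpy()
        b_end = grp["end"].to_numpy()
        lo = np.searchsorted(p_end, b_start, side="right")
        hi = np.searchsorted(p_start, b_end, side="left")
        rows = grp.index.to_numpy()
        for r, bs, be, i0, i1 in zip(rows, b_start, b_end, lo, hi):
            best, best_ov = -1, 0
            for i in range(i0, i1):
                ov = min(int(p_end[i]), int(be)) - max(int(p_start[i]), int(bs))
                if ov > best_ov:  # strictly larger keeps the leftmost on ties
                    best, best_ov = int(p_idx[i]), ov
            assign[r] = best
    return assign


def build_peak_features(bins: pd.DataFrame, merged_peaks: pd.DataFrame,
                        psems: Sequence[PSEM], genome, track,
                        normalize_affinity: bool = True) -> pd.DataFrame:
    """Peak-setup feature matrix: bins inherit their best-overlap peak's row.

    Affinities and the median signal are computed once per merged peak; bins
    with no overlapping peak get all-zero rows (outer-join fill).  Because
    merged peaks vary in length and summed occupancies grow with the number
    of scored windows, affinities are by default divided by the per-motif
    window count of the peak (mean occupancy per window); otherwise any
    motif column would partly encode peak width rather than motif evidence.
    """
    peaks = merged_peaks.reset_index(drop=True)
    names = [p.name for p in psems]
    columns = names + [PEAK_SIGNAL_COLUMN]
    matrix = np.zeros((len(bins), len(columns)))
    if len(peaks):
        peak_aff = affinities_for_intervals(genome, peaks, psems).to_numpy()
        if normalize_affinity:
            lengths = (peaks["end"] - peaks["start"]).to_numpy()
            for k, psem in enumerate(psems):
                nwin = np.maximum(lengths - psem.width + 1, 1)
                peak_aff[:, k] = peak_aff[:, k] / nwin
        peak_med = median_signal(peaks, track)
        assign = _best_peak_per_bin(bins.reset_index(drop=True), peaks)
        covered = assign >= 0
        matrix[covered, :-1] = peak_aff[assign[covered]]
        matrix[covered, -1] = peak_med[assign[covered]]
    out = pd.DataFrame(matrix, index=_bin_index(bins), columns=columns)
    out.attrs["setup"] = "peak"
    return out


def build_bin_features(bins: pd.DataFrame, psems: Sequence[PSEM], genome,
                       tracks: Sequence, bin_size: int | None = None) -> pd.DataFrame:
    """Bin-setup feature matrix: per-bin affinities plus bin/left/right coverage.

    Coverage is the mean per-base signal over the window; with several
    replicate tracks the median across replicates is taken.  Neighbor
    windows sit at +/- bin_size on the lattice; neighbors falling off the
    chromosome contribute 0.
    """
    if not tracks:
        raise DataError("at least one replicate signal track is required")
    if bin_size is None:
        widths = (bins["end"] - bins["start"]).unique()
        bin_size = int(widths[0])
    names = [p.name for p in psems]
    aff = affinities_for_intervals(genome, bins, psems).to_numpy()
    n = len(bins)
    cov = np.zeros((len(tracks), 3, n))  # replicate x (bin,left,right) x bins
    for chrom, grp in bins.groupby("chrom", sort=False):
        length = len(_fetch_chrom(genome, str(chrom)))
        rows = grp.index.to_numpy()
        starts = grp["start"].to_numpy(np.int64)
        ends = grp["end"].to_numpy(np.int64)
        for t_i, track in enumerate(tracks):
            base = track.values(str(chrom), 0, length)
            csum = np.concatenate(([0.0], np.cumsum(base)))

            def window_mean(s: np.ndarray, e: np.ndarray) -> np.ndarray:
                ok = (s >= 0) & (e <= length)
                vals = np.zeros(len(s))
                vals[ok] = (csum[e[ok]] - csum[s[ok]]) / (e[ok] - s[ok])
                return vals

            cov[t_i, 0, rows] = window_mean(starts, ends)
            cov[t_i, 1, rows] = window_mean(starts - bin_size, ends - bin_size)
            cov[t_i, 2, rows] = window_mean(starts + bin_size, ends + bin_size)
    med = np.median(cov, axis=0)
    matrix = np.column_stack([aff, med[0], med[1], med[2]])
    out = pd.DataFrame(matrix, index=_bin_index(bins),
                       columns=names + list(BIN_SIGNAL_COLUMNS))
    out.attrs["setup"] = "bin"
    return out


def write_feature_matrix(features: pd.DataFrame, path: str | Path) -> None:
    out = features.reset_index()
    out.to_csv(path, sep="\t", index=False)


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    frame = frame.set_index(["chrom", "start", "end"])
    return frame
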