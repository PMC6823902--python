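"""Motif models and biophysical TF binding affinities.

A transcription factor's sequence preference is described by a position
frequency/weight matrix (PFM/PWM).  For affinity scoring the PWM is converted
into a position-specific energy matrix (PSEM) of per-position *mismatch*
energies: the most preferred base at each position has energy 0 and every
other base pays ``(1/lambda) * ln(p_max / p_base)``.

The affinity of a sequence for a motif of width ``W`` follows the TRAP
occupancy model: every window of length ``W`` on both strands is occupied
with probability

    p(window) = R0 * exp(-E) / (1 + R0 * exp(-E)),

where ``E`` is the summed mismatch energy of the window and ``R0`` absorbs
TF concentration and binding constant.  The affinity of the sequence is the
sum of the occupancies of all windows.  The defaults ``lambda = 0.7`` and
``ln R0 = 0.584 * W - 5.66`` are the published TRAP parameter settings.

Windows containing ``N`` contribute zero occupancy; sequences shorter than
the motif have affinity 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import CoordinateError

BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int codes A=0 C=1 G=2 T=3; anything else 4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class PWM:
    """Position weight/frequency matrix, ``(width, 4)`` in A,C,G,T column order."""

    name: str
    matrix: np.ndarray
    is_probability: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or self.matrix.shape[0] < 1:
            raise ValueError(f"{self.name}: PWM matrix must be width x 4 with width >= 1")
        if not np.all(np.isfinite(self.matrix)) or np.any(self.matrix < 0):
            raise ValueError(f"{self.name}: PWM entries must be finite and nonnegative")
        if self.is_probability:
            sums = self.matrix.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-6):
                raise ValueError(f"{self.name}: probability rows must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def probabilities(self, pseudocount: float = 0.0,
                      background: Sequence[float] | None = None) -> np.ndarray:
        """Per-position base probabilities (regularized counts if needed)."""
        bg = _background(background)
        if self.is_probability and pseudocount == 0.0:
            return self.matrix.copy()
        counts = self.matrix + pseudocount * bg
        return counts / counts.sum(axis=1, keepdims=True)


@dataclass
class PSEM:
    """Position-specific energy matrix: per-position, per-base mismatch energies.

    Each row has a zero at (one of) the per-position maximum-probability
    base(s); ``lnR0`` is the log of the scaled binding constant R0.
    """

    name: str
    energies: np.ndarray
    lnR0: float
    lam: float = 0.7

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if self.energies.ndim != 2 or self.energies.shape[1] != 4:
            raise ValueError(f"{self.name}: PSEM energies must be width x 4")
        if not np.all(np.isfinite(self.energies)) or np.any(self.energies < 0):
            raise ValueError(f"{self.name}: energies must be finite and nonnegative")
        if np.any(self.energies.min(axis=1) > 1e-9):
            raise ValueError(f"{self.name}: every PSEM row must contain a zero energy")
        if self.lam <= 0:
            raise ValueError(f"{self.name}: lambda must be positive")

    @property
    def width(self) -> int:
        return self.energies.shape[0]

    @property
    def r0(self) -> float:
        return float(np.exp(self.lnR0))


def _background(background: Sequence[float] | None) -> np.ndarray:
    if background is None:
        return np.full(4, 0.25)
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or np.any(bg <= 0):
        raise ValueError("background must be 4 positive frequencies")
    return bg / bg.sum()


def gc_background(gc: float) -> np.ndarray:
    """A,C,G,T background frequencies for a given GC fraction."""
    at = (1.0 - gc) / 2.0
    return np.array([at, gc / 2.0, gc / 2.0, at])


# ---------------------------------------------------------------------------
# PFM text I/O (JASPAR-style: '>name' header, 4 rows in A/C/G/T order)

def _parse_pfm_row(line: str) -> list[float]:
    stripped = line.strip()
    if stripped and stripped[0].upper() in BASES:
        rest = stripped[1:]
        if not rest or rest[0] in " \t:[|":
            stripped = rest
    stripped = stripped.strip().lstrip(":|").replace("[", " ").replace("]", " ")
    fields = stripped.split()
    try:
        return [float(x) for x in fields]
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in PFM row: {line!r}") from exc


def read_pfm(path: str | Path) -> list[PWM]:
    """Read one or more motifs from a JASPAR-style plain-text file."""
    text = Path(path).read_text()
    records: list[PWM] = []
    name: str | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal name, rows
        if name is None and not rows:
            return
        if len(rows) != 4:
            raise ValueError(f"motif {name!r}: expected 4 base rows, got {len(rows)}")
        if len({len(r) for r in rows}) != 1:
            raise ValueError(f"motif {name!r}: row-length mismatch")
        mat = np.array(rows, dtype=float).T
        sums = mat.sum(axis=1)
        is_prob = bool(np.all(np.abs(sums - 1.0) <= 1e-6))
        records.append(PWM(name or f"motif{len(records) + 1}", mat, is_probability=is_prob))
        name, rows = None, []

    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].split()[0] if line[1:].split() else ""
        else:
            rows.append(_parse_pfm_row(line))
    flush()
    return records


def write_pfm(path: str | Path, pwms: Iterable[PWM]) -> None:
    lines: list[str] = []
    for pwm in pwms:
        lines.append(f">{pwm.name}")
        for b, base in enumerate(BASES):
            vals = " ".join(format(v, ".17g") for v in pwm.matrix[:, b])
            lines.append(f"{base} {vals}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PWM -> PSEM conversion

def pwm_to_psem(pwm: PWM, lam: float = 0.7, pseudocount: float = 1.0,
                background: Sequence[float] | None = None,
                prob_floor: float = 1e-4) -> PSEM:
    """Convert a PWM to a PSEM.

    Count matrices are regularized with ``pseudocount`` distributed by the
    background frequencies; probability matrices are floored at ``prob_floor``
    to avoid log(0).  Energies are ``(1/lam) * ln(p_max / p)`` and
    ``lnR0 = 0.584 * width - 5.66`` (the TRAP width law).
    """
    if pwm.is_probability:
        p = np.maximum(pwm.matrix, prob_floor)
    else:
        p = pwm.probabilities(pseudocount=pseudocount, background=background)
        if not np.all(np.isfinite(p)) or np.any(p <= 0):
            raise FloatingPointError(f"{pwm.name}: degenerate probabilities after regularization")
    pmax = p.max(axis=1, keepdims=True)
    energies = np.log(pmax / p) / lam
    np.clip(energies, 0.0, None, out=energies)
    lnR0 = 0.584 * pwm.width - 5.66
    return PSEM(pwm.name, energies, lnR0, lam)


# ---------------------------------------------------------------------------
# TRAP affinity

def _window_scores(idx: np.ndarray, psem: PSEM) -> np.ndarray:
    """Combined both-strand occupancy per window start; N windows score 0."""
    w = psem.width
    n = idx.size - w + 1
    if n <= 0:
        return np.zeros(0)
    fwd = np.zeros((w, 5))
    fwd[:, :4] = psem.energies
    # Reverse-strand window at start i scores the reverse complement, which is
    # equivalent to scoring the forward bases with the position- and
    # base-reversed energy matrix.
    rev = np.zeros((w, 5))
    rev[:, :4] = psem.energies[::-1, ::-1]
    e_fwd = np.zeros(n)
    e_rev = np.zeros(n)
    for j in range(w):
        col = idx[j:j + n]
        e_fwd += fwd[j, col]
        e_rev += rev[j, col]
    r0 = psem.r0
    x_fwd = r0 * np.exp(-e_fwd)
    x_rev = r0 * np.exp(-e_rev)
    p = x_fwd / (1.0 + x_fwd) + x_rev / (1.0 + x_rev)
    if (idx == 4).any():
        cn = np.concatenate(([0], np.cumsum(idx == 4)))
        p[(cn[w:] - cn[:-w]) > 0] = 0.0
    return p


def trap_affinity(seq: str, psem: PSEM, aggregate: str = "sum") -> float:
    """TRAP affinity of ``seq`` for ``psem`` (both strands).

    ``aggregate='sum'`` (default) sums window occupancies; ``'max'`` returns
    the best single-window occupancy instead.
    """
    scores = _window_scores(encode_sequence(seq), psem)
    if scores.size == 0:
        return 0.0
    if aggregate == "sum":
        return float(scores.sum())
    if aggregate == "max":
        return float(scores.max())
    raise ValueError(f"unknown aggregate {aggregate!r}")


def _fetch_chrom(genome, chrom: str) -> str:
    if isinstance(genome, Mapping):
        if chrom not in genome:
            raise CoordinateError(f"unknown chromosome {chrom!r}")
        return genome[chrom]
    if isinstance(genome, (str, Path)):
        import pyfaidx

        fasta = pyfaidx.Fasta(str(genome))
        if chrom not in fasta:
            raise CoordinateError(f"unknown chromosome {chrom!r}")
        return str(fasta[chrom])
    # pyfaidx.Fasta or anything mapping-like with __contains__/__getitem__
    if chrom not in genome:
        raise CoordinateError(f"unknown chromosome {chrom!r}")
    return str(genome[chrom])


def _intervals_frame(intervals) -> pd.DataFrame:
    if isinstance(intervals, pd.DataFrame):
        cols = {c.lower(): c for c in intervals.columns}
        chrom = cols.get("chrom", "chrom")
        start = cols.get("start", "start")
        end = cols.get("end", cols.get("stop", "end"))
        return intervals[[chrom, start, end]].set_axis(["chrom", "start", "end"], axis=1)
    return pd.DataFrame(list(intervals), columns=["chrom", "start", "end"])


def affinities_for_intervals(genome, intervals, psems: Sequence[PSEM],
                             aggregate: str = "sum") -> pd.DataFrame:
    """Affinity table: rows = intervals, columns = motifs (input order).

    ``genome`` may be a dict of sequences, a pyfaidx ``Fasta`` or a FASTA
    path.  Intervals are 0-based half-open; out-of-bounds intervals raise
    :class:`CoordinateError`.
    """
    frame = _intervals_frame(intervals)
    names = [p.name for p in psems]
    out = np.zeros((len(frame), len(psems)))
    if len(frame) == 0:
        return pd.DataFrame(out, columns=names)
    for chrom, grp in frame.groupby("chrom", sort=False):
        seq = _fetch_chrom(genome, str(chrom))
        length = len(seq)
        starts = grp["start"].to_numpy(dtype=np.int64)
        ends = grp["end"].to_numpy(dtype=np.int64)
        if (starts < 0).any() or (ends > length).any() or (starts > ends).any():
            raise CoordinateError(f"interval outside chromosome {chrom!r} (length {length})")
        rows = frame.index.get_indexer(grp.index)
        idx = encode_sequence(seq)
        for k, psem in enumerate(psems):
            w = psem.width
            if aggregate == "sum":
                scores = _window_scores(idx, psem)
                csum = np.concatenate(([0.0], np.cumsum(scores)))
                nwin = np.maximum(ends - starts - w + 1, 0)
                vals = np.zeros(len(grp))
                sel = nwin > 0
                vals[sel] = csum[(starts + nwin)[sel]] - csum[starts[sel]]
                out[rows, k] = vals
            else:
                for r, (a, b) in zip(rows, zip(starts, ends)):
                    out[r, k] = trap_affinity(seq[a:b], psem, aggregate=aggregate)
    result = pd.DataFrame(out, columns=names)
    result.index = frame.index
    return result
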