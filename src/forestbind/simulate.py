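"""Synthetic multi-tissue TF binding benchmarks.

The generator emulates the statistical structure that the cross-tissue
binding predictor assumes, without any external download:

* one shared genome (i.i.d. nucleotides at a configurable GC fraction) — as
  in real data, tissues share the sequence and differ only in accessibility;
* per tissue, a set of planted target-TF binding sites, each accompanied by
  an instance of that tissue's co-factor motif within ``cofactor_max_offset``
  bp — tissue-specific co-binding is what the ensemble model exploits;
* per tissue, a smooth accessibility signal: Gaussian bumps centered on the
  tissue's bound sites plus optional decoy bumps at unbound positions
  (accessible chromatin that the target TF does not bind — without these the
  unbound class would be trivially separable by accessibility alone), with
  independent replicate noise; peaks are the thresholded signal runs,
  emulating a peak caller with a minimum peak width;
* challenge-style B/U/A bin labels derived from the planted sites: a bin
  overlapping a site is bound, a near-miss within one bin width is
  ambiguous, everything else unbound.

A fraction of sites may be "weak" (sub-threshold accessibility bump): they
remain bound and visible in the raw signal but are missed by peak calling,
emulating the main failure mode that distinguishes peak-based from
bin-based feature designs.

All outputs are fully determined by ``SimulationConfig.seed``.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigError, CoordinateError, PlacementError
from .features import SignalTrack, average_tracks, merge_peaks, write_bed
from .intervals import make_bins, write_labels
from .motifs import PWM, write_pfm

_TISSUE_NAMES = ("liver", "kidney", "heart", "lung", "brain", "muscle", "skin", "colon")
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Conditions of a synthetic multi-tissue binding study."""

    target_motif: PWM
    cofactor_motifs: dict[str, list[PWM]]
    decoy_motifs: list[PWM] = field(default_factory=list)
    genome_length: int = 200_000
    n_chromosomes: int = 2
    gc_content: float = 0.41
    n_bound_sites_per_tissue: int = 500
    n_decoy_peaks_per_tissue: int = 300
    bound_site_amplitude: tuple[float, float] = (0.8, 1.6)
    decoy_peak_amplitude: tuple[float, float] = (0.5, 1.3)
    decoy_target_fraction: float = 0.5
    decoy_cofactor_mismatches: int = 3
    accessibility_peak_width_mean: float = 150.0
    peak_threshold: float = 0.25
    min_peak_width: int = 50
    signal_noise_sd: float = 0.0
    weak_site_fraction: float = 0.0
    weak_site_amplitude: float = 0.15
    cofactor_max_offset: int = 100
    n_replicates: int = 2
    bin_size: int = 200
    step: int = 50
    signal_resolution: int = 10
    seed: int = 0

    @property
    def tissues(self) -> list[str]:
        return list(self.cofactor_motifs)

    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.genome_length for i in range(self.n_chromosomes)}

    def all_motifs(self) -> list[PWM]:
        motifs = [self.target_motif]
        for mots in self.cofactor_motifs.values():
            motifs.extend(mots)
        motifs.extend(self.decoy_motifs)
        seen: set[str] = set()
        unique = []
        for m in motifs:
            if m.name not in seen:
                seen.add(m.name)
                unique.append(m)
        return unique

    def validate(self) -> None:
        if not np.isfinite(self.gc_content) or not 0.0 <= self.gc_content <= 1.0:
            raise ConfigError(f"gc_content must be a finite fraction in [0,1], "
                              f"got {self.gc_content}")
        if self.genome_length < 10 * self.bin_size:
            raise ConfigError("genome_length must be at least 10 x bin_size")
        if self.n_chromosomes < 1:
            raise ConfigError("need at least one chromosome")
        if self.signal_noise_sd < 0 or not np.isfinite(self.signal_noise_sd):
            raise ConfigError("signal_noise_sd must be a nonnegative finite real")
        if not 0.0 <= self.weak_site_fraction <= 1.0:
            raise ConfigError("weak_site_fraction must be in [0,1]")
        if self.n_replicates < 1:
            raise ConfigError("need at least one replicate")
        if self.signal_resolution < 1:
            raise ConfigError("signal_resolution must be positive")
        if not self.cofactor_motifs:
            raise ConfigError("need at least one tissue with a co-factor motif")
        widths = [m.width for m in self.all_motifs()]
        if max(widths) >= self.genome_length:
            raise ConfigError("motifs must be shorter than the genome")


def make_peaked_pwm(name: str, width: int, rng, dominant: float = 0.85,
                    total: float = 100.0) -> PWM:
    """Random informative count PWM: one dominant base per position."""
    rng = np.random.default_rng(rng)
    consensus = rng.integers(0, 4, size=width)
    rest = total * (1.0 - dominant) / 3.0
    mat = np.full((width, 4), rest)
    mat[np.arange(width), consensus] = total * dominant
    return PWM(name, mat)


def default_config(n_tissues: int = 3, n_decoys: int = 36, seed: int = 0,
                   **overrides) -> SimulationConfig:
    """Standard study conditions.

    One shared target motif; a distinct co-factor motif per tissue, with
    each tissue planting its own co-factor plus the next tissue's
    (cyclically), so co-factor landscapes are tissue-specific yet partially
    shared across tissues — as real co-factor repertoires are, and as
    cross-tissue generalization requires.  A pool of decoy motifs is scored
    but never planted (stand-ins for the large motif collection screened in
    practice).
    """
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(2 + n_tissues + n_decoys)
    target = make_peaked_pwm("TARGET", 12, streams[0])
    tissues = [(_TISSUE_NAMES[i] if i < len(_TISSUE_NAMES) else f"tissue{i + 1}")
               for i in range(n_tissues)]
    cof_pool = [make_peaked_pwm(f"COF_{t.upper()}", 10, streams[2 + i])
                for i, t in enumerate(tissues)]
    if n_tissues == 1:
        cofactors = {tissues[0]: [cof_pool[0]]}
    else:
        cofactors = {t: [cof_pool[i], cof_pool[(i + 1) % n_tissues]]
                     for i, t in enumerate(tissues)}
    decoys = [make_peaked_pwm(f"DECOY{i + 1:03d}", 8 + (i % 5), streams[2 + n_tissues + i])
              for i in range(n_decoys)]
    return SimulationConfig(target_motif=target, cofactor_motifs=cofactors,
                            decoy_motifs=decoys, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# Genome

def simulate_genome(config: SimulationConfig) -> dict[str, str]:
    """i.i.d. nucleotide sequences at the configured GC fraction, per chromosome."""
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    at = (1.0 - config.gc_content) / 2.0
    gc = config.gc_content / 2.0
    p = np.array([at, gc, gc, at])
    genome = {}
    for chrom in config.chrom_sizes():
        codes = rng.choice(4, size=config.genome_length, p=p)
        genome[chrom] = _BASE_BYTES[codes].tobytes().decode("ascii")
    return genome


# ---------------------------------------------------------------------------
# Site planting

class _Occupancy:
    """Per-chromosome registry of non-overlapping reserved intervals."""

    def __init__(self) -> None:
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}

    def free(self, chrom: str, start: int, end: int) -> bool:
        starts = self._starts.setdefault(chrom, [])
        ends = self._ends.setdefault(chrom, [])
        i = bisect.bisect_left(starts, end)
        if i > 0 and ends[i - 1] > start:
            return False
        return True

    def reserve(self, chrom: str, start: int, end: int) -> None:
        starts = self._starts.setdefault(chrom, [])
        ends = self._ends.setdefault(chrom, [])
        i = bisect.bisect_left(starts, start)
        starts.insert(i, start)
        ends.insert(i, end)


def _site_instance(pwm: PWM, rng) -> str:
    """A high-affinity motif instance: the consensus with at most one
    mismatch (mismatches in real bound sites are rare, and the mismatch
    energy of a peaked PWM is steep, so instances further from consensus
    would carry almost no occupancy)."""
    seq = list(pwm.consensus())
    probs = pwm.probabilities()
    j = int(rng.integers(pwm.width))
    b = int(rng.choice(4, p=probs[j]))
    seq[j] = "ACGT"[b]
    return "".join(seq)


def _degraded_instance(pwm: PWM, rng, n_mismatches: int) -> str:
    """A near-miss motif instance: consensus with ``n_mismatches`` forced
    non-consensus bases, giving intermediate rather than saturating
    occupancy."""
    seq = list(pwm.consensus())
    positions = rng.choice(pwm.width, size=min(n_mismatches, pwm.width), replace=False)
    for j in positions:
        choices = [b for b in range(4) if "ACGT"[b] != seq[j]]
        seq[j] = "ACGT"[int(rng.choice(choices))]
    return "".join(seq)


def plant_sites(genome: Mapping[str, str], config: SimulationConfig
                ) -> tuple[dict[str, pd.DataFrame], dict[str, str]]:
    """Plant target + co-factor motif instances into a shared genome.

    For every tissue, ``n_bound_sites_per_tissue`` non-overlapping positions
    receive a target-motif instance sampled from the PWM, and an instance of
    the tissue's co-factor motif within ``+/- cofactor_max_offset`` bp; these
    rows are flagged ``kind='bound'``.  In addition,
    ``n_decoy_peaks_per_tissue`` decoy accessible regions per tissue are
    placed away from that tissue's own bound sites (``kind='decoy'``): they
    receive an accessibility bump but no binding label, and a fraction of
    them (``decoy_target_fraction``) carries a target-motif instance
    *without* a co-factor — the classic unbound motif occurrence in open
    chromatin that makes co-factor context informative.  Decoy regions may
    coincide with *other* tissues' bound sites, emulating chromatin that is
    open in several tissues while binding stays tissue-specific.  All
    planted motif instances across tissues are mutually non-overlapping.

    Returns the per-tissue site tables (BED-sorted, with bump amplitudes)
    and the modified genome shared by all tissues.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    chroms = list(genome)
    arrays = {c: bytearray(genome[c].encode("ascii")) for c in chroms}
    occupied = _Occupancy()
    w_target = config.target_motif.width
    margin = config.cofactor_max_offset + max(m.width for m in config.all_motifs()) + 1
    records_by_tissue: dict[str, list] = {t: [] for t in config.tissues}

    for tissue in config.tissues:
        cof_list = config.cofactor_motifs[tissue]
        for k in range(config.n_bound_sites_per_tissue):
            cof = cof_list[k % len(cof_list)]
            w_cof = cof.width
            # allowed co-factor start offsets relative to the site start,
            # excluding overlap with the site itself
            left = np.arange(-config.cofactor_max_offset, -w_cof + 1)
            right = np.arange(w_target, config.cofactor_max_offset + 1)
            offsets = np.concatenate([left, right])
            if offsets.size == 0:
                raise ConfigError("cofactor_max_offset too small for the motif widths")
            placed = False
            for _attempt in range(2000):
                chrom = chroms[rng.integers(len(chroms))]
                length = len(arrays[chrom])
                pos = int(rng.integers(margin, length - margin - w_target))
                off = int(offsets[rng.integers(offsets.size)])
                c_start = pos + off
                spans = [(pos, pos + w_target), (c_start, c_start + w_cof)]
                if all(occupied.free(chrom, a, b) for a, b in spans):
                    for a, b in spans:
                        occupied.reserve(chrom, a, b)
                    arrays[chrom][pos:pos + w_target] = _site_instance(
                        config.target_motif, rng).encode("ascii")
                    arrays[chrom][c_start:c_start + w_cof] = _site_instance(
                        cof, rng).encode("ascii")
                    weak = rng.random() < config.weak_site_fraction
                    amp = (config.weak_site_amplitude if weak else
                           float(rng.uniform(*config.bound_site_amplitude)))
                    records_by_tissue[tissue].append(
                        ("bound", chrom, pos, pos + w_target, amp,
                         c_start, c_start + w_cof, cof.name))
                    placed = True
                    break
            if not placed:
                raise PlacementError(
                    f"cannot place site {k + 1}/{config.n_bound_sites_per_tissue} "
                    f"for tissue {tissue!r} without overlap")

    # Decoy accessible regions stay clear of every tissue's bound sites (so
    # their bins are consistently unbound in all tissues).  A fraction of
    # them carries a target-motif instance together with a *degraded*
    # co-factor instance nearby: the realistic near-miss composite site that
    # is open and motif-bearing yet unbound, yielding intermediate rather
    # than confident classifier votes.
    cof_pool = []
    seen_cof = set()
    for mots in config.cofactor_motifs.values():
        for m in mots:
            if m.name not in seen_cof:
                seen_cof.add(m.name)
                cof_pool.append(m)
    bound_mid: dict[str, list[float]] = {c: [] for c in chroms}
    for recs in records_by_tissue.values():
        for rec in recs:
            bound_mid[rec[1]].append((rec[2] + rec[3]) / 2.0)
    mid_arrays = {c: np.array(v) for c, v in bound_mid.items()}
    exclusion = config.bin_size + config.accessibility_peak_width_mean
    amp_lo, amp_hi = config.decoy_peak_amplitude
    for tissue in config.tissues:
        for _k in range(config.n_decoy_peaks_per_tissue):
            placed = False
            for _attempt in range(2000):
                chrom = chroms[rng.integers(len(chroms))]
                length = len(arrays[chrom])
                pos = int(rng.integers(margin, length - margin - w_target))
                center = pos + w_target / 2.0
                mids = mid_arrays[chrom]
                if mids.size and np.abs(mids - center).min() <= exclusion:
                    continue
                with_target = rng.random() < config.decoy_target_fraction
                if not with_target:
                    records_by_tissue[tissue].append(
                        ("decoy", chrom, pos, pos + w_target,
                         float(rng.uniform(amp_lo, amp_hi)), -1, -1, ""))
                    placed = True
                    break
                cof = cof_pool[int(rng.integers(len(cof_pool)))]
                w_cof = cof.width
                left = np.arange(-config.cofactor_max_offset, -w_cof + 1)
                right = np.arange(w_target, config.cofactor_max_offset + 1)
                offsets = np.concatenate([left, right])
                off = int(offsets[rng.integers(offsets.size)])
                c_start = pos + off
                spans = [(pos, pos + w_target), (c_start, c_start + w_cof)]
                if not all(occupied.free(chrom, a, b) for a, b in spans):
                    continue
                for a, b in spans:
                    occupied.reserve(chrom, a, b)
                arrays[chrom][pos:pos + w_target] = _site_instance(
                    config.target_motif, rng).encode("ascii")
                arrays[chrom][c_start:c_start + w_cof] = _degraded_instance(
                    cof, rng, config.decoy_cofactor_mismatches).encode("ascii")
                records_by_tissue[tissue].append(
                    ("decoy", chrom, pos, pos + w_target,
                     float(rng.uniform(amp_lo, amp_hi)), c_start, c_start + w_cof,
                     f"degraded:{cof.name}"))
                placed = True
                break
            if not placed:
                raise PlacementError(f"cannot place decoy region for tissue {tissue!r}")

    sites: dict[str, pd.DataFrame] = {}
    for tissue, recs in records_by_tissue.items():
        frame = pd.DataFrame(recs, columns=["kind", "chrom", "start", "end",
                                            "amplitude", "cofactor_start",
                                            "cofactor_end", "cofactor"])
        sites[tissue] = frame.sort_values(["chrom", "start"],
                                          kind="stable").reset_index(drop=True)
    genome_out = {c: arrays[c].decode("ascii") for c in chroms}
    return sites, genome_out


def bound_sites(frame: pd.DataFrame) -> pd.DataFrame:
    """Only the bound rows of a site table (drops decoy accessible regions)."""
    if "kind" in frame.columns:
        return frame[frame["kind"] == "bound"].reset_index(drop=True)
    return frame


# ---------------------------------------------------------------------------
# Accessibility

@dataclass
class AccessibilityData:
    """Per (tissue, replicate) peak BED frames and bedGraph signal frames."""

    peaks: dict[tuple[str, int], pd.DataFrame]
    signals: dict[tuple[str, int], pd.DataFrame]


def _add_bumps(signal: np.ndarray, centers: np.ndarray, amps: np.ndarray,
               sigma: float, res: int) -> None:
    n = signal.size
    half = int(np.ceil(5 * sigma / res))
    x_grid = np.arange(n) * res + res / 2.0
    for c, a in zip(centers, amps):
        i = int(c // res)
        lo, hi = max(0, i - half), min(n, i + half + 1)
        signal[lo:hi] += a * np.exp(-0.5 * ((x_grid[lo:hi] - c) / sigma) ** 2)


def _runs_to_intervals(mask: np.ndarray, res: int, min_width: int) -> pd.DataFrame:
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(np.int8), [0]))))
    starts = edges[0::2] * res
    ends = edges[1::2] * res
    keep = (ends - starts) >= min_width
    return pd.DataFrame({"start": starts[keep].astype(np.int64),
                         "end": ends[keep].astype(np.int64)})


def simulate_accessibility(sites: Mapping[str, pd.DataFrame],
                           config: SimulationConfig) -> AccessibilityData:
    """Smooth per-tissue accessibility with replicate noise.

    The noiseless signal is a sum of Gaussian bumps (sd = peak width / 4) at
    the centers of the tissue's planted regions — bound sites at their site
    amplitude, decoy accessible regions at theirs (on average weaker,
    mirroring the occupancy/accessibility link).  Each replicate adds
    independent Gaussian noise, clipped at 0.  Peaks are the runs where the
    replicate signal reaches ``peak_threshold``, after discarding runs
    shorter than ``min_peak_width``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 3])
    res = config.signal_resolution
    sigma = config.accessibility_peak_width_mean / 4.0
    chrom_sizes = config.chrom_sizes()
    n_points = {c: size // res for c, size in chrom_sizes.items()}

    peaks: dict[tuple[str, int], pd.DataFrame] = {}
    signals: dict[tuple[str, int], pd.DataFrame] = {}

    for tissue in config.tissues:
        site_frame = sites.get(tissue, pd.DataFrame(columns=["chrom", "start", "end"]))
        if len(site_frame):
            if (site_frame["end"] > site_frame["chrom"].map(chrom_sizes)).any():
                raise CoordinateError(f"tissue {tissue!r}: site outside genome")

        noiseless = {}
        for chrom, npts in n_points.items():
            signal = np.zeros(npts)
            own = site_frame[site_frame["chrom"] == chrom]
            if len(own):
                centers = (own["start"].to_numpy() + own["end"].to_numpy()) / 2.0
                amps = (own["amplitude"].to_numpy(float)
                        if "amplitude" in own.columns else np.ones(len(own)))
                _add_bumps(signal, centers, amps, sigma, res)
            noiseless[chrom] = signal

        for rep in range(1, config.n_replicates + 1):
            sig_parts, peak_parts = [], []
            for chrom, npts in n_points.items():
                sig = noiseless[chrom]
                if config.signal_noise_sd > 0:
                    sig = sig + rng.normal(0.0, config.signal_noise_sd, size=npts)
                sig = np.clip(sig, 0.0, None)
                starts = np.arange(npts, dtype=np.int64) * res
                sig_parts.append(pd.DataFrame({"chrom": chrom, "start": starts,
                                               "end": starts + res, "value": sig}))
                iv = _runs_to_intervals(sig >= config.peak_threshold, res,
                                        config.min_peak_width)
                iv.insert(0, "chrom", chrom)
                peak_parts.append(iv)
            signals[(tissue, rep)] = pd.concat(sig_parts, ignore_index=True)
            peaks[(tissue, rep)] = pd.concat(peak_parts, ignore_index=True)

    return AccessibilityData(peaks=peaks, signals=signals)


# ---------------------------------------------------------------------------
# Labels

def emit_labels(sites: Mapping[str, pd.DataFrame], bins: pd.DataFrame,
                bin_size: int | None = None) -> pd.DataFrame:
    """Challenge-style label table derived from the planted sites.

    Per tissue: a bin overlapping a site by >= 1 bp is B; a bin within one
    bin width of a site but not overlapping it is A; all other bins are U.
    """
    if bin_size is None:
        widths = (bins["end"] - bins["start"]).unique()
        bin_size = int(widths[0]) if len(widths) else 200
    out = bins[["chrom", "start", "end"]].reset_index(drop=True).copy()
    for tissue, frame in sites.items():
        frame = bound_sites(frame)
        labels = np.full(len(out), "U", dtype=object)
        for chrom, grp in out.groupby("chrom", sort=False):
            own = frame[frame["chrom"] == chrom]
            if not len(own):
                continue
            s_start = own["start"].to_numpy()[None, :]
            s_end = own["end"].to_numpy()[None, :]
            b_start = grp["start"].to_numpy()[:, None]
            b_end = grp["end"].to_numpy()[:, None]
            overlap = ((s_start < b_end) & (s_end > b_start)).any(axis=1)
            near = ((s_start < b_end + bin_size) & (s_end > b_start - bin_size)).any(axis=1)
            rows = grp.index.to_numpy()
            labels[rows[near]] = "A"
            labels[rows[overlap]] = "B"
        out[tissue] = labels
    return out


# ---------------------------------------------------------------------------
# Dataset assembly and file output

@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: dict[str, str]
    sites: dict[str, pd.DataFrame]
    accessibility: AccessibilityData
    bins: pd.DataFrame
    labels: pd.DataFrame

    def tracks(self, tissue: str) -> list[SignalTrack]:
        sizes = self.config.chrom_sizes()
        return [SignalTrack(self.accessibility.signals[(tissue, rep)], sizes)
                for rep in range(1, self.config.n_replicates + 1)]

    def merged_peaks(self, tissue: str) -> pd.DataFrame:
        reps = [self.accessibility.peaks[(tissue, rep)]
                for rep in range(1, self.config.n_replicates + 1)]
        return merge_peaks(reps)

    def peak_track(self, tissue: str) -> SignalTrack:
        return average_tracks(self.tracks(tissue))


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator: genome, sites, accessibility, bins, labels."""
    genome0 = simulate_genome(config)
    sites, genome = plant_sites(genome0, config)
    accessibility = simulate_accessibility(sites, config)
    bins = make_bins(config.chrom_sizes(), config.bin_size, config.step)
    labels = emit_labels(sites, bins, config.bin_size)
    return SimulatedDataset(config=config, genome=genome, sites=sites,
                            accessibility=accessibility, bins=bins, labels=labels)


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_bedgraph(frame: pd.DataFrame, path: str | Path) -> None:
    frame[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False, float_format="%.6g")


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> None:
    """Write the dataset as plain-text files (FASTA/BED/bedGraph/TSV/PFM)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(dataset.genome, out / "genome.fa")
    write_pfm(out / "motifs.pfm", dataset.config.all_motifs())
    write_labels(dataset.labels, out / "labels.tsv")
    for tissue, frame in dataset.sites.items():
        write_bed(frame, out / f"sites_{tissue}.bed")
    for (tissue, rep), frame in dataset.accessibility.peaks.items():
        write_bed(frame, out / f"peaks_{tissue}_rep{rep}.bed")
    for (tissue, rep), frame in dataset.accessibility.signals.items():
        write_bedgraph(frame, out / f"signal_{tissue}_rep{rep}.bedGraph")


# ---------------------------------------------------------------------------
# Interaction-matrix fixture

def make_interaction_matrix(target: str, partners: list[str], others: list[str],
                            high: float = 0.8, low: float = 0.05,
                            seed: int = 0) -> pd.DataFrame:
    """Synthetic protein-interaction probability matrix with a planted clique.

    The target and its partners interact with probability around ``high``;
    all other pairs around ``low``.  Entries are asymmetric (independent
    noise per direction), in [0, 1].
    """
    rng = np.random.default_rng([seed, 9])
    symbols = [target] + list(partners) + list(others)
    n = len(symbols)
    mat = np.clip(rng.normal(low, low / 3.0, size=(n, n)), 0.0, 1.0)
    clique = np.arange(1 + len(partners))
    for i in clique:
        for j in clique:
            if i != j:
                mat[i, j] = np.clip(rng.normal(high, high / 10.0), 0.0, 1.0)
    np.fill_diagonal(mat, 1.0)
    return pd.DataFrame(mat, index=symbols, columns=symbols)
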