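"""Synthetic dataset generator: determinism, planted structure, labels."""

import numpy as np
import pandas as pd
import pytest

from forestbind import simulate
from forestbind.exceptions import ConfigError
from forestbind.intervals import make_bins, read_labels
from forestbind.motifs import affinities_for_intervals, pwm_to_psem
from forestbind.simulate import (
    bound_sites,
    default_config,
    emit_labels,
    plant_sites,
    simulate_accessibility,
    simulate_dataset,
    simulate_genome,
    write_dataset,
)


def small_config(**overrides):
    defaults = dict(n_tissues=2, n_decoys=6, seed=3, genome_length=40_000,
                    n_bound_sites_per_tissue=40, n_decoy_peaks_per_tissue=25)
    defaults.update(overrides)
    return default_config(**defaults)


class TestGenome:
    def test_gc_zero_gives_only_a_and_t(self):
        genome = simulate_genome(small_config(gc_content=0.0))
        assert set("".join(genome.values())) <= {"A", "T"}

    def test_gc_fraction_within_binomial_bound(self):
        cfg = small_config(gc_content=0.5, genome_length=100_000, n_chromosomes=1)
        seq = simulate_genome(cfg)["chr1"]
        gc = sum(b in "GC" for b in seq)
        n, p = len(seq), 0.5
        assert abs(gc - n * p) <= 3 * np.sqrt(n * p * (1 - p))

    def test_out_of_range_gc_raises(self):
        with pytest.raises(ConfigError):
            simulate_genome(small_config(gc_content=1.5))
        with pytest.raises(ConfigError):
            simulate_genome(small_config(gc_content=float("nan")))

    def test_same_seed_gives_identical_fasta_bytes(self, tmp_path):
        for run in ("a", "b"):
            simulate.write_fasta(simulate_genome(small_config()),
                                 tmp_path / f"{run}.fa")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()


class TestDatasetDeterminism:
    def test_full_dataset_bytes_identical_across_runs(self, tmp_path):
        for run in ("a", "b"):
            out = tmp_path / run
            write_dataset(simulate_dataset(small_config()), out)
            assert sorted(p.name for p in out.iterdir())
        files_a = sorted((tmp_path / "a").iterdir())
        files_b = sorted((tmp_path / "b").iterdir())
        assert [p.name for p in files_a] == [p.name for p in files_b]
        for pa, pb in zip(files_a, files_b):
            assert pa.read_bytes() == pb.read_bytes(), pa.name


class TestPlantSites:
    def test_zero_sites_leave_genome_unmodified(self):
        cfg = small_config(n_bound_sites_per_tissue=0, n_decoy_peaks_per_tissue=0)
        genome = simulate_genome(cfg)
        sites, modified = plant_sites(genome, cfg)
        assert modified == genome
        for frame in sites.values():
            assert len(frame) == 0

    def test_planted_motif_instances_do_not_overlap(self):
        # plain decoy regions plant no sequence; only bound sites, their
        # co-factors and motif-bearing decoys occupy genome intervals
        cfg = small_config()
        sites, _ = plant_sites(simulate_genome(cfg), cfg)
        spans = []
        for frame in sites.values():
            for _, r in frame.iterrows():
                planted = r.kind == "bound" or str(r.cofactor).startswith("degraded")
                if planted:
                    spans.append((r.chrom, r.start, r.end))
                if r.cofactor_start >= 0:
                    spans.append((r.chrom, r.cofactor_start, r.cofactor_end))
        spans.sort()
        for (c1, s1, e1), (c2, s2, e2) in zip(spans, spans[1:]):
            assert c1 != c2 or s2 >= e1

    def test_tissue_specific_cofactor_repertoires(self):
        cfg = default_config(n_tissues=3, n_decoys=4, seed=3, genome_length=60_000,
                            n_bound_sites_per_tissue=40, n_decoy_peaks_per_tissue=10)
        sites, _ = plant_sites(simulate_genome(cfg), cfg)
        planted = {t: set(bound_sites(f)["cofactor"]) for t, f in sites.items()}
        tissues = cfg.tissues
        own = {t: {m.name for m in cfg.cofactor_motifs[t]} for t in tissues}
        for t in tissues:
            assert planted[t] == own[t]
        # repertoires are pairwise distinct but partially shared
        for a in tissues:
            for b in tissues:
                if a != b:
                    assert own[a] != own[b]
                    assert own[a] & own[b]

    def test_disjoint_cofactor_sets_plant_different_instances(self):
        from forestbind.motifs import PWM
        import numpy as np
        rng = np.random.default_rng(0)

        def pwm(name):
            mat = np.full((8, 4), 5.0)
            mat[np.arange(8), rng.integers(0, 4, 8)] = 85.0
            return PWM(name, mat)

        cfg = simulate.SimulationConfig(
            target_motif=pwm("TARGET"),
            cofactor_motifs={"a": [pwm("COF_A")], "b": [pwm("COF_B")]},
            genome_length=30_000, n_bound_sites_per_tissue=20,
            n_decoy_peaks_per_tissue=0, seed=4)
        sites, _ = plant_sites(simulate_genome(cfg), cfg)
        assert set(bound_sites(sites["a"])["cofactor"]) == {"COF_A"}
        assert set(bound_sites(sites["b"])["cofactor"]) == {"COF_B"}

    def test_cofactor_lies_within_offset_of_site(self):
        cfg = small_config()
        sites, _ = plant_sites(simulate_genome(cfg), cfg)
        for frame in sites.values():
            b = bound_sites(frame)
            rel = b["cofactor_start"] - b["start"]
            assert (rel.abs() <= cfg.cofactor_max_offset).all()

    def test_planted_sites_score_higher_target_affinity_than_random(self):
        cfg = small_config()
        genome0 = simulate_genome(cfg)
        sites, genome = plant_sites(genome0, cfg)
        psem = pwm_to_psem(cfg.target_motif)
        tissue = cfg.tissues[0]
        b = bound_sites(sites[tissue])
        planted = [(r.chrom, max(0, r.start - 20), r.end + 20)
                   for r in b.itertuples()]
        rng = np.random.default_rng(0)
        random_iv = [("chr1", int(s), int(s) + 52)
                     for s in rng.integers(0, cfg.genome_length - 60, size=200)]
        aff_p = affinities_for_intervals(genome, planted, [psem]).to_numpy().mean()
        aff_r = affinities_for_intervals(genome, random_iv, [psem]).to_numpy().mean()
        assert aff_p > 5 * aff_r

    def test_impossible_placement_raises(self):
        cfg = small_config(genome_length=2000, n_bound_sites_per_tissue=500)
        with pytest.raises(simulate.PlacementError):
            plant_sites(simulate_genome(cfg), cfg)


class TestAccessibility:
    def test_no_sites_and_no_noise_gives_flat_zero_signal_and_no_peaks(self):
        cfg = small_config(n_bound_sites_per_tissue=0, n_decoy_peaks_per_tissue=0)
        sites, _ = plant_sites(simulate_genome(cfg), cfg)
        acc = simulate_accessibility(sites, cfg)
        for frame in acc.signals.values():
            assert (frame["value"] == 0).all()
        for frame in acc.peaks.values():
            assert len(frame) == 0

    def test_every_bound_site_lies_inside_a_peak(self):
        cfg = small_config()
        ds = simulate_dataset(cfg)
        for tissue in cfg.tissues:
            merged = ds.merged_peaks(tissue)
            ps = merged["start"].to_numpy()
            pe = merged["end"].to_numpy()
            pc = merged["chrom"].to_numpy()
            for r in bound_sites(ds.sites[tissue]).itertuples():
                inside = (pc == r.chrom) & (ps <= r.start) & (pe >= r.end)
                assert inside.any(), f"{tissue} site {r.start} not in a peak"

    def test_replicates_differ_but_peaks_overlap_reciprocally(self):
        cfg = small_config(signal_noise_sd=0.02)
        ds = simulate_dataset(cfg)
        tissue = cfg.tissues[0]
        s1 = ds.accessibility.signals[(tissue, 1)]["value"].to_numpy()
        s2 = ds.accessibility.signals[(tissue, 2)]["value"].to_numpy()
        assert not np.array_equal(s1, s2)

        def coverage(frame):
            mask = np.zeros(cfg.genome_length * cfg.n_chromosomes, dtype=bool)
            offset = {c: i * cfg.genome_length
                      for i, c in enumerate(cfg.chrom_sizes())}
            for r in frame.itertuples():
                mask[offset[r.chrom] + r.start:offset[r.chrom] + r.end] = True
            return mask

        m1 = coverage(ds.accessibility.peaks[(tissue, 1)])
        m2 = coverage(ds.accessibility.peaks[(tissue, 2)])
        inter = (m1 & m2).sum()
        assert inter >= 0.9 * m1.sum()
        assert inter >= 0.9 * m2.sum()

    def test_weak_sites_stay_out_of_peaks_but_keep_raw_signal(self):
        cfg = small_config(weak_site_fraction=1.0)
        ds = simulate_dataset(cfg)
        tissue = cfg.tissues[0]
        merged = ds.merged_peaks(tissue)
        track = ds.peak_track(tissue)
        b = bound_sites(ds.sites[tissue])
        ps, pe = merged["start"].to_numpy(), merged["end"].to_numpy()
        pc = merged["chrom"].to_numpy()
        for r in b.itertuples():
            overlap = (pc == r.chrom) & (ps < r.end) & (pe > r.start)
            assert not overlap.any()
            center = (r.start + r.end) // 2
            assert track.mean(r.chrom, center - 20, center + 20) > 0.05


class TestLabels:
    def test_no_sites_gives_all_unbound(self):
        bins = make_bins({"chr1": 2000})
        labels = emit_labels({"liver": pd.DataFrame(
            columns=["kind", "chrom", "start", "end"])}, bins)
        assert (labels["liver"] == "U").all()

    def test_site_inside_one_bin_marks_the_four_covering_bins(self):
        bins = make_bins({"chr1": 2000})
        sites = {"liver": pd.DataFrame(
            [{"kind": "bound", "chrom": "chr1", "start": 700, "end": 710}])}
        labels = emit_labels(sites, bins)
        bound = labels[labels["liver"] == "B"]
        assert bound["start"].tolist() == [550, 600, 650, 700]

    def test_near_miss_bins_are_ambiguous(self):
        bins = make_bins({"chr1": 2000})
        sites = {"liver": pd.DataFrame(
            [{"kind": "bound", "chrom": "chr1", "start": 700, "end": 710}])}
        labels = emit_labels(sites, bins)
        amb = set(labels.loc[labels["liver"] == "A", "start"])
        # within one bin width (200 bp) of the site but not overlapping
        assert amb == {350, 400, 450, 500, 750, 800, 850, 900}

    def test_decoy_regions_stay_unbound(self):
        cfg = small_config()
        ds = simulate_dataset(cfg)
        for tissue in cfg.tissues:
            decoys = ds.sites[tissue][ds.sites[tissue]["kind"] == "decoy"]
            lab = ds.labels
            for r in decoys.itertuples():
                hit = lab[(lab["chrom"] == r.chrom) & (lab["start"] < r.end)
                          & (lab["end"] > r.start)]
                assert (hit[tissue] != "B").all()

    def test_label_table_round_trips_through_reader(self, tmp_path):
        ds = simulate_dataset(small_config())
        path = tmp_path / "labels.tsv"
        simulate.write_labels(ds.labels, path)
        back = read_labels(path, bins=ds.bins, strict=True)
        pd.testing.assert_frame_equal(back, ds.labels)

    def test_per_tissue_bound_counts_match_site_bookkeeping(self):
        ds = simulate_dataset(small_config())
        for tissue in ds.config.tissues:
            n_b = (ds.labels[tissue] == "B").sum()
            n_sites = len(bound_sites(ds.sites[tissue]))
            # every site covers 4-5 bins; neighbouring sites may share bins
            assert 3 * n_sites <= n_b <= 5 * n_sites
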