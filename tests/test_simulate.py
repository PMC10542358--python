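"""Synthetic-data generator: planted structure matches its stated parameters."""

import math

import numpy as np
import pandas as pd
import pytest

from rloopm5c import (
    PipelineError,
    SimulationParams,
    SPIKEIN_SEQUENCE,
    simulate_bisulfite_counts,
    simulate_dataset,
    simulate_drip_peaks,
    simulate_genome,
    plant_m5c_sites,
    plant_rloop_regions,
    write_dataset,
)


def _sense_base(genome, chrom, pos, strand):
    b = genome[chrom][pos]
    return b if strand == "+" else {"A": "T", "C": "G", "G": "C", "T": "A"}[b]


class TestGenome:
    def test_gc_fraction_within_binomial_bound(self):
        params = SimulationParams(n_chroms=1, chrom_length=100_000, n_transcripts=0,
                                  n_rloops=0, gc_fraction=0.5, seed=5)
        genome, _ = simulate_genome(params)
        seq = genome["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) < 3 * math.sqrt(0.25 / 100_000)

    def test_zero_transcripts(self):
        params = SimulationParams(n_transcripts=0, n_rloops=0, seed=0)
        genome, tx = simulate_genome(params)
        assert tx == [] and len(genome) == params.n_chroms

    def test_same_seed_identical(self):
        params = SimulationParams(seed=9)
        g1, t1 = simulate_genome(params)
        g2, t2 = simulate_genome(params)
        assert g1 == g2 and t1 == t2

    def test_transcripts_non_overlapping_fixed_strand(self):
        _, tx = simulate_genome(SimulationParams(seed=2))
        by_chrom = {}
        for t in tx:
            assert t.strand in "+-"
            by_chrom.setdefault(t.chrom, []).append(t)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda t: t.start)
            for a, b in zip(ivs, ivs[1:]):
                assert a.end <= b.start

    def test_infeasible_placement_rejected(self):
        params = SimulationParams(n_chroms=1, chrom_length=1000, n_transcripts=3,
                                  transcript_length=500, n_rloops=0)
        with pytest.raises(PipelineError, match="cannot place"):
            simulate_genome(params)


class TestRloopRegions:
    def test_realized_skew_and_gc(self):
        params = SimulationParams(n_chroms=1, chrom_length=100_000, n_transcripts=10,
                                  transcript_length=5_000, n_rloops=5,
                                  rloop_length=2_000, rloop_gc=0.6, rloop_skew=0.4,
                                  seed=3)
        genome, tx = simulate_genome(params)
        rloops, genome = plant_rloop_regions(genome, tx, params)
        for r in rloops:
            seq = genome.fetch(r)
            if r.strand == "-":
                seq = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            g, c = seq.count("G"), seq.count("C")
            assert abs((g - c) / (g + c) - 0.4) < 0.05
            assert abs((g + c) / len(seq) - 0.6) < 0.05

    def test_zero_regions_leaves_genome_unchanged(self):
        params = SimulationParams(n_rloops=0, seed=4)
        genome, tx = simulate_genome(params)
        rloops, genome2 = plant_rloop_regions(genome, tx, params)
        assert rloops == [] and genome2 == genome

    def test_zero_skew_symmetric(self):
        params = SimulationParams(n_chroms=1, chrom_length=60_000, n_transcripts=6,
                                  transcript_length=5_000, n_rloops=4,
                                  rloop_length=2_000, rloop_gc=0.5, rloop_skew=0.0,
                                  seed=6)
        genome, tx = simulate_genome(params)
        rloops, genome = plant_rloop_regions(genome, tx, params)
        for r in rloops:
            seq = genome.fetch(r)
            g, c = seq.count("G"), seq.count("C")
            # skew estimate has sd ~ 1/sqrt(n_GC) at zero true skew
            assert abs((g - c) / (g + c)) < 4 / math.sqrt(g + c)

    def test_infeasible_skew_gc_rejected(self):
        with pytest.raises(PipelineError, match="jointly infeasible"):
            SimulationParams(rloop_gc=0.0, rloop_skew=1.0)


class TestPlantSites:
    def test_full_colocalization_forces_rloop_placement(self):
        params = SimulationParams(colocalization=1.0, seed=8)
        ds = simulate_dataset(params)
        dep = ds.truth[ds.truth["dependent"]]
        assert dep["in_rloop"].all()

    def test_zero_colocalization_is_uniform(self):
        # uniform placement: in-R-loop fraction matches the fraction of
        # transcript cytosines inside R-loop regions, within a binomial CI
        params = SimulationParams(colocalization=0.0, n_dependent=400,
                                  n_independent=0, seed=12)
        ds = simulate_dataset(params)
        counts = ds.counts["WT_dmg"]
        from rloopm5c import annotate_sites_in_peaks
        c_in = annotate_sites_in_peaks(counts, ds.rloops).mean()
        dep_in = ds.truth[ds.truth["dependent"]]["in_rloop"].mean()
        se = math.sqrt(c_in * (1 - c_in) / 400)
        assert abs(dep_in - c_in) < 4 * se

    def test_truth_levels_pass_through(self):
        params = SimulationParams(level_induced=0.30, level_basal=0.02,
                                  frac_damage_induced=1.0, seed=1)
        ds = simulate_dataset(params)
        dep = ds.truth[ds.truth["dependent"]]
        assert (dep["level_WT_dmg"] == 0.30).all()
        assert (dep["level_KO_dmg"] == 0.02).all()
        assert (dep["level_WT_nodmg"] == 0.02).all()

    def test_sites_are_sense_strand_cytosines(self, default_dataset):
        ds = default_dataset
        for rec in ds.truth.itertuples():
            assert _sense_base(ds.genome, rec.chrom, rec.pos, rec.strand) == "C"

    def test_dependent_ordering(self, default_dataset):
        dep = default_dataset.truth[default_dataset.truth["dependent"]]
        assert (dep["level_KO_dmg"] <= dep["level_WT_dmg"]).all()

    def test_too_many_sites_rejected(self):
        params = SimulationParams(n_chroms=1, chrom_length=5_000, n_transcripts=1,
                                  transcript_length=500, n_rloops=1, rloop_length=200,
                                  n_dependent=5_000, n_independent=0)
        genome, tx = simulate_genome(params)
        rloops, genome = plant_rloop_regions(genome, tx, params)
        with pytest.raises(PipelineError):
            plant_m5c_sites(genome, tx, rloops, params)


class TestBisulfiteCounts:
    def test_spikein_sequence_structure(self):
        # the printed spike-in is 50 nt with 5 cytosines
        assert len(SPIKEIN_SEQUENCE) == 50
        assert SPIKEIN_SEQUENCE.count("C") == 5

    def test_spikein_table(self, default_dataset):
        sp = default_dataset.spikein
        assert len(sp) == 5
        assert list(sp["pos"]) == [i for i, b in enumerate(SPIKEIN_SEQUENCE) if b == "C"]

    def test_zero_level_zero_epsilon_gives_zero_unconverted(self):
        params = SimulationParams(nonconversion=0.0, n_dependent=0, n_independent=0,
                                  n_rloops=0, seed=3)
        ds = simulate_dataset(params)
        for df in ds.counts.values():
            assert (df["n_unconverted"] == 0).all()
        assert (ds.spikein["n_unconverted"] == 0).all()

    def test_observed_fraction_converges_to_truth(self):
        # empirical fraction within 4 sigma of the planted level at high coverage
        params = SimulationParams(coverage_mean=10_000, coverage_dispersion=0.0,
                                  nonconversion=0.0, level_independent=0.2,
                                  n_dependent=0, n_independent=50, seed=21)
        ds = simulate_dataset(params)
        df = ds.counts["WT_dmg"].merge(ds.truth, on=["chrom", "pos", "strand"])
        frac = df["n_unconverted"] / (df["n_unconverted"] + df["n_converted"])
        bound = 4 * np.sqrt(0.2 * 0.8 / 10_000)
        assert (np.abs(frac - 0.2) < bound).all()

    def test_every_transcript_cytosine_has_a_row(self, default_dataset):
        ds = default_dataset
        n_sense_c = 0
        for tx in ds.transcripts:
            seq = ds.genome.fetch(tx)
            n_sense_c += seq.count("C") if tx.strand == "+" else seq.count("G")
        for df in ds.counts.values():
            assert len(df) == n_sense_c


class TestDripPeaks:
    def _mini(self, **kw):
        params = SimulationParams(n_chroms=1, chrom_length=50_000, n_transcripts=10,
                                  transcript_length=3_000, n_rloops=5,
                                  rloop_length=500, seed=30, **kw)
        genome, tx = simulate_genome(params)
        rloops, genome = plant_rloop_regions(genome, tx, params)
        return genome, rloops, params

    def test_zero_artifacts(self):
        genome, rloops, params = self._mini(n_artifact_peaks=0, peak_jitter=0)
        untreated, rnaseh = simulate_drip_peaks(genome, rloops, params)
        assert rnaseh == []
        assert len(untreated) == len(rloops)

    def test_zero_jitter_matches_truth_coordinates(self):
        genome, rloops, params = self._mini(n_artifact_peaks=0, peak_jitter=0)
        untreated, _ = simulate_drip_peaks(genome, rloops, params)
        assert [(p.chrom, p.start, p.end) for p in untreated] == \
               [(r.chrom, r.start, r.end) for r in rloops]

    def test_artifacts_shared_verbatim(self):
        genome, rloops, params = self._mini(n_artifact_peaks=10)
        untreated, rnaseh = simulate_drip_peaks(genome, rloops, params)
        assert len(rnaseh) == 10
        for a in rnaseh:
            assert a in untreated

    def test_union_is_rloops_plus_artifacts(self):
        genome, rloops, params = self._mini(n_artifact_peaks=7, peak_jitter=0)
        untreated, rnaseh = simulate_drip_peaks(genome, rloops, params)
        assert len(untreated) == len(rloops) + len(rnaseh)
        rloop_derived = [p for p in untreated if p not in rnaseh]
        assert [(p.chrom, p.start, p.end) for p in rloop_derived] == \
               [(r.chrom, r.start, r.end) for r in rloops]


class TestDeterminism:
    def test_emitted_files_byte_identical(self, tmp_path):
        params = SimulationParams(seed=17, n_chroms=1, chrom_length=20_000,
                                  n_transcripts=5, transcript_length=2_000,
                                  n_rloops=3, rloop_length=300,
                                  n_dependent=20, n_independent=20)
        p1 = write_dataset(simulate_dataset(params), tmp_path / "a")
        p2 = write_dataset(simulate_dataset(params), tmp_path / "b")
        assert p1.keys() == p2.keys()
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key
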