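"""Windowed GC statistics, enrichment grids and sequence contexts."""

import math

import numpy as np
import pandas as pd
import pytest

from rloopm5c import (
    GenomeSequence,
    Interval,
    PipelineError,
    build_obs_exp_grid,
    compare_top_bottom_contexts,
    extract_contexts,
    reverse_complement,
    site_grid_distribution,
    windowed_gc_stats,
)


def brute_force_window_stats(seq, start, w):
    win = seq[start:start + w]
    g, c, n = win.count("G"), win.count("C"), win.count("N")
    skew = float("nan") if (n > 0 or g + c == 0) else (g - c) / (g + c)
    return skew, (g + c) / w


class TestWindowedStats:
    def test_all_g_window(self):
        df = windowed_gc_stats(GenomeSequence({"chr1": "G" * 50}), 50)
        assert df["gc_skew"].iloc[0] == 1.0 and df["gc_fraction"].iloc[0] == 1.0

    def test_at_only_window_undefined_skew(self):
        df = windowed_gc_stats(GenomeSequence({"chr1": "A" * 25 + "T" * 25}), 50)
        assert np.isnan(df["gc_skew"].iloc[0]) and df["gc_fraction"].iloc[0] == 0.0

    def test_skew_arithmetic(self):
        df = windowed_gc_stats(GenomeSequence({"chr1": "G" * 30 + "C" * 20}), 50)
        assert df["gc_skew"].iloc[0] == pytest.approx(0.2)
        assert df["gc_fraction"].iloc[0] == 1.0

    def test_n_window_flagged_undefined(self):
        df = windowed_gc_stats(GenomeSequence({"chr1": "G" * 49 + "N"}), 50)
        assert df["has_n"].iloc[0] and np.isnan(df["gc_skew"].iloc[0])

    def test_terminal_partial_tile_dropped(self):
        df = windowed_gc_stats(GenomeSequence({"chr1": "A" * 120}), 50)
        assert list(df["start"]) == [0, 50]

    def test_window_size_validation(self):
        with pytest.raises(PipelineError):
            windowed_gc_stats(GenomeSequence({"chr1": "ACGT"}), 1)

    def test_matches_brute_force_on_random_genome(self, rng):
        seq = "".join(rng.choice(list("ACGTN"), p=[0.3, 0.2, 0.2, 0.28, 0.02],
                                 size=4_973))
        df = windowed_gc_stats(GenomeSequence({"chr1": seq}), 50)
        for rec in df.itertuples():
            skew, gc = brute_force_window_stats(seq, rec.start, 50)
            assert rec.gc_fraction == pytest.approx(gc)
            if math.isnan(skew):
                assert np.isnan(rec.gc_skew)
            else:
                assert rec.gc_skew == pytest.approx(skew)

    def test_minus_facet_flips_skew_to_sense_strand(self):
        genome = GenomeSequence({"chr1": "G" * 100})
        tx = [Interval("chr1", 0, 100, "-")]
        df = windowed_gc_stats(genome, 50, transcripts=tx)
        assert (df["facet_strand"] == "-").all()
        assert (df["gc_skew"] == -1.0).all()

    def test_strand_antisymmetry(self, rng):
        # reverse-complementing the genome negates every defined skew and
        # preserves gc_fraction (windows come back in reverse order)
        seq = "".join(rng.choice(list("ACGT"), size=1_000))
        fwd = windowed_gc_stats(GenomeSequence({"chr1": seq}), 50)
        rev = windowed_gc_stats(GenomeSequence({"chr1": reverse_complement(seq)}), 50)
        fwd_skew = fwd["gc_skew"].to_numpy()
        rev_skew = rev["gc_skew"].to_numpy()[::-1]
        np.testing.assert_allclose(rev_skew, -fwd_skew)
        np.testing.assert_allclose(rev["gc_fraction"].to_numpy()[::-1],
                                   fwd["gc_fraction"].to_numpy())

    def test_in_rloop_annotation(self):
        genome = GenomeSequence({"chr1": "A" * 200})
        df = windowed_gc_stats(genome, 50, rloops=[Interval("chr1", 60, 90)])
        assert list(df["in_rloop"]) == [False, True, False, False]


def _windows_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "gc_skew", "gc_fraction",
                                       "has_n", "facet_strand", "in_rloop"])


class TestObsExpGrid:
    def test_forced_ratio(self):
        # all observed mass in one cell, expected uniform over 4 cells
        rows = [("chr1", i * 50, 0.55, 0.875, False, "+", True) for i in range(8)]
        for i, (sk, gc) in enumerate([(0.55, 0.875), (0.55, 0.925),
                                      (0.65, 0.875), (0.65, 0.925)] * 5):
            rows.append(("chr1", 1000 + i * 50, sk, gc, False, "+", False))
        grids = build_obs_exp_grid(_windows_frame(rows))
        ratio = grids["+"].ratio
        assert np.nanmax(ratio) == pytest.approx(4.0)

    def test_conservation(self, default_dataset):
        ds = default_dataset
        windows = windowed_gc_stats(ds.genome, 50, ds.transcripts, ds.rloops)
        grids = build_obs_exp_grid(windows)
        n_obs_binned = sum(g.observed.sum() for g in grids.values())
        n_obs_undef = sum(g.n_observed_undefined for g in grids.values())
        assert n_obs_binned + n_obs_undef == int(windows["in_rloop"].sum())
        any_grid = next(iter(grids.values()))
        assert (any_grid.expected.sum() + any_grid.n_expected_undefined
                == int((~windows["in_rloop"]).sum()))

    def test_no_observed_windows_rejected(self):
        rows = [("chr1", 0, 0.1, 0.5, False, "+", False)]
        with pytest.raises(PipelineError):
            build_obs_exp_grid(_windows_frame(rows))

    def test_uneven_bin_width_rejected(self):
        rows = [("chr1", 0, 0.1, 0.5, False, "+", True)]
        with pytest.raises(PipelineError, match="evenly"):
            build_obs_exp_grid(_windows_frame(rows), skew_bin_width=0.3)


class TestSiteGrid:
    def test_zero_sites(self):
        rows = [("chr1", 0, 0.25, 0.5, False, "+", False)]
        sites = pd.DataFrame(columns=["chrom", "pos", "strand"])
        counts, excl = site_grid_distribution(sites, _windows_frame(rows), 50)
        assert excl == 0 and all(g.sum() == 0 for g in counts.values())

    def test_single_site_lands_in_its_cell(self):
        rows = [("chr1", 0, 0.25, 1.0, False, "+", False)]
        sites = pd.DataFrame([("chr1", 10, "+")], columns=["chrom", "pos", "strand"])
        counts, excl = site_grid_distribution(sites, _windows_frame(rows), 50)
        assert counts["+"].sum() == 1 and excl == 0
        i, j = np.argwhere(counts["+"])[0]
        # skew 0.25 -> bin [0.2, 0.3) -> index 12; gc 1.0 -> last bin
        assert (i, j) == (12, 19)

    def test_site_outside_windows_excluded(self):
        rows = [("chr1", 0, 0.25, 1.0, False, "+", False)]
        sites = pd.DataFrame([("chr1", 510, "+")], columns=["chrom", "pos", "strand"])
        _, excl = site_grid_distribution(sites, _windows_frame(rows), 50)
        assert excl == 1


class TestContexts:
    def test_offset_zero_is_always_c(self, default_dataset):
        ds = default_dataset
        ctx = extract_contexts(ds.genome, ds.truth, flank_k=5)
        assert ctx.n_sites > 0
        assert ctx.frequency("C")[ctx.flank_k] == 1.0

    def test_plus_and_minus_strand_windows(self):
        genome = GenomeSequence({"chr1": "AACGG" + "TTTTT"})
        sites = pd.DataFrame([("chr1", 3, "+"), ("chr1", 2, "-")],
                             columns=["chrom", "pos", "strand"])
        # minus site: sense base at pos 2 is complement of 'C' -> G; use a
        # genome where pos 2 is G on + so sense is C
        genome = GenomeSequence({"chr1": "AAGGGTTTTT"})
        sites = pd.DataFrame([("chr1", 2, "-")], columns=["chrom", "pos", "strand"])
        ctx = extract_contexts(genome, sites, flank_k=2)
        # window on +: positions 0..4 = AAGGG; revcomp = CCCTT, centre C
        assert ctx.frequency("C")[2] == 1.0
        assert ctx.frequency("T")[4] == 1.0

    def test_uniform_sequence_background_frequency(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=120_000))
        genome = GenomeSequence({"chr1": seq})
        pos = [int(p) for p in rng.integers(20, 119_980, size=4_000)]
        sites = pd.DataFrame({"chrom": "chr1", "pos": pos, "strand": "+"})
        ctx = extract_contexts(genome, sites, flank_k=10)
        g = ctx.frequency("G")
        bound = 3 * math.sqrt(0.25 * 0.75 / ctx.n_sites)
        offsets = ctx.offsets
        assert all(abs(g[i] - 0.25) < bound for i in range(len(offsets))
                   if offsets[i] != 0)

    def test_edge_sites_excluded_with_count(self):
        genome = GenomeSequence({"chr1": "C" * 30})
        sites = pd.DataFrame([("chr1", 2, "+"), ("chr1", 15, "+")],
                             columns=["chrom", "pos", "strand"])
        ctx = extract_contexts(genome, sites, flank_k=10)
        assert ctx.n_sites == 1 and ctx.n_excluded == 1

    def test_n_containing_windows_excluded(self):
        genome = GenomeSequence({"chr1": "A" * 10 + "C" + "N" + "A" * 10})
        sites = pd.DataFrame([("chr1", 10, "+")], columns=["chrom", "pos", "strand"])
        ctx = extract_contexts(genome, sites, flank_k=5)
        assert ctx.n_sites == 0 and ctx.n_excluded == 1


class TestTopBottomContexts:
    def _calls(self, n, meth):
        return pd.DataFrame({
            "chrom": "chr1", "pos": np.arange(20, 20 + n) * 30, "strand": "+",
            "coverage": 50, "n_unconverted": (np.asarray(meth) * 50).astype(int),
            "meth_fraction": meth, "p": 0.0, "q": 0.0, "status": "called",
            "best": False})

    def test_half_quantile_partitions(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=2_000))
        genome = GenomeSequence({"chr1": seq})
        calls = self._calls(10, np.linspace(0.1, 0.9, 10))
        top, bottom = compare_top_bottom_contexts(calls, genome, 5, 0.5)
        assert top.n_sites + top.n_excluded == 5
        assert bottom.n_sites + bottom.n_excluded == 5

    def test_identical_contexts_identical_matrices(self):
        genome = GenomeSequence({"chr1": "ACGTT" * 400})
        pos = np.arange(10, 60) * 5 + 1  # every 'C' in the repeating unit
        calls = pd.DataFrame({
            "chrom": "chr1", "pos": pos, "strand": "+", "coverage": 50,
            "n_unconverted": np.arange(len(pos)), "p": 0.0, "q": 0.0,
            "meth_fraction": np.linspace(0.05, 0.95, len(pos)),
            "status": "called", "best": False})
        top, bottom = compare_top_bottom_contexts(calls, genome, 4, 0.2)
        np.testing.assert_array_equal(top.counts, bottom.counts)

    def test_quantile_validation(self):
        with pytest.raises(PipelineError):
            compare_top_bottom_contexts(self._calls(10, [0.5] * 10),
                                        GenomeSequence({"chr1": "A" * 1000}), 5, 0.9)
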