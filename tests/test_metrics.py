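"""Site metrics: metaprofiles, span/deletion classification, adjacency,
signal matrices, correlations and fold changes."""

import numpy as np
import pytest

from dsbskew.metrics import (
    SiteSignalMatrix,
    adjacent_open_sites,
    classify_correlation,
    correlate_sites,
    detect_deletions,
    fold_change,
    metaprofile,
    profile_fwhm,
    site_signal_matrix,
    span_fraction,
)
from dsbskew.simulate import (
    FactorProfile,
    SimulationConfig,
    fragments_to_records,
    simulate_fragments,
    simulate_genome,
)
from dsbskew.sites import GenomicSite
from dsbskew.tracks import FragmentRecord, StrandedTrack, compute_coverage
from conftest import random_fragment_records


def make_track(plus, minus=None, bin_size=50):
    plus = np.asarray(plus, float)
    minus = np.zeros_like(plus) if minus is None else np.asarray(minus, float)
    return StrandedTrack("chr1", bin_size, plus, minus)


class TestMetaprofile:
    def test_window_equal_to_track_is_the_track_slice(self):
        values = np.arange(40, dtype=float)
        tracks = {"chr1": make_track(values)}
        site = GenomicSite("chr1", 998, 1002, cut=1000, site_class="DSB")
        matrix, mean, offsets = metaprofile(tracks, [site], window=500)
        assert np.array_equal(mean, values[10:30])
        assert offsets[0] == -500 and offsets[-1] == 450

    def test_all_zero_track_gives_zero_profile(self):
        tracks = {"chr1": make_track(np.zeros(100))}
        site = GenomicSite("chr1", 2000, 2008, cut=2004, site_class="DSB")
        _, mean, _ = metaprofile(tracks, [site], window=1000)
        assert not np.any(mean)

    def test_minus_oriented_site_is_mirrored(self):
        values = np.zeros(100)
        values[25] = 5.0  # asymmetric feature left of the cut
        tracks = {"chr1": make_track(values)}
        fwd = GenomicSite("chr1", 1498, 1502, cut=1500, orientation="+",
                          site_class="DSB")
        rev = GenomicSite("chr1", 1498, 1502, cut=1500, orientation="-",
                          site_class="DSB")
        _, mf, _ = metaprofile(tracks, [fwd], window=1000)
        _, mr, _ = metaprofile(tracks, [rev], window=1000)
        assert np.array_equal(mr, mf[::-1])

    def test_narrow_footprint_profile_sharper_than_broad(self):
        profiles = {}
        for name, sigma in (("narrow", 150.0), ("broad", 1000.0)):
            cfg = SimulationConfig(
                seed=61, genome_length=120_000, dsb_sites=[60_000],
                cut_efficiency=1.0, resected_fraction=0.0, rejoined_fraction=0.0,
                n_fragments=40_000,
                factor_profile=FactorProfile(
                    footprint_sigma=sigma, dsb_induction_fold=25.0
                ),
            )
            genome, sites = simulate_genome(cfg)
            records = fragments_to_records(simulate_fragments(cfg, genome, sites), cfg)
            tracks = compute_coverage(records, {"chr1": 120_000}, 50)
            _, mean, offsets = metaprofile(tracks, sites, window=5000)
            profiles[name] = profile_fwhm(mean, offsets)
        assert profiles["narrow"] < profiles["broad"]


def brute_force_span_counts(records, cut, tol):
    """Exhaustive per-fragment oracle for the span/end/other classification."""
    n = {"spanning": 0, "ending": 0, "other": 0}
    for r in records:
        lo, hi = cut - tol, cut + tol
        ending = lo <= r.start <= hi or lo <= r.end <= hi
        spanning = r.start <= lo and r.end >= hi
        overlaps = r.start < hi and r.end > lo
        if ending:
            n["ending"] += 1
        elif spanning:
            n["spanning"] += 1
        elif overlaps:
            n["other"] += 1
    return n


class TestSpanFraction:
    def test_matches_brute_force_oracle_on_random_fragments(self):
        rng = np.random.default_rng(67)
        records = random_fragment_records(rng, 1_000, chrom_len=3_000)
        site = GenomicSite("chr1", 1496, 1504, cut=1500, site_class="DSB")
        sc = span_fraction(records, site, tolerance=5)
        oracle = brute_force_span_counts(records, 1500, 5)
        assert (sc.n_spanning, sc.n_ending, sc.n_other) == (
            oracle["spanning"], oracle["ending"], oracle["other"],
        )
        assert sc.n_spanning + sc.n_ending + sc.n_other == sum(oracle.values())

    def test_full_cutting_without_rejoining_leaves_no_spanners(self):
        cfg = SimulationConfig(
            seed=71, cut_efficiency=1.0, rejoined_fraction=0.0, n_fragments=20_000
        )
        genome, sites = simulate_genome(cfg)
        records = fragments_to_records(simulate_fragments(cfg, genome, sites), cfg)
        sc = span_fraction(records, sites[0], tolerance=5)
        assert sc.n_spanning == 0 and sc.fraction_ending == 1.0

    def test_no_cutting_fraction_ending_near_zero(self):
        cfg = SimulationConfig(seed=73, cut_efficiency=0.0, n_fragments=50_000)
        genome, sites = simulate_genome(cfg)
        records = fragments_to_records(simulate_fragments(cfg, genome, sites), cfg)
        sc = span_fraction(records, sites[0], tolerance=5)
        # only random shear termini fall in the +-5 bp window
        assert sc.fraction_ending < 0.1

    def test_deletion_bearing_fragment_still_spans(self):
        rec = FragmentRecord(
            "chr1", 1000, 2000, flags=(99, 147), template_strand="+",
            gap_blocks=((1496, 1505),),
        )
        site = GenomicSite("chr1", 1496, 1504, cut=1500, site_class="DSB")
        sc = span_fraction([rec], site, tolerance=5)
        assert sc.n_spanning == 1


class TestDetectDeletions:
    SITE = GenomicSite("chr1", 1496, 1504, cut=1500, site_class="DSB")

    def test_nine_bp_gap_at_cut_counted(self):
        rec = FragmentRecord(
            "chr1", 1000, 2000, flags=(99, 147), template_strand="+",
            gap_blocks=((1500, 1509),),
        )
        assert detect_deletions([rec], self.SITE) == {9: 1}

    def test_no_gaps_empty_histogram(self):
        rec = FragmentRecord("chr1", 1000, 2000, flags=(99, 147))
        assert detect_deletions([rec], self.SITE) == {}

    def test_simulated_junction_deletion_is_the_modal_length(self, tmp_path):
        cfg = SimulationConfig(
            seed=79, cut_efficiency=1.0, rejoined_fraction=0.3,
            resected_fraction=0.0, deletion_length=9, n_fragments=10_000,
        )
        genome, sites = simulate_genome(cfg)
        from dsbskew.simulate import emit_sam
        from dsbskew.tracks import read_fragments

        sam = tmp_path / "del.sam"
        emit_sam(simulate_fragments(cfg, genome, sites), genome, cfg, sam)
        records = read_fragments(sam)
        hist = detect_deletions(records, sites[0], tolerance=5)
        assert hist and max(hist, key=hist.get) == 9


class TestAdjacentOpenSites:
    def make_dsb(self, cut, chrom="chr1"):
        return GenomicSite(chrom, cut - 4, cut + 4, cut=cut, label=f"d{cut}",
                           site_class="DSB")

    def test_boundary_distances(self):
        dsb = [self.make_dsb(100_000)]
        mk = lambda c: GenomicSite("chr1", c - 100, c + 100, label=f"o{c}")
        selected = adjacent_open_sites(dsb, [mk(110_000), mk(101_000), mk(160_000)])
        assert [s.start + 100 for s in selected] == [110_000]

    def test_matches_exhaustive_filter_on_random_sites(self):
        rng = np.random.default_rng(83)
        cuts = [200_000, 500_000, 800_000]
        dsb = [self.make_dsb(c) for c in cuts]
        centers = rng.integers(1_000, 999_000, size=200)
        opens = [
            GenomicSite("chr1", int(c - 150), int(c + 150), label=f"o{i}")
            for i, c in enumerate(centers)
        ]
        got = {s.start for s in adjacent_open_sites(dsb, opens)}
        expected = set()
        for o in opens:
            d = min(abs(o.center - c) for c in cuts)
            zone = any(o.start <= c + 1_500 and o.end >= c - 1_500 for c in cuts)
            if 1_500 < d < 50_000 and not zone:
                expected.add(o.start)
        assert got == expected

    def test_invariant_to_input_order_and_duplicate_dsbs(self):
        rng = np.random.default_rng(89)
        dsb = [self.make_dsb(c) for c in (200_000, 500_000)]
        opens = [
            GenomicSite("chr1", int(c), int(c) + 300, label=f"o{i}")
            for i, c in enumerate(rng.integers(1_000, 700_000, size=50))
        ]
        a = adjacent_open_sites(dsb, opens)
        b = adjacent_open_sites(dsb[::-1] + dsb, opens[::-1])
        assert [(s.chrom, s.start, s.end) for s in a] == [
            (s.chrom, s.start, s.end) for s in b
        ]


class TestSiteSignalMatrix:
    def _sites(self, n=12):
        return [
            GenomicSite("chr1", 2_000 * (i + 1) - 4, 2_000 * (i + 1) + 4,
                        cut=2_000 * (i + 1), label=f"s{i}", site_class="DSB")
            for i in range(n)
        ]

    def test_constant_track_gives_constant_entries(self):
        tracks = {"a": {"chr1": make_track(np.full(600, 3.5))}}
        m = site_signal_matrix(tracks, self._sites(), window=500)
        assert np.allclose(m.values, 3.5)

    def test_scale_factor_linearity(self):
        base = np.abs(np.sin(np.arange(600))) + 0.1
        tracks = {
            "a": {"chr1": make_track(base)},
            "b": {"chr1": StrandedTrack("chr1", 50, base * 2, np.zeros(600),
                                        scale_factor=2.0)},
        }
        m = site_signal_matrix(tracks, self._sites(), window=500)
        assert np.allclose(m.values[:, 1], 2 * m.values[:, 0])

    def test_replicate_concordance_on_simulated_data(self):
        """Same config, different seeds: site signals rank concordantly.

        The probed sites span a wide occupancy range (graded open-chromatin
        peaks plus induced cuts), as site-signal correlation is only
        meaningful over heterogeneous sites.
        """
        from dsbskew.simulate import OpenPeak

        peaks = [
            OpenPeak(center=20_000 * (i + 1), width=300.0, occupancy=occ)
            for i, occ in enumerate([0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 0.1, 3.0])
        ]
        tracks = {}
        for rep, seed in enumerate((301, 302)):
            cfg = SimulationConfig(
                seed=seed, genome_length=200_000, dsb_sites=[50_000, 150_000],
                cut_efficiency=0.8, open_peaks=peaks, n_fragments=100_000,
            )
            genome, sites = simulate_genome(cfg)
            records = fragments_to_records(simulate_fragments(cfg, genome, sites), cfg)
            tracks[f"rep{rep}"] = compute_coverage(records, {"chr1": 200_000}, 50)
        probe = sites + [
            GenomicSite("chr1", int(p.center - 300), int(p.center + 300),
                        label=f"peak{i}", site_class="open_chromatin")
            for i, p in enumerate(peaks)
        ]
        m = site_signal_matrix(tracks, probe, window=1_000)
        rho, labels = correlate_sites(m)
        assert rho.loc["rep0", "rep1"] >= 0.9
        assert labels.loc["rep0", "rep1"] == "strong"


class TestCorrelateAndFold:
    def _matrix(self, values, samples):
        sites = [
            GenomicSite("chr1", 10 * i + 1, 10 * i + 5, label=f"s{i}")
            for i in range(values.shape[0])
        ]
        return SiteSignalMatrix(sites=sites, samples=samples, values=values,
                                window_bp=100)

    def test_self_negation_and_monotone_invariance(self):
        rng = np.random.default_rng(97)
        col = rng.gamma(2.0, 10.0, 30)
        values = np.column_stack([col, -col, np.exp(col / col.max() * 3)])
        rho, labels = correlate_sites(self._matrix(values, ["a", "neg", "mono"]))
        assert rho.loc["a", "a"] == 1.0 and labels.loc["a", "a"] == "strong"
        assert rho.loc["a", "neg"] == -1.0 and labels.loc["a", "neg"] == "weak"
        assert rho.loc["a", "mono"] == pytest.approx(1.0)

    def test_zero_variance_column_reported_undefined(self):
        values = np.column_stack([np.arange(15.0), np.full(15, 2.0)])
        rho, labels = correlate_sites(self._matrix(values, ["a", "flat"]))
        assert np.isnan(rho.loc["a", "flat"])
        assert labels.loc["a", "flat"] == "undefined"

    def test_correlation_class_thresholds(self):
        assert classify_correlation(0.7) == "strong"
        assert classify_correlation(0.5) == "moderate"
        assert classify_correlation(0.49) == "weak"

    def test_fold_change_arithmetic(self):
        values = np.column_stack([np.zeros(12), np.full(12, 9.0)])
        m = self._matrix(values, ["a", "b"])
        folds, median = fold_change(m, "a", "b", pseudocount=1.0)
        assert np.allclose(folds, 10.0) and median == 10.0
        same, med1 = fold_change(m, "a", "a")
        assert np.allclose(same, 1.0) and med1 == 1.0
        with pytest.raises(ValueError):
            fold_change(m, "a", "b", pseudocount=-1.0)

    def test_induction_fold_recovered_from_simulation(self):
        base = dict(
            genome_length=200_000, dsb_sites=[50_000, 150_000], n_fragments=60_000,
            resected_fraction=0.0, rejoined_fraction=0.0,
        )
        cfg0 = SimulationConfig(seed=5, cut_efficiency=0.0, **base)
        cfg1 = SimulationConfig(
            seed=6, cut_efficiency=1.0,
            factor_profile=FactorProfile(dsb_induction_fold=10.0), **base
        )
        genome, sites = simulate_genome(cfg0)
        tracks = {}
        for name, cfg in (("noDSB", cfg0), ("DSB", cfg1)):
            records = fragments_to_records(simulate_fragments(cfg, genome, sites), cfg)
            tracks[name] = compute_coverage(records, {"chr1": 200_000}, 50)
        m = site_signal_matrix(tracks, sites, window=1_000)
        _, median = fold_change(m, "noDSB", "DSB", pseudocount=0.01)
        assert 7.0 <= median <= 13.0
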