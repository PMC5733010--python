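"""ED statistic, sliding-window fit, threshold arithmetic and peak calling."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsascan.ed_scan import (
    CandidateRegion,
    ChromTrack,
    FittedTrack,
    ScanConfig,
    SiteScore,
    base_frequencies,
    call_candidate_regions,
    compute_threshold,
    euclidean_distance,
    run_scan,
    score_sites,
    sliding_window_fit,
)
from bsascan.errors import AnalysisError, ConfigError, ContractError
from bsascan.simdata import simulate_dataset
from bsascan.site_filters import filter_ed_input
from bsascan.variant_io import BulkVariantSite

from conftest import make_biallelic, make_snp


class TestBaseFrequencies:
    def test_direct_normalisation(self):
        fv = base_frequencies(make_snp(c1=(10, 0, 0, 10), c2=(30, 0, 10, 0)))
        assert fv.freqs_r01 == (0.5, 0, 0, 0.5)
        assert fv.freqs_r02 == (0.75, 0, 0.25, 0)

    def test_zero_depth_is_a_contract_violation(self):
        with pytest.raises(ContractError):
            base_frequencies(make_snp(c1=(0, 0, 0, 0), c2=(10, 0, 0, 0)))

    @given(
        st.lists(st.integers(0, 100), min_size=4, max_size=4).filter(
            lambda c: sum(c) > 0
        )
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_frequencies_sum_to_one(self, counts):
        fv = base_frequencies(make_snp(c1=tuple(counts), c2=(5, 5, 5, 5)))
        assert abs(sum(fv.freqs_r01) - 1.0) < 1e-12
        assert abs(sum(fv.freqs_r02) - 1.0) < 1e-12


class TestEuclideanDistance:
    def test_identical_pools_score_zero(self):
        s = euclidean_distance(make_snp(c1=(10, 0, 10, 0), c2=(20, 0, 20, 0)))
        assert s.ed == 0.0 and s.powered_ed == 0.0

    def test_opposite_fixation_is_sqrt_two(self):
        s = euclidean_distance(make_snp(c1=(10, 0, 0, 0), c2=(0, 0, 0, 10)))
        assert s.ed == pytest.approx(np.sqrt(2), abs=1e-12)
        assert s.powered_ed == pytest.approx(2**2.5, abs=1e-9)

    def test_hand_computed_intermediate_case(self):
        s = euclidean_distance(make_snp(c1=(30, 0, 10, 0), c2=(10, 0, 30, 0)))
        assert s.ed == pytest.approx(np.sqrt(0.5), abs=1e-12)
        assert s.powered_ed == pytest.approx(0.5**2.5, abs=1e-12)

    def test_power_one_is_identity(self):
        site = make_snp(c1=(30, 0, 10, 0), c2=(10, 0, 30, 0))
        s = euclidean_distance(site, power=1.0)
        assert s.powered_ed == s.ed

    def test_vectorised_scoring_matches_per_site(self):
        rng = np.random.default_rng(3)
        sites = [
            make_snp(pos=i + 1, c1=tuple(rng.integers(1, 30, 4)),
                     c2=tuple(rng.integers(1, 30, 4)))
            for i in range(200)
        ]
        vec = score_sites(sites)
        for s, v in zip(sites, vec):
            assert euclidean_distance(s).ed == pytest.approx(v.ed, abs=1e-14)

    def test_biallelic_closed_form_on_random_sites(self):
        """For two-allele sites ED = sqrt(2)|f1 - f2| exactly."""
        rng = np.random.default_rng(11)
        n = 10_000
        depth = 200
        a1 = rng.integers(0, depth + 1, n)
        a2 = rng.integers(0, depth + 1, n)
        sites = [
            BulkVariantSite(
                "A01", i + 1, "A", ("G",),
                (int(depth - x), 0, int(x), 0), (int(depth - y), 0, int(y), 0),
            )
            for i, (x, y) in enumerate(zip(a1, a2))
        ]
        eds = np.array([s.ed for s in score_sites(sites)])
        expected = np.sqrt(2) * np.abs(a1 - a2) / depth
        assert np.max(np.abs(eds - expected)) < 1e-12
        assert np.all(eds >= 0) and np.all(eds <= np.sqrt(2) + 1e-12)

    def test_monotone_in_frequency_divergence(self):
        eds = [
            euclidean_distance(
                make_biallelic("A01", 1, f1=0.5 + d, f2=0.5 - d, depth=1000)
            ).ed
            for d in np.linspace(0, 0.5, 26)
        ]
        assert all(b >= a for a, b in zip(eds, eds[1:]))


class TestScanConfig:
    @pytest.mark.parametrize(
        "kwargs", [{"power": 0.5}, {"window": 0}, {"step": 0},
                   {"window": 100, "step": 200}]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            ScanConfig(**kwargs)


class TestSlidingWindowFit:
    def test_constant_signal_fits_exactly(self):
        scores = [
            SiteScore("A01", p, 0.2 ** (1 / 5), 0.2)
            for p in range(1_000, 100_001, 1_000)
        ]
        cfg = ScanConfig(window=10_000, step=5_000, min_snps=1)
        track = sliding_window_fit(scores, cfg, {"A01": 100_000})
        vals = track.chroms["A01"].values
        defined = vals[~np.isnan(vals)]
        assert len(defined) > 0
        assert np.allclose(defined, 0.2, atol=1e-12)

    def test_single_snp_window_reports_that_snp(self):
        scores = [SiteScore("A01", 5_000, 0.4, 0.4**5)]
        cfg = ScanConfig(window=10_000, step=10_000, min_snps=1)
        track = sliding_window_fit(scores, cfg, {"A01": 10_000})
        assert track.chroms["A01"].values[0] == pytest.approx(0.4**5)

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(17)
        pos = np.sort(rng.choice(np.arange(1, 3_000_001), 1_000, replace=False))
        powered = rng.uniform(0, 1, 1_000)
        scores = [
            SiteScore("A01", int(p), float(v ** (1 / 5)), float(v))
            for p, v in zip(pos, powered)
        ]
        cfg = ScanConfig(window=200_000, step=50_000, min_snps=1)
        track = sliding_window_fit(scores, cfg, {"A01": 3_000_000})
        ct = track.chroms["A01"]
        for c, got in zip(ct.centers, ct.values):
            inside = powered[(pos >= c - 100_000) & (pos < c + 100_000)]
            want = inside.mean() if len(inside) else np.nan
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)

    def test_sparse_windows_are_undefined_not_zero(self):
        scores = [SiteScore("A01", 5_000, 0.4, 0.4**5)]
        cfg = ScanConfig(window=10_000, step=10_000, min_snps=10)
        track = sliding_window_fit(scores, cfg, {"A01": 50_000})
        assert np.isnan(track.chroms["A01"].values).all()

    def test_mask_excludes_snps_from_fit(self):
        scores = [
            SiteScore("A01", p, 0.1, 0.1) for p in range(1_000, 50_001, 1_000)
        ] + [SiteScore("A01", 25_500, 1.4, 1.4)]
        cfg = ScanConfig(window=10_000, step=10_000, min_snps=1,
                         mask={"A01": [(25_400, 25_600)]})
        track = sliding_window_fit(scores, cfg, {"A01": 50_000})
        assert np.nanmax(track.chroms["A01"].values) == pytest.approx(0.1)


class TestThreshold:
    def test_hand_computed_toy_vector(self):
        track = FittedTrack(window=10, step=10)
        track.chroms["A01"] = ChromTrack(
            "A01", np.arange(5.0), np.array([1.0, 2, 3, 4, 5]), np.full(5, 10)
        )
        t = compute_threshold(track)
        assert t.median == 3.0
        assert t.sd == pytest.approx(np.sqrt(2.5), abs=1e-12)
        assert t.tau == pytest.approx(7.743416, abs=1e-6)

    def test_invariant_under_window_permutation(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 1, 101)
        t1 = FittedTrack(10, 10)
        t1.chroms["A01"] = ChromTrack("A01", np.arange(101.0), vals, np.full(101, 10))
        t2 = FittedTrack(10, 10)
        t2.chroms["A01"] = ChromTrack(
            "A01", np.arange(101.0), rng.permutation(vals), np.full(101, 10)
        )
        assert compute_threshold(t1).tau == pytest.approx(
            compute_threshold(t2).tau, abs=1e-12
        )

    def test_degenerate_variance_calls_no_regions(self):
        track = FittedTrack(10, 10)
        track.chroms["A01"] = ChromTrack(
            "A01", np.arange(5.0) * 10 + 5, np.full(5, 0.3), np.full(5, 10)
        )
        t = compute_threshold(track)
        assert t.sd == 0.0 and t.tau == 0.3
        scores = [SiteScore("A01", int(c), 0.3, 0.3) for c in range(1, 50)]
        assert call_candidate_regions(track, t.tau, scores) == []

    def test_too_few_windows_is_an_analysis_error(self):
        track = FittedTrack(10, 10)
        track.chroms["A01"] = ChromTrack(
            "A01", np.array([5.0]), np.array([0.3]), np.array([10])
        )
        with pytest.raises(AnalysisError):
            compute_threshold(track)


class TestCallRegions:
    def _toy_track(self, values, W=1_000):
        centers = np.arange(W / 2, W * len(values), W, dtype=float)
        track = FittedTrack(window=W, step=W)
        track.chroms["A01"] = ChromTrack(
            "A01", centers, np.asarray(values, dtype=float),
            np.full(len(values), 10),
        )
        return track

    def test_single_run_extracted(self):
        values = [0.1] * 8 + [0.9, 0.95, 0.9] + [0.1] * 8
        track = self._toy_track(values)
        scores = [
            SiteScore("A01", int(c), v, v)
            for c, v in zip(track.chroms["A01"].centers, values)
        ]
        regions = call_candidate_regions(track, 0.5, scores)
        assert len(regions) == 1
        r = regions[0]
        # windows 9-11 -> SNPs at their centers bound the region
        assert (r.start, r.end) == (8_500, 10_500)
        assert r.peak_value == pytest.approx(0.95)
        assert r.n_snps == 3

    def test_no_window_above_threshold(self):
        track = self._toy_track([0.1] * 10)
        assert call_candidate_regions(track, 0.5, []) == []

    def test_gap_tolerance_bridges_undefined_windows(self):
        values = [0.1] * 3 + [0.9, np.nan, 0.9] + [0.1] * 3
        track = self._toy_track(values)
        scores = [
            SiteScore("A01", int(c), 0.9, 0.9)
            for c in track.chroms["A01"].centers
        ]
        strict = call_candidate_regions(track, 0.5, scores, gap_tolerance=0)
        bridged = call_candidate_regions(track, 0.5, scores, gap_tolerance=1)
        assert len(strict) == 2
        assert len(bridged) == 1


def test_bulk_swap_symmetry(tiny_sim_config):
    """Swapping bulk labels leaves ED, the track, tau and regions unchanged."""
    sites, _ = simulate_dataset(tiny_sim_config)
    surv = filter_ed_input([s for s in sites if s.variant_class == "snp"]).survivors
    swapped = [
        BulkVariantSite(s.chrom, s.pos, s.ref, s.alts, s.counts_r02,
                        s.counts_r01, s.ad_r02, s.ad_r01)
        for s in surv
    ]
    cfg = ScanConfig(window=500_000, step=100_000, min_snps=5)
    lengths = dict(tiny_sim_config.chrom_lengths)
    res_a = run_scan(surv, cfg, lengths)
    res_b = run_scan(swapped, cfg, lengths)
    assert [s.ed for s in res_a.scores] == [s.ed for s in res_b.scores]
    assert res_a.threshold.tau == pytest.approx(res_b.threshold.tau, abs=1e-14)
    assert [(r.start, r.end) for r in res_a.regions] == [
        (r.start, r.end) for r in res_b.regions
    ]


def test_region_invariants():
    r = CandidateRegion("A06", 1_824_886, 2_347_097, 0.9, 523)
    assert r.length == 2_347_097 - 1_824_886 + 1
    with pytest.raises(ValueError):
        CandidateRegion("A06", 10, 5, 0.9, 1)
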