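import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfcrscreen import io as gio
from tfcrscreen.core import (
    assign_contributing_tfbs,
    call_summits,
    compute_density,
    compute_sc,
    compute_tc,
    compute_window,
    identify_tfcrs,
)
from tfcrscreen.models import AccessibilityPeak, TfcrParams, TfbsRecord

from conftest import brute_force_density, brute_force_maxima, make_tfbs

SIGMA = 300.0
BP = TfcrParams(sigma=SIGMA, grid_step=1)


def kernel(d, sigma=SIGMA):
    return math.exp(-(d**2) / (2 * sigma**2))


class TestDensity:
    def test_single_site_has_unit_maximum_at_midpoint(self):
        profile = compute_density(make_tfbs("chr1", [1000]), BP)
        coords = profile.coordinates()
        i = int(np.argmax(profile.values))
        assert coords[i] == 1000
        assert profile.values[i] == pytest.approx(1.0, abs=1e-12)

    def test_empty_input_gives_empty_profile(self):
        profile = compute_density([], BP)
        assert profile.is_empty

    def test_two_site_density_matches_direct_kernel_sum(self):
        # sites at 1000 and 1200: density(1100) = 2*exp(-100^2/(2*300^2))
        profile = compute_density(make_tfbs("chr1", [1000, 1200]), BP)
        coords = profile.coordinates()
        value = profile.values[coords == 1100][0]
        assert value == pytest.approx(2 * kernel(100), abs=1e-12)
        assert value == pytest.approx(1.8919, abs=1e-4)

    def test_mixed_chromosomes_rejected(self):
        sites = make_tfbs("chr1", [100]) + make_tfbs("chr2", [200])
        with pytest.raises(ValueError, match="one chromosome"):
            compute_density(sites, BP)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_grid_density_matches_per_bp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        positions = sorted(int(p) for p in rng.integers(5000, 25_000, size=60))
        profile = compute_density(make_tfbs("chr1", positions), BP)
        oracle = brute_force_density(
            positions, profile.grid_start, len(profile.values), SIGMA
        )
        assert np.max(np.abs(profile.values - oracle)) <= 1e-9


class TestSummits:
    def test_single_site_summit_at_midpoint(self):
        profile = compute_density(make_tfbs("chr1", [1000]), BP)
        assert call_summits(profile) == [1000]

    def test_close_pair_is_unimodal_with_summit_at_center(self):
        # two equal kernels separated by less than 2*sigma sum to one mode
        profile = compute_density(make_tfbs("chr1", [1000, 1200]), BP)
        assert call_summits(profile) == [1100]

    def test_distant_pair_gives_two_summits_near_each_site(self):
        profile = compute_density(make_tfbs("chr1", [1000, 3000]), BP)
        summits = call_summits(profile)
        assert len(summits) == 2
        assert abs(summits[0] - 1000) <= BP.grid_step
        assert abs(summits[1] - 3000) <= BP.grid_step

    def test_plateau_reported_at_midpoint_with_low_tie(self):
        from tfcrscreen.core import DensityProfile

        values = np.array([0.0, 1.0, 2.0, 2.0, 1.0, 0.0])
        profile = DensityProfile(chrom="chr1", grid_start=100, grid_step=10,
                                 values=values)
        assert call_summits(profile) == [120]  # indices 2,3 -> floor mid 2

    def test_summit_sets_match_oracle_on_random_sets(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(5, 80))
            positions = sorted(int(p) for p in rng.integers(0, 20_000, size=n))
            profile = compute_density(make_tfbs("chr1", positions), BP)
            oracle_dens = brute_force_density(
                positions, profile.grid_start, len(profile.values), SIGMA
            )
            expected = [
                profile.grid_start + i for i in brute_force_maxima(oracle_dens)
            ]
            got = call_summits(profile)
            assert len(got) == len(expected)
            assert all(abs(a - b) <= 1 for a, b in zip(got, expected))


class TestContribution:
    def test_site_at_summit_included(self):
        (site,) = make_tfbs("chr1", [5000])
        assert assign_contributing_tfbs(5000, [site], BP) == (site,)

    def test_600bp_site_included_700bp_excluded(self):
        near, far = make_tfbs("chr1", [5600, 5700])
        assert kernel(600) == pytest.approx(0.1353, abs=1e-4)
        assert kernel(700) == pytest.approx(0.0657, abs=1e-4)
        contrib = assign_contributing_tfbs(5000, [near, far], BP)
        assert contrib == (near,)

    @settings(max_examples=200, derandomize=True)
    @given(distance=st.integers(min_value=0, max_value=2000))
    def test_membership_equals_closed_form_distance_test(self, distance):
        summit = 100_000
        (site,) = make_tfbs("chr1", [summit + distance])
        analytic = abs(site.midpoint - summit) < SIGMA * math.sqrt(2 * math.log(10.0))
        try:
            member = site in assign_contributing_tfbs(summit, [site], BP)
        except RuntimeError:
            member = False
        assert member == analytic


class TestWindowAndScores:
    def test_lone_contributor_at_summit_gives_pad_window(self):
        window = compute_window(5000, make_tfbs("chr1", [5000]), BP)
        assert window == (4850, 5150)

    def test_window_halfwidth_is_maxdist_plus_pad(self):
        contributors = make_tfbs("chr1", [5000, 5100, 5400])
        assert compute_window(5000, contributors, BP) == (4450, 5550)
        assert compute_window(5000, make_tfbs("chr1", [5050]), BP) == (4800, 5200)

    def test_empty_contributors_is_error(self):
        with pytest.raises(ValueError):
            compute_window(5000, [], BP)
        with pytest.raises(ValueError):
            compute_tc([])

    def test_tc_counts_distinct_tfs(self):
        assert compute_tc(make_tfbs("chr1", [100, 200, 300], ["A", "B", "C"])) == 3
        assert compute_tc(make_tfbs("chr1", [100, 200, 300], ["A", "A", "A"])) == 1
        assert compute_tc(make_tfbs("chr1", [100, 200, 300], ["A", "A", "B"])) == 2

    def test_sc_is_mean_of_overlapping_peak_scores(self):
        peaks = [
            AccessibilityPeak("chr1", 900, 1100, 10.0),
            AccessibilityPeak("chr1", 1500, 1600, 20.0),
        ]
        assert compute_sc((1000, 2000), peaks) == pytest.approx(15.0)

    def test_sc_zero_without_overlap(self):
        assert compute_sc((1000, 2000), []) == 0.0

    def test_half_open_adjacency_is_not_overlap(self):
        peaks = [AccessibilityPeak("chr1", 800, 1000, 99.0)]
        assert compute_sc((1000, 2000), peaks) == 0.0

    @settings(max_examples=100, derandomize=True)
    @given(
        offsets=st.lists(
            st.integers(min_value=-600, max_value=600), min_size=1, max_size=20
        )
    )
    def test_window_contains_all_contributors_with_pad(self, offsets):
        summit = 50_000
        contributors = make_tfbs("chr1", sorted(set(summit + o for o in offsets)))
        ws, we = compute_window(summit, contributors, BP)
        maxdist = max(abs(t.midpoint - summit) for t in contributors)
        assert (we - ws) == 2 * (maxdist + BP.window_pad)
        assert all(ws <= t.midpoint < we for t in contributors)


class TestIdentify:
    def test_single_site_composition(self):
        tfbs = make_tfbs("chr1", [1000], ["A"])
        peaks = [AccessibilityPeak("chr1", 900, 1200, 8.0)]
        (tfcr,) = identify_tfcrs(tfbs, peaks, TfcrParams())
        assert tfcr.summit == 1000
        assert (tfcr.window_start, tfcr.window_end) == (850, 1150)
        assert tfcr.tc == 1 and tfcr.sc == 8.0

    def test_close_pair_merges_with_tc2_and_pad_window(self):
        tfbs = make_tfbs("chr1", [1000, 1200], ["A", "B"])
        (tfcr,) = identify_tfcrs(tfbs, [], BP)
        assert tfcr.summit == 1100
        assert (tfcr.window_start, tfcr.window_end) == (850, 1350)
        assert tfcr.tc == 2

    def test_two_distant_clusters_give_two_tfcrs_with_local_tc(self):
        cluster_a = make_tfbs("chr1", [10_000 + o for o in (-60, -30, 0, 30, 60)],
                              tf_names=list("ABCDE"))
        cluster_b = make_tfbs("chr1", [60_000 + o for o in (-40, 0, 40)],
                              tf_names=list("ABC"))
        tfcrs = identify_tfcrs(cluster_a + cluster_b, [], TfcrParams())
        assert len(tfcrs) == 2
        assert tfcrs[0].tc == 5 and tfcrs[1].tc == 3

    def test_affine_equivariance_under_coordinate_doubling(self):
        rng = np.random.default_rng(11)
        positions = sorted(int(p) for p in rng.integers(10_000, 40_000, size=30))
        base = identify_tfcrs(make_tfbs("chr1", positions), [], BP)
        doubled = identify_tfcrs(
            make_tfbs("chr1", [2 * p for p in positions]),
            [],
            TfcrParams(sigma=2 * SIGMA, grid_step=2),
        )
        assert len(base) == len(doubled)
        for a, b in zip(base, doubled):
            assert abs(b.summit - 2 * a.summit) <= 2

    def test_identify_is_deterministic(self, tmp_path):
        rng = np.random.default_rng(5)
        positions = sorted(int(p) for p in rng.integers(0, 100_000, size=200))
        tfbs = make_tfbs("chr1", positions)
        peaks = [AccessibilityPeak("chr1", 0, 100_000, 3.0)]
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        gio.write_tfcr_table(identify_tfcrs(tfbs, peaks, TfcrParams()), a)
        gio.write_tfcr_table(identify_tfcrs(tfbs, peaks, TfcrParams()), b)
        assert a.read_bytes() == b.read_bytes()

    def test_no_tfbs_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert identify_tfcrs([], [], TfcrParams()) == []

    def test_peaks_filtered_by_condition(self):
        tfbs = make_tfbs("chr1", [1000])
        peaks = [
            AccessibilityPeak("chr1", 900, 1200, 8.0, condition="tumor"),
            AccessibilityPeak("chr1", 900, 1200, 50.0, source="DNase",
                              condition="normal"),
        ]
        (tfcr,) = identify_tfcrs(tfbs, peaks, TfcrParams(), condition="tumor")
        assert tfcr.sc == 8.0
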