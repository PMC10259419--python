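"""Cyclic peak detection, pairing and orientation-map tests.

The peak finder is checked against an exhaustive brute-force oracle
(explicit cyclic walk to the neighboring higher ground for prominences),
and the pairing step against enumeration of all admissible pairings.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scatterfiber import (
    AzimuthalProfile,
    FiberPopulation,
    build_phantom,
    find_peaks_cyclic,
    pair_peaks_to_orientations,
    peak_distance,
    render_sli_stack,
    sli_forward_profile,
)
from scatterfiber.peak_analysis import PeakSet, analyze_profile_map
from scatterfiber.profile_extraction import angular_stack_to_profiles


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the implementation under test)
# ---------------------------------------------------------------------------

def oracle_cyclic_peaks(values):
    """All cyclic local maxima (plateau-aware) with exact prominences.

    Returns a list of (representative_bin, prominence).  A plateau's
    representative is its left-middle bin.  Prominence: walk left and right
    from the peak until a strictly higher sample (or a full circle), track
    the minimum on each walk, and take height minus the higher minimum.
    """
    values = list(values)
    n = len(values)
    if len(set(values)) == 1:
        return []
    peaks = []
    for i in range(n):
        v = values[i]
        if values[(i - 1) % n] == v:
            continue  # not the leftmost bin of its plateau
        # plateau extent to the right
        j = i
        while values[(j + 1) % n] == v:
            j += 1
        if values[(i - 1) % n] < v and values[(j + 1) % n] < v:
            rep = (i + (j - i) // 2) % n
            # prominence by explicit cyclic walk
            mins = []
            for step in (-1, 1):
                m = v
                k = rep
                for _ in range(n):
                    k = (k + step) % n
                    if values[k] > v:
                        break
                    m = min(m, values[k])
                mins.append(m)
            peaks.append((rep, v - max(mins)))
    return peaks


def oracle_best_pairing(positions, tol=35.0):
    """Best pairing by exhaustive enumeration over all pair subsets."""
    def sep(a, b):
        d = abs(a - b) % 360.0
        return min(d, 360.0 - d)

    idx = range(len(positions))
    admissible = [(i, j) for i, j in itertools.combinations(idx, 2)
                  if 180.0 - sep(positions[i], positions[j]) <= tol]
    best = []
    best_key = (-1, 0.0)
    for r in range(len(admissible) + 1):
        for combo in itertools.combinations(admissible, r):
            used = [k for p in combo for k in p]
            if len(used) != len(set(used)):
                continue
            dev = sum(180.0 - sep(positions[i], positions[j]) for i, j in combo)
            key = (len(combo), -dev)
            if key > best_key:
                best_key, best = key, list(combo)
    return best


def mids(positions, pairing):
    out = set()
    for i, j in pairing:
        a, b = positions[i], positions[j]
        span = (b - a) % 360.0
        if span > 180.0:
            a, b = b, a
            span = 360.0 - span
        out.add(round(((a + span / 2.0) % 360.0) % 180.0, 6))
    return out


# ---------------------------------------------------------------------------
# find_peaks_cyclic
# ---------------------------------------------------------------------------

class TestFindPeaksCyclic:
    def test_two_isolated_spikes(self):
        values = np.ones(24)
        values[2] = 5.0   # 30 deg
        values[14] = 5.0  # 210 deg
        peaks = find_peaks_cyclic(AzimuthalProfile.from_values(values))
        assert np.allclose(sorted(peaks.positions_deg), [30.0, 210.0])
        assert np.allclose(peaks.prominences, [4.0, 4.0])
        assert peaks.profile_amplitude == 4.0
        # spike of height 4 over baseline 1, half-prominence crossings
        # interpolate halfway to the neighbours: one bin width total
        assert np.allclose(peaks.widths_deg, [15.0, 15.0])

    def test_flat_profile_has_no_peaks(self):
        peaks = find_peaks_cyclic(AzimuthalProfile.from_values(np.full(24, 3.0)))
        assert len(peaks) == 0

    def test_prominence_threshold_is_relative(self):
        values = np.ones(24)
        values[2] = 5.0
        values[14] = 5.0
        values[8] = 1.2  # bump prominence 0.2 < 0.08 * 4 = 0.32
        peaks = find_peaks_cyclic(AzimuthalProfile.from_values(values))
        assert np.allclose(sorted(peaks.positions_deg), [30.0, 210.0])
        # scaling the profile must not change the decision
        peaks_scaled = find_peaks_cyclic(
            AzimuthalProfile.from_values(values * 123.0))
        assert np.allclose(peaks_scaled.positions_deg, peaks.positions_deg)

    def test_peak_wrapping_the_cyclic_boundary(self):
        values = np.ones(24)
        values[23] = 3.0
        values[0] = 5.0
        values[1] = 3.0
        peaks = find_peaks_cyclic(AzimuthalProfile.from_values(values))
        assert len(peaks) == 1
        assert np.isclose(peaks.positions_deg[0] % 360.0, 0.0)

    def test_needs_eight_valid_bins(self):
        with pytest.raises(ValueError):
            find_peaks_cyclic(AzimuthalProfile.from_values(np.ones(6)))

    def test_invalid_bins_interrupt_peaks(self):
        values = np.ones(24)
        values[2] = 5.0
        values[14] = 5.0
        valid = np.ones(24, dtype=bool)
        valid[13:16] = False  # kill the 210-deg peak's support
        peaks = find_peaks_cyclic(AzimuthalProfile.from_values(values, valid))
        assert np.allclose(peaks.positions_deg, [30.0])

    @given(st.data())
    @settings(derandomize=True, max_examples=150, deadline=None)
    def test_matches_brute_force_oracle(self, data):
        """Positions (±1 bin) and prominences (exact) equal the oracle's."""
        n = data.draw(st.integers(min_value=8, max_value=48))
        values = np.array(data.draw(st.lists(
            st.integers(min_value=0, max_value=6), min_size=n, max_size=n)),
            dtype=float)
        peaks = find_peaks_cyclic(AzimuthalProfile.from_values(values),
                                  prominence_frac=0.08)
        amplitude = values.max() - values.min()
        expected = [(p, pr) for p, pr in oracle_cyclic_peaks(values)
                    if pr > 0.08 * amplitude]
        assert len(peaks) == len(expected)
        width = 360.0 / n
        got = sorted(zip(peaks.positions_deg, peaks.prominences))
        exp = sorted((b * width, pr) for b, pr in expected)

        def cyc(a, b):
            d = abs(a - b) % 360.0
            return min(d, 360.0 - d)

        # refinement can wrap a boundary peak, so the two circularly sorted
        # lists may differ by a rotation; find the rotation that aligns them
        m = len(got)
        aligned = m == 0 or any(
            all(cyc(got[(i + rot) % m][0], exp[i][0]) <= width
                and got[(i + rot) % m][1] == pytest.approx(exp[i][1], abs=1e-12)
                for i in range(m))
            for rot in range(m))
        assert aligned

    @given(st.integers(min_value=0, max_value=23),
           st.floats(min_value=0.01, max_value=1000.0))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_shift_and_scale_equivariance(self, shift, scale):
        base = sli_forward_profile([FiberPopulation(70.0)], n_bins=24,
                                   baseline=0.1).values
        ref = find_peaks_cyclic(AzimuthalProfile.from_values(base))
        moved = find_peaks_cyclic(
            AzimuthalProfile.from_values(np.roll(base, shift) * scale))
        expected = np.sort((ref.positions_deg + shift * 15.0) % 360.0)
        assert np.allclose(np.sort(moved.positions_deg), expected, atol=1e-9)
        assert np.allclose(np.sort(moved.prominences),
                           np.sort(ref.prominences) * scale)
        assert peak_distance(moved) == pytest.approx(peak_distance(ref))


# ---------------------------------------------------------------------------
# pair_peaks_to_orientations / peak_distance
# ---------------------------------------------------------------------------

def _peakset(positions):
    positions = np.asarray(positions, dtype=float)
    return PeakSet(positions, np.ones_like(positions),
                   np.full_like(positions, 30.0), 1.0)


class TestPairing:
    @pytest.mark.parametrize("positions, expected", [
        ([0.0, 180.0], {90.0}),
        ([30.0, 210.0], {120.0}),
        ([30.0, 90.0, 210.0, 270.0], {120.0, 0.0}),
        ([10.0, 175.0], {92.5}),
        ([0.0, 120.0, 240.0], set()),   # no pair within 180 +/- 35
        ([45.0], set()),
    ])
    def test_worked_examples(self, positions, expected):
        got = pair_peaks_to_orientations(_peakset(positions))
        assert {round(o, 6) for o in got} == expected

    def test_fod_mode_rotates_by_90(self):
        got = pair_peaks_to_orientations(_peakset([30.0, 210.0]), mode="fod")
        assert got == [pytest.approx(30.0)]

    @given(st.lists(st.floats(min_value=0.0, max_value=359.99),
                    min_size=2, max_size=6))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_matches_exhaustive_pairing_oracle(self, positions):
        got = pair_peaks_to_orientations(_peakset(positions))
        best = oracle_best_pairing(positions)
        assert len(got) == min(len(best), 3)
        if len(best) <= 3:
            assert {round(o, 6) for o in got} == mids(positions, best)

    def test_orientation_count_capped_at_three(self):
        positions = [0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0]
        got = pair_peaks_to_orientations(_peakset(positions))
        assert len(got) == 3


class TestPeakDistance:
    @pytest.mark.parametrize("positions, expected", [
        ([45.0], 0.0),
        ([30.0, 210.0], 180.0),
        ([40.0, 180.0], 140.0),
    ])
    def test_defined_cases(self, positions, expected):
        assert peak_distance(_peakset(positions)) == pytest.approx(expected)

    @pytest.mark.parametrize("positions", [[], [10.0, 90.0, 170.0]])
    def test_undefined_cases(self, positions):
        assert np.isnan(peak_distance(_peakset(positions)))


# ---------------------------------------------------------------------------
# analyze_profile_map (end-to-end on a noiseless phantom)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def analyzed():
    layout = [
        {"name": "uni", "rect": (2, 10, 2, 10),
         "populations": [{"phi": 70.0}]},
        {"name": "cross", "rect": (2, 10, 10, 18),
         "populations": [{"phi": 40.0}, {"phi": 100.0}]},
    ]
    phantom = build_phantom(layout, (12, 20), seed=0)
    stack = render_sli_stack(phantom, noise_model="none", baseline=0.1)
    omap, params = analyze_profile_map(angular_stack_to_profiles(stack))
    return phantom, omap, params


class TestAnalyzeProfileMap:
    def test_unidirectional_region(self, analyzed):
        phantom, omap, _ = analyzed
        sel = phantom.region_labels == 1
        assert np.all(omap.n_orientations[sel] == 1)
        assert np.allclose(omap.orientations_deg[sel, 0], 70.0, atol=2.4)
        assert np.allclose(omap.peak_distance_deg[sel], 180.0, atol=2.0)

    def test_crossing_region(self, analyzed):
        phantom, omap, _ = analyzed
        sel = phantom.region_labels == 2
        assert np.all(omap.n_orientations[sel] == 2)
        got = np.sort(omap.orientations_deg[sel][:, :2], axis=1)
        assert np.allclose(got[:, 0], 40.0, atol=2.4)
        assert np.allclose(got[:, 1], 100.0, atol=2.4)

    def test_background_pixels(self, analyzed):
        phantom, omap, params = analyzed
        bg = ~phantom.tissue_mask
        assert np.all(omap.n_peaks[bg] == 0)
        assert np.all(omap.n_orientations[bg] == 0)
        assert np.allclose(params.average[bg], 0.1)

    def test_parameter_map_ordering(self, analyzed):
        _, _, params = analyzed
        assert np.all(params.minimum <= params.average + 1e-12)
        assert np.all(params.average <= params.maximum + 1e-12)
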