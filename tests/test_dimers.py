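"""Per-dimer occupancy profiles, footprint classification, identity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from satfrag import (
    DimerProfile,
    OccupancyTrack,
    classify,
    occupancy_fold_range,
    pairwise_identity,
    per_dimer_occupancy,
)


def track(values):
    return OccupancyTrack(ref_name="t", coverage=np.asarray(values, float),
                          n_fragments=0)


UNITS2 = [(0, 340), (340, 680)]


class TestPerDimer:
    def test_flat_track_equal_units_centered_centroid(self):
        profiles = per_dimer_occupancy(track(np.ones(680)), UNITS2)
        assert profiles[0].occupancy == profiles[1].occupancy == 1.0
        # flat coverage centroid sits at the unit midpoint (+-0.5 for
        # the discrete grid), the default reference point
        for p in profiles:
            assert abs(p.centroid_offset) <= 0.5

    def test_coverage_confined_to_monomer_a(self):
        cov = np.zeros(680)
        cov[:170] = 2.0
        p = per_dimer_occupancy(track(cov), UNITS2)[0]
        assert p.monomer_b_occ == 0.0
        assert p.monomer_a_occ == 2.0
        assert p.occupancy == pytest.approx(1.0)

    def test_occupancy_is_mean_of_monomers(self, rng):
        cov = rng.random(680)
        for p in per_dimer_occupancy(track(cov), UNITS2):
            assert p.occupancy == pytest.approx(
                (p.monomer_a_occ + p.monomer_b_occ) / 2
            )

    def test_interval_outside_track_rejected(self):
        with pytest.raises(ValueError):
            per_dimer_occupancy(track(np.ones(100)), [(0, 340)])

    def test_centroid_relative_to_box_start(self):
        cov = np.zeros(340)
        cov[100:110] = 1.0  # centroid at 104.5
        p = per_dimer_occupancy(track(cov), [(0, 340)], box_starts=[60])[0]
        assert p.centroid_offset == pytest.approx(44.5)


class TestFoldRange:
    def test_equal_units(self):
        ps = [DimerProfile(i, 2.0, 2.0, 2.0, 0.0) for i in range(3)]
        assert occupancy_fold_range(ps) == 1.0

    def test_arithmetic(self):
        ps = [DimerProfile(i, v, v, v, 0.0) for i, v in enumerate((1.0, 10.0, 50.0))]
        assert occupancy_fold_range(ps) == 50.0

    def test_zero_units_get_pseudocount(self):
        ps = [DimerProfile(0, 0.0, 0, 0, 0.0), DimerProfile(1, 5.0, 5, 5, 0.0)]
        assert occupancy_fold_range(ps, pseudocount=1.0) == 5.0

    def test_all_zero_rejected(self):
        ps = [DimerProfile(i, 0.0, 0, 0, 0.0) for i in range(2)]
        with pytest.raises(ValueError):
            occupancy_fold_range(ps)

    def test_single_unit_rejected(self):
        with pytest.raises(ValueError):
            occupancy_fold_range([DimerProfile(0, 1.0, 1, 1, 0.0)])


class TestClassify:
    def test_centered_symmetric(self):
        p = classify(DimerProfile(0, 1.0, 1.0, 1.0, 0.0))
        assert (p.orientation, p.symmetry) == ("centered", "symmetric")

    def test_three_to_one_monomer_ratio_is_asymmetric_a(self):
        p = classify(DimerProfile(0, 2.0, 3.0, 1.0, 0.0))
        assert p.symmetry == "asymmetric_a"

    def test_mirror_flips_orientation(self):
        up = classify(DimerProfile(0, 1.0, 1.0, 1.0, -40.0))
        down = classify(DimerProfile(0, 1.0, 1.0, 1.0, 40.0))
        assert (up.orientation, down.orientation) == ("upstream", "downstream")

    def test_boundary_inside_tolerance_is_centered(self):
        assert classify(DimerProfile(0, 1, 1, 1, 25.0)).orientation == "centered"

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(1e-6, 1e6), st.floats(0.1, 10), st.floats(0.1, 10),
           st.floats(-170, 170))
    def test_scale_invariance(self, c, a, b, off):
        from hypothesis import assume

        # stay off the decision boundaries, where float rescaling could
        # legitimately flip the label
        assume(abs(a / b - 1.5) > 1e-6 and abs(b / a - 1.5) > 1e-6)
        assume(abs(abs(off) - 25.0) > 1e-6)
        base = classify(DimerProfile(0, (a + b) / 2, a, b, off))
        scaled = classify(DimerProfile(0, c * (a + b) / 2, c * a, c * b, off))
        assert (base.orientation, base.symmetry) == (scaled.orientation, scaled.symmetry)


class TestPairwiseIdentity:
    def test_identical_units_100(self, unit340):
        m = pairwise_identity([unit340, unit340])
        np.testing.assert_allclose(m, 100.0)

    def test_34_differences_is_90_percent(self, unit340):
        seq = unit340.sequence
        swap = {"A": "C", "C": "G", "G": "T", "T": "A"}
        other = list(seq)
        for pos in range(0, 340, 10):  # 34 positions
            other[pos] = swap[other[pos]]
        m = pairwise_identity([seq, "".join(other)])
        assert m[0, 1] == pytest.approx(90.0)
        assert m[1, 0] == m[0, 1]

    def test_equals_direct_hamming_count(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 50)) for _ in range(4)]
        m = pairwise_identity(seqs)
        for i in range(4):
            for j in range(4):
                ham = sum(a != b for a, b in zip(seqs[i], seqs[j]))
                assert m[i, j] == pytest.approx(100.0 * (1 - ham / 50))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity(["ACGT", "ACGTA"])


def test_footprint_classification_recovers_truth_at_50x(rng):
    """Symmetric (whole-dimer) vs one-monomer footprints simulated at 50x
    mean coverage with Poisson noise are classified at >=95% accuracy."""
    n_units, period = 40, 340
    truth = rng.choice(["symmetric", "asymmetric_a", "asymmetric_b"], n_units)
    cov = np.zeros(n_units * period)
    for i, label in enumerate(truth):
        lo = i * period
        if label == "symmetric":
            lam = np.full(period, 50.0)
        elif label == "asymmetric_a":
            lam = np.r_[np.full(period // 2, 50.0), np.zeros(period - period // 2)]
        else:
            lam = np.r_[np.zeros(period // 2), np.full(period - period // 2, 50.0)]
        cov[lo : lo + period] = rng.poisson(lam)
    units = [(i * period, (i + 1) * period) for i in range(n_units)]
    profiles = [classify(p) for p in per_dimer_occupancy(track(cov), units)]
    acc = np.mean([p.symmetry == t for p, t in zip(profiles, truth)])
    assert acc >= 0.95


def test_simulated_two_unit_array_recovers_50_fold_range(unit340):
    """A 1:50 truth occupancy contrast is recovered within Poisson
    sampling error from 10^4 fragments."""
    from collections import Counter

    from satfrag import FragmentModel, SatelliteArray, simulate_fragments

    base = [unit340, unit340]
    arr = SatelliteArray(
        name="two", units=list(base),
        truth_occupancy=np.array([1.0, 50.0]),
        truth_fraction_weights=np.tile([0.25] * 4, (2, 1)),
    )
    frags = simulate_fragments(arr, FragmentModel(), 10_000, seed=31, jitter_sd=20.0)
    counts = Counter(f.unit_index for f in frags)
    profiles = [
        DimerProfile(i, float(counts[i]), 0.0, 0.0, 0.0) for i in range(2)
    ]
    fold = occupancy_fold_range(profiles)
    # E[low] ~ 196; 3 sigma on the ratio is ~ +-11
    assert 38 < fold < 64
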