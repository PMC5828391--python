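"""Simulator: dimer construction, divergence, truth labels, read emission."""

import numpy as np
import pytest
from scipy import stats

from satfrag import (
    CENP_B_BOX,
    DimerUnit,
    FragmentModel,
    SatelliteArray,
    assign_truth_occupancy,
    build_dimer,
    emit_fastq,
    evolve_array,
    scan_motifs,
    simulate_fragments,
)
from satfrag._seq import revcomp
from satfrag.synthetic import WEIGHTS_PERFECT_BOX, random_genome


class TestBuildDimer:
    def test_340_unit_has_single_perfect_box_at_offset(self, rng):
        a = "".join(rng.choice(list("ACGT"), 170))
        b = "".join(rng.choice(list("ACGT"), 170))
        unit = build_dimer(a, b, 60)
        assert len(unit) == 340
        assert unit.sequence[60:75] == CENP_B_BOX
        hits = scan_motifs(unit.sequence)
        assert [h.start for h in hits] == [60]

    def test_342_unit_from_unequal_monomers(self, rng):
        a = "".join(rng.choice(list("ACGT"), 170))
        b = "".join(rng.choice(list("ACGT"), 172))
        assert len(build_dimer(a, b, 60)) == 342

    @pytest.mark.parametrize("offset", [330, -1, 400])
    def test_box_offset_out_of_range(self, offset):
        with pytest.raises(ValueError):
            build_dimer("A" * 170, "C" * 170, offset)

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            build_dimer("N" * 170, "A" * 170, 60)

    def test_bad_total_length_rejected(self):
        with pytest.raises(ValueError):
            build_dimer("A" * 100, "C" * 100, 60)


class TestEvolveArray:
    def test_zero_rate_gives_identical_units_and_perfect_boxes(self, unit340):
        arr = evolve_array(unit340, 10, 0.0, seed=5)
        assert len({u.sequence for u in arr.units}) == 1
        assert np.all(arr.box_scores() == 1.0)

    def test_rate_out_of_range(self, unit340):
        with pytest.raises(ValueError):
            evolve_array(unit340, 5, 0.3)

    def test_high_divergence_kills_boxes_at_binomial_rate(self, unit340):
        # at per-base rate 0.25 the box carries Binomial(15, 0.25)
        # mismatches; score hits 0 when >=4 of them occur
        p_dead = 1.0 - stats.binom.cdf(3, 15, 0.25)
        n = 500
        arr = evolve_array(unit340, n, 0.25, seed=1)
        frac = float((arr.box_scores() == 0.0).mean())
        sd = np.sqrt(p_dead * (1 - p_dead) / n)
        assert abs(frac - p_dead) < 3 * sd

    def test_determinism(self, unit340):
        a1 = evolve_array(unit340, 5, 0.1, seed=7)
        a2 = evolve_array(unit340, 5, 0.1, seed=7)
        assert [u.sequence for u in a1.units] == [u.sequence for u in a2.units]


class TestTruthAssignment:
    def test_identity_link_no_noise_equals_box_score(self, unit340):
        arr = evolve_array(unit340, 20, 0.1, seed=11)
        arr = assign_truth_occupancy(arr, link=lambda s: s + 1e-9, noise_sd=0.0)
        np.testing.assert_allclose(arr.truth_occupancy, arr.box_scores() + 1e-9)

    def test_perfect_box_gets_high_salt_weight(self, occupied_array):
        np.testing.assert_allclose(
            occupied_array.truth_fraction_weights,
            np.tile(WEIGHTS_PERFECT_BOX, (5, 1)),
        )

    def test_weights_always_sum_to_one(self, unit340):
        arr = evolve_array(unit340, 30, 0.2, seed=13)
        arr = assign_truth_occupancy(arr, noise_sd=0.5, seed=13)
        np.testing.assert_allclose(arr.truth_fraction_weights.sum(axis=1), 1.0)

    def test_non_monotone_link_rejected(self, occupied_array):
        with pytest.raises(ValueError):
            assign_truth_occupancy(occupied_array, link=lambda s: 1.0 - s + 0.1)

    def test_negative_link_rejected(self, occupied_array):
        with pytest.raises(ValueError):
            assign_truth_occupancy(occupied_array, link=lambda s: s - 0.5)


class TestSimulateFragments:
    def test_dimeric_only_zero_sd_gives_exact_period_lengths(
        self, occupied_array, dimeric_model
    ):
        frags = simulate_fragments(occupied_array, dimeric_model, 50, seed=1)
        assert {f.length for f in frags} == {340}

    def test_counts_proportional_to_occupancy(self, unit340):
        # two units at 1:50 truth; expected low-unit count 1/51 of total
        arr = evolve_array(unit340, 2, 0.0, seed=1)
        arr = SatelliteArray(
            name=arr.name,
            units=arr.units,
            truth_occupancy=np.array([1.0, 50.0]),
            truth_fraction_weights=np.tile([0.25] * 4, (2, 1)),
        )
        n = 10_200
        frags = simulate_fragments(arr, FragmentModel(), n, seed=2)
        n_low = sum(f.unit_index == 0 for f in frags)
        p = 1 / 51
        sd = np.sqrt(n * p * (1 - p))
        assert abs(n_low - n * p) < 4 * sd

    def test_fraction_labels_follow_unit_weights(self, occupied_array):
        frags = simulate_fragments(occupied_array, FragmentModel(), 4000, seed=3)
        share = sum(f.fraction in ("high_salt", "pellet") for f in frags) / 4000
        assert 0.78 < share < 0.88  # truth 0.83 for perfect boxes

    def test_all_zero_occupancy_rejected(self, unit340):
        arr = evolve_array(unit340, 2, 0.0, seed=1)
        arr = SatelliteArray(
            name="z", units=arr.units,
            truth_occupancy=np.zeros(2),
            truth_fraction_weights=np.tile([0.25] * 4, (2, 1)),
        )
        with pytest.raises(ValueError):
            simulate_fragments(arr, FragmentModel(), 10)

    def test_missing_truth_rejected(self, homogeneous_array):
        with pytest.raises(ValueError):
            simulate_fragments(homogeneous_array, FragmentModel(), 10)


class TestEmitFastq:
    def test_pair_geometry_and_count_conservation(self, occupied_array, tmp_path):
        frags = simulate_fragments(
            occupied_array,
            FragmentModel(regime_weights=(0.0, 0.0, 1.0),
                          regime_length_sds=(1, 1, 0)),
            20, seed=4,
        )
        r1, r2, tr = tmp_path / "r1.fq", tmp_path / "r2.fq", tmp_path / "t.tsv"
        n = emit_fastq(frags, r1, r2, tr,
                       spike_in=(random_genome(2000, seed=1), 1000), seed=5)
        assert n == 20 + 1000
        lines = r1.read_text().splitlines()
        assert len(lines) == 4 * n
        assert len(tr.read_text().splitlines()) == n + 1  # header
        # 340-nt fragment, 250-nt reads: R1 suffix and revcomp(R2) prefix
        # share 2*250 - 340 = 160 nt
        seq1 = lines[1]
        seq2 = r2.read_text().splitlines()[1]
        assert len(seq1) == len(seq2) == 250
        assert seq1[-160:] == revcomp(seq2)[:160]

    def test_short_fragment_reads_truncate(self, tmp_path):
        from satfrag import SimulatedFragment

        frag = SimulatedFragment(id="f", sequence="ACGT" * 25, unit_index=0,
                                 fraction="no_salt", start=0)
        emit_fastq([frag], tmp_path / "1.fq", tmp_path / "2.fq",
                   tmp_path / "t.tsv", read_length=250)
        seq1 = (tmp_path / "1.fq").read_text().splitlines()[1]
        seq2 = (tmp_path / "2.fq").read_text().splitlines()[1]
        assert len(seq1) == len(seq2) == 100
        assert seq2 == revcomp(seq1)

    def test_seed_determinism_byte_identical(self, occupied_array, tmp_path):
        frags = simulate_fragments(occupied_array, FragmentModel(), 50, seed=6)
        outs = []
        for tag in ("a", "b"):
            r1 = tmp_path / f"{tag}.1.fq"
            emit_fastq(frags, r1, tmp_path / f"{tag}.2.fq",
                       tmp_path / f"{tag}.tsv", per_base_error=0.01,
                       spike_in=(random_genome(1000, seed=2), 30), seed=9)
            outs.append(r1.read_bytes())
        assert outs[0] == outs[1]

    def test_read_length_floor(self, tmp_path):
        with pytest.raises(ValueError):
            emit_fastq([], tmp_path / "1.fq", tmp_path / "2.fq",
                       tmp_path / "t.tsv", read_length=10)


def test_zero_divergence_array_has_one_box_per_period(homogeneous_array):
    hits = scan_motifs(homogeneous_array.sequence)
    assert len(hits) == len(homogeneous_array.units)
    assert set(np.diff([h.start for h in hits])) == {homogeneous_array.period}
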