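"""Ground-truth alpha-satellite simulator.

Human centromeric alpha satellite is a ~171-bp AT-rich tandem repeat; the
functional, CENP-A-enriched arrays are built from 340-bp (SF1-like) or
342-bp (SF2-like) head-to-tail *dimeric* units carrying one CENP-B box
per dimer. This module builds such arrays with known per-unit divergence,
assigns each dimer a ground-truth CCAN occupancy tied (monotonically) to
the strength of its CENP-B box, partitions particles across salt
fractions, draws nuclease-protected fragments in three length regimes
(subnucleosomal ~100 bp, nucleosomal ~160-185 bp, dimeric ~340 bp), and
emits paired-end reads plus a truth table — so every downstream stage of
the pipeline can be tested against known answers without any external
data.

The mutation model is substitution-only (no indels): this keeps the dimer
period exact, so the period-folding used downstream stays well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from ._seq import BASES, check_dna, revcomp
from .motifs import CENP_B_BOX, motif_score

FRACTIONS = ("no_salt", "low_salt", "high_salt", "pellet")

#: Salt-fraction weights for a unit with a perfect CENP-B box: most of
#: its particles resist extraction until 500 mM NaCl (or stay in the
#: pellet), so the pooled high-salt + pellet share of a homogeneous array
#: exceeds 80%.
WEIGHTS_PERFECT_BOX = (0.02, 0.15, 0.68, 0.15)
#: Weights for a unit whose box has degenerated to score 0: particles are
#: less stable and partition toward the soluble low-salt fractions.
WEIGHTS_NO_BOX = (0.10, 0.40, 0.35, 0.15)

#: Default multiplicative occupancy range across the box-score scale.
#: score 0 -> 1x, score 1 -> 50x, log-linear in between, matching the
#: up-to-~50-fold spread in per-dimer enrichment seen on real arrays.
DEFAULT_LINK_FOLD = 50.0


def default_link(score: float) -> float:
    """Log-linear box-score -> relative occupancy link, range 1-50x."""
    return float(DEFAULT_LINK_FOLD**score)


@dataclass(frozen=True)
class DimerUnit:
    """One 340/342-nt head-to-tail dimeric repeat unit.

    ``cenpb_box_offset`` is the 0-based start of the 15-nt CENP-B box
    core within the unit; ``box_strand`` is its orientation.
    """

    sequence: str
    cenpb_box_offset: int
    box_strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.sequence) not in (340, 342):
            raise ValueError(
                f"dimer unit must be 340 or 342 nt, got {len(self.sequence)}"
            )
        if not 0 <= self.cenpb_box_offset <= len(self.sequence) - len(CENP_B_BOX):
            raise ValueError(
                f"box offset {self.cenpb_box_offset} out of range for "
                f"{len(self.sequence)}-nt unit"
            )
        if self.box_strand not in "+-":
            raise ValueError("box_strand must be '+' or '-'")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def box_site(self) -> str:
        """The 15-nt sequence at the box position, box-strand oriented."""
        site = self.sequence[
            self.cenpb_box_offset : self.cenpb_box_offset + len(CENP_B_BOX)
        ]
        return site if self.box_strand == "+" else revcomp(site)

    @property
    def box_score(self) -> float:
        """Identity of this unit's box site to the ancestral core."""
        return motif_score(self.box_site)


@dataclass
class SatelliteArray:
    """A tandem array of dimeric units with optional ground truth.

    Units are strictly head-to-tail with no spacers, so the array
    sequence is the concatenation of unit sequences and unit ``i``
    occupies ``[i*period, (i+1)*period)``.
    """

    name: str
    units: list[DimerUnit]
    divergence_rate: float = 0.0
    truth_occupancy: np.ndarray | None = None
    truth_fraction_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.units:
            raise ValueError("array needs at least one unit")
        periods = {len(u) for u in self.units}
        if len(periods) != 1:
            raise ValueError("all units in an array must share one period")
        if self.truth_occupancy is not None:
            occ = np.asarray(self.truth_occupancy, dtype=float)
            if occ.shape != (len(self.units),) or not np.all(np.isfinite(occ)) or occ.min() < 0:
                raise ValueError("truth_occupancy must be finite, >=0, one per unit")
            self.truth_occupancy = occ
        if self.truth_fraction_weights is not None:
            w = np.asarray(self.truth_fraction_weights, dtype=float)
            if w.shape != (len(self.units), len(FRACTIONS)):
                raise ValueError("truth_fraction_weights must be n_units x 4")
            if not np.allclose(w.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("each unit's fraction weights must sum to 1")
            self.truth_fraction_weights = w

    @property
    def period(self) -> int:
        return len(self.units[0])

    @property
    def sequence(self) -> str:
        return "".join(u.sequence for u in self.units)

    def __len__(self) -> int:
        return self.period * len(self.units)

    def unit_intervals(self) -> list[tuple[int, int]]:
        """Half-open [start, end) interval of each unit in array coords."""
        p = self.period
        return [(i * p, (i + 1) * p) for i in range(len(self.units))]

    def box_starts(self) -> list[int]:
        """Absolute start of each unit's CENP-B box in array coords."""
        p = self.period
        return [i * p + u.cenpb_box_offset for i, u in enumerate(self.units)]

    def box_scores(self) -> np.ndarray:
        return np.array([u.box_score for u in self.units])


@dataclass(frozen=True)
class FragmentModel:
    """Gaussian mixture over the three protected-fragment regimes.

    ``subnucleosomal`` (~100 bp) models partial particles released under
    untethered-nuclease conditions, ``nucleosomal`` (~160-185 bp) the
    major CCAN-protected peak, and ``dimeric`` (~340 bp) whole-dimer
    protection. Lengths are truncated to [25, 500] nt — below 25 nt the
    merge filter would drop them, and 500 nt brackets the observed ~100
    to 450 bp range.
    """

    regime_weights: tuple[float, float, float] = (0.2, 0.6, 0.2)
    regime_length_means: tuple[float, float, float] = (100.0, 172.0, 340.0)
    regime_length_sds: tuple[float, float, float] = (10.0, 8.0, 15.0)
    min_length: int = 25
    max_length: int = 500

    def __post_init__(self) -> None:
        w = np.asarray(self.regime_weights, float)
        if w.min() < 0 or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("regime weights must be >=0 and sum to 1")
        if min(self.regime_length_means) <= 0:
            raise ValueError("regime length means must be positive")


@dataclass(frozen=True)
class SimulatedFragment:
    """A protected fragment with its provenance."""

    id: str
    sequence: str
    unit_index: int  # -1 for background/spike fragments
    fraction: str
    start: int  # array coordinate of fragment start

    @property
    def length(self) -> int:
        return len(self.sequence)


def _write_box(seq: str, offset: int) -> str:
    return seq[:offset] + CENP_B_BOX + seq[offset + len(CENP_B_BOX) :]


def build_dimer(monomer_a: str, monomer_b: str, box_offset: int) -> DimerUnit:
    """Join two monomers head-to-tail and stamp a perfect CENP-B box.

    The monomer lengths must sum to 340 or 342 nt. The ancestral 15-nt
    box core is written into the concatenated unit at ``box_offset``
    (normally inside monomer A — the classic one-box-per-dimer layout).
    """
    monomer_a = check_dna(monomer_a, "monomer_a")
    monomer_b = check_dna(monomer_b, "monomer_b")
    seq = monomer_a + monomer_b
    if len(seq) not in (340, 342):
        raise ValueError(f"monomer lengths must sum to 340 or 342, got {len(seq)}")
    if not 0 <= box_offset <= len(seq) - len(CENP_B_BOX):
        raise ValueError(f"box offset {box_offset} out of range (unit {len(seq)} nt)")
    return DimerUnit(
        sequence=_write_box(seq, box_offset),
        cenpb_box_offset=box_offset,
        box_strand="+",
    )


def ancestral_dimer(period: int = 340, box_offset: int = 60, seed: int = 2018) -> DimerUnit:
    """A synthetic ancestral dimer: AT-rich random monomers plus one box.

    The monomer backbone is drawn once from a fixed-seed generator at
    60% A+T (alpha satellite is AT-rich); it is a synthetic stand-in for
    a real suprachromosomal-family consensus, adequate because every
    downstream statistic depends only on repeat geometry, box content and
    divergence, not on the particular backbone.
    """
    if period not in (340, 342):
        raise ValueError("period must be 340 or 342")
    rng = np.random.default_rng(seed)
    probs = [0.3, 0.2, 0.2, 0.3]  # A, C, G, T
    backbone = "".join(rng.choice(list(BASES), size=period, p=probs))
    half = period // 2
    return build_dimer(backbone[:half], backbone[half:], box_offset)


def evolve_array(
    unit: DimerUnit,
    n_units: int,
    divergence_rate: float,
    seed: int = 1,
    name: str = "array",
) -> SatelliteArray:
    """Expand an ancestral dimer into an array of independently mutated copies.

    Each copy is mutated per base with probability ``divergence_rate``
    (substitutions only, uniform over the three alternative bases), the
    neutral accumulation that degrades CENP-B boxes on ageing arrays.
    With per-base rate r the expected pairwise identity between two
    copies is (1-r)^2 + r^2/3 ~ 1 - 2r(1-r).
    """
    if not 0.0 <= divergence_rate <= 0.25:
        raise ValueError("divergence_rate must be in [0, 0.25]")
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    rng = np.random.default_rng(seed)
    base = np.frombuffer(unit.sequence.encode(), dtype=np.uint8)
    alts = {b: [o for o in b"ACGT" if o != b] for b in b"ACGT"}
    units = []
    for _ in range(n_units):
        seq = base.copy()
        hit = np.flatnonzero(rng.random(seq.size) < divergence_rate)
        for pos in hit:
            seq[pos] = rng.choice(alts[seq[pos]])
        units.append(
            DimerUnit(
                sequence=seq.tobytes().decode(),
                cenpb_box_offset=unit.cenpb_box_offset,
                box_strand=unit.box_strand,
            )
        )
    return SatelliteArray(name=name, units=units, divergence_rate=divergence_rate)


def assign_truth_occupancy(
    array: SatelliteArray,
    link: Callable[[float], float] = default_link,
    noise_sd: float = 0.0,
    seed: int = 1,
) -> SatelliteArray:
    """Attach ground-truth occupancy and salt-fraction weights per unit.

    Occupancy of unit i is ``link(box_score_i)`` times lognormal noise
    with the given log-scale sd; ``link`` must be monotone non-decreasing
    and positive on [0, 1] (strong boxes stabilise the CCAN particle, so
    occupancy rises with box score). Fraction weights interpolate
    linearly in box score between the degenerate-box and perfect-box
    presets, shifting mass toward high-salt/pellet as the box improves.
    """
    grid = np.linspace(0.0, 1.0, 5)
    vals = np.array([link(s) for s in grid], dtype=float)
    if np.any(vals <= 0) or np.any(np.diff(vals) < 0):
        raise ValueError("link must be positive and monotone non-decreasing on [0,1]")

    rng = np.random.default_rng(seed)
    scores = array.box_scores()
    occ = np.array([link(s) for s in scores])
    if noise_sd > 0:
        occ = occ * np.exp(rng.normal(0.0, noise_sd, size=occ.size))
    w0 = np.asarray(WEIGHTS_NO_BOX)
    w1 = np.asarray(WEIGHTS_PERFECT_BOX)
    weights = (1.0 - scores)[:, None] * w0 + scores[:, None] * w1
    return SatelliteArray(
        name=array.name,
        units=array.units,
        divergence_rate=array.divergence_rate,
        truth_occupancy=occ,
        truth_fraction_weights=weights,
    )


def _draw_lengths(model: FragmentModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Mixture lengths truncated to [min_length, max_length] by rejection."""
    means = np.asarray(model.regime_length_means)
    sds = np.asarray(model.regime_length_sds)
    regimes = rng.choice(3, size=n, p=model.regime_weights)
    lengths = rng.normal(means[regimes], sds[regimes])
    bad = (lengths < model.min_length) | (lengths > model.max_length)
    while bad.any():
        redo = regimes[bad]
        lengths[bad] = rng.normal(means[redo], sds[redo])
        bad = (lengths < model.min_length) | (lengths > model.max_length)
    return np.rint(lengths).astype(int)


def simulate_fragments(
    array: SatelliteArray,
    model: FragmentModel | None = None,
    n_fragments: int = 1000,
    seed: int = 1,
    jitter_sd: float = 40.0,
    id_prefix: str = "frag",
) -> list[SimulatedFragment]:
    """Draw protected fragments from an array with assigned occupancy.

    Fragments are allocated to units with probability proportional to
    ``truth_occupancy``, centred on the unit's CENP-B box (the anchor of
    the protected particle) with Gaussian positional jitter, lengths
    drawn from the regime mixture, and each
    fragment inherits a salt-fraction label drawn from its unit's
    categorical weights (solubility is a property of the particle, hence
    of the unit, not of the individual cut).
    """
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    if array.truth_occupancy is None or array.truth_fraction_weights is None:
        raise ValueError("array lacks ground truth; call assign_truth_occupancy first")
    occ = array.truth_occupancy
    if occ.sum() <= 0:
        raise ValueError("array has all-zero occupancy")

    rng = np.random.default_rng(seed)
    n_units = len(array.units)
    p = array.period
    total = len(array)
    seq = array.sequence

    unit_idx = rng.choice(n_units, size=n_fragments, p=occ / occ.sum())
    lengths = _draw_lengths(model or FragmentModel(), n_fragments, rng)
    anchors = np.array(
        [u.cenpb_box_offset + len(CENP_B_BOX) / 2 for u in array.units]
    )
    centers = unit_idx * p + anchors[unit_idx] + rng.normal(
        0.0, jitter_sd, size=n_fragments
    )
    starts = np.rint(centers - lengths / 2).astype(int)
    starts = np.clip(starts, 0, np.maximum(total - lengths, 0))

    frac_cum = np.cumsum(array.truth_fraction_weights, axis=1)
    u = rng.random(n_fragments)
    frac_idx = (u[:, None] > frac_cum[unit_idx]).sum(axis=1)

    out = []
    for i in range(n_fragments):
        s, l = int(starts[i]), int(lengths[i])
        out.append(
            SimulatedFragment(
                id=f"{id_prefix}_{i:06d}",
                sequence=seq[s : s + l],
                unit_index=int(unit_idx[i]),
                fraction=FRACTIONS[int(frac_idx[i])],
                start=s,
            )
        )
    return out


def simulate_background_fragments(
    array: SatelliteArray,
    model: FragmentModel | None = None,
    n_fragments: int = 1000,
    seed: int = 1,
    id_prefix: str = "bg",
) -> list[SimulatedFragment]:
    """Uniform, occupancy-blind fragments emulating a nonspecific IgG
    control: starts uniform over the array, salt fraction uniform."""
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    rng = np.random.default_rng(seed)
    seq = array.sequence
    total = len(array)
    lengths = _draw_lengths(model or FragmentModel(), n_fragments, rng)
    lengths = np.minimum(lengths, total)
    starts = rng.integers(0, np.maximum(total - lengths + 1, 1))
    frac_idx = rng.integers(0, len(FRACTIONS), size=n_fragments)
    return [
        SimulatedFragment(
            id=f"{id_prefix}_{i:06d}",
            sequence=seq[int(starts[i]) : int(starts[i]) + int(lengths[i])],
            unit_index=-1,
            fraction=FRACTIONS[int(frac_idx[i])],
            start=int(starts[i]),
        )
        for i in range(n_fragments)
    ]


# ---------------------------------------------------------------- FASTQ out

_Q_GOOD = chr(37 + 33)  # Phred 37
_Q_ERR = chr(11 + 33)  # Phred 11 at simulated sequencing errors


def _read_with_errors(
    seq: str, per_base_error: float, rng: np.random.Generator
) -> tuple[str, str]:
    qual = [_Q_GOOD] * len(seq)
    if per_base_error > 0:
        arr = list(seq)
        for pos in np.flatnonzero(rng.random(len(seq)) < per_base_error):
            arr[pos] = rng.choice([b for b in BASES if b != arr[pos]])
            qual[pos] = _Q_ERR
        seq = "".join(arr)
    return seq, "".join(qual)


def emit_fastq(
    fragments: Sequence[SimulatedFragment],
    r1_path: str | Path,
    r2_path: str | Path,
    truth_path: str | Path,
    read_length: int = 250,
    per_base_error: float = 0.0,
    spike_in: tuple[str, int] | None = None,
    seed: int = 1,
) -> int:
    """Write paired-end reads and a provenance table for the fragments.

    R1 is the first ``read_length`` nt of each fragment, R2 the reverse
    complement of the last ``read_length`` nt (both truncated at the
    fragment end), with flat Phred-37 qualities dropped to Phred 11 at
    simulated error positions. Spike-in reads — nucleosome-sized pieces
    of an exogenous calibration genome — are appended with ``spike_``
    names so callers can count them unambiguously. Returns the number of
    pairs written.
    """
    if read_length < 20:
        raise ValueError("read_length must be >= 20")
    rng = np.random.default_rng(seed)

    items: list[SimulatedFragment] = list(fragments)
    if spike_in is not None:
        genome, n_spike = spike_in
        genome = check_dna(genome, "spike-in genome")
        lengths = np.clip(
            np.rint(rng.normal(167, 15, size=n_spike)).astype(int), 50, len(genome)
        )
        starts = rng.integers(0, len(genome) - lengths + 1)
        for i in range(n_spike):
            s, l = int(starts[i]), int(lengths[i])
            items.append(
                SimulatedFragment(
                    id=f"spike_{i:06d}",
                    sequence=genome[s : s + l],
                    unit_index=-1,
                    fraction="spike",
                    start=s,
                )
            )

    with open(r1_path, "w") as f1, open(r2_path, "w") as f2, open(
        truth_path, "w"
    ) as ft:
        ft.write("fragment_id\tunit_index\tfraction\tlength\tstart\n")
        for frag in items:
            fwd = frag.sequence[:read_length]
            rev = revcomp(frag.sequence[-read_length:])
            s1, q1 = _read_with_errors(fwd, per_base_error, rng)
            s2, q2 = _read_with_errors(rev, per_base_error, rng)
            f1.write(f"@{frag.id}/1\n{s1}\n+\n{q1}\n")
            f2.write(f"@{frag.id}/2\n{s2}\n+\n{q2}\n")
            ft.write(
                f"{frag.id}\t{frag.unit_index}\t{frag.fraction}"
                f"\t{frag.length}\t{frag.start}\n"
            )
    return len(items)


def random_genome(length: int = 5000, seed: int = 99, gc: float = 0.41) -> str:
    """Uniform-composition random sequence usable as a spike-in genome."""
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(BASES), size=length, p=p))
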