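"""End-to-end placement of fragments on tandem-repeat references.

Mapping here is exhaustive, ungapped and end-to-end: a fragment is slid
over every start position of both strands of a reference and the
placement with the fewest mismatches wins (leftmost start, then plus
strand, on ties). That matches the no-clipping, no-indel contract used
for repeat references, and at desk scale (references of at most tens of
kb) the O(n*m) scan is fast and dependency-free.

Because tandem repeats make every placement ambiguous up to the repeat
period, occupancy over a repeat unit is computed by mapping to a
*triplicated* copy of the unit consensus and folding coverage back onto
one period (position p contributes to p mod period). The triplication
gives interior copies so fragments spanning a unit boundary still map
end-to-end; the folding makes the profile invariant to which of the
three copies the aligner happened to pick.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._seq import encode, revcomp, window_mismatches
from .merge import MergedFragment
from .synthetic import DimerUnit


@dataclass(frozen=True)
class RepeatHit:
    """Ungapped placement of one fragment on a reference."""

    fragment_id: str
    ref_name: str
    start: int  # 0-based
    end: int  # exclusive; end - start == fragment length
    strand: str
    n_mismatches: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class OccupancyTrack:
    """Per-base calibrated coverage over one reference."""

    ref_name: str
    coverage: np.ndarray  # float, length == reference length
    n_fragments: int
    calibration_factor: float = 1.0

    def __len__(self) -> int:
        return self.coverage.size


def align_end_to_end(
    fragment: MergedFragment | str,
    reference: str,
    ref_name: str = "ref",
    max_mismatch_frac: float = 0.1,
    fragment_id: str | None = None,
) -> RepeatHit | None:
    """Best ungapped end-to-end placement of a fragment, or None.

    Scans every start position on both strands; the best hit minimises
    mismatches with ties broken by leftmost start then plus strand.
    Returns None when even the best placement exceeds
    ``max_mismatch_frac`` x fragment length.
    """
    if isinstance(fragment, MergedFragment):
        seq = fragment.sequence
        fid = fragment_id if fragment_id is not None else fragment.id
    else:
        seq = fragment
        fid = fragment_id if fragment_id is not None else ""
    seq = seq.upper()
    if len(seq) > len(reference):
        raise ValueError(
            f"fragment ({len(seq)} nt) longer than reference ({len(reference)} nt)"
        )

    ref = encode(reference.upper())
    best: tuple[int, int, int] | None = None  # (mismatches, start, strand_rank)
    for rank, query in enumerate((encode(seq), encode(revcomp(seq)))):
        mm = window_mismatches(ref, query)
        i = int(np.argmin(mm))  # argmin is leftmost on ties
        cand = (int(mm[i]), i, rank)
        if best is None or cand < best:
            best = cand
    n_mm, start, rank = best
    if n_mm > max_mismatch_frac * len(seq):
        return None
    return RepeatHit(
        fragment_id=fid,
        ref_name=ref_name,
        start=start,
        end=start + len(seq),
        strand="+-"[rank],
        n_mismatches=n_mm,
    )


def map_fragments(
    fragments: Iterable[MergedFragment | str],
    reference: str,
    ref_name: str = "ref",
    max_mismatch_frac: float = 0.1,
) -> list[RepeatHit]:
    """Map many fragments to one reference, dropping the unmappable."""
    hits = []
    for i, frag in enumerate(fragments):
        fid = None if isinstance(frag, MergedFragment) else f"frag_{i:06d}"
        hit = align_end_to_end(
            frag, reference, ref_name=ref_name,
            max_mismatch_frac=max_mismatch_frac, fragment_id=fid,
        )
        if hit is not None:
            hits.append(hit)
    return hits


def triplicate_consensus(unit: DimerUnit | str) -> str:
    """Three tandem copies of a repeat unit, the edge-effect-free
    mapping reference whose middle copy has full flanking context."""
    seq = unit.sequence if isinstance(unit, DimerUnit) else unit
    return seq * 3


def coverage_from_hits(hits: Sequence[RepeatHit], ref_length: int) -> np.ndarray:
    """Raw per-base fragment depth implied by a set of hits."""
    delta = np.zeros(ref_length + 1)
    for h in hits:
        if h.start < 0 or h.end > ref_length:
            raise ValueError(
                f"hit [{h.start},{h.end}) outside reference of length {ref_length}"
            )
        delta[h.start] += 1
        delta[h.end] -= 1
    return np.cumsum(delta[:-1])


def fold_to_middle_dimer(hits: Sequence[RepeatHit], period: int) -> np.ndarray:
    """Collapse coverage on a triplicated reference onto one period.

    Every covered base at position p contributes to folded position
    p mod period; total coverage mass is conserved exactly. The result
    is the average-occupancy profile over the (conceptual) middle dimer,
    free of reference edge effects.
    """
    cov = coverage_from_hits(hits, 3 * period)
    return cov.reshape(3, period).sum(axis=0)


def build_track(
    hits: Sequence[RepeatHit],
    reference: str,
    calibration_factor: float = 1.0,
    ref_name: str | None = None,
) -> OccupancyTrack:
    """Per-base depth scaled by a spike-in calibration factor."""
    if calibration_factor <= 0:
        raise ValueError("calibration_factor must be > 0")
    cov = coverage_from_hits(hits, len(reference))
    return OccupancyTrack(
        ref_name=ref_name or (hits[0].ref_name if hits else "ref"),
        coverage=cov * calibration_factor,
        n_fragments=len(hits),
        calibration_factor=calibration_factor,
    )


def write_bedgraph(
    track_or_values: OccupancyTrack | np.ndarray,
    path: str | Path,
    ref_name: str | None = None,
) -> None:
    """Write a per-base track as bedGraph (0-based half-open, runs merged)."""
    if isinstance(track_or_values, OccupancyTrack):
        values = track_or_values.coverage
        name = ref_name or track_or_values.ref_name
    else:
        values = np.asarray(track_or_values, dtype=float)
        name = ref_name or "ref"
    with open(path, "w") as fh:
        start = 0
        for i in range(1, values.size + 1):
            if i == values.size or values[i] != values[start]:
                if values[start] != 0:
                    fh.write(f"{name}\t{start}\t{i}\t{values[start]:g}\n")
                start = i
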