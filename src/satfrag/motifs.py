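"""CENP-B box detection, scoring, and density statistics.

The CENP-B box is a 17-bp motif bound by the centromere protein CENP-B;
its middle 15 bp (``TTCGTTGGAAACGGG``) is the ancestral core found at
regular intervals in homogeneous alpha-satellite arrays, and it is the
unit of scoring here. A candidate 15-mer is scored by identity to the
core on a 0-to-1 scale: a perfect match scores 1, each mismatch subtracts
0.25, and anything with four or more mismatches scores 0. The scanner
reports every window on either strand within the mismatch budget, which
is exactly the set of sites with a nonzero score, making the scan and the
score mutually consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import check_dna, encode, revcomp, window_mismatches

#: Ancestral 15-bp core of the 17-bp CENP-B box.
CENP_B_BOX = "TTCGTTGGAAACGGG"

#: Score lost per mismatch; >=4 mismatches floors the score at 0.
SCORE_PER_MISMATCH = 0.25


@dataclass(frozen=True)
class MotifHit:
    """One accepted CENP-B box occurrence on a scanned sequence."""

    ref_name: str
    start: int  # 0-based, forward-strand coordinates
    strand: str  # '+' or '-'
    n_mismatches: int
    score: float

    @property
    def end(self) -> int:
        return self.start + len(CENP_B_BOX)


@dataclass(frozen=True)
class MotifSummary:
    """Per-sequence motif statistics: best box score and density per kb."""

    ref_name: str
    best_score: float
    density: float  # accepted hits per kilobase of scanned sequence
    n_hits: int


def motif_score(site: str, motif: str = CENP_B_BOX) -> float:
    """Identity score of a 15-nt site against the CENP-B box core.

    15/15 matches -> 1.0; each mismatch subtracts 0.25; more than three
    mismatches -> 0.0.
    """
    site = check_dna(site, "site")
    motif = check_dna(motif, "motif")
    if len(site) != len(motif):
        raise ValueError(
            f"site length {len(site)} != motif length {len(motif)}"
        )
    m = sum(a != b for a, b in zip(site, motif))
    return max(0.0, 1.0 - SCORE_PER_MISMATCH * m)


def _collapse(hits: list[MotifHit], width: int) -> list[MotifHit]:
    """Collapse overlapping same-strand hits to the best-scoring one.

    Within a chain of mutually overlapping windows the hit with the
    fewest mismatches wins; ties go to the leftmost start.
    """
    out: list[MotifHit] = []
    for strand in "+-":
        chain: list[MotifHit] = []
        for h in (h for h in hits if h.strand == strand):
            if chain and h.start < chain[-1].start + width:
                chain.append(h)
            else:
                if chain:
                    out.append(min(chain, key=lambda x: (x.n_mismatches, x.start)))
                chain = [h]
        if chain:
            out.append(min(chain, key=lambda x: (x.n_mismatches, x.start)))
    return sorted(out, key=lambda h: (h.start, h.strand))


def scan_motifs(
    sequence: str,
    motif: str = CENP_B_BOX,
    max_mismatches: int = 3,
    ref_name: str = "seq",
) -> list[MotifHit]:
    """Find all CENP-B box occurrences with at most ``max_mismatches``.

    Both strands are scanned; minus-strand hits are reported in
    forward-strand coordinates. Overlapping hits on the same strand are
    collapsed to the best-scoring (leftmost on tie) occurrence, and the
    result is sorted by start. Returns an empty list when the sequence is
    shorter than the motif or carries no acceptable window.
    """
    sequence = check_dna(sequence, "sequence")
    motif = check_dna(motif, "motif")
    w = len(motif)
    if len(sequence) < w:
        return []

    ref = encode(sequence)
    fwd = encode(motif)
    rev = encode(revcomp(motif))

    hits: list[MotifHit] = []
    for strand, query in (("+", fwd), ("-", rev)):
        mm = window_mismatches(ref, query)
        for start in np.flatnonzero(mm <= max_mismatches):
            n = int(mm[start])
            hits.append(
                MotifHit(
                    ref_name=ref_name,
                    start=int(start),
                    strand=strand,
                    n_mismatches=n,
                    score=max(0.0, 1.0 - SCORE_PER_MISMATCH * n),
                )
            )
    return _collapse(hits, w)


def motif_density(
    sequence: str, motif: str = CENP_B_BOX, ref_name: str = "seq"
) -> MotifSummary:
    """Accepted-hit density (hits/kb) and best score for one sequence."""
    if len(sequence) < 1:
        raise ValueError("sequence must be non-empty")
    hits = scan_motifs(sequence, motif, ref_name=ref_name)
    best = max((h.score for h in hits), default=0.0)
    return MotifSummary(
        ref_name=ref_name,
        best_score=best,
        density=len(hits) / (len(sequence) / 1000.0),
        n_hits=len(hits),
    )
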