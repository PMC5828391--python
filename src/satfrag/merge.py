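"""Overlap-merging of paired-end reads into full-length fragments.

On homogeneous tandem repeats, fragment length cannot be inferred by
mapping the two ends independently — both ends map ambiguously. Merging
overlapping 250 x 250 read pairs reconstructs each insert directly, so
its length is known exactly regardless of where it maps. The contract
mirrors standard overlap mergers (quality 25 3'-trim, minimum merged
length 25, minimum overlap 15): the longest suffix(R1)/prefix(revcomp R2)
overlap within the mismatch budget (one mismatch per 10 overlap nt) is
accepted, and disagreements inside the overlap resolve to the
higher-quality base.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

from ._seq import revcomp


@dataclass(frozen=True)
class MergedFragment:
    """A full-length insert reconstructed from one overlapping pair."""

    id: str
    sequence: str
    quality: str
    n_overlap: int
    source: str = "merged"

    @property
    def length(self) -> int:
        return len(self.sequence)


def _trim3(seq: str, qual: str, min_quality: int) -> tuple[str, str]:
    """Drop 3' bases until the terminal base meets the quality floor."""
    end = len(seq)
    while end > 0 and ord(qual[end - 1]) - 33 < min_quality:
        end -= 1
    return seq[:end], qual[:end]


def merge_pair(
    r1_seq: str,
    r1_qual: str,
    r2_seq: str,
    r2_qual: str,
    min_quality: int = 25,
    min_length: int = 25,
    min_overlap: int = 15,
    fragment_id: str = "",
) -> MergedFragment | None:
    """Merge one read pair; return None when the pair cannot be merged.

    R2 is reverse-complemented, then the longest overlap of length >=
    ``min_overlap`` between the R1 suffix and the R2 prefix with at most
    ``floor(overlap/10)`` mismatches is taken. Pairs with no acceptable
    overlap, or whose merged product is shorter than ``min_length``, come
    back as None (unmerged/discarded).
    """
    if len(r1_seq) != len(r1_qual) or len(r2_seq) != len(r2_qual):
        raise ValueError("sequence/quality length mismatch")

    r1_seq, r1_qual = _trim3(r1_seq.upper(), r1_qual, min_quality)
    r2_seq, r2_qual = _trim3(r2_seq.upper(), r2_qual, min_quality)
    rc2 = revcomp(r2_seq)
    rq2 = r2_qual[::-1]

    n1, n2 = len(r1_seq), len(rc2)
    if min(n1, n2) < min_overlap:
        return None

    a = np.frombuffer(r1_seq.encode(), dtype=np.uint8)
    b = np.frombuffer(rc2.encode(), dtype=np.uint8)
    for olen in range(min(n1, n2), min_overlap - 1, -1):
        mism = int(np.count_nonzero(a[n1 - olen :] != b[:olen]))
        if mism <= olen // 10:
            break
    else:
        return None

    # consensus over the overlap: higher-quality base wins, max quality kept
    seq_parts = [r1_seq[: n1 - olen]]
    qual_parts = [r1_qual[: n1 - olen]]
    ov_seq = []
    ov_qual = []
    for i in range(olen):
        b1, q1 = r1_seq[n1 - olen + i], r1_qual[n1 - olen + i]
        b2, q2 = rc2[i], rq2[i]
        if b1 == b2 or q1 >= q2:
            ov_seq.append(b1)
        else:
            ov_seq.append(b2)
        ov_qual.append(max(q1, q2))
    seq_parts.append("".join(ov_seq))
    qual_parts.append("".join(ov_qual))
    seq_parts.append(rc2[olen:])
    qual_parts.append(rq2[olen:])

    merged = "".join(seq_parts)
    if len(merged) < min_length:
        return None
    return MergedFragment(
        id=fragment_id,
        sequence=merged,
        quality="".join(qual_parts),
        n_overlap=olen,
    )


def read_paired_fastq(
    r1_path: str | Path, r2_path: str | Path
) -> Iterator[tuple[str, str, str, str, str]]:
    """Yield (id, r1_seq, r1_qual, r2_seq, r2_qual) from two FASTQ files."""
    it1 = SeqIO.parse(str(r1_path), "fastq")
    it2 = SeqIO.parse(str(r2_path), "fastq")
    for rec1, rec2 in zip(it1, it2):
        name = rec1.id.removesuffix("/1")
        q1 = "".join(chr(q + 33) for q in rec1.letter_annotations["phred_quality"])
        q2 = "".join(chr(q + 33) for q in rec2.letter_annotations["phred_quality"])
        yield name, str(rec1.seq), q1, str(rec2.seq), q2


def merge_fastq(
    r1_path: str | Path,
    r2_path: str | Path,
    min_quality: int = 25,
    min_length: int = 25,
    min_overlap: int = 15,
) -> tuple[list[MergedFragment], list[str]]:
    """Merge every pair in two FASTQ files.

    Returns the merged fragments and the ids of pairs left unmerged.
    """
    merged: list[MergedFragment] = []
    unmerged: list[str] = []
    for name, s1, q1, s2, q2 in read_paired_fastq(r1_path, r2_path):
        frag = merge_pair(
            s1, q1, s2, q2,
            min_quality=min_quality,
            min_length=min_length,
            min_overlap=min_overlap,
            fragment_id=name,
        )
        if frag is None:
            unmerged.append(name)
        else:
            merged.append(frag)
    return merged, unmerged


def length_histogram(
    fragments: Iterable[MergedFragment],
    bin_width: int = 5,
    restrict_to: set[str] | None = None,
    lo: int = 25,
    hi: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Fragment-length histogram over [lo, hi].

    ``restrict_to`` limits the histogram to the named fragment ids (e.g.
    those that mapped to one contig). Returns (counts, bin_edges); counts
    sum to the number of (restricted) fragments in range.
    """
    lengths = [
        f.length
        for f in fragments
        if restrict_to is None or f.id in restrict_to
    ]
    if not lengths:
        raise ValueError("no fragments to histogram (empty after restriction)")
    edges = np.arange(lo, hi + bin_width + 1, bin_width)
    counts, edges = np.histogram(lengths, bins=edges)
    return counts, edges
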