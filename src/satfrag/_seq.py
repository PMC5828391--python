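"""Low-level DNA sequence helpers shared across modules.

Sequences are plain Python strings (ACGT, case-insensitive at entry
points); hot loops work on uint8 numpy arrays produced by :func:`encode`.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# byte-value lookup: A,C,G,T -> 0..3, everything else -> 255
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _ENC[_b] = _i

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode ACGT (either case) as uint8 codes 0..3.

    Raises ValueError on any other character, including ambiguity codes:
    the ungapped scanners in this package have no mismatch semantics for
    them.
    """
    arr = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() == 255:
        bad = seq[int(np.argmax(arr == 255))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return arr


def check_dna(seq: str, name: str = "sequence") -> str:
    """Validate and uppercase a DNA string."""
    up = seq.upper()
    if not set(up) <= set("ACGT"):
        bad = sorted(set(up) - set("ACGT"))
        raise ValueError(f"{name} contains non-ACGT characters: {bad}")
    return up


def window_mismatches(reference: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Mismatch count of ``query`` against every window of ``reference``.

    Returns an int array of length ``len(reference) - len(query) + 1``;
    entry ``i`` is the Hamming distance between the query and
    ``reference[i:i+len(query)]``. Ungapped by construction.
    """
    m = query.size
    if reference.size < m:
        raise ValueError("reference shorter than query")
    windows = np.lib.stride_tricks.sliding_window_view(reference, m)
    return (windows != query).sum(axis=1)
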