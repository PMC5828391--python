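"""Spike-in calibration, fold enrichment, salt-fraction recovery, and
motif-enrichment correlation.

Calibrated counts scale each sample's raw repeat-mapped read count by a
constant over its spike-in count, making occupancy comparable across
antibodies and salt fractions; fold enrichment is the ratio of a
specific antibody's calibrated count to a nonspecific IgG control, with
an optional pseudocount guarding depleted contigs. Percent recovery
normalises per-fraction counts to the total for one antibody. The
motif-enrichment association is the Pearson product-moment correlation
between per-contig CENP-B box statistics (best score or density per kb)
and fold enrichment.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_SCALE = 10_000.0


def calibrate(raw_count: int, spike_count: int, scale_const: float = DEFAULT_SCALE) -> float:
    """Spike-in calibrated count: raw x scale_const / spike.

    ``scale_const`` is arbitrary (it cancels in every ratio); the default
    keeps calibrated counts in a readable range.
    """
    if spike_count < 1:
        raise ValueError("spike_count must be >= 1")
    return raw_count * scale_const / spike_count


def fold_enrichment(
    target_calibrated: float, igg_calibrated: float, pseudocount: float = 1.0
) -> float:
    """Ratio of calibrated antibody count to calibrated IgG count.

    The pseudocount (in calibrated units) keeps the ratio finite on
    depleted contigs; pass 0 for exact ratios.
    """
    if target_calibrated < 0 or igg_calibrated < 0:
        raise ValueError("calibrated counts must be >= 0")
    return (target_calibrated + pseudocount) / (igg_calibrated + pseudocount)


def percent_recovery(fraction_counts: Mapping[str, float]) -> dict[str, float]:
    """Each fraction's share of the total, in percent (sums to 100)."""
    total = float(sum(fraction_counts.values()))
    if total <= 0:
        raise ValueError("at least one fraction count must be positive")
    if min(fraction_counts.values()) < 0:
        raise ValueError("fraction counts must be >= 0")
    return {k: 100.0 * v / total for k, v in fraction_counts.items()}


def correlate_motif_enrichment(
    table: pd.DataFrame,
    x: str = "best_score",
    y: str = "fold_enrichment",
    log10_y: bool = False,
) -> tuple[float, int]:
    """Pearson r between a motif statistic and fold enrichment.

    ``x`` names the motif column (``best_score`` or ``density``); ``y``
    the enrichment column. Values are used untransformed by default; set
    ``log10_y`` to correlate against log10 enrichment instead. Returns
    (r, n). Requires at least 3 finite rows and nonzero variance in both
    variables.
    """
    xv = np.asarray(table[x], dtype=float)
    yv = np.asarray(table[y], dtype=float)
    ok = np.isfinite(xv) & np.isfinite(yv)
    xv, yv = xv[ok], yv[ok]
    if xv.size < 3:
        raise ValueError("need at least 3 finite rows to correlate")
    if log10_y:
        if yv.min() <= 0:
            raise ValueError("log10 correlation needs positive enrichment values")
        yv = np.log10(yv)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("zero variance in one of the variables")
    r, _ = stats.pearsonr(xv, yv)
    return float(r), int(xv.size)
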