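"""Peak-level quality control.

Two cleaning steps precede any correlation: a low-quality filter that drops
peaks whose value distribution betrays uncovered regions (the same value —
typically a pre-normalization zero — repeated in more than 5% of the samples
of any single cancer type), and a per-peak Tukey-fence outlier mask
([Q1 - 1.5*IQR, Q3 + 1.5*IQR]) whose flagged entries are excluded from the
pairwise correlations but never removed from the matrix itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import PeakMatrix

logger = logging.getLogger(__name__)


@dataclass
class OutlierMask:
    """Boolean table, same shape as the matrix; True = excluded outlier."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)

    @property
    def n_flagged(self) -> int:
        return int(self.values.sum())


def _max_identical_count(block: np.ndarray) -> np.ndarray:
    """Per row, the multiplicity of the most frequent value in ``block``."""
    s = np.sort(block, axis=1)
    n = s.shape[1]
    if n == 1:
        return np.ones(s.shape[0], dtype=int)
    eq = s[:, 1:] == s[:, :-1]
    best = np.ones(s.shape[0], dtype=int)
    run = np.ones(s.shape[0], dtype=int)
    for j in range(eq.shape[1]):
        run = np.where(eq[:, j], run + 1, 1)
        best = np.maximum(best, run)
    return best


def low_quality_peaks(matrix: PeakMatrix, max_identical_fraction: float = 0.05) -> list[str]:
    """Peak ids failing the repeated-value rule in at least one group.

    A peak fails if some value occurs in strictly more than
    ``max_identical_fraction`` of the samples of any single cancer-type
    group (single pseudo-group when no labels are present).
    """
    bad = np.zeros(matrix.n_peaks, dtype=bool)
    for group, cols in matrix.groups().items():
        if cols.size == 0:
            logger.warning("group %r has no samples; skipped", group)
            continue
        counts = _max_identical_count(matrix.values[:, cols])
        bad |= counts > max_identical_fraction * cols.size
    return [pid for pid, b in zip(matrix.peak_ids, bad) if b]


def filter_low_quality(matrix: PeakMatrix, max_identical_fraction: float = 0.05) -> PeakMatrix:
    """Drop low-quality peaks; returns the surviving submatrix."""
    dropped = set(low_quality_peaks(matrix, max_identical_fraction))
    keep = [pid for pid in matrix.peak_ids if pid not in dropped]
    logger.info(
        "low-quality filter: dropped %d/%d peaks (identical value in >%.1f%% of a group)",
        len(dropped), matrix.n_peaks, 100 * max_identical_fraction,
    )
    return matrix.subset_peaks(keep)


def mask_outliers(matrix: PeakMatrix) -> OutlierMask:
    """Tukey-fence outlier mask per peak row across the current cohort.

    Quartiles use linear interpolation of order statistics (the type-7
    estimator, the default of R's ``quantile`` and ``numpy.percentile``).
    Rows with fewer than 4 values yield an all-false mask.
    """
    if matrix.n_samples < 4:
        logger.warning(
            "only %d samples; too few for quartile fences, nothing masked", matrix.n_samples
        )
        return OutlierMask(np.zeros_like(matrix.values, dtype=bool))
    q1, q3 = np.percentile(matrix.values, [25, 75], axis=1)
    iqr = q3 - q1
    lo = (q1 - 1.5 * iqr)[:, None]
    hi = (q3 + 1.5 * iqr)[:, None]
    mask = (matrix.values < lo) | (matrix.values > hi)
    logger.info(
        "outlier mask: flagged %d/%d entries (%.3f%%)",
        mask.sum(), mask.size, 100 * mask.sum() / mask.size,
    )
    return OutlierMask(mask)
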