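"""Synthetic cohort generator with the statistical structure the pipeline assumes.

A latent-factor linear-Gaussian model: samples carry scores on a small
number of latent factors; *hub blocks* of peaks load on a single factor each
(giving the planted within-block pairwise correlation), while background
peaks are independent noise. Factors are distinguished by how many blocks
load on them — factor 1 carries the most peaks, so the principal components
of the planted hub set recover the factors in order. Factor 2 is the
smoking axis: heavy smokers' factor-2 scores have their standard deviation
multiplied by ``variance_inflation``, and survival times follow an
exponential hazard increasing with the factor-2 signal.

Data pathologies of real peak matrices are emulated after the fact:
non-negativity by shifting each peak so its minimum is 0 (a pure shift, so
planted correlations are preserved exactly), a fraction of entries replaced
by a repeated constant 0 (uncovered regions before normalization — what the
low-quality filter must catch), and a fraction of entries multiplied by a
large factor (heavy-tailed outliers — what the IQR mask must catch).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    ClinicalRecord,
    GeneSet,
    GeneSetCollection,
    Peak,
    PeakGeneMap,
    PeakMatrix,
)

logger = logging.getLogger(__name__)

POSITIVE_SET_NAME = "HALLMARK_SYNTH_POSITIVE"


@dataclass
class SyntheticConfig:
    """Generator settings; defaults define the standard test conditions.

    ``variance_inflation`` multiplies the standard deviation of heavy
    smokers' factor-2 scores. ``hazard_coef`` is the log-hazard increment
    per unit of the factor-2 signal; with ``hazard_on='abs_score'`` the
    signal is |factor-2 score|, with ``'outside_indicator'`` it is the 0/1
    indicator of |factor-2| above its cohort mean (making the true
    outside-vs-inside hazard ratio exactly exp(hazard_coef)).
    """

    n_peaks: int = 2000
    n_samples: int = 100
    n_hub_blocks: int = 20
    block_size: int = 10
    within_block_corr: float = 0.7
    n_cancer_types: int = 1
    n_factors: int = 5
    heavy_fraction: float = 0.5
    variance_inflation: float = 2.0
    hazard_coef: float = 0.5
    hazard_on: str = "abs_score"
    baseline_hazard: float = math.log(2) / 730.0  # per day; median ~2 years at baseline
    pfs_hazard_multiplier: float = 1.5
    censor_rate: float = 0.3
    zero_inflation: float = 0.05
    outlier_rate: float = 0.02
    outlier_multiplier: float = 10.0
    genes_per_block: int = 2
    n_decoy_sets: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.n_hub_blocks * self.block_size > self.n_peaks:
            raise ValueError("n_hub_blocks * block_size exceeds n_peaks")
        if not 0 < self.within_block_corr <= 1:
            raise ValueError("within_block_corr must be in (0, 1]")
        if not 0 < self.heavy_fraction < 1:
            raise ValueError("heavy_fraction must be in (0, 1)")
        if self.variance_inflation < 1:
            raise ValueError("variance_inflation must be >= 1")
        for name in ("censor_rate", "zero_inflation", "outlier_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.n_factors < 2:
            raise ValueError("need at least 2 factors (factor 2 is the smoking axis)")
        if self.hazard_on not in ("abs_score", "outside_indicator"):
            raise ValueError("hazard_on must be 'abs_score' or 'outside_indicator'")
        if self.n_samples < 4:
            raise ValueError("need at least 4 samples")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a generated dataset."""

    hub_peak_ids: set[str]
    blocks: list[list[str]] = field(default_factory=list)
    factor_of_block: list[int] = field(default_factory=list)
    factor_scores: pd.DataFrame | None = None  # samples x factors
    group_assignment: dict[str, str] = field(default_factory=dict)
    outlier_mask: np.ndarray | None = None
    zero_mask: np.ndarray | None = None


def blocks_per_factor(n_hub_blocks: int, n_factors: int) -> list[int]:
    """Deterministic block counts per factor, steeply front-loaded.

    Counts follow geometrically halving weights (2^(F-1), ..., 2, 1) via
    rounding of the cumulative sums. The steep profile keeps the
    eigenvalues of the planted correlation structure well separated, so
    the factor order stays recoverable by PCA even from small cohorts
    where sample eigenvalues fluctuate strongly.
    """
    f = min(n_factors, n_hub_blocks)
    w = 2.0 ** np.arange(f - 1, -1, -1)
    cum = np.round(np.cumsum(w) / w.sum() * n_hub_blocks).astype(int)
    counts = np.diff(np.concatenate([[0], cum]))
    return counts.tolist()


def generate(
    config: SyntheticConfig,
) -> tuple[PeakMatrix, list[ClinicalRecord], PeakGeneMap, GeneSetCollection, SyntheticTruth]:
    """Generate a complete synthetic study, deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_peaks
    n_hub = config.n_hub_blocks * config.block_size

    # -- cohort structure --------------------------------------------------
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    n_heavy = int(round(n * config.heavy_fraction))
    heavy = np.zeros(n, dtype=bool)
    heavy[rng.permutation(n)[:n_heavy]] = True
    cancer_types = [f"CT{(i % config.n_cancer_types) + 1:02d}" for i in range(n)]

    # -- latent factors ----------------------------------------------------
    scores = rng.standard_normal((n, config.n_factors))
    scores[heavy, 1] *= config.variance_inflation

    # -- peak heights ------------------------------------------------------
    c = config.within_block_corr
    lam, noise_sd = math.sqrt(c), math.sqrt(1.0 - c)
    values = rng.standard_normal((p, n))  # background noise, overwritten for hub rows
    counts = blocks_per_factor(config.n_hub_blocks, config.n_factors)
    factor_of_block: list[int] = []
    for f_idx, cnt in enumerate(counts):
        factor_of_block.extend([f_idx] * cnt)

    order = rng.permutation(p)
    hub_rows = order[:n_hub]
    for b in range(config.n_hub_blocks):
        rows = hub_rows[b * config.block_size : (b + 1) * config.block_size]
        f = scores[:, factor_of_block[b]]
        values[rows] = lam * f[None, :] + noise_sd * rng.standard_normal(
            (config.block_size, n)
        )

    # non-negativity: shift each peak so its minimum is exactly 0
    values -= values.min(axis=1, keepdims=True)

    zero_mask = rng.random((p, n)) < config.zero_inflation
    values[zero_mask] = 0.0
    outlier_mask = (rng.random((p, n)) < config.outlier_rate) & ~zero_mask
    values[outlier_mask] *= config.outlier_multiplier

    chroms = [f"chr{(i % 22) + 1}" for i in range(p)]
    peaks = [
        Peak(f"peak_{i + 1:06d}", chroms[i], 1000 + 1000 * i, 1000 + 1000 * i + 501)
        for i in range(p)
    ]
    matrix = PeakMatrix(
        peaks=peaks,
        sample_ids=sample_ids,
        values=values,
        sample_group=dict(zip(sample_ids, cancer_types)),
    )

    # -- clinical table ----------------------------------------------------
    pack_years = np.where(
        heavy, rng.uniform(20.0, 60.0, n), rng.uniform(0.0, 20.0 - 1e-9, n)
    )
    f2 = scores[:, 1]
    if config.hazard_on == "abs_score":
        signal = np.abs(f2)
    else:
        signal = (np.abs(f2) > np.abs(f2).mean()).astype(float)
    os_time, os_event = _exponential_survival(
        rng, config.baseline_hazard, config.hazard_coef, signal, config.censor_rate
    )
    pfs_time, pfs_event = _exponential_survival(
        rng,
        config.baseline_hazard * config.pfs_hazard_multiplier,
        config.hazard_coef,
        signal,
        config.censor_rate,
    )
    stages = rng.choice(["I", "II", "III", "IV"], n, p=[0.35, 0.3, 0.25, 0.1])
    clinical = [
        ClinicalRecord(
            sample_id=sample_ids[i],
            pack_years=float(pack_years[i]),
            os_time=float(os_time[i]),
            os_event=bool(os_event[i]),
            pfs_time=float(pfs_time[i]),
            pfs_event=bool(pfs_event[i]),
            age=float(np.clip(rng.normal(65, 8), 30, 90)),
            gender=str(rng.choice(["female", "male"])),
            stage=str(stages[i]),
            t_factor=f"T{int(rng.integers(1, 5))}",
            n_factor=f"N{int(rng.integers(0, 3))}",
            m_factor=f"M{int(rng.integers(0, 2))}",
            cancer_type=cancer_types[i],
        )
        for i in range(n)
    ]

    # -- peak-gene map and gene sets --------------------------------------
    blocks = [
        [peaks[r].peak_id for r in hub_rows[b * config.block_size : (b + 1) * config.block_size]]
        for b in range(config.n_hub_blocks)
    ]
    entries: list[tuple[str, str]] = []
    hub_genes: list[str] = []
    for b, block in enumerate(blocks):
        genes = [f"GENE_HUB_{b + 1:02d}_{g + 1}" for g in range(config.genes_per_block)]
        hub_genes.extend(genes)
        for pid in block:
            for g in genes:
                entries.append((pid, g))
    background_rows = order[n_hub:]
    n_bg_genes = max(len(background_rows) // 2, 1)
    bg_genes = [f"GENE_BG_{i + 1:05d}" for i in range(n_bg_genes)]
    for j, r in enumerate(background_rows):
        entries.append((peaks[r].peak_id, bg_genes[j % n_bg_genes]))

    collection = GeneSetCollection()
    collection.sets[POSITIVE_SET_NAME] = GeneSet(
        POSITIVE_SET_NAME, "synthetic positive set fed by hub-block genes", tuple(hub_genes)
    )
    decoy_size = min(len(hub_genes), len(bg_genes))
    for d in range(config.n_decoy_sets):
        chosen = rng.choice(bg_genes, size=decoy_size, replace=False)
        name = f"HALLMARK_SYNTH_DECOY_{d + 1:02d}"
        collection.sets[name] = GeneSet(name, "synthetic decoy set", tuple(sorted(chosen)))

    truth = SyntheticTruth(
        hub_peak_ids={pid for blk in blocks for pid in blk},
        blocks=blocks,
        factor_of_block=factor_of_block,
        factor_scores=pd.DataFrame(
            scores,
            index=sample_ids,
            columns=[f"factor_{j + 1}" for j in range(config.n_factors)],
        ),
        group_assignment={
            sample_ids[i]: ("heavy" if heavy[i] else "light") for i in range(n)
        },
        outlier_mask=outlier_mask,
        zero_mask=zero_mask,
    )
    logger.info(
        "synthetic cohort: %d peaks (%d planted hubs) x %d samples (%d heavy)",
        p, n_hub, n, n_heavy,
    )
    return matrix, clinical, PeakGeneMap(entries=entries), collection, truth


def _exponential_survival(
    rng: np.random.Generator,
    baseline: float,
    coef: float,
    signal: np.ndarray,
    censor_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times with hazard baseline*exp(coef*signal) and
    uniform-on-[0, T] censoring applied to a ``censor_rate`` fraction."""
    rate = baseline * np.exp(coef * signal)
    times = rng.exponential(1.0 / rate)
    event = np.ones_like(times, dtype=bool)
    censored = rng.random(times.shape) < censor_rate
    times = np.where(censored, rng.uniform(0.0, times), times)
    event[censored] = False
    return times, event


def empirical_block_correlation(matrix: PeakMatrix, truth: SyntheticTruth) -> float:
    """Mean absolute pairwise Pearson correlation within planted blocks.

    Blocks with fewer than two peaks are skipped; NaN is returned (with a
    warning) when no block admits a pairwise correlation.
    """
    index = {pid: i for i, pid in enumerate(matrix.peak_ids)}
    vals: list[float] = []
    for block in truth.blocks:
        rows = [index[pid] for pid in block if pid in index]
        if len(rows) < 2:
            continue
        r = np.corrcoef(matrix.values[rows])
        iu = np.triu_indices(len(rows), k=1)
        vals.extend(np.abs(r[iu]).tolist())
    if not vals:
        logger.warning("no block with >=2 peaks; block correlation undefined")
        return float("nan")
    return float(np.mean(vals))
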