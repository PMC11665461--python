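"""PCA on hub peaks, axis distances, borders, and smoking-group comparison.

Samples are the observations and hub peaks the variables; variables are
centered and (by default) scaled to unit variance, matching the defaults of
the standard multivariate toolchains. A sample's *distance from the PC-k
axis* is the absolute value of its score on component k; the *border* is the
cohort mean of those distances and splits the cohort into an inside
(distance strictly below the border) and an outside group. Light (<20
pack-years) and heavy (>=20) smokers are compared on the distances with a
two-tailed unpaired t-test after iterative two-sided Grubbs outlier
exclusion within each group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .io import ClinicalRecord, PeakMatrix, clinical_index

logger = logging.getLogger(__name__)


@dataclass
class PcaResult:
    """Per-sample component scores and per-peak component correlations.

    ``explained_fraction`` is each component's share of the total variance of
    the scaled variables; ``peak_pc_correlation[i, k]`` is the Pearson
    correlation of hub peak i's heights with the component-(k+1) scores.
    Component indices in the public API are 1-based (component 2 = PC2).
    """

    sample_ids: list[str]
    peak_ids: list[str]
    scores: np.ndarray
    explained_fraction: np.ndarray
    peak_pc_correlation: np.ndarray
    n_components: int

    def component_scores(self, component_index: int) -> np.ndarray:
        if not 1 <= component_index <= self.n_components:
            raise ValueError(
                f"component_index {component_index} outside 1..{self.n_components}"
            )
        return self.scores[:, component_index - 1]


@dataclass
class AxisPartition:
    """Inside/outside split of a cohort by absolute PC-axis distance."""

    component_index: int
    sample_ids: list[str]
    distance: dict[str, float]
    border: float
    inside: set[str] = field(default_factory=set)
    outside: set[str] = field(default_factory=set)

    def indicator(self) -> dict[str, int]:
        """outside = 1 (the exposure of interest), inside = 0."""
        return {s: int(s in self.outside) for s in self.sample_ids}


@dataclass
class GroupComparison:
    group_a: list[str]  # light smokers
    group_b: list[str]  # heavy smokers
    excluded: list[str]
    t_statistic: float
    p_value: float
    mean_a: float
    mean_b: float
    significant: bool


def run_pca(
    matrix: PeakMatrix,
    hub_ids: Sequence[str],
    n_components: int = 5,
    scale_unit: bool = True,
    mask=None,
) -> PcaResult:
    """PCA of samples over the hub-peak variables.

    Constant peaks are dropped (with a warning) before scaling. Scaling uses
    the population standard deviation (divisor N). Each component's sign is
    fixed so that the variable with the largest absolute correlation to the
    component correlates positively, making score signs reproducible.

    ``mask`` (an outlier mask aligned to ``matrix``) does not affect the
    decomposition itself, only the reported peak-PC correlations, which are
    then computed over each peak's unmasked entries — mirroring the rule
    that fence outliers are excluded from every Pearson correlation.
    """
    if matrix.n_samples < 3:
        raise ValueError("PCA needs at least 3 samples")
    index = {pid: i for i, pid in enumerate(matrix.peak_ids)}
    hub_rows = [index[pid] for pid in hub_ids]
    sub = matrix.subset_peaks(list(hub_ids))
    X = sub.values.T.astype(float)  # samples x peaks
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not np.all(keep):
        dropped = [pid for pid, k in zip(sub.peak_ids, keep) if not k]
        logger.warning("dropping %d constant hub peaks before PCA: %s...",
                       len(dropped), dropped[:3])
        X, sd = X[:, keep], sd[keep]
    peak_ids = [pid for pid, k in zip(sub.peak_ids, keep) if k]
    if X.shape[1] < n_components:
        logger.warning(
            "only %d usable hub peaks for %d requested components", X.shape[1], n_components
        )
    Xc = X - X.mean(axis=0)
    if scale_unit:
        Xc = Xc / sd
    u, s, _vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((s ** 2).sum())
    k = int(min(n_components, (s > s[0] * 1e-12).sum() if s.size else 0))
    if k == 0:
        raise ValueError("input matrix has rank 0 after centering")
    scores = u[:, :k] * s[:k]
    explained = (s[:k] ** 2) / total

    if mask is None:
        # peak-PC correlation (raw peak heights vs scores; scale-invariant)
        z_x = Xc / np.sqrt((Xc ** 2).sum(axis=0))
        z_s = scores / np.sqrt((scores ** 2).sum(axis=0))
        corr = z_x.T @ z_s
    else:
        mvals = mask.values if hasattr(mask, "values") else np.asarray(mask, bool)
        obs = ~mvals[hub_rows][keep]  # peaks x samples observation indicator
        corr = _masked_peak_score_correlation(X.T, obs, scores)

    for c in range(k):
        lead = np.argmax(np.abs(corr[:, c]))
        if corr[lead, c] < 0:
            scores[:, c] *= -1.0
            corr[:, c] *= -1.0
    return PcaResult(
        sample_ids=list(matrix.sample_ids),
        peak_ids=peak_ids,
        scores=scores,
        explained_fraction=explained,
        peak_pc_correlation=np.clip(corr, -1.0, 1.0),
        n_components=k,
    )


def _masked_peak_score_correlation(
    values: np.ndarray, obs: np.ndarray, scores: np.ndarray
) -> np.ndarray:
    """Pearson r of each peak row with each score column over unmasked entries."""
    m = obs.astype(float)
    v = values * m
    n = m.sum(axis=1, keepdims=True)
    sx = v.sum(axis=1, keepdims=True)
    sxx = (v * v).sum(axis=1, keepdims=True)
    ss = m @ scores
    sss = m @ (scores ** 2)
    sxs = v @ scores
    with np.errstate(invalid="ignore", divide="ignore"):
        num = n * sxs - sx * ss
        den = np.sqrt((n * sxx - sx ** 2) * (n * sss - ss ** 2))
        r = num / den
    r[~np.isfinite(r)] = 0.0
    return r


def axis_partition(pca: PcaResult, component_index: int) -> AxisPartition:
    """Split samples at the mean absolute score on the given component."""
    scores = pca.component_scores(component_index)
    dist = np.abs(scores)
    border = float(dist.mean())
    distance = dict(zip(pca.sample_ids, dist.tolist()))
    inside = {s for s, d in distance.items() if d < border}
    outside = {s for s in pca.sample_ids if s not in inside}
    return AxisPartition(
        component_index=component_index,
        sample_ids=list(pca.sample_ids),
        distance=distance,
        border=border,
        inside=inside,
        outside=outside,
    )


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value from the Student-t quantile."""
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t ** 2 / (n - 2 + t ** 2))


def grubbs_exclude(
    values: Sequence[float], alpha: float = 0.05
) -> tuple[list[float], list[int]]:
    """Iteratively remove the most extreme value while Grubbs' G exceeds its
    critical value; returns (kept values, excluded original indices)."""
    vals = list(map(float, values))
    idx = list(range(len(vals)))
    excluded: list[int] = []
    while len(vals) >= 3:
        a = np.asarray(vals)
        m, s = a.mean(), a.std(ddof=1)
        if s == 0:
            break
        i = int(np.argmax(np.abs(a - m)))
        g = abs(a[i] - m) / s
        if g > grubbs_critical(len(vals), alpha):
            excluded.append(idx.pop(i))
            removed = vals.pop(i)
            logger.info("Grubbs: excluded value %.4g (G=%.3f, n=%d)", removed, g, len(vals) + 1)
        else:
            break
    return vals, excluded


def compare_groups(
    partition: AxisPartition,
    clinical: Sequence[ClinicalRecord],
    alpha: float = 0.05,
    equal_var: bool = False,
) -> GroupComparison:
    """Light vs heavy smokers on axis distances (Grubbs then t-test).

    Welch's unequal-variance form is the default; ``equal_var=True`` gives
    the pooled Student test. Samples with unknown smoking history are
    dropped before testing.
    """
    by_sample = clinical_index(clinical)
    groups: dict[str, list[str]] = {"light": [], "heavy": []}
    for s in partition.sample_ids:
        rec = by_sample.get(s)
        if rec is None or rec.smoking_group == "unknown":
            continue
        groups[rec.smoking_group].append(s)
    if not groups["light"] or not groups["heavy"]:
        raise ValueError("both smoking groups must be non-empty")

    kept: dict[str, list[float]] = {}
    excluded: list[str] = []
    for name, members in groups.items():
        dists = [partition.distance[s] for s in members]
        vals, exc = grubbs_exclude(dists, alpha)
        kept[name] = vals
        excluded.extend(members[i] for i in exc)
        if not vals:
            raise ValueError(f"group {name!r} emptied by outlier exclusion")
    if min(len(kept["light"]), len(kept["heavy"])) < 2:
        raise ValueError("need at least 2 samples per group after exclusions")
    t, p = stats.ttest_ind(kept["light"], kept["heavy"], equal_var=equal_var)
    return GroupComparison(
        group_a=groups["light"],
        group_b=groups["heavy"],
        excluded=excluded,
        t_statistic=float(t),
        p_value=float(p),
        mean_a=float(np.mean(kept["light"])),
        mean_b=float(np.mean(kept["heavy"])),
        significant=bool(p < alpha),
    )
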