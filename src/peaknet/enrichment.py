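"""Component-peak selection and gene-set overlap enrichment.

Peaks defining a principal component are those whose absolute correlation
with the component scores strictly exceeds a threshold (default 0.8); the
sign is ignored because a component's orientation is arbitrary. Their genes
(via the peak-gene relationship map) form an unranked query list, so
enrichment is the classic hypergeometric overlap test against each gene set
— the "compute overlaps" usage of MSigDB-style collections, not the ranked
running-sum statistic, which is undefined for an unranked query. P-values
are Benjamini-Hochberg adjusted across all tested sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .axis import PcaResult
from .io import GeneSetCollection, PeakGeneMap

logger = logging.getLogger(__name__)

DEFAULT_PC_CORR_THRESHOLD = 0.8
DEFAULT_FDR_CUTOFF = 0.05


@dataclass
class EnrichmentResult:
    set_name: str
    overlap_genes: list[str]
    overlap_count: int
    set_size: int
    query_size: int
    universe_size: int
    p_value: float
    q_value: float

    @property
    def significant(self) -> bool:
        return self.q_value < DEFAULT_FDR_CUTOFF


def select_component_peaks(
    pca: PcaResult, component_index: int, threshold: float = DEFAULT_PC_CORR_THRESHOLD
) -> list[str]:
    """Peaks with |peak-PC correlation| strictly greater than ``threshold``."""
    if not 1 <= component_index <= pca.n_components:
        raise ValueError(f"component_index {component_index} outside 1..{pca.n_components}")
    corr = pca.peak_pc_correlation[:, component_index - 1]
    chosen = [pid for pid, r in zip(pca.peak_ids, corr) if abs(r) > threshold]
    logger.info(
        "component %d: %d/%d peaks with |r| > %.2f",
        component_index, len(chosen), len(pca.peak_ids), threshold,
    )
    return chosen


def peaks_to_genes(peaks: Sequence[str], pgmap: PeakGeneMap) -> list[str]:
    """Deduplicated, sorted union of genes mapped by the given peaks."""
    mapped = pgmap.mapped_peaks()
    unmapped = [p for p in peaks if p not in mapped]
    if unmapped:
        logger.info("%d/%d peaks have no gene mapping", len(unmapped), len(peaks))
    genes = pgmap.genes_for(peaks)
    if not genes:
        logger.warning("no genes mapped from %d peaks; enrichment will be skipped", len(peaks))
    return genes


def overlap_enrichment(
    query: Sequence[str],
    sets: GeneSetCollection,
    universe: Sequence[str],
) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail overlap test per gene set, BH-adjusted.

    For each set, with universe size N, in-universe set size K and query
    size n, the p-value is P(X >= overlap) for X ~ Hypergeom(N, K, n).
    Query genes outside the universe are dropped with a warning. Results
    are sorted by q, then p, then name.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("gene universe is empty")
    q = sorted(set(query))
    outside = [g for g in q if g not in uni]
    if outside:
        logger.warning("%d query genes outside the universe were dropped", len(outside))
        q = [g for g in q if g in uni]
    n = len(q)
    names, pvals, partial = [], [], []
    for gs in sets:
        members = set(gs.genes) & uni
        overlap = sorted(set(q) & members)
        k, K = len(overlap), len(members)
        # upper tail P(X >= k); survival function is P(X > k-1)
        p = float(stats.hypergeom.sf(k - 1, len(uni), K, n)) if k > 0 else 1.0
        names.append(gs.name)
        pvals.append(min(p, 1.0))
        partial.append((overlap, k, K))
    if not names:
        return []
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(
            set_name=name,
            overlap_genes=ov,
            overlap_count=k,
            set_size=K,
            query_size=n,
            universe_size=len(uni),
            p_value=p,
            q_value=float(qv),
        )
        for name, p, qv, (ov, k, K) in zip(names, pvals, qvals, partial)
    ]
    results.sort(key=lambda r: (r.q_value, r.p_value, r.set_name))
    return results
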