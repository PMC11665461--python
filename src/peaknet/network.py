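"""Peak-peak correlation network and hub selection.

Two peaks are connected *directly* when the absolute Pearson correlation of
their heights across samples is at least ``r_threshold`` (default 0.4, chosen
against a background noise level of roughly 0.2). They are connected
*indirectly* when they share at least one direct neighbor but are not
directly connected themselves; the indirect rule is applied for exactly one
level of intermediation by default (no transitive closure). A peak's
connection count is its number of distinct peers over direct and indirect
edges together, and the hub set is the top decile by that count.

Correlations are computed over pairwise-complete, unmasked observations so
that outlier values excluded by the QC mask simply drop out of each pair.
The computation streams over row blocks, so a full dense peaks x peaks
table is never required for edge construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .io import PeakMatrix
from .qc import OutlierMask

logger = logging.getLogger(__name__)

DEFAULT_R_THRESHOLD = 0.4
#: empirical background correlation level the 0.4 cutoff is calibrated against
NOISE_LEVEL = 0.2
DEFAULT_MIN_PAIRS = 8


def _as_values(matrix) -> np.ndarray:
    return matrix.values if isinstance(matrix, PeakMatrix) else np.asarray(matrix, float)


def _prepare(values: np.ndarray, mask) -> tuple[np.ndarray, np.ndarray]:
    """Zero-filled data and observation-indicator matrices, rows pre-centered.

    Centering each row on its observed mean is a numerical-conditioning step
    only: Pearson correlation is shift-invariant, including on the
    pairwise-complete subsets, because the shift is constant within a row.
    """
    obs = np.ones_like(values, dtype=bool)
    if mask is not None:
        m = mask.values if isinstance(mask, OutlierMask) else np.asarray(mask, bool)
        if m.shape != values.shape:
            raise ValueError(f"mask shape {m.shape} != matrix shape {values.shape}")
        obs &= ~m
    ind = obs.astype(float)
    counts = np.maximum(ind.sum(axis=1), 1.0)
    centered = values - (np.where(obs, values, 0.0).sum(axis=1) / counts)[:, None]
    return np.where(obs, centered, 0.0), ind


def _corr_block(
    vi: np.ndarray, mi: np.ndarray, v: np.ndarray, m: np.ndarray, min_pairs: int
) -> np.ndarray:
    """Pairwise-complete Pearson r between a row block and all rows."""
    n = mi @ m.T
    sx = vi @ m.T
    sy = mi @ v.T
    sxx = (vi * vi) @ m.T
    syy = mi @ (v * v).T
    sxy = vi @ v.T
    with np.errstate(invalid="ignore", divide="ignore"):
        nn = np.where(n > 0, n, np.nan)
        cov = sxy - sx * sy / nn
        varx = sxx - sx * sx / nn
        vary = syy - sy * sy / nn
        r = cov / np.sqrt(varx * vary)
    # zero-variance guard: variances numerically <= 0 relative to the row scale
    tiny = 1e-12
    scale = np.sqrt(np.maximum(sxx, 0.0) * np.maximum(syy, 0.0))
    invalid = (n < min_pairs) | (varx <= tiny * np.maximum(scale, 1.0)) | (
        vary <= tiny * np.maximum(scale, 1.0)
    )
    r = np.where(invalid, np.nan, np.clip(r, -1.0, 1.0))
    return r


def pairwise_correlation(
    matrix,
    mask=None,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    block_size: int = 1024,
) -> np.ndarray:
    """Dense symmetric table of pairwise-complete Pearson correlations.

    Entries are NaN when fewer than ``min_pairs`` complete observations
    remain after masking, or when either side has zero variance on the
    complete subset. Suitable for cohorts whose full square table fits in
    memory; edge construction for larger inputs should go through
    :func:`network_from_matrix`, which streams.
    """
    values = _as_values(matrix)
    if values.shape[1] < 2:
        raise ValueError("need at least 2 samples to correlate")
    v, m = _prepare(values, mask)
    n = values.shape[0]
    out = np.empty((n, n), dtype=float)
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        out[start:stop] = _corr_block(v[start:stop], m[start:stop], v, m, min_pairs)
    # exact symmetry despite floating-point noise in the blocked products
    out = (out + out.T) / 2.0
    np.fill_diagonal(out, 1.0)
    return out


def iter_direct_adjacency_blocks(
    matrix,
    mask=None,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    block_size: int = 1024,
) -> Iterator[tuple[int, sp.csr_matrix]]:
    """Yield (row offset, boolean row-block of the direct-edge adjacency)."""
    values = _as_values(matrix)
    v, m = _prepare(values, mask)
    n = values.shape[0]
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        r = _corr_block(v[start:stop], m[start:stop], v, m, min_pairs)
        with np.errstate(invalid="ignore"):
            adj = np.abs(r) >= r_threshold
        adj[np.isnan(r)] = False
        for i in range(start, stop):
            adj[i - start, i] = False
        yield start, sp.csr_matrix(adj)


@dataclass
class CorrelationNetwork:
    """Direct/indirect peak connectivity and per-node connection counts."""

    node_ids: list[str]
    direct: sp.csr_matrix
    indirect: sp.csr_matrix
    r_threshold: float = DEFAULT_R_THRESHOLD
    noise_level: float = NOISE_LEVEL
    _degree: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def degree(self) -> np.ndarray:
        """Distinct peers over the union of direct and indirect edges."""
        if self._degree is None:
            union = (self.direct + self.indirect).astype(bool)
            self._degree = np.asarray(union.sum(axis=1)).ravel().astype(int)
        return self._degree

    @property
    def degree_map(self) -> dict[str, int]:
        return dict(zip(self.node_ids, self.degree.tolist()))

    def _edge_set(self, adj: sp.spmatrix) -> set[tuple[str, str]]:
        coo = sp.triu(adj, k=1).tocoo()
        return {
            tuple(sorted((self.node_ids[i], self.node_ids[j])))
            for i, j in zip(coo.row, coo.col)
        }

    @property
    def direct_edges(self) -> set[tuple[str, str]]:
        return self._edge_set(self.direct)

    @property
    def indirect_edges(self) -> set[tuple[str, str]]:
        return self._edge_set(self.indirect)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        g.add_edges_from((a, b, {"kind": "direct"}) for a, b in self.direct_edges)
        g.add_edges_from((a, b, {"kind": "indirect"}) for a, b in self.indirect_edges)
        return g


def _network_from_direct(
    direct: sp.csr_matrix,
    node_ids: Sequence[str],
    r_threshold: float,
    indirect_depth: int = 1,
) -> CorrelationNetwork:
    direct = direct.astype(bool).tocsr()
    direct.setdiag(False)
    direct.eliminate_zeros()
    n = direct.shape[0]
    if indirect_depth < 0:
        raise ValueError("indirect_depth must be >= 0")
    reach = direct.copy()
    paths = direct.copy()
    for _ in range(indirect_depth):
        paths = (paths @ direct).astype(bool)
        reach = (reach + paths).astype(bool)
    indirect = (reach.astype(int) - reach.multiply(direct)).astype(bool).tolil()
    indirect.setdiag(False)
    indirect = indirect.tocsr()
    indirect.eliminate_zeros()
    return CorrelationNetwork(
        node_ids=list(node_ids), direct=direct, indirect=indirect, r_threshold=r_threshold
    )


def build_network(
    corr: np.ndarray,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    node_ids: Sequence[str] | None = None,
    indirect_depth: int = 1,
) -> CorrelationNetwork:
    """Network from a dense correlation table (NaN entries carry no edge)."""
    corr = np.asarray(corr, float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation table must be square")
    if node_ids is None:
        node_ids = [f"n{i}" for i in range(corr.shape[0])]
    with np.errstate(invalid="ignore"):
        adj = np.abs(corr) >= r_threshold
    adj[np.isnan(corr)] = False
    np.fill_diagonal(adj, False)
    return _network_from_direct(sp.csr_matrix(adj), node_ids, r_threshold, indirect_depth)


def network_from_matrix(
    matrix: PeakMatrix,
    mask: OutlierMask | None = None,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    block_size: int = 1024,
    indirect_depth: int = 1,
) -> CorrelationNetwork:
    """Build the network directly from a matrix, streaming in row blocks."""
    blocks = [
        blk
        for _, blk in iter_direct_adjacency_blocks(
            matrix, mask, r_threshold, min_pairs, block_size
        )
    ]
    direct = sp.vstack(blocks).tocsr()
    # enforce symmetry: blockwise float noise could in principle differ across
    # the diagonal; an edge requires both triangles to agree
    direct = direct.maximum(direct.T)
    net = _network_from_direct(direct, matrix.peak_ids, r_threshold, indirect_depth)
    logger.info(
        "network: %d nodes, %d direct and %d indirect edges",
        net.n_nodes, sp.triu(net.direct, 1).nnz, sp.triu(net.indirect, 1).nnz,
    )
    return net


def select_hubs(network: CorrelationNetwork, fraction: float = 0.10) -> list[str]:
    """The ``floor(fraction * n_nodes)`` most-connected peaks.

    Ties at the cutoff degree are broken by lexicographic peak id so the
    selection is deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    k = math.floor(fraction * network.n_nodes)
    if k == 0:
        raise ValueError(
            f"fraction {fraction} of {network.n_nodes} nodes selects 0 peaks; "
            "increase the fraction or the network size"
        )
    deg = network.degree
    order = sorted(range(network.n_nodes), key=lambda i: (-deg[i], network.node_ids[i]))
    chosen = order[:k]
    logger.info(
        "hub selection: %d/%d peaks, cutoff degree %d", k, network.n_nodes, deg[chosen[-1]]
    )
    return [network.node_ids[i] for i in chosen]
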