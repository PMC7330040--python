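"""Weighted co-expression network construction and module detection.

The network is built from a genes x samples log2 expression matrix:
pairwise Pearson correlations are raised to a soft-threshold power
(``beta``, default 6, chosen for approximate scale-free topology) to give a
weighted adjacency, which is transformed into the topological overlap
measure (TOM) -- a similarity that credits two genes both for their direct
correlation and for the neighbours they share.  Modules are detected by
average-linkage hierarchical clustering on TOM dissimilarity (1 - TOM) with
a static tree cut, and modules whose eigengenes are nearly collinear are
merged below an eigengene-dissimilarity threshold (default 0.10).

Conventions (stated once, enforced everywhere):

* adjacency has a zero diagonal; connectivity k_i = sum_j a_ij;
* TOM has a unit diagonal; entries lie in [0, 1];
* genes too small to form a module carry the reserved label
  ``"unassigned"`` (the grey-module convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress, rankdata

logger = logging.getLogger("tmenet")

#: reserved module label for genes not assigned to any module
UNASSIGNED = "unassigned"


class DataError(ValueError):
    """Raised when an input matrix or table violates its contract."""


@dataclass
class NetworkParams:
    """Parameters of network construction and module detection.

    Attributes
    ----------
    beta : int
        Soft-threshold power applied to |correlation|.  Default 6.
    merge_threshold : float
        Eigengene dissimilarity (1 - cor) below which two modules are
        merged.  Default 0.10.
    cut_height : float
        Static tree-cut height on 1 - TOM average-linkage dendrogram.
    min_module_size : int
        Clusters smaller than this are labelled ``unassigned``.
    correlation : str
        Correlation method tag; only ``"pearson"`` is implemented.
    signed : bool
        If True use the signed adjacency ((1 + cor)/2)^beta instead of
        the default unsigned |cor|^beta.
    linkage_method : str
        Hierarchical linkage for module detection (default average).
    """

    beta: int = 6
    merge_threshold: float = 0.10
    cut_height: float = 0.99
    min_module_size: int = 30
    correlation: str = "pearson"
    signed: bool = False
    linkage_method: str = "average"

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not 0 < self.merge_threshold < 1:
            raise ValueError("merge_threshold must lie in (0, 1)")
        if not 0 < self.cut_height < 2:
            raise ValueError("cut_height must lie in (0, 2)")
        if self.min_module_size < 3:
            raise ValueError("min_module_size must be >= 3")
        if self.correlation != "pearson":
            raise ValueError("only Pearson correlation is supported")


# ---------------------------------------------------------------------------
# count filtering and quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns to the mean empirical distribution.

    Each sample (column) is mapped onto the distribution obtained by
    averaging the sorted value vectors of all samples; ties within a
    column receive the mean of the reference values they span.
    """
    arr = values.to_numpy(dtype=float)
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    n = arr.shape[0]
    for j in range(arr.shape[1]):
        ranks = rankdata(arr[:, j], method="average")  # 1..n, ties averaged
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), ref)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def filter_and_normalize(
    counts: pd.DataFrame,
    count_min: int = 5,
    sample_frac: float = 0.8,
    signal_min: float = 5.0,
) -> pd.DataFrame:
    """Low-count filtering, quantile normalization and signal filtering.

    Genes with counts below ``count_min`` in at least ``sample_frac`` of
    samples are removed; the remaining matrix is log2(x+1)-transformed and
    quantile-normalized to the mean empirical distribution; finally only
    genes whose normalized signal exceeds ``signal_min`` in at least
    ``sample_frac`` of samples are retained as network substrate.

    Parameters
    ----------
    counts : DataFrame
        Non-negative integer counts, genes as rows, samples as columns.

    Returns
    -------
    DataFrame
        Normalized log2 expression over the retained genes.
    """
    if counts.shape[1] < 2:
        raise DataError("at least 2 samples are required")
    if (counts.to_numpy() < 0).any():
        raise DataError("counts must be non-negative")
    low = (counts < count_min).mean(axis=1) >= sample_frac
    kept = counts.loc[~low]
    if kept.empty:
        raise DataError("no genes survive the low-count filter")
    logger.info("count filter removed %d/%d genes", int(low.sum()), len(counts))
    norm = quantile_normalize(np.log2(kept + 1.0))
    high = (norm > signal_min).mean(axis=1) >= sample_frac
    expr = norm.loc[high]
    if expr.empty:
        raise DataError("no genes survive the signal filter")
    logger.info("signal filter retained %d/%d genes", len(expr), len(norm))
    return expr


# ---------------------------------------------------------------------------
# adjacency and topological overlap
# ---------------------------------------------------------------------------

def adjacency(expr: pd.DataFrame, params: NetworkParams | None = None) -> pd.DataFrame:
    """Soft-thresholded weighted adjacency a_ij = |cor(x_i, x_j)|^beta.

    The diagonal is set to zero (the connectivity convention).  Genes with
    zero variance cannot be correlated and are dropped with a log entry.
    """
    params = params or NetworkParams()
    if expr.shape[1] < 3:
        raise DataError("at least 3 samples are required for correlation")
    sd = expr.std(axis=1, ddof=0)
    if (sd == 0).any():
        dropped = list(expr.index[sd == 0])
        logger.warning("dropping %d zero-variance genes: %s", len(dropped), dropped[:10])
        expr = expr.loc[sd > 0]
    cor = np.corrcoef(expr.to_numpy(dtype=float))
    cor = np.clip(cor, -1.0, 1.0)
    if params.signed:
        adj = ((1.0 + cor) / 2.0) ** params.beta
    else:
        adj = np.abs(cor) ** params.beta
    np.fill_diagonal(adj, 0.0)
    return pd.DataFrame(adj, index=expr.index, columns=expr.index)


def connectivity(adj: pd.DataFrame) -> pd.Series:
    """Whole-network connectivity k_i = sum_j a_ij (zero diagonal assumed)."""
    return adj.sum(axis=1)


def fit_connectivity_powerlaw(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit on a connectivity vector.

    Connectivities are binned into ``n_bins`` equal-width bins; the log10
    relative frequency is regressed on the log10 mean connectivity of each
    non-empty bin.  Returns (r_squared, slope); the slope is negative for
    scale-free-like degree distributions.
    """
    k = np.asarray(k, dtype=float)
    if np.ptp(k) == 0:
        raise DataError("all connectivities equal; scale-free fit undefined")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    mean_k, freq = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        mean_k.append(k[mask].mean())
        freq.append(mask.mean())
    mean_k, freq = np.array(mean_k), np.array(freq)
    ok = (mean_k > 0) & (freq > 0)
    if ok.sum() < 2:
        raise DataError("fewer than 2 usable bins; scale-free fit undefined")
    fit = linregress(np.log10(mean_k[ok]), np.log10(freq[ok]))
    return float(fit.rvalue**2), float(fit.slope)


def scale_free_fit(adj: pd.DataFrame, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology criterion (R^2, slope) of an adjacency matrix."""
    return fit_connectivity_powerlaw(connectivity(adj).to_numpy(), n_bins=n_bins)


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """Unsigned topological overlap matrix (TOM) of a weighted adjacency.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j, where
    l_ij = sum_u a_iu a_uj counts shared-neighbour weight and
    k_i = sum_u a_iu; TOM_ii = 1.  High TOM means two genes are both
    directly correlated and embedded in the same neighbourhood.
    """
    A = adj.to_numpy(dtype=float)
    if A.shape[0] != A.shape[1]:
        raise DataError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-12):
        raise DataError("adjacency must be symmetric")
    if A.min() < 0 or A.max() > 1:
        raise DataError("adjacency entries must lie in [0, 1]")
    A = A.copy()
    np.fill_diagonal(A, 0.0)  # zero-diagonal convention
    L = A @ A  # the zero diagonal excludes u in {i, j} automatically
    k = A.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - A
    tom = (L + A) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)  # symmetrize rounding noise
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


# ---------------------------------------------------------------------------
# module detection and merging
# ---------------------------------------------------------------------------

def _canonicalize(labels: pd.Series) -> pd.Series:
    """Relabel modules GM1, GM2, ... by decreasing size.

    Ties are broken by the lexicographically smallest member gene so that
    the labelling is a pure function of the partition.
    """
    groups: dict[str, list[str]] = {}
    for gene, lab in labels.items():
        if lab != UNASSIGNED:
            groups.setdefault(lab, []).append(gene)
    order = sorted(groups, key=lambda m: (-len(groups[m]), min(groups[m])))
    mapping = {old: f"GM{i + 1}" for i, old in enumerate(order)}
    mapping[UNASSIGNED] = UNASSIGNED
    return labels.map(mapping).rename("module")


def detect_modules(tom: pd.DataFrame, params: NetworkParams | None = None) -> pd.Series:
    """Detect co-expression modules from a TOM matrix.

    Average-linkage hierarchical clustering on the dissimilarity 1 - TOM,
    cut statically at ``params.cut_height``; clusters smaller than
    ``params.min_module_size`` are labelled ``unassigned``.  Labels are
    deterministic: GM1 is the largest module.

    Returns
    -------
    Series
        gene -> module label, indexed like ``tom``.
    """
    params = params or NetworkParams()
    genes = tom.index
    if len(genes) < params.min_module_size:
        raise DataError("fewer genes than min_module_size")
    diss = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(diss, 0.0)
    Z = linkage(squareform(diss, checks=False), method=params.linkage_method)
    clusters = fcluster(Z, t=params.cut_height, criterion="distance")
    labels = pd.Series(
        [f"c{c}" for c in clusters], index=genes, name="module", dtype=object
    )
    sizes = labels.value_counts()
    small = sizes[sizes < params.min_module_size].index
    labels[labels.isin(small)] = UNASSIGNED
    if (labels == UNASSIGNED).all():
        logger.warning("tree cut at %.3f yields no module of size >= %d",
                       params.cut_height, params.min_module_size)
        return labels
    return _canonicalize(labels)


def merge_close_modules(
    partition: pd.Series,
    expr: pd.DataFrame,
    params: NetworkParams | None = None,
) -> pd.Series:
    """Merge modules whose eigengenes are nearly collinear.

    Iteratively merges the module pair with the smallest eigengene
    dissimilarity 1 - cor(ME_a, ME_b) while that dissimilarity is below
    ``params.merge_threshold``, recomputing eigengenes after every merge.
    Terminates because the module count strictly decreases.
    """
    from .eigengenes import module_eigengene  # local import avoids a cycle

    params = params or NetworkParams()
    labels = partition.copy()
    while True:
        modules = sorted(set(labels) - {UNASSIGNED})
        if len(modules) < 2:
            break
        eig = pd.DataFrame(
            {m: module_eigengene(expr, labels.index[labels == m]) for m in modules}
        ).T
        cor = np.corrcoef(eig.to_numpy())
        best: tuple[float, str, str] | None = None
        for i in range(len(modules)):
            for j in range(i + 1, len(modules)):
                d = 1.0 - cor[i, j]
                if best is None or d < best[0] - 1e-15:
                    best = (d, modules[i], modules[j])
        assert best is not None
        d, a, b = best
        if d >= params.merge_threshold:
            break
        keep, drop = (a, b) if (labels == a).sum() >= (labels == b).sum() else (b, a)
        logger.info("merging module %s into %s (ME dissimilarity %.4f)", drop, keep, d)
        labels[labels == drop] = keep
    return _canonicalize(labels)


def build_network(
    expr: pd.DataFrame, params: NetworkParams | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Adjacency -> TOM -> detected + merged modules in one call."""
    params = params or NetworkParams()
    tom = topological_overlap(adjacency(expr, params))
    partition = detect_modules(tom, params)
    if (partition != UNASSIGNED).any():
        partition = merge_close_modules(partition, expr.loc[tom.index], params)
    return tom, partition
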