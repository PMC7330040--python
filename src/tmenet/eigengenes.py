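"""Module eigengenes and their relation to clinical traits.

The eigengene of a module is the first principal component of its
standardized member expression: one score per sample summarizing the
module's dominant pattern.  Eigengenes are standardized to mean 0 / sd 1
and sign-oriented so that their mean correlation with member genes is
non-negative; the orientation makes them invariant to a global sign flip
of the member genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr, ttest_ind, ttest_rel
from statsmodels.stats.multitest import multipletests

from .network import UNASSIGNED, DataError

logger = logging.getLogger("tmenet")


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def module_eigengene(expr: pd.DataFrame, members: Iterable[str]) -> pd.Series:
    """First-principal-component summary of a module over samples.

    Member genes are standardized (mean 0, sd 1 per gene), the first right
    singular vector of the member block gives the sample scores, which are
    re-standardized and oriented so the mean correlation with member genes
    is >= 0.

    Parameters
    ----------
    expr : DataFrame
        Full genes x samples log2 expression matrix.
    members : iterable of str
        Gene ids of the module; members absent from ``expr`` are ignored.
    """
    members = [g for g in members if g in expr.index]
    if len(members) == 0:
        raise DataError("no module members present in the expression matrix")
    if expr.shape[1] < 3:
        raise DataError("at least 3 samples are required")
    X = expr.loc[members].to_numpy(dtype=float)
    keep = X.std(axis=1, ddof=0) > 0
    if not keep.all():
        logger.warning("dropping %d constant member genes", int((~keep).sum()))
        X = X[keep]
    if X.shape[0] == 0:
        raise DataError("all module members are constant")
    Z = _standardize_rows(X)
    if Z.shape[0] == 1:
        logger.warning("single-member module: eigengene is the standardized gene")
        pc = Z[0]
    else:
        _, _, vt = np.linalg.svd(Z, full_matrices=False)
        pc = vt[0]
    pc = (pc - pc.mean()) / pc.std(ddof=0)
    # orient: mean member correlation (= mean of Z @ pc / n) must be >= 0
    mean_cor = float((Z @ pc).mean() / Z.shape[1])
    if mean_cor < 0 or (mean_cor == 0 and pc[np.nonzero(pc)[0][0]] < 0):
        pc = -pc
    return pd.Series(pc, index=expr.columns, name="eigengene")


def eigengene_matrix(expr: pd.DataFrame, partition: pd.Series) -> pd.DataFrame:
    """Eigengenes for every assigned module: modules x samples.

    Module rows follow the partition's canonical label order (GM1, GM2, ...);
    ``unassigned`` genes contribute no eigengene.
    """
    modules = sorted(set(partition) - {UNASSIGNED},
                     key=lambda m: (len(m), m))  # GM2 < GM10
    if not modules:
        raise DataError("partition contains no assigned module")
    rows = {m: module_eigengene(expr, partition.index[partition == m])
            for m in modules}
    return pd.DataFrame(rows).T.rename_axis("module")


def module_trait_correlation(
    eig: pd.DataFrame, traits: pd.DataFrame | pd.Series
) -> pd.DataFrame:
    """Pearson correlation of each eigengene with each trait.

    Traits may be binary (coded 0/1) or numeric.  Two-sided p-values come
    from the t distribution with n-2 df; Benjamini-Hochberg FDR is applied
    across modules separately for each trait.

    Returns a tidy table (module, trait, r, p, fdr).
    """
    if isinstance(traits, pd.Series):
        traits = traits.to_frame()
    traits = traits.loc[eig.columns]
    rows = []
    for trait in traits.columns:
        t = traits[trait].to_numpy(dtype=float)
        if np.ptp(t) == 0:
            raise DataError(f"trait {trait!r} is constant; correlation undefined")
        ps = []
        for m in eig.index:
            r, p = pearsonr(eig.loc[m].to_numpy(dtype=float), t)
            rows.append({"module": m, "trait": trait, "r": float(r), "p": float(p)})
            ps.append(p)
        fdr = multipletests(ps, method="fdr_bh")[1]
        for row, q in zip(rows[-len(ps):], fdr):
            row["fdr"] = float(q)
    return pd.DataFrame(rows)


def module_group_tests(
    eig: pd.DataFrame,
    samples: pd.DataFrame,
    comparison: Sequence[str],
    paired: bool = False,
) -> pd.DataFrame:
    """Per-module two-group comparison of eigengene values.

    Unpaired comparisons use Welch's two-sample t test; paired comparisons
    match samples of the two groups by patient id and use the paired t
    test.  BH FDR is applied across modules.

    Parameters
    ----------
    samples : DataFrame
        Sample annotation indexed by sample id with columns ``group`` and
        (for paired tests) ``patient``.
    comparison : (group_a, group_b)
    """
    ga, gb = comparison
    ids_a = samples.index[samples["group"] == ga]
    ids_b = samples.index[samples["group"] == gb]
    ids_a = [s for s in ids_a if s in eig.columns]
    ids_b = [s for s in ids_b if s in eig.columns]
    if not ids_a or not ids_b:
        raise DataError(f"both groups {ga!r} and {gb!r} must be present")
    if paired:
        pat_a = {samples.loc[s, "patient"]: s for s in ids_a}
        pat_b = {samples.loc[s, "patient"]: s for s in ids_b}
        shared = sorted(set(pat_a) & set(pat_b))
        orphans = sorted(set(pat_a) ^ set(pat_b))
        if orphans:
            raise DataError(f"unmatched patients for paired test: {orphans}")
        if not shared:
            raise DataError("no matched patient pairs")
        ids_a = [pat_a[p] for p in shared]
        ids_b = [pat_b[p] for p in shared]
    rows = []
    for m in eig.index:
        a = eig.loc[m, ids_a].to_numpy(dtype=float)
        b = eig.loc[m, ids_b].to_numpy(dtype=float)
        if paired:
            stat, p = ttest_rel(a, b)
        else:
            stat, p = ttest_ind(a, b, equal_var=False)
        if np.isnan(p):  # both groups constant and equal
            stat, p = 0.0, 1.0
        rows.append({"module": m, "statistic": float(stat), "p": float(p)})
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


@dataclass
class Dendrogram:
    """Average-linkage dendrogram with deterministic leaf order."""

    linkage_matrix: np.ndarray
    labels: list[str]

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in leaves_list(self.linkage_matrix)]

    def to_newick(self) -> str:
        """Serialize to a Newick string with branch lengths."""
        root = to_tree(self.linkage_matrix)

        def rec(node, parent_dist: float) -> str:
            length = max(parent_dist - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            return (f"({rec(node.left, node.dist)},{rec(node.right, node.dist)})"
                    f":{length:.6g}")

        return f"({rec(root.left, root.dist)},{rec(root.right, root.dist)});"


def cluster_eigengenes(
    eig: pd.DataFrame, trait: pd.Series | None = None
) -> Dendrogram:
    """Hierarchically cluster eigengenes (optionally with a trait leaf).

    The trait, if given, is standardized and appended as a pseudo-eigengene
    so its position in the dendrogram shows which modules track it.
    Average linkage on the dissimilarity 1 - Pearson correlation.
    """
    if len(eig) < 2:
        raise DataError("at least 2 eigengenes are required")
    M = eig.copy()
    if trait is not None:
        t = trait.loc[eig.columns].to_numpy(dtype=float)
        if np.ptp(t) == 0:
            raise DataError("constant trait cannot be clustered")
        M.loc[trait.name or "trait"] = (t - t.mean()) / t.std(ddof=0)
    cor = np.corrcoef(M.to_numpy(dtype=float))
    diss = np.clip(1.0 - cor, 0.0, 2.0)
    np.fill_diagonal(diss, 0.0)
    Z = linkage(squareform(diss, checks=False), method="average")
    return Dendrogram(Z, list(M.index))


def score_modules_external(
    expr_ext: pd.DataFrame, partition: pd.Series, min_members: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recompute module eigengenes in an external expression cohort.

    Members absent from the external matrix are dropped (never imputed);
    modules with fewer than ``min_members`` surviving genes are skipped
    with a warning.  Returns the external eigengene matrix and a coverage
    report (module, n_members, n_present, coverage) so users can judge
    how transferable each score is.
    """
    rows, cov = {}, []
    for m in sorted(set(partition) - {UNASSIGNED}, key=lambda s: (len(s), s)):
        members = list(partition.index[partition == m])
        present = [g for g in members if g in expr_ext.index]
        cov.append({"module": m, "n_members": len(members),
                    "n_present": len(present),
                    "coverage": len(present) / len(members)})
        if len(present) < min_members:
            logger.warning("module %s: only %d/%d members present; skipped",
                           m, len(present), len(members))
            continue
        rows[m] = module_eigengene(expr_ext, present)
    if not rows:
        raise DataError("no module has enough members in the external matrix")
    return pd.DataFrame(rows).T.rename_axis("module"), pd.DataFrame(cov)
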