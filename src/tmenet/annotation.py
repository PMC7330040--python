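"""Module annotation: cell-type enrichment, signature overlap, gene-set
enrichment and hub/connectivity structure.

Modules discovered in bulk tumor expression are interpreted by (i) scoring
them in purified cell-type reference profiles and testing the scores with
one-way ANOVA, (ii) overlapping their member lists with curated signatures
(EMT, angiogenesis, immune phenotypes, ...) against a random-signature
null of identical size, (iii) hypergeometric over-representation of gene
sets among a hit list, plus a ranked-list minimum-hypergeometric (mHG)
score, and (iv) ranking hub genes by intramodular connectivity (the sum of
a gene's topological-overlap values to its module mates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, f_oneway, fisher_exact, hypergeom
from statsmodels.stats.multitest import multipletests

from .network import UNASSIGNED, DataError

logger = logging.getLogger("tmenet")


@dataclass
class ReferenceProfiles:
    """Expression of purified cell populations.

    ``expression`` is genes x profile-samples; ``celltypes`` maps each
    profile sample to its cell-type label (>= 2 types, >= 1 profile each).
    """

    expression: pd.DataFrame
    celltypes: pd.Series

    def __post_init__(self) -> None:
        self.celltypes = self.celltypes.loc[self.expression.columns]
        if self.celltypes.nunique() < 2:
            raise DataError("reference profiles need at least 2 cell types")


# ---------------------------------------------------------------------------
# cell-type enrichment
# ---------------------------------------------------------------------------

def celltype_enrichment_anova(
    refs: ReferenceProfiles, partition: pd.Series
) -> pd.DataFrame:
    """One-way ANOVA of per-profile module scores across cell types.

    The module score of a reference profile is the mean of the member
    genes' standardized expression (PC-1 is unstable at the small profile
    counts typical of purified references, so the mean is used).  Returns
    a table (module, F, p, fdr, enrichment_score, top_celltype); modules
    with fewer than 2 member genes in the references are skipped with a
    warning.
    """
    X = refs.expression.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    Z = pd.DataFrame((X - mu) / sd, index=refs.expression.index,
                     columns=refs.expression.columns)
    types = sorted(refs.celltypes.unique())
    rows = []
    for m in sorted(set(partition) - {UNASSIGNED}, key=lambda s: (len(s), s)):
        members = [g for g in partition.index[partition == m] if g in Z.index]
        if len(members) < 2:
            logger.warning("module %s has <2 members in references; skipped", m)
            continue
        score = Z.loc[members].mean(axis=0)
        groups = [score[refs.celltypes == t].to_numpy() for t in types]
        F, p = f_oneway(*groups)
        if np.isnan(F):  # all profile scores identical
            F, p = 0.0, 1.0
        means = {t: g.mean() for t, g in zip(types, groups)}
        rows.append({
            "module": m, "F": float(F), "p": float(p),
            "top_celltype": max(types, key=lambda t: means[t]),
        })
    if not rows:
        raise DataError("no module could be scored in the reference profiles")
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    out["enrichment_score"] = -np.log10(np.maximum(out["p"], 1e-300))
    return out


# ---------------------------------------------------------------------------
# signature overlap with random-signature null
# ---------------------------------------------------------------------------

def signature_overlap(
    partition: pd.Series,
    signatures: dict[str, set[str]],
    universe: set[str] | None = None,
    n_null: int = 1000,
    seed: int = 0,
    test: str = "chi2",
) -> pd.DataFrame:
    """Size-corrected module/signature overlap with a random-signature null.

    The observed statistic is
    ``overlap_pct = 100 * |module & signature| / |module|``, which corrects
    for variable module size.  The null distribution comes from ``n_null``
    random gene sets of the signature's size drawn uniformly from the
    universe (summarized as ``null_mean_pct`` / ``null_sd_pct`` for the
    hollow-bar display; set ``n_null=0`` to skip).  The p-value tests the
    2x2 membership table (module&sig, module-only, sig-only, neither) with
    a chi-square test without continuity correction; ``test="fisher"``
    switches to Fisher's exact test.
    """
    if test not in {"chi2", "fisher"}:
        raise ValueError("test must be 'chi2' or 'fisher'")
    if universe is None:
        universe = set(partition.index)
    universe_idx = {g: i for i, g in enumerate(sorted(universe))}
    N = len(universe_idx)
    rng = np.random.default_rng(seed)
    rows = []
    for m in sorted(set(partition) - {UNASSIGNED}, key=lambda s: (len(s), s)):
        module = set(partition.index[partition == m]) & universe
        if not module:
            logger.warning("module %s has no genes in the universe; skipped", m)
            continue
        module_mask = np.zeros(N, dtype=bool)
        module_mask[[universe_idx[g] for g in module]] = True
        for name, sig in signatures.items():
            if len(sig) > N:
                raise DataError(f"signature {name!r} exceeds the universe")
            sig_u = set(sig) & universe
            k = len(module & sig_u)
            table = np.array([
                [k, len(module) - k],
                [len(sig_u) - k, N - len(module) - len(sig_u) + k],
            ])
            if test == "chi2":
                if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
                    p = 1.0
                else:
                    p = float(chi2_contingency(table, correction=False)[1])
            else:
                p = float(fisher_exact(table, alternative="two-sided")[1])
            if n_null > 0:
                null_pct = np.empty(n_null)
                for i in range(n_null):
                    draw = rng.choice(N, size=len(sig_u), replace=False)
                    null_pct[i] = 100.0 * module_mask[draw].sum() / len(module)
                null_mean = float(null_pct.mean())
                null_sd = float(null_pct.std(ddof=1))
            else:
                null_mean = null_sd = float("nan")
            rows.append({
                "module": m, "signature": name,
                "overlap_count": int(k), "module_size": len(module),
                "overlap_pct": 100.0 * k / len(module),
                "null_mean_pct": null_mean, "null_sd_pct": null_sd,
                "p": p,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# hypergeometric over-representation
# ---------------------------------------------------------------------------

def ora_hypergeometric(
    hits: set[str], gene_sets: dict[str, set[str]], universe: set[str]
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of gene sets in hits.

    For each set, p = P(X >= overlap) with X hypergeometric(N=|universe|,
    K=|set|, n=|hits|); BH FDR across sets and enrichment score
    -log10(p) are added.  Empty hit lists give p = 1 everywhere.
    """
    if not hits <= universe:
        raise DataError("hits must be a subset of the universe")
    N, n = len(universe), len(hits)
    rows = []
    for name, s in gene_sets.items():
        s_u = set(s) & universe
        k = len(hits & s_u)
        p = 1.0 if n == 0 else float(hypergeom.sf(k - 1, N, len(s_u), n))
        rows.append({"gene_set": name, "set_size": len(s_u),
                     "overlap": k, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    out["enrichment_score"] = -np.log10(np.maximum(out["p"], 1e-300))
    return out


def ranked_min_hypergeometric(
    ranked_universe: list[str],
    gene_set: set[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Minimum hypergeometric (mHG) enrichment score on a ranked gene list.

    For every prefix length n, HGT(n) is the upper-tail hypergeometric
    probability of observing at least ``|gene_set & top-n|`` set members in
    the top n; the mHG score is ``min_n HGT(n)`` over n = 1..N-1.  Its
    p-value is estimated by ``n_perm`` random rank permutations with the
    add-one correction, so the smallest attainable p is 1/(n_perm+1).
    """
    if not gene_set:
        raise DataError("gene_set must be nonempty")
    if not set(gene_set) <= set(ranked_universe):
        raise DataError("gene_set must be contained in the ranked universe")
    N = len(ranked_universe)
    B = len(gene_set)
    member = np.array([g in gene_set for g in ranked_universe])

    def mhg(mask: np.ndarray) -> float:
        b = np.cumsum(mask)[:-1]  # prefixes n = 1..N-1
        n = np.arange(1, N)
        return float(hypergeom.sf(b - 1, N, B, n).min())

    score = mhg(member)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if mhg(rng.permutation(member)) <= score:
            hits += 1
    return score, (hits + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# connectivity, hubs, and network export
# ---------------------------------------------------------------------------

def intramodular_connectivity(
    tom: pd.DataFrame, partition: pd.Series
) -> pd.DataFrame:
    """Intramodular connectivity kIM and hub rank of every gene.

    kIM(g) = sum of TOM(g, h) over the other genes h of g's module; rank 1
    is the module hub (ties broken by gene id).  Unassigned genes get
    kIM = NaN and no rank.
    """
    partition = partition.loc[tom.index]
    rows = []
    for m in sorted(set(partition), key=lambda s: (len(s), s)):
        members = list(partition.index[partition == m])
        if m == UNASSIGNED:
            rows += [{"gene": g, "module": m, "kIM": np.nan, "rank": np.nan}
                     for g in members]
            continue
        sub = tom.loc[members, members].to_numpy(dtype=float)
        kim = sub.sum(axis=1) - np.diag(sub)
        order = sorted(range(len(members)), key=lambda i: (-kim[i], members[i]))
        rank = {members[i]: r + 1 for r, i in enumerate(order)}
        rows += [{"gene": g, "module": m, "kIM": float(k), "rank": rank[g]}
                 for g, k in zip(members, kim)]
    return pd.DataFrame(rows)


def hub_neighborhood(
    gene: str,
    tom: pd.DataFrame,
    partition: pd.Series,
    n_per_module: int = 10,
    modules: list[str] | None = None,
) -> pd.DataFrame:
    """Top TOM neighbours of a focal gene within each requested module.

    Returns an edge list (source, target, module, weight) of the
    ``n_per_module`` highest-TOM genes of each module relative to the
    focal gene (ties broken by gene id; whole module returned when it is
    smaller than ``n_per_module``).
    """
    if gene not in tom.index:
        raise DataError(f"unknown gene {gene!r}")
    partition = partition.loc[tom.index]
    if modules is None:
        modules = sorted(set(partition) - {UNASSIGNED}, key=lambda s: (len(s), s))
    rows = []
    for m in modules:
        members = [g for g in partition.index[partition == m] if g != gene]
        ranked = sorted(members, key=lambda g2: (-tom.loc[gene, g2], g2))
        for g2 in ranked[:n_per_module]:
            rows.append({"source": gene, "target": g2, "module": m,
                         "weight": float(tom.loc[gene, g2])})
    return pd.DataFrame(rows)


def top_edges(tom: pd.DataFrame, quantile: float = 0.99) -> pd.DataFrame:
    """Global edge list above a TOM quantile, for network rendering.

    Off-diagonal TOM values at or above the given quantile are exported as
    (source, target, weight), each undirected pair once, sorted by
    decreasing weight then gene ids.
    """
    A = tom.to_numpy(dtype=float)
    iu = np.triu_indices_from(A, k=1)
    w = A[iu]
    thr = np.quantile(w, quantile)
    keep = w >= thr
    genes = np.asarray(tom.index)
    out = pd.DataFrame({
        "source": genes[iu[0][keep]],
        "target": genes[iu[1][keep]],
        "weight": w[keep],
    })
    return out.sort_values(
        ["weight", "source", "target"], ascending=[False, True, True]
    ).reset_index(drop=True)
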