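"""Gene-level somatic copy-number classification and SNV filtering.

Copy number: segmented absolute copy-number calls are mapped onto gene
models (1-based, fully-closed coordinates) and each sample x gene pair is
classified into five categories::

    deletion       CN < 1.0
    loss           1.0 <= CN < 1.85
    diploid        1.85 <= CN <= 2.15
    gain           2.15 < CN <= 4.0
    amplification  CN > 4.0

When a gene spans several segments the copy number most deviating from 2
is selected -- except that any overlapping segment with CN < 1.0 forces
the deletion category regardless of other segments.

Somatic SNVs: a cascade of read-support, allele-frequency and statistical
filters (boundary-inclusive thresholds), with a per-rule audit of first
failures.  A BLOSUM80-derived severity ordering ranks mutation
consequences: missense < inframe indel < splice < frameshift = nonsense.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .eigengenes import Dendrogram
from .network import DataError

logger = logging.getLogger("tmenet")


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CNSegment:
    """A segmented absolute copy-number call (1-based, closed interval)."""

    sample: str
    chrom: str
    start: int
    end: int
    cn: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DataError(f"segment start > end: {self}")
        if self.cn < 0:
            raise DataError(f"negative copy number: {self}")


@dataclass(frozen=True)
class GeneModel:
    """Genomic extent of a gene (1-based, closed interval)."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DataError(f"gene start > end: {self}")


def bed_to_gene_models(bed: pd.DataFrame) -> list[GeneModel]:
    """Convert half-open 0-based BED rows (chrom, start, end, name) to
    1-based closed gene models."""
    return [GeneModel(gene=r["name"], chrom=r["chrom"],
                      start=int(r["start"]) + 1, end=int(r["end"]))
            for _, r in bed.iterrows()]


@dataclass(frozen=True)
class GeneCNCall:
    sample: str
    gene: str
    selected_cn: float
    category: str


@dataclass
class VariantRecord:
    """A somatic variant call with the fields the filter cascade consumes.

    ``n_supporting`` is the supporting-read count in the matched normal;
    whether a caller reports alt-supporting or reference-supporting
    coverage there differs between tools, so the field is named neutrally
    and either semantics can be supplied.  ``p_somatic`` is the somatic
    Fisher-exact p-value of the tumor/normal read-count contrast.
    """

    sample: str
    patient: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    mutation_type: str
    t_alt_reads: int
    n_supporting: int
    vaf_tumor: float
    vaf_normal: float
    p_somatic: float
    dist_read_end: int
    p_base_quality: Optional[float] = None
    p_mapping_quality: Optional[float] = None
    p_strand_bias: Optional[float] = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Variant identity used for concordance: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)


# ---------------------------------------------------------------------------
# copy-number classification
# ---------------------------------------------------------------------------

CN_CATEGORIES = ("deletion", "loss", "diploid", "gain", "amplification")


def cn_category(cn: float) -> str:
    """Map an absolute copy number to its five-way category."""
    if cn < 1.0:
        return "deletion"
    if cn < 1.85:
        return "loss"
    if cn <= 2.15:
        return "diploid"
    if cn <= 4.0:
        return "gain"
    return "amplification"


def _check_non_overlapping(segments: Sequence[CNSegment]) -> None:
    by_key: dict[tuple[str, str], list[CNSegment]] = {}
    for s in segments:
        by_key.setdefault((s.sample, s.chrom), []).append(s)
    for (sample, chrom), segs in by_key.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:  # closed intervals overlap
                raise DataError(
                    f"overlapping segments for {sample} on {chrom}: "
                    f"[{a.start},{a.end}] and [{b.start},{b.end}]")


def classify_gene_copy_number(
    segments: Sequence[CNSegment], genes: Sequence[GeneModel]
) -> list[GeneCNCall]:
    """Per sample x gene copy-number category from segment overlaps.

    Any base overlap counts (closed-interval arithmetic).  Among a gene's
    overlapping segments the CN most deviating from 2 is selected (ties at
    equal deviation resolve to the lower CN, logged); a segment with
    CN < 1.0 forces the deletion category.  Genes with no overlapping
    segment produce no call and are reported in the log.
    """
    _check_non_overlapping(segments)
    segs_by: dict[tuple[str, str], list[CNSegment]] = {}
    samples: set[str] = set()
    for s in segments:
        segs_by.setdefault((s.sample, s.chrom), []).append(s)
        samples.add(s.sample)
    calls: list[GeneCNCall] = []
    n_uncovered = 0
    for sample in sorted(samples):
        for g in genes:
            cns = [s.cn for s in segs_by.get((sample, g.chrom), [])
                   if s.start <= g.end and s.end >= g.start]
            if not cns:
                n_uncovered += 1
                continue
            deleted = [c for c in cns if c < 1.0]
            if deleted:
                chosen = min(deleted)
                cat = "deletion"
            else:
                best = max(abs(c - 2.0) for c in cns)
                cands = [c for c in cns if abs(c - 2.0) == best]
                chosen = min(cands)  # tie at equal deviation -> loss side
                if len(set(cands)) > 1:
                    logger.info("CN tie for %s/%s resolved to lower CN %.3f",
                                sample, g.gene, chosen)
                cat = cn_category(chosen)
            calls.append(GeneCNCall(sample, g.gene, float(chosen), cat))
    if n_uncovered:
        logger.info("%d sample x gene pairs had no overlapping segment",
                    n_uncovered)
    return calls


# ---------------------------------------------------------------------------
# SNV filter cascade
# ---------------------------------------------------------------------------

@dataclass
class FilterThresholds:
    """Thresholds of the somatic SNV filter cascade (boundary-inclusive)."""

    min_tumor_reads: int = 8
    min_normal_reads: int = 6
    min_vaf_tumor: float = 0.1
    max_vaf_normal: float = 0.1
    max_p_somatic: float = 0.05
    min_dist_read_end: int = 5
    alpha_screens: float = 0.05


#: cascade order; each entry is (rule name, predicate(variant, thresholds))
_RULES = (
    ("min_tumor_reads", lambda v, t: v.t_alt_reads >= t.min_tumor_reads),
    ("min_normal_reads", lambda v, t: v.n_supporting >= t.min_normal_reads),
    ("min_vaf_tumor", lambda v, t: v.vaf_tumor >= t.min_vaf_tumor),
    ("max_vaf_normal", lambda v, t: v.vaf_normal <= t.max_vaf_normal),
    ("p_somatic", lambda v, t: v.p_somatic <= t.max_p_somatic),
    ("dist_read_end", lambda v, t: v.dist_read_end >= t.min_dist_read_end),
    ("base_quality", lambda v, t: v.p_base_quality >= t.alpha_screens),
    ("mapping_quality", lambda v, t: v.p_mapping_quality >= t.alpha_screens),
    ("strand_bias", lambda v, t: v.p_strand_bias >= t.alpha_screens),
)

_SCREEN_FIELDS = ("p_base_quality", "p_mapping_quality", "p_strand_bias")


def filter_somatic_snvs(
    variants: Iterable[VariantRecord],
    thresholds: FilterThresholds | None = None,
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Apply the somatic SNV filter cascade.

    A variant passes when every rule holds: tumor supporting reads >= 8,
    normal supporting reads >= 6, tumor VAF >= 0.1, normal VAF <= 0.1,
    somatic Fisher p <= 0.05, distance of the variant base from the read
    end (or beginning) >= 5, and the base-quality / mapping-quality /
    strand-bias screens are non-significant at alpha (a screen flags an
    artifact when its p-value falls below alpha).

    Variants missing a screen p-value cannot be fully evaluated; they are
    counted as ``not_evaluable`` and never passed.  The audit maps each
    rule to its rejection count with first-failing-rule attribution, plus
    ``passed`` and ``not_evaluable`` entries; audit rule counts sum to
    input - passed - not_evaluable.
    """
    thresholds = thresholds or FilterThresholds()
    audit = {name: 0 for name, _ in _RULES}
    audit["passed"] = 0
    audit["not_evaluable"] = 0
    passed: list[VariantRecord] = []
    for v in variants:
        failed = None
        for name, rule in _RULES:
            if name in ("base_quality", "mapping_quality", "strand_bias"):
                pval = getattr(v, "p_" + name)
                if pval is None or (isinstance(pval, float) and np.isnan(pval)):
                    failed = "not_evaluable"
                    break
            if not rule(v, thresholds):
                failed = name
                break
        if failed is None:
            passed.append(v)
            audit["passed"] += 1
        else:
            audit[failed] += 1
    return passed, audit


# ---------------------------------------------------------------------------
# mutation severity
# ---------------------------------------------------------------------------

#: BLOSUM80-derived consequence ordering; frameshift and nonsense tie at the top
SEVERITY_ORDER = {
    "missense": 1,
    "inframe_indel": 2,
    "splice": 3,
    "frameshift_indel": 4,
    "nonsense": 4,
}


def severity_rank(mutation_type: str) -> int:
    """Ordinal severity of a mutation consequence (0 = outside the ordering)."""
    rank = SEVERITY_ORDER.get(mutation_type)
    if rank is None:
        if mutation_type not in ("synonymous", "other"):
            logger.warning("unknown mutation type %r; severity 0", mutation_type)
        return 0
    return rank


def max_severity_per_gene(variants: Iterable[VariantRecord]) -> pd.DataFrame:
    """Maximum severity rank per sample x gene (tidy table)."""
    best: dict[tuple[str, str], int] = {}
    for v in variants:
        key = (v.sample, v.gene)
        best[key] = max(best.get(key, 0), severity_rank(v.mutation_type))
    return pd.DataFrame(
        [{"sample": s, "gene": g, "severity": r} for (s, g), r in sorted(best.items())]
    )


# ---------------------------------------------------------------------------
# group frequencies, concordance, mutation-profile clustering
# ---------------------------------------------------------------------------

def alteration_frequencies_and_tests(
    variants: Sequence[VariantRecord],
    cn_calls: Sequence[GeneCNCall],
    samples: pd.DataFrame,
    groups: Sequence[str],
    include_cn: bool = True,
) -> pd.DataFrame:
    """Per-gene alteration frequencies in two groups with Fisher tests.

    A sample is altered in a gene when it carries a passing non-synonymous
    mutation (severity rank >= 1) or, when ``include_cn``, an
    amplification or deletion call.  Reports per-group altered fractions,
    the two-sided Fisher exact p of the 2x2 gene x group table, and BH FDR
    across genes.
    """
    ga, gb = groups
    ids_a = set(samples.index[samples["group"] == ga])
    ids_b = set(samples.index[samples["group"] == gb])
    if not ids_a or not ids_b:
        raise DataError(f"both groups {ga!r} and {gb!r} must be nonempty")
    altered: dict[str, set[str]] = {}
    for v in variants:
        if severity_rank(v.mutation_type) >= 1:
            altered.setdefault(v.gene, set()).add(v.sample)
    if include_cn:
        for c in cn_calls:
            if c.category in ("amplification", "deletion"):
                altered.setdefault(c.gene, set()).add(c.sample)
    rows = []
    for gene in sorted(altered):
        hit = altered[gene]
        a1, b1 = len(hit & ids_a), len(hit & ids_b)
        if a1 == 0 and b1 == 0:
            continue
        table = [[a1, len(ids_a) - a1], [b1, len(ids_b) - b1]]
        p = float(fisher_exact(table, alternative="two-sided")[1])
        rows.append({
            "gene": gene,
            f"freq_{ga}": a1 / len(ids_a), f"freq_{gb}": b1 / len(ids_b),
            f"n_{ga}": a1, f"n_{gb}": b1, "p": p,
        })
    if not rows:
        raise DataError("no altered gene observed in either group")
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def pairwise_concordance(
    variants: Sequence[VariantRecord],
    samples: pd.DataFrame,
    group_a: str,
    group_b: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shared-variant concordance between matched samples of two groups.

    Variant identity is (chrom, pos, ref, alt).  For each patient with one
    sample in each group, concordance = shared / (shared + a_only +
    b_only).  Patients missing one side are excluded with a log entry.
    Returns (per-patient table, per-gene table); the per-gene table pools
    shared/private counts over patients within each gene.
    """
    sample_group = samples["group"]
    sample_patient = samples["patient"]
    by_sample: dict[str, set] = {}
    gene_of: dict[tuple, str] = {}
    for v in variants:
        by_sample.setdefault(v.sample, set()).add(v.key)
        gene_of[v.key] = v.gene
    side_a = {sample_patient[s]: s for s in samples.index
              if sample_group[s] == group_a}
    side_b = {sample_patient[s]: s for s in samples.index
              if sample_group[s] == group_b}
    rows, gene_counts = [], {}
    for patient in sorted(set(side_a) | set(side_b)):
        if patient not in side_a or patient not in side_b:
            logger.info("patient %s lacks a %s/%s pair; excluded",
                        patient, group_a, group_b)
            continue
        va = by_sample.get(side_a[patient], set())
        vb = by_sample.get(side_b[patient], set())
        shared, a_only, b_only = va & vb, va - vb, vb - va
        total = len(shared) + len(a_only) + len(b_only)
        rows.append({
            "patient": patient, "shared": len(shared),
            "a_only": len(a_only), "b_only": len(b_only),
            "concordance": len(shared) / total if total else float("nan"),
        })
        for key in shared:
            d = gene_counts.setdefault(gene_of[key], [0, 0])
            d[0] += 1
        for key in a_only | b_only:
            d = gene_counts.setdefault(gene_of[key], [0, 0])
            d[1] += 1
    if not rows:
        raise DataError(f"no patient has samples in both {group_a} and {group_b}")
    per_gene = pd.DataFrame(
        [{"gene": g, "shared": s, "private": pvt,
          "concordance": s / (s + pvt) if s + pvt else float("nan")}
         for g, (s, pvt) in sorted(gene_counts.items())]
    )
    return pd.DataFrame(rows), per_gene


def cluster_mutation_profiles(
    variants: Sequence[VariantRecord], samples: pd.DataFrame
) -> Dendrogram:
    """Average-linkage clustering of samples by Jaccard mutation distance.

    Samples are encoded as binary vectors over all observed variant sites;
    the Jaccard distance 1 - |A&B|/|A|B| drives average-linkage
    clustering.  A sample with zero variants is at distance 1 from every
    other sample (logged).
    """
    ids = list(samples.index)
    if len(ids) < 2:
        raise DataError("at least 2 samples are required")
    sites = sorted({v.key for v in variants})
    site_idx = {k: i for i, k in enumerate(sites)}
    M = np.zeros((len(ids), len(sites)), dtype=bool)
    pos = {s: i for i, s in enumerate(ids)}
    for v in variants:
        if v.sample in pos:
            M[pos[v.sample], site_idx[v.key]] = True
    empty = [s for s in ids if not M[pos[s]].any()]
    if empty:
        logger.warning("samples with zero variants (distance 1 to all): %s", empty)
    inter = (M.astype(int) @ M.T.astype(int)).astype(float)
    counts = M.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = 1.0 - np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    return Dendrogram(Z, ids)
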