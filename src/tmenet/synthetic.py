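"""Synthetic matched-trio cohort generator with planted ground truth.

Emulates the statistical structure of a colorectal-cancer liver-metastasis
cohort: four sample groups (AN adjacent normal, CNM primary without
metastasis, CWM primary with metastasis, CLM matched liver metastasis),
block-correlated expression with planted co-expression modules driven by
latent factors, a binary metastasis trait that shifts chosen module
factors in the CWM/CLM groups, purified cell-type reference profiles in
which designated modules are elevated, absolute-copy-number segments
tiling a small genome, matched primary/metastasis somatic variant tables
with controllable concordance, and survival times whose hazard depends on
module activity.

The factor model: member gene g of module m has expression
``base_g + lambda_g * f_m + eps`` with ``f_m ~ N(group shift, 1)`` per
sample, ``lambda_g ~ U(loading_range)`` and ``eps ~ N(0, noise_sd^2)``;
the expected within-module correlation is ``lambda^2 / (lambda^2 +
noise_sd^2)``.  Background genes are pure noise and carry the reserved
truth label ``unassigned``.  Counts are obtained by exponentiation plus
Poisson noise at a configurable depth, so the count-filter stage has real
work to do.

Everything is driven by one ``numpy`` Generator: identical config + seed
gives bit-identical cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alterations import CNSegment, GeneModel, VariantRecord
from .annotation import ReferenceProfiles
from .eigengenes import eigengene_matrix
from .network import UNASSIGNED
from .outcome import SurvivalRecord

logger = logging.getLogger("tmenet")


class ConfigError(ValueError):
    """Raised when a cohort configuration is internally inconsistent."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SegmentParams:
    """Copy-number segment generation: a small 3-chromosome genome tiled by
    exponential-length segments whose category frequencies are controlled."""

    chrom_lengths: Mapping[str, int] = field(default_factory=lambda: {
        "chr1": 120_000_000, "chr2": 100_000_000, "chr3": 80_000_000})
    mean_segment_length: float = 8_000_000.0
    min_segment_length: int = 100_000
    category_probs: Mapping[str, float] = field(default_factory=lambda: {
        "deletion": 0.05, "loss": 0.15, "diploid": 0.50,
        "gain": 0.20, "amplification": 0.10})

    #: absolute-CN band sampled uniformly within each category
    CN_BANDS = {
        "deletion": (0.0, 1.0), "loss": (1.0, 1.85), "diploid": (1.85, 2.15),
        "gain": (2.15, 4.0), "amplification": (4.0, 8.0),
    }


@dataclass
class VariantParams:
    """Somatic variant generation for matched primary/metastasis pairs.

    ``concordance`` is the value ``pairwise_concordance`` should measure:
    with per-sample mutation count n, the shared-site count is
    s = n * 2c / (1 + c) so that s / (s + 2(n - s)) = c.  Shared sites
    reuse one set of filter-field draws on both sides (same DNA context),
    so filtering removes them symmetrically and the measured concordance
    stays at c.  ``fail_fraction`` is the per-rule probability that a
    variant is drawn violating that filter rule.  ``driver_probs`` gives
    per-group probabilities of a guaranteed-passing missense mutation in a
    designated driver gene (shared within a primary/metastasis pair).
    """

    mean_mutations: float = 60.0
    concordance: float = 0.9
    fail_fraction: float = 0.02
    driver_probs: Mapping[str, float] = field(default_factory=lambda: {
        "CNM": 0.5, "CWM": 0.05, "CLM": 0.05})
    type_probs: Mapping[str, float] = field(default_factory=lambda: {
        "missense": 0.55, "synonymous": 0.18, "nonsense": 0.06,
        "splice": 0.05, "frameshift_indel": 0.08, "inframe_indel": 0.04,
        "other": 0.04})


@dataclass
class SurvivalParams:
    """Exponential event times with log-hazard linear in module eigengenes;
    independent exponential censoring at the stated expected rate."""

    baseline_hazard: float = 0.025  # events per month; median ~28 months
    coefficients: Mapping[int, float] = field(default_factory=lambda: {0: 0.9})
    censoring_rate: float = 0.3


@dataclass
class SyntheticCohortConfig:
    """Full specification of a synthetic matched-trio cohort."""

    n_genes: int = 2000
    module_sizes: Sequence[int] = (300, 250, 200, 150, 100)
    n_background_genes: int = 1000
    samples_per_group: Mapping[str, int] = field(default_factory=lambda: {
        "AN": 8, "CNM": 12, "CWM": 22, "CLM": 22})
    loading_range: tuple[float, float] = (0.7, 0.95)
    noise_sd: float = 0.5
    background_sd: float = 0.8
    trait_effects: Mapping[int, Mapping[str, float]] = field(
        default_factory=lambda: {0: {"CWM": 1.5, "CLM": 1.5}})
    base_expression_range: tuple[float, float] = (6.5, 10.0)
    low_expression_fraction: float = 0.15
    library_size_sd: float = 0.2
    depth: float = 1.0
    celltypes: Sequence[str] = ("epithelial", "fibroblast", "endothelial",
                                "leukocyte")
    celltype_module_map: Mapping[str, Sequence[int]] = field(
        default_factory=lambda: {"fibroblast": (0,), "endothelial": (1,),
                                 "leukocyte": (2,)})
    profiles_per_celltype: int = 4
    reference_shift: float = 2.0
    reference_noise_sd: float = 1.0
    signature_member_fraction: float = 0.5
    signature_n_extra: int = 50
    segment_params: SegmentParams = field(default_factory=SegmentParams)
    variant_params: VariantParams = field(default_factory=VariantParams)
    survival_params: SurvivalParams = field(default_factory=SurvivalParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.module_sizes) + self.n_background_genes != self.n_genes:
            raise ConfigError(
                "sum(module_sizes) + n_background_genes must equal n_genes")
        if self.noise_sd <= 0 or self.background_sd <= 0:
            raise ConfigError("noise standard deviations must be positive")
        if not all(n > 0 for n in self.samples_per_group.values()):
            raise ConfigError("every sample group must be nonempty")
        if not 0 <= self.variant_params.concordance <= 1:
            raise ConfigError("concordance must lie in [0, 1]")
        if self.survival_params.baseline_hazard <= 0:
            raise ConfigError("baseline hazard must be positive")
        if self.survival_params.censoring_rate < 0:
            raise ConfigError("censoring rate must be non-negative")
        n_modules = len(self.module_sizes)
        for m in self.trait_effects:
            if not 0 <= m < n_modules:
                raise ConfigError(f"trait_effects references module {m}")
        for ct, mods in self.celltype_module_map.items():
            if ct not in self.celltypes:
                raise ConfigError(f"unknown cell type {ct!r}")
            for m in mods:
                if not 0 <= m < n_modules:
                    raise ConfigError(
                        f"celltype_module_map references module {m}")
        for m in self.survival_params.coefficients:
            if not 0 <= m < n_modules:
                raise ConfigError(f"survival coefficients reference module {m}")


@dataclass
class SyntheticCohort:
    """A generated multi-omics bundle with known ground truth."""

    config: SyntheticCohortConfig
    counts: pd.DataFrame
    expression: pd.DataFrame
    truth_partition: pd.Series
    samples: pd.DataFrame
    references: ReferenceProfiles
    signatures: dict[str, set[str]]
    segments: list[CNSegment]
    gene_models: list[GeneModel]
    variants: list[VariantRecord]
    survival: list[SurvivalRecord]

    @property
    def truth_factors(self) -> pd.DataFrame:
        """Eigengenes computed on the truth partition (modules x samples)."""
        return eigengene_matrix(self.expression, self.truth_partition)


# ---------------------------------------------------------------------------
# samples and expression
# ---------------------------------------------------------------------------

def _make_samples(config: SyntheticCohortConfig,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Sample sheet with patient pairing: CWM/CLM share patients (trios add
    an AN sample of the same patient), CNM and surplus samples are solo."""
    counts = config.samples_per_group
    n_pairs = min(counts.get("CWM", 0), counts.get("CLM", 0))
    rows = []
    solo = 0
    for group in counts:
        for i in range(counts[group]):
            sid = f"{group}_{i + 1:02d}"
            if group in ("CWM", "CLM") and i < n_pairs:
                patient = f"P{i + 1:02d}"
            elif group == "AN" and i < n_pairs:
                patient = f"P{i + 1:02d}"  # trio: AN of a paired patient
            else:
                solo += 1
                patient = f"S{solo:02d}"
            rows.append({
                "sample": sid, "patient": patient, "group": group,
                "metastasis": 1 if group in ("CWM", "CLM") else 0,
            })
    df = pd.DataFrame(rows).set_index("sample")
    df["msi"] = (rng.random(len(df)) < 0.1).astype(int)
    return df


def _make_expression(
    config: SyntheticCohortConfig,
    samples: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.DataFrame]:
    """Factor-model expression; returns (expression, counts, truth, factors)."""
    n_mod = len(config.module_sizes)
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    sample_ids = list(samples.index)
    n_samples = len(sample_ids)

    factors = rng.standard_normal((n_mod, n_samples))
    group_of = samples["group"]
    for m, shifts in config.trait_effects.items():
        for g, delta in shifts.items():
            mask = (group_of == g).to_numpy()
            factors[m, mask] += delta

    expr = np.empty((config.n_genes, n_samples))
    labels = np.full(config.n_genes, UNASSIGNED, dtype=object)
    lo, hi = config.base_expression_range
    pos = 0
    for m, size in enumerate(config.module_sizes):
        lam = rng.uniform(*config.loading_range, size=size)
        base = rng.uniform(lo, hi, size=size)
        eps = rng.normal(0.0, config.noise_sd, size=(size, n_samples))
        expr[pos:pos + size] = (base[:, None] + lam[:, None] * factors[m] + eps)
        labels[pos:pos + size] = f"M{m + 1}"
        pos += size
    n_bg = config.n_background_genes
    low = rng.random(n_bg) < config.low_expression_fraction
    base_bg = np.where(low, rng.uniform(0.0, 2.0, n_bg),
                       rng.uniform(lo, hi, n_bg))
    expr[pos:] = base_bg[:, None] + rng.normal(
        0.0, config.background_sd, size=(n_bg, n_samples))

    lib = np.exp(rng.normal(0.0, config.library_size_sd, size=n_samples))
    lam_counts = config.depth * lib[None, :] * np.maximum(2.0**expr - 1.0, 0.0)
    counts = rng.poisson(lam_counts)

    expr_df = pd.DataFrame(expr, index=genes, columns=sample_ids)
    counts_df = pd.DataFrame(counts, index=genes, columns=sample_ids)
    truth = pd.Series(labels, index=genes, name="module")
    fac = pd.DataFrame(factors, index=[f"M{m + 1}" for m in range(n_mod)],
                       columns=sample_ids)
    return expr_df, counts_df, truth, fac


# ---------------------------------------------------------------------------
# reference profiles and signatures
# ---------------------------------------------------------------------------

def generate_reference_profiles(
    config: SyntheticCohortConfig,
    truth: pd.Series,
    rng: np.random.Generator | None = None,
) -> ReferenceProfiles:
    """Purified cell-type reference profiles.

    Each cell type contributes ``profiles_per_celltype`` replicate
    profiles of baseline noise; member genes of the modules mapped to that
    cell type are shifted up by ``reference_shift``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    genes = list(truth.index)
    cols, labels = [], []
    data = []
    for ct in config.celltypes:
        elevated = np.zeros(len(genes), dtype=bool)
        for m in config.celltype_module_map.get(ct, ()):
            if not 0 <= m < len(config.module_sizes):
                raise ConfigError(f"celltype_module_map references module {m}")
            elevated |= (truth == f"M{m + 1}").to_numpy()
        for r in range(config.profiles_per_celltype):
            prof = rng.normal(0.0, config.reference_noise_sd, size=len(genes))
            prof[elevated] += config.reference_shift
            data.append(prof)
            cols.append(f"{ct}_{r + 1}")
            labels.append(ct)
    expr = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    return ReferenceProfiles(expr, pd.Series(labels, index=cols, name="celltype"))


def _make_signatures(
    config: SyntheticCohortConfig, truth: pd.Series, rng: np.random.Generator
) -> dict[str, set[str]]:
    """Planted signatures: a fraction of each mapped module's members plus
    random background genes, and one fully random control signature."""
    background = list(truth.index[truth == UNASSIGNED])
    sigs: dict[str, set[str]] = {}
    mapped = sorted({m for mods in config.celltype_module_map.values()
                     for m in mods})
    for m in mapped:
        members = list(truth.index[truth == f"M{m + 1}"])
        n_pick = max(2, int(round(config.signature_member_fraction * len(members))))
        pick = rng.choice(members, size=min(n_pick, len(members)), replace=False)
        extra = rng.choice(background,
                           size=min(config.signature_n_extra, len(background)),
                           replace=False)
        sigs[f"SIG_M{m + 1}"] = set(pick) | set(extra)
    n_rand = config.signature_n_extra + 50
    sigs["SIG_RANDOM"] = set(rng.choice(list(truth.index), size=n_rand,
                                        replace=False))
    return sigs


# ---------------------------------------------------------------------------
# segments, gene models, variants
# ---------------------------------------------------------------------------

def _place_gene_models(
    config: SyntheticCohortConfig, genes: Sequence[str],
    rng: np.random.Generator,
) -> list[GeneModel]:
    chroms = list(config.segment_params.chrom_lengths)
    lengths = np.array([config.segment_params.chrom_lengths[c] for c in chroms],
                       dtype=float)
    probs = lengths / lengths.sum()
    models = []
    for g in genes:
        c = chroms[rng.choice(len(chroms), p=probs)]
        L = config.segment_params.chrom_lengths[c]
        size = int(rng.integers(20_000, 150_000))
        start = int(rng.integers(1, max(L - size, 2)))
        models.append(GeneModel(gene=g, chrom=c, start=start,
                                end=min(start + size - 1, L)))
    return models


def _tile_segments(
    config: SyntheticCohortConfig, sample: str, rng: np.random.Generator
) -> list[CNSegment]:
    sp = config.segment_params
    cats = list(sp.category_probs)
    probs = np.array([sp.category_probs[c] for c in cats], dtype=float)
    probs = probs / probs.sum()
    segs = []
    for chrom, L in sp.chrom_lengths.items():
        pos = 1
        while pos <= L:
            length = max(sp.min_segment_length,
                         int(rng.exponential(sp.mean_segment_length)))
            end = min(pos + length - 1, L)
            cat = cats[rng.choice(len(cats), p=probs)]
            lo, hi = SegmentParams.CN_BANDS[cat]
            cn = float(rng.uniform(lo, hi))
            segs.append(CNSegment(sample=sample, chrom=chrom,
                                  start=pos, end=end, cn=cn))
            pos = end + 1
    return segs


_BASES = ("A", "C", "G", "T")


def _draw_filter_fields(vp: VariantParams, rng: np.random.Generator) -> dict:
    """Filter fields drawn to pass every rule, then each rule independently
    violated with probability ``fail_fraction``."""
    f = {
        "t_alt_reads": int(8 + rng.poisson(20)),
        "n_supporting": int(6 + rng.poisson(30)),
        "vaf_tumor": float(rng.uniform(0.1, 0.9)),
        "vaf_normal": float(rng.uniform(0.0, 0.1)),
        "p_somatic": float(rng.uniform(0.0, 0.05)),
        "dist_read_end": int(rng.integers(5, 50)),
        "p_base_quality": float(rng.uniform(0.05, 1.0)),
        "p_mapping_quality": float(rng.uniform(0.05, 1.0)),
        "p_strand_bias": float(rng.uniform(0.05, 1.0)),
    }
    q = vp.fail_fraction
    if q > 0:
        if rng.random() < q:
            f["t_alt_reads"] = int(rng.integers(0, 8))
        if rng.random() < q:
            f["n_supporting"] = int(rng.integers(0, 6))
        if rng.random() < q:
            f["vaf_tumor"] = float(rng.uniform(0.0, 0.1 - 1e-9))
        if rng.random() < q:
            f["vaf_normal"] = float(rng.uniform(0.1 + 1e-9, 0.5))
        if rng.random() < q:
            f["p_somatic"] = float(rng.uniform(0.05 + 1e-9, 1.0))
        if rng.random() < q:
            f["dist_read_end"] = int(rng.integers(0, 5))
        if rng.random() < q:
            f["p_base_quality"] = float(rng.uniform(0.0, 0.05 - 1e-9))
        if rng.random() < q:
            f["p_mapping_quality"] = float(rng.uniform(0.0, 0.05 - 1e-9))
        if rng.random() < q:
            f["p_strand_bias"] = float(rng.uniform(0.0, 0.05 - 1e-9))
    return f


def _draw_site(gene_models: Sequence[GeneModel],
               vp: VariantParams,
               rng: np.random.Generator) -> dict:
    g = gene_models[rng.integers(0, len(gene_models))]
    pos = int(rng.integers(g.start, g.end + 1))
    ref = _BASES[rng.integers(0, 4)]
    alt = rng.choice([b for b in _BASES if b != ref])
    types = list(vp.type_probs)
    probs = np.array([vp.type_probs[t] for t in types], dtype=float)
    mtype = types[rng.choice(len(types), p=probs / probs.sum())]
    return {"gene": g.gene, "chrom": g.chrom, "pos": pos,
            "ref": ref, "alt": str(alt), "mutation_type": mtype}


def generate_segments_and_variants(
    config: SyntheticCohortConfig,
    samples: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[list[CNSegment], list[VariantRecord], list[GeneModel]]:
    """Copy-number segments, gene models and somatic variant tables.

    Segments tile each chromosome of every tumor sample without overlap;
    gene models are placed independently so a fraction of genes straddles
    segment boundaries.  CWM/CLM pairs share a concordance-controlled
    fraction of variant sites; CNM samples carry private variants only;
    AN samples carry none.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    vp = config.variant_params
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    gene_models = _place_gene_models(config, genes, rng)
    driver = next(g for g in gene_models
                  if g.gene == f"G{sum(config.module_sizes) + 1:04d}")

    tumor = samples.index[samples["group"] != "AN"]
    segments: list[CNSegment] = []
    for s in tumor:
        segments.extend(_tile_segments(config, s, rng))

    variants: list[VariantRecord] = []

    def add(sample: str, patient: str, site: dict, fields: dict) -> None:
        variants.append(VariantRecord(sample=sample, patient=patient,
                                      **site, **fields))

    c = vp.concordance
    pairs: dict[str, dict[str, str]] = {}
    for s in tumor:
        grp = samples.loc[s, "group"]
        if grp in ("CWM", "CLM"):
            pairs.setdefault(samples.loc[s, "patient"], {})[grp] = s
    for patient in sorted(pairs):
        sides = pairs[patient]
        if len(sides) < 2:  # unpaired surplus sample: all private
            (grp, s), = sides.items()
            for _ in range(max(1, rng.poisson(vp.mean_mutations))):
                add(s, patient, _draw_site(gene_models, vp, rng),
                    _draw_filter_fields(vp, rng))
            continue
        n = max(1, rng.poisson(vp.mean_mutations))
        n_shared = int(round(n * 2 * c / (1 + c))) if c > 0 else 0
        n_priv = n - n_shared
        for _ in range(n_shared):
            site = _draw_site(gene_models, vp, rng)
            fields = _draw_filter_fields(vp, rng)  # one context, both sides
            add(sides["CWM"], patient, site, fields)
            add(sides["CLM"], patient, site, fields)
        for grp in ("CWM", "CLM"):
            for _ in range(n_priv):
                add(sides[grp], patient, _draw_site(gene_models, vp, rng),
                    _draw_filter_fields(vp, rng))
        if rng.random() < vp.driver_probs.get("CWM", 0.0):
            site = {"gene": driver.gene, "chrom": driver.chrom,
                    "pos": driver.start + 10, "ref": "C", "alt": "T",
                    "mutation_type": "missense"}
            fields = _draw_filter_fields(vp, rng)
            fields.update(t_alt_reads=30, n_supporting=40, vaf_tumor=0.4,
                          vaf_normal=0.0, p_somatic=0.001, dist_read_end=20,
                          p_base_quality=0.9, p_mapping_quality=0.9,
                          p_strand_bias=0.9)
            add(sides["CWM"], patient, dict(site), dict(fields))
            add(sides["CLM"], patient, dict(site), dict(fields))
    for s in samples.index[samples["group"] == "CNM"]:
        patient = samples.loc[s, "patient"]
        for _ in range(max(1, rng.poisson(vp.mean_mutations))):
            add(s, patient, _draw_site(gene_models, vp, rng),
                _draw_filter_fields(vp, rng))
        if rng.random() < vp.driver_probs.get("CNM", 0.0):
            fields = _draw_filter_fields(vp, rng)
            fields.update(t_alt_reads=30, n_supporting=40, vaf_tumor=0.4,
                          vaf_normal=0.0, p_somatic=0.001, dist_read_end=20,
                          p_base_quality=0.9, p_mapping_quality=0.9,
                          p_strand_bias=0.9)
            add(s, patient, {"gene": driver.gene, "chrom": driver.chrom,
                             "pos": driver.start + 10, "ref": "C", "alt": "T",
                             "mutation_type": "missense"}, fields)
    return segments, variants, gene_models


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def generate_survival(
    config: SyntheticCohortConfig,
    eigengenes: pd.DataFrame,
    samples: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> list[SurvivalRecord]:
    """Exponential survival with log-hazard linear in module eigengenes.

    One record per primary-tumor sample (groups CNM and CWM).  The hazard
    of sample s is ``baseline * exp(sum_m coeff_m * ME_m(s))``; censoring
    is independent exponential with expected probability
    ``censoring_rate`` at the baseline hazard (``censoring_rate >= 1``
    censors every record).
    """
    sp = config.survival_params
    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    ids = [s for s in samples.index
           if samples.loc[s, "group"] in ("CNM", "CWM") and s in eigengenes.columns]
    records = []
    for s in ids:
        lh = np.log(sp.baseline_hazard)
        for m, coef in sp.coefficients.items():
            lh += coef * float(eigengenes.loc[f"M{m + 1}", s])
        t_event = rng.exponential(1.0 / np.exp(lh))
        if sp.censoring_rate >= 1.0:
            records.append(SurvivalRecord(s, max(t_event, 1e-6), 0))
            continue
        if sp.censoring_rate > 0:
            mu = sp.baseline_hazard * sp.censoring_rate / (1 - sp.censoring_rate)
            t_cens = rng.exponential(1.0 / mu)
        else:
            t_cens = np.inf
        t = min(t_event, t_cens)
        records.append(SurvivalRecord(s, max(t, 1e-6), int(t_event <= t_cens)))
    return records


# ---------------------------------------------------------------------------
# top-level generator
# ---------------------------------------------------------------------------

def generate_cohort(config: SyntheticCohortConfig | None = None) -> SyntheticCohort:
    """Generate the full matched-trio cohort from one seeded Generator."""
    config = config or SyntheticCohortConfig()
    rng = np.random.default_rng(config.seed)
    samples = _make_samples(config, rng)
    expression, counts, truth, _factors = _make_expression(config, samples, rng)
    references = generate_reference_profiles(config, truth, rng)
    signatures = _make_signatures(config, truth, rng)
    segments, variants, gene_models = generate_segments_and_variants(
        config, samples, rng)
    eig = eigengene_matrix(expression, truth)
    survival = generate_survival(config, eig, samples, rng)
    return SyntheticCohort(
        config=config, counts=counts, expression=expression,
        truth_partition=truth, samples=samples, references=references,
        signatures=signatures, segments=segments, gene_models=gene_models,
        variants=variants, survival=survival,
    )
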