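"""Readers and writers for the plain-text formats the pipeline consumes.

Expression and count matrices are TSV with genes as rows and samples as
columns; gene sets use GMT semantics; copy-number segments use a SEG-like
TSV (sample, chrom, start, end, cn) with 1-based closed coordinates;
variants use a MAF-like TSV with the filter fields as columns; survival
and phenotype tables are simple TSVs.  All writers emit deterministic,
sorted output so that re-runs are byte-identical.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .alterations import CNSegment, GeneCNCall, GeneModel, VariantRecord
from .outcome import SurvivalRecord


# ---------------------------------------------------------------------------
# matrices and tables
# ---------------------------------------------------------------------------

def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "gene",
                 float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index_label=index_label,
              float_format=float_format)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False,
                float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index=index, float_format=float_format)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_partition(partition: pd.Series, path: str | Path) -> None:
    partition.rename("module").to_csv(path, sep="\t", index_label="gene")


def read_partition(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].rename("module")


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample")


def read_samples(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def write_gmt(signatures: dict[str, set[str] | Sequence[str]],
              path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(signatures):
            genes = "\t".join(sorted(signatures[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = set(parts[2:])
    return out


# ---------------------------------------------------------------------------
# segments, gene models, variants, survival
# ---------------------------------------------------------------------------

def write_segments(segments: Iterable[CNSegment], path: str | Path) -> None:
    df = pd.DataFrame([asdict(s) for s in segments])
    df.sort_values(["sample", "chrom", "start"]).to_csv(path, sep="\t",
                                                        index=False)


def read_segments(path: str | Path) -> list[CNSegment]:
    df = pd.read_csv(path, sep="\t")
    return [CNSegment(r["sample"], r["chrom"], int(r["start"]),
                      int(r["end"]), float(r["cn"]))
            for _, r in df.iterrows()]


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    df = pd.DataFrame([asdict(g) for g in genes])
    df.sort_values(["chrom", "start", "gene"]).to_csv(path, sep="\t",
                                                      index=False)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    return [GeneModel(r["gene"], r["chrom"], int(r["start"]), int(r["end"]))
            for _, r in df.iterrows()]


def write_variants(variants: Iterable[VariantRecord], path: str | Path) -> None:
    df = pd.DataFrame([asdict(v) for v in variants])
    df.sort_values(["sample", "chrom", "pos", "alt"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g")


def read_variants(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        out.append(VariantRecord(
            sample=r["sample"], patient=r["patient"], gene=r["gene"],
            chrom=r["chrom"], pos=int(r["pos"]), ref=r["ref"], alt=r["alt"],
            mutation_type=r["mutation_type"],
            t_alt_reads=int(r["t_alt_reads"]),
            n_supporting=int(r["n_supporting"]),
            vaf_tumor=float(r["vaf_tumor"]), vaf_normal=float(r["vaf_normal"]),
            p_somatic=float(r["p_somatic"]),
            dist_read_end=int(r["dist_read_end"]),
            p_base_quality=float(r["p_base_quality"]),
            p_mapping_quality=float(r["p_mapping_quality"]),
            p_strand_bias=float(r["p_strand_bias"]),
        ))
    return out


def write_cn_calls(calls: Iterable[GeneCNCall], path: str | Path) -> None:
    df = pd.DataFrame([asdict(c) for c in calls])
    df.sort_values(["sample", "gene"]).to_csv(path, sep="\t", index=False,
                                              float_format="%.6g")


def write_survival(records: Iterable[SurvivalRecord], path: str | Path) -> None:
    df = pd.DataFrame([asdict(r) for r in records])
    df.sort_values("sample").to_csv(path, sep="\t", index=False,
                                    float_format="%.6g")


def read_survival(path: str | Path) -> list[SurvivalRecord]:
    df = pd.read_csv(path, sep="\t")
    return [SurvivalRecord(r["sample"], float(r["time"]), int(r["event"]))
            for _, r in df.iterrows()]
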