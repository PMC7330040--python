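"""Differential expression stand-in and outcome analysis.

Differential expression here is a Welch / paired t contrast on log2
expression with BH FDR and the conventional DEG rule (FDR < 0.05 and
linear fold change >= 2, i.e. |log2 FC| >= 1).  It deliberately is not a
negative-binomial count model; DEG lists from count-model engines will
differ, and counts reported here should be read as the t-test's answer.

Outcome analysis dichotomizes a per-sample module score at its mean into
High/Low groups and compares their survival with Kaplan-Meier estimates
and the two-group log-rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.stats import ttest_ind, ttest_rel
from statsmodels.stats.multitest import multipletests

from .network import DataError

logger = logging.getLogger("tmenet")


@dataclass(frozen=True)
class SurvivalRecord:
    """Follow-up of one sample: time in months, event 1 = observed."""

    sample: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise DataError(f"non-positive survival time: {self}")
        if self.event not in (0, 1):
            raise DataError(f"event must be 0 or 1: {self}")


# ---------------------------------------------------------------------------
# differential expression (t-test stand-in)
# ---------------------------------------------------------------------------

def differential_expression(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    groups: Sequence[str],
    paired: bool = False,
    fdr_max: float = 0.05,
    min_abs_log2_fc: float = 1.0,
) -> pd.DataFrame:
    """Per-gene two-group contrast on log2 expression.

    log2_fc is the mean log2 difference (group_a - group_b); p-values come
    from Welch's t (or the paired t, matching samples by patient); BH FDR
    across genes; ``is_deg`` = (fdr < fdr_max) & (|log2_fc| >=
    min_abs_log2_fc).  Genes constant in both groups get p = 1 and are
    flagged in the log.
    """
    ga, gb = groups
    ids_a = [s for s in samples.index[samples["group"] == ga] if s in expr.columns]
    ids_b = [s for s in samples.index[samples["group"] == gb] if s in expr.columns]
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise DataError("each group needs at least 2 samples")
    if paired:
        pat_a = {samples.loc[s, "patient"]: s for s in ids_a}
        pat_b = {samples.loc[s, "patient"]: s for s in ids_b}
        shared = sorted(set(pat_a) & set(pat_b))
        if len(shared) < 2:
            raise DataError("paired contrast needs at least 2 matched patients")
        ids_a = [pat_a[p] for p in shared]
        ids_b = [pat_b[p] for p in shared]
    A = expr[ids_a].to_numpy(dtype=float)
    B = expr[ids_b].to_numpy(dtype=float)
    log2_fc = A.mean(axis=1) - B.mean(axis=1)
    if paired:
        stat, p = ttest_rel(A, B, axis=1)
    else:
        stat, p = ttest_ind(A, B, axis=1, equal_var=False)
    flat = np.isnan(p)
    if flat.any():
        logger.info("%d genes constant in both groups (p set to 1)", flat.sum())
        p = np.where(flat, 1.0, p)
        stat = np.where(flat, 0.0, stat)
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({
        "gene": expr.index, "log2_fc": log2_fc, "t": stat, "p": p, "fdr": fdr,
        "is_deg": (fdr < fdr_max) & (np.abs(log2_fc) >= min_abs_log2_fc),
    }).set_index("gene")


# ---------------------------------------------------------------------------
# mean split and survival
# ---------------------------------------------------------------------------

def mean_split(scores: pd.Series) -> pd.Series:
    """Dichotomize per-sample scores at the cohort mean.

    High <=> score strictly above the mean; scores exactly at the mean go
    to Low (documented tie rule).  Constant scores are an error.
    """
    if len(scores) < 2:
        raise DataError("at least 2 samples are required")
    vals = scores.to_numpy(dtype=float)
    if np.ptp(vals) == 0:
        raise DataError("constant scores cannot be mean-split")
    return pd.Series(np.where(vals > vals.mean(), "High", "Low"),
                     index=scores.index, name="split")


def kaplan_meier_logrank(
    survival: Sequence[SurvivalRecord], labels: pd.Series
) -> tuple[dict[str, pd.DataFrame], float, float]:
    """Kaplan-Meier curves and the two-group log-rank test.

    Parameters
    ----------
    survival : records with matching sample ids
    labels : Series sample -> {"High", "Low"} (any two labels work)

    Returns
    -------
    curves : dict label -> DataFrame(time, survival) product-limit estimate
    chi2, p : log-rank statistic (1 df) and p-value
    """
    recs = [r for r in survival if r.sample in labels.index]
    if not recs:
        raise DataError("no survival record matches the labels")
    df = pd.DataFrame({
        "time": [r.time for r in recs],
        "event": [r.event for r in recs],
        "label": [labels[r.sample] for r in recs],
    })
    groups = sorted(df["label"].unique())
    if len(groups) != 2:
        raise DataError(f"exactly 2 groups required, got {groups}")
    if df["event"].sum() == 0:
        raise DataError("no events observed; log-rank undefined")
    curves = {}
    for g in groups:
        sub = df[df["label"] == g]
        if sub.empty:
            raise DataError(f"group {g!r} has no subjects")
        km = KaplanMeierFitter()
        km.fit(sub["time"], sub["event"])
        sf = km.survival_function_
        curves[g] = pd.DataFrame({
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf.iloc[:, 0].to_numpy(dtype=float),
        })
    a, b = (df[df["label"] == g] for g in groups)
    res = logrank_test(a["time"], b["time"], a["event"], b["event"])
    return curves, float(res.test_statistic), float(res.p_value)


def responder_comparison(
    scores: pd.Series, response: pd.Series
) -> tuple[float, float]:
    """Welch t comparison of module scores between responders and
    non-responders (any binary labelling).

    Returns (t statistic, two-sided p).  The statistic's sign follows the
    sorted label order (first label minus second).
    """
    response = response.loc[scores.index]
    classes = sorted(response.unique())
    if len(classes) != 2:
        raise DataError(f"exactly 2 response classes required, got {classes}")
    a = scores[response == classes[0]].to_numpy(dtype=float)
    b = scores[response == classes[1]].to_numpy(dtype=float)
    stat, p = ttest_ind(a, b, equal_var=False)
    return float(stat), float(p)
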