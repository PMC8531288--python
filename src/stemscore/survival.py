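"""Kaplan-Meier / log-rank survival stratification by signature expression.

Subjects are split at the median of their mean expression over a signature's
up-genes (strictly above → "high", at or below → "low", the same boundary
rule as the cell-level median split), then compared with the two-group
log-rank test. Product-limit estimation and the log-rank statistic delegate
to lifelines; at tied times events precede censorings (so a subject censored
at an event time counts as at risk for that event), the standard convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .io import GeneSignature, ValidationError
from .scoring import MedianSplitClassifier

logger = logging.getLogger("stemscore")


def _check_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    for col in ("time", "event"):
        if col not in cohort.columns:
            raise ValidationError(f"cohort table needs a {col!r} column")
    if len(cohort) < 1:
        raise ValidationError("empty cohort")
    if (cohort["time"] <= 0).any():
        raise ValidationError("follow-up times must be positive")
    if not cohort["event"].isin([0, 1]).all():
        raise ValidationError("event indicator must be 0 or 1")
    return cohort


def km_curve(cohort: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns one row per distinct observed time: time, at_risk, events,
    censored, survival (the estimate just after that time).
    """
    cohort = _check_cohort(cohort)
    kmf = KaplanMeierFitter()
    kmf.fit(cohort["time"], cohort["event"])
    table = kmf.event_table[kmf.event_table.index > 0]
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame({
        "time": table.index.to_numpy(dtype=float),
        "at_risk": table["at_risk"].to_numpy(dtype=int),
        "events": table["observed"].to_numpy(dtype=int),
        "censored": table["censored"].to_numpy(dtype=int),
    })
    out["survival"] = [float(surv.loc[t]) for t in out["time"]]
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p_value: float
    n_a: int
    n_b: int


def logrank_test(cohort: pd.DataFrame, group_col: str = "group",
                 group_a: str | None = None, group_b: str | None = None
                 ) -> LogrankResult:
    """Two-group log-rank test (1 df): observed vs expected events under the
    hypergeometric null at each distinct event time.

    With no events at all the statistic is 0 and p = 1 (warned).
    """
    cohort = _check_cohort(cohort)
    groups = sorted(cohort[group_col].unique(), key=str)
    if group_a is None or group_b is None:
        if len(groups) != 2:
            raise ValidationError(f"expected exactly 2 groups, found {groups}")
        group_a, group_b = groups
    a = cohort[cohort[group_col] == group_a]
    b = cohort[cohort[group_col] == group_b]
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both groups must be non-empty")
    if cohort["event"].sum() == 0:
        logger.warning("no events in either group; log-rank statistic is 0")
        return LogrankResult(0.0, 1.0, len(a), len(b))
    res = _ll_logrank(a["time"], b["time"], event_observed_A=a["event"],
                      event_observed_B=b["event"])
    stat = float(res.test_statistic)
    p = float(res.p_value)
    if not np.isfinite(stat):
        stat, p = 0.0, 1.0
    return LogrankResult(stat, p, len(a), len(b))


def stratify_by_signature(expr: pd.DataFrame, sig: GeneSignature,
                          cohort: pd.DataFrame) -> pd.DataFrame:
    """Median-split a cohort by mean expression of the signature's up-genes.

    *expr* is genes × subjects; its columns must cover every cohort
    subject_id. Returns the cohort with a ``group`` column in {high, low}
    and a ``signature_mean`` column.
    """
    cohort = _check_cohort(cohort)
    if "subject_id" not in cohort.columns:
        raise ValidationError("cohort table needs a subject_id column")
    missing_subj = set(cohort["subject_id"]) - set(expr.columns)
    if missing_subj:
        raise ValidationError(f"{len(missing_subj)} subjects missing from expression")
    genes = [g for g in sig.up_genes if g in expr.index]
    if not genes:
        raise ValidationError(f"no up-gene of signature {sig.name} in the expression table")
    if len(genes) < len(sig.up_genes):
        logger.warning("signature %s: %d up-genes absent from the expression table",
                       sig.name, len(sig.up_genes) - len(genes))
    means = expr.loc[genes, cohort["subject_id"]].mean(axis=0).to_numpy()
    clf = MedianSplitClassifier(positive_label="high", negative_label="low")
    labels = clf.fit(means).predict(means)
    out = cohort.copy()
    out["signature_mean"] = means
    out["group"] = labels
    return out
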