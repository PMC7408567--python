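"""Score-based cohort stratification and clinical analyses.

High/low grouping takes the top and bottom 30% of the per-cancer glycolysis
score distribution (floor arithmetic, lexicographic tie-breaking on
(score, sample_id)); cohorts whose groups fall below ``min_group`` samples
are flagged ineligible and excluded from downstream per-cancer analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import TestResult, two_sample_test
from .survival import CoxFit, SurvivalFit, cox_fit, km_logrank

logger = logging.getLogger(__name__)

DEFAULT_Q = 0.30
DEFAULT_MIN_GROUP = 30


@dataclass
class GroupLabels:
    labels: pd.Series  # sample_id -> {'high','low','mid'}
    q: float
    eligible: bool
    n_high: int
    n_low: int

    def samples(self, which: str) -> list[str]:
        return list(self.labels.index[self.labels == which])


def classify_by_score(
    scores: pd.Series, q: float = DEFAULT_Q, min_group: int = DEFAULT_MIN_GROUP
) -> GroupLabels:
    """Label the top floor(q*n) samples 'high', the bottom floor(q*n) 'low'.

    Ties straddling a quantile boundary are resolved by ascending
    (score, sample_id) lexicographic order, so group sizes are exact and the
    split is deterministic.
    """
    if not 0 < q <= 0.5:
        raise ValueError(f"q must be in (0, 0.5], got {q}")
    scores = scores.dropna()
    n = scores.size
    if n == 0:
        raise ValueError("no samples to classify")
    k = int(np.floor(q * n))
    order = sorted(scores.index, key=lambda s: (scores[s], str(s)))
    labels = pd.Series("mid", index=scores.index, name="group")
    labels[order[:k]] = "low"
    if k > 0:
        labels[order[-k:]] = "high"
    eligible = k >= min_group
    if not eligible:
        logger.info("cohort ineligible: group size %d < min_group %d", k, min_group)
    return GroupLabels(labels=labels, q=q, eligible=eligible, n_high=k, n_low=k)


def classify_per_cancer(
    scores: pd.Series,
    clinical: pd.DataFrame,
    q: float = DEFAULT_Q,
    min_group: int = DEFAULT_MIN_GROUP,
) -> dict[str, GroupLabels]:
    """Per-cancer-type high/low split on tumor samples only."""
    tumors = clinical[clinical["sample_type"] == "tumor"]
    out: dict[str, GroupLabels] = {}
    for ct, sub in tumors.groupby("cancer_type", sort=True):
        s = scores.reindex(sub.index).dropna()
        if s.empty:
            continue
        out[str(ct)] = classify_by_score(s, q=q, min_group=min_group)
    return out


def tumor_normal_compare(
    scores: pd.Series, clinical: pd.DataFrame, min_normals: int = 30
) -> dict[str, TestResult]:
    """Rank-sum tumor-vs-normal score comparison per cancer type.

    Run only where the cancer type has at least ``min_normals`` normals.
    """
    out: dict[str, TestResult] = {}
    for ct, sub in clinical.groupby("cancer_type", sort=True):
        tum = scores.reindex(sub.index[sub["sample_type"] == "tumor"]).dropna()
        nor = scores.reindex(sub.index[sub["sample_type"] == "normal"]).dropna()
        if nor.size < min_normals:
            logger.info("skip %s: %d normals < %d", ct, nor.size, min_normals)
            continue
        out[str(ct)] = two_sample_test(tum, nor, method="rank_sum")
    return out


def stage_association(scores: pd.Series, clinical: pd.DataFrame) -> dict[str, TestResult]:
    """Welch t of scores in stage IV vs stage I tumors, per cancer type."""
    out: dict[str, TestResult] = {}
    tumors = clinical[clinical["sample_type"] == "tumor"]
    for ct, sub in tumors.groupby("cancer_type", sort=True):
        s1 = scores.reindex(sub.index[sub["stage"] == "I"]).dropna()
        s4 = scores.reindex(sub.index[sub["stage"] == "IV"]).dropna()
        if s1.size < 2 or s4.size < 2:
            logger.info("skip %s: stage I n=%d, stage IV n=%d", ct, s1.size, s4.size)
            continue
        out[str(ct)] = two_sample_test(s4, s1, method="welch_t")
    return out


def survival_by_group(labels: GroupLabels, clinical: pd.DataFrame) -> SurvivalFit:
    """KM + log-rank on the high vs low groups."""
    keep = labels.labels[labels.labels.isin(["high", "low"])]
    clin = clinical.reindex(keep.index).dropna(subset=["os_time", "os_event"])
    keep = keep.reindex(clin.index)
    return km_logrank(keep, clin["os_time"], clin["os_event"])


_STAGE_NUM = {"I": 1, "II": 2, "III": 3, "IV": 4}


def cox_by_covariates(
    clinical: pd.DataFrame,
    covariates: pd.DataFrame,
) -> CoxFit:
    """Cox model of overall survival on arbitrary per-sample covariates."""
    clin = clinical.reindex(covariates.index).dropna(subset=["os_time", "os_event"])
    cov = covariates.reindex(clin.index).dropna()
    clin = clin.reindex(cov.index)
    return cox_fit(cov, clin["os_time"], clin["os_event"])


def encode_stage(stage: pd.Series) -> pd.Series:
    """Ordinal I..IV -> 1..4; missing stays missing."""
    return stage.map(_STAGE_NUM)
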