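"""Normative-threshold multi-region hypoperfusion classifier.

For each target region a normative cutoff ``tau_r = HC_mean_r - k * HC_SD_r``
is derived from healthy controls; a subject's region is called affected when
its SUVr is at or below the cutoff (inclusive), and the subject is positive
for a disease-like hypoperfusion scan when at least ``m`` target regions are
affected.  The (k, m) grid {2.0, 2.5, 3.0} x {1, 3, 5} probes the
sensitivity/specificity trade-off of the rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from tauperf.core import CohortTable, SuvrMatrix, align_cohort

DEFAULT_K_GRID = (2.0, 2.5, 3.0)
DEFAULT_M_GRID = (1, 3, 5)


@dataclass(frozen=True)
class ThresholdModel:
    """Per-region normative cutoffs from healthy controls."""

    k: float
    labels: tuple[str, ...]
    hc_mean: dict[str, float]
    hc_sd: dict[str, float]
    tau: dict[str, float]

    def __post_init__(self) -> None:
        if any(self.hc_sd[lab] < 0 for lab in self.labels):
            raise ValueError("hc_sd must be non-negative")


@dataclass(frozen=True)
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else float("nan")

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn) if (self.tn + self.fn) else float("nan")


def fit_thresholds(hc_matrix: SuvrMatrix, target_regions, k: float) -> ThresholdModel:
    """Normative per-region mean/SD (denominator n-1) from HC subjects."""
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if hc_matrix.n_subjects < 2:
        raise ValueError("need at least 2 healthy controls to fit thresholds")
    labels = tuple(target_regions)
    unknown = [lab for lab in labels if lab not in set(hc_matrix.region_labels)]
    if unknown:
        raise ValueError(f"target label(s) not in matrix: {unknown}")
    sub = hc_matrix.values[list(labels)]
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=1)
    tau = mean - k * sd
    return ThresholdModel(
        k=k, labels=labels,
        hc_mean=mean.to_dict(), hc_sd=sd.to_dict(), tau=tau.to_dict(),
    )


def classify_subject(suvr_row, model: ThresholdModel, m: int = 1) -> dict:
    """Classify one subject: affected iff SUVr <= tau (inclusive boundary)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    row = pd.Series(suvr_row) if not isinstance(suvr_row, pd.Series) else suvr_row
    missing = [lab for lab in model.labels if lab not in row.index or pd.isna(row[lab])]
    if missing:
        raise ValueError(f"missing target region value(s): {missing}")
    affected = [lab for lab in model.labels if row[lab] <= model.tau[lab]]
    return {
        "positive": len(affected) >= m,
        "n_affected": len(affected),
        "affected_labels": tuple(affected),
    }


def classify_matrix(matrix: SuvrMatrix, model: ThresholdModel, m: int = 1) -> pd.DataFrame:
    """Vectorized per-subject calls over a whole matrix."""
    sub = matrix.values[list(model.labels)]
    tau = np.array([model.tau[lab] for lab in model.labels])
    affected = sub.to_numpy() <= tau
    n_affected = affected.sum(axis=1)
    return pd.DataFrame(
        {"n_affected": n_affected, "positive": n_affected >= m},
        index=sub.index,
    )


def evaluate_grid(
    matrix: SuvrMatrix,
    cohort: CohortTable,
    hc_matrix: SuvrMatrix,
    target_regions,
    k_grid=DEFAULT_K_GRID,
    m_grid=DEFAULT_M_GRID,
    positive_group: str = "FOURRT",
    negative_group: str = "OTHER_ND",
) -> pd.DataFrame:
    """Confusion metrics of the threshold rule over the (k, m) grid.

    The evaluation cohort is restricted to the positive and negative groups;
    thresholds come from the separate HC matrix.  Returns one row per (k, m)
    with counts and sensitivity/specificity/PPV/NPV.
    """
    aligned = align_cohort(matrix, cohort)
    t = aligned.cohort.table
    mask = t["group"].isin([positive_group, negative_group]).to_numpy()
    if (t.loc[mask, "group"] == positive_group).sum() == 0:
        raise ValueError(f"no subjects in positive group {positive_group!r}")
    if (t.loc[mask, "group"] == negative_group).sum() == 0:
        raise ValueError(f"no subjects in negative group {negative_group!r}")
    eval_matrix = aligned.matrix.subset(t.loc[mask, "subject_id"])
    is_pos = (t.loc[mask, "group"] == positive_group).to_numpy()

    rows = []
    for k in k_grid:
        model = fit_thresholds(hc_matrix, target_regions, k)
        for m in m_grid:
            calls = classify_matrix(eval_matrix, model, m)["positive"].to_numpy()
            cm = ConfusionMetrics(
                tp=int(np.sum(calls & is_pos)),
                fp=int(np.sum(calls & ~is_pos)),
                tn=int(np.sum(~calls & ~is_pos)),
                fn=int(np.sum(~calls & is_pos)),
            )
            rows.append({
                "k": k, "m": m,
                "tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn,
                "sensitivity": cm.sensitivity, "specificity": cm.specificity,
                "ppv": cm.ppv, "npv": cm.npv,
            })
    return pd.DataFrame(rows)
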