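"""ROC/AUC with DeLong inference and covariate-adjusted partial correlation.

The AUC is computed as the Mann-Whitney probability that a random positive
outscores a random negative (ties counted 1/2).  Variances and the paired
comparison of two correlated AUCs use DeLong's placement-value method; the
95% confidence interval is a normal approximation truncated to [0, 1].

Partial correlation residualizes both variables on the covariates (with
intercept) by least squares and reports the Pearson correlation of the
residuals with ``t = r * sqrt(df / (1 - r^2))``, ``df = n - 2 - c``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from tauperf.core import CohortTable


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    comparison_p: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError(f"AUC out of [0,1]: {self.auc}")


@dataclass(frozen=True)
class PartialCorrResult:
    r: float
    p: float
    n_complete: int
    covariates: tuple[str, ...]


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values: per-positive and per-negative win fractions."""
    diff = pos[:, None] - neg[None, :]
    wins = (diff > 0).astype(float) + 0.5 * (diff == 0)
    return wins.mean(axis=1), 1.0 - wins.mean(axis=0)


def _split_by_label(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape[0] != y.shape[0]:
        raise ValueError("scores and labels length mismatch")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    pos = s[y == classes.max()]
    neg = s[y == classes.min()]
    return pos, neg


def roc_auc(scores, labels, alpha: float = 0.05) -> RocResult:
    """AUC with a DeLong-variance normal-approximation confidence interval."""
    pos, neg = _split_by_label(scores, labels)
    v10, v01 = _placements(pos, neg)
    auc = float(v10.mean())
    m, n = len(pos), len(neg)
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return RocResult(
        auc=auc,
        ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)),
        n_pos=m, n_neg=n,
    )


def delong_paired_test(scores_a, scores_b, labels) -> float:
    """Two-sided DeLong test of AUC_a vs AUC_b on the same subjects."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("scores_a and scores_b length mismatch")
    pos_a, neg_a = _split_by_label(a, labels)
    pos_b, neg_b = _split_by_label(b, labels)
    v10a, v01a = _placements(pos_a, neg_a)
    v10b, v01b = _placements(pos_b, neg_b)
    auc_a, auc_b = v10a.mean(), v10b.mean()
    m, n = len(pos_a), len(neg_a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var_diff = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var_diff <= 0:
        # identical (or perfectly coupled) placements: no detectable difference
        return 1.0 if np.isclose(auc_a, auc_b) else 0.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    return float(2.0 * stats.norm.sf(abs(z)))


def partial_correlation(x, y, covariate_table: pd.DataFrame) -> PartialCorrResult:
    """Partial Pearson correlation of x and y given covariates.

    Incomplete cases are removed listwise; constant covariates (absorbed by
    the intercept) are dropped; remaining collinear covariates raise an
    error naming them.
    """
    x = pd.Series(np.asarray(x, dtype=float)).reset_index(drop=True)
    y = pd.Series(np.asarray(y, dtype=float)).reset_index(drop=True)
    cov = covariate_table.reset_index(drop=True).astype(float)
    frame = pd.concat([x.rename("_x"), y.rename("_y"), cov], axis=1)
    complete = frame.dropna()
    names = list(cov.columns)

    # constant covariates duplicate the intercept; drop them
    kept = [c for c in names if complete[c].nunique() > 1]
    n = len(complete)
    c = len(kept)
    if n < c + 3:
        raise ValueError(f"too few complete cases ({n}) for {c} covariates")
    design = np.column_stack([np.ones(n)] + [complete[cname].to_numpy() for cname in kept])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        # identify offending columns incrementally
        bad = []
        cols = [np.ones(n)]
        for cname in kept:
            trial = np.column_stack(cols + [complete[cname].to_numpy()])
            if np.linalg.matrix_rank(trial) < trial.shape[1]:
                bad.append(cname)
            else:
                cols.append(complete[cname].to_numpy())
        raise ValueError(f"collinear covariate(s): {bad}")

    def _resid(v: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(design, v, rcond=None)
        return v - design @ beta

    rx = _resid(complete["_x"].to_numpy())
    ry = _resid(complete["_y"].to_numpy())
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    if denom == 0:
        raise ValueError("zero residual variance; correlation undefined")
    r = float(np.clip((rx * ry).sum() / denom, -1.0, 1.0))
    df = n - 2 - c
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r ** 2))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return PartialCorrResult(r=r, p=p, n_complete=n, covariates=tuple(names))


CLINICAL_SCALES = ("pspr", "seadl", "moca")
SCORE_COLUMNS = ("score_perfusion", "score_tau", "score_combined")


def clinical_association_report(
    scores: pd.DataFrame,
    cohort: CohortTable,
    group: str = "FOURRT",
    covariates: tuple[str, ...] = ("age", "sex", "disease_duration_months"),
) -> pd.DataFrame:
    """Partial correlations of expression scores with clinical scales.

    Restricted to the given diagnostic group; one row per (scale, score)
    cell with r, p and the complete-case n, covariates adjusted throughout
    (sex encoded as a single indicator).  Cells without enough complete
    cases are marked unavailable (NaN r/p).
    """
    t = cohort.table[cohort.table["group"] == group].set_index("subject_id")
    common = [sid for sid in scores.index if sid in t.index]
    if not common:
        raise ValueError(f"no subjects of group {group!r} with scores")
    t = t.loc[common]
    sc = scores.loc[common]

    cov = pd.DataFrame(index=t.index)
    for name in covariates:
        if name == "sex":
            cov["sex"] = (t["sex"] == "F").astype(float)
        else:
            cov[name] = t[name].astype(float)

    rows = []
    for scale in CLINICAL_SCALES:
        for score_col in SCORE_COLUMNS:
            if score_col not in sc.columns:
                continue
            try:
                res = partial_correlation(sc[score_col], t[scale], cov)
                rows.append({"scale": scale, "score": score_col, "r": res.r,
                             "p": res.p, "n": res.n_complete})
            except ValueError:
                rows.append({"scale": scale, "score": score_col, "r": np.nan,
                             "p": np.nan, "n": int(t[scale].notna().sum())})
    return pd.DataFrame(rows)
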