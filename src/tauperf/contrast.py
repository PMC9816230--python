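"""Region-wise covariate-adjusted group contrast with FDR control.

Each of the 246 regional SUVr columns is compared between two diagnostic
groups by an ANCOVA: a linear model ``suvr ~ group + age + sex`` whose group
term is tested by a partial F on one degree of freedom (equivalently the
squared t of the group coefficient).  The 246 raw p-values are corrected by
Benjamini-Hochberg step-up FDR, and group differences are reported as signed
percent differences of the raw group means, mirroring the published table
layout (significant rows first, sorted by descending |percent difference|).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from tauperf.atlas import RegionAtlas, load_atlas
from tauperf.core import CohortTable, SuvrMatrix, align_cohort


def percent_difference(mean_a: float, mean_b: float) -> float:
    """Signed percent difference of ``mean_a`` relative to reference ``mean_b``."""
    if mean_b == 0:
        raise ValueError("reference mean is zero; percent difference undefined")
    return 100.0 * (mean_a - mean_b) / mean_b


def benjamini_hochberg(p_values, q: float = 0.01):
    """Benjamini-Hochberg step-up FDR correction.

    Returns ``(adjusted, reject)`` where ``adjusted[i] = min_{j>=i} m*p_(j)/j``
    (on the sorted scale, capped at 1) mapped back to input order, and
    ``reject`` flags ``adjusted <= q``.  Stable under permutation of inputs.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted, adjusted <= q


def _ancova_design(cohort: CohortTable, groups: tuple[str, str]) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix [1, group, age, sex] and row mask for the two groups.

    Constant (zero-variance) covariate columns carry no information and are
    dropped with a warning, so the degenerate limit is a plain two-sample
    t-test; covariates collinear with the group indicator raise.
    """
    import warnings

    t = cohort.table
    mask = t["group"].isin(groups).to_numpy()
    sub = t[mask]
    for g in groups:
        if (sub["group"] == g).sum() < 2:
            raise ValueError(f"need >= 2 subjects in group {g!r}")
    g_ind = (sub["group"] == groups[0]).to_numpy(dtype=float)
    age = sub["age"].to_numpy(dtype=float)
    sex = (sub["sex"] == "F").to_numpy(dtype=float)
    if np.any(~np.isfinite(age)):
        raise ValueError("age missing for some subjects")
    cols = [np.ones(len(sub)), g_ind]
    for name, col in (("age", age), ("sex", sex)):
        if np.ptp(col) == 0:
            warnings.warn(f"covariate {name!r} is constant; dropped", stacklevel=3)
        else:
            cols.append(col)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "singular ANCOVA design (a covariate is collinear with the group "
            "indicator, e.g. single-sex groups); drop the offending covariate"
        )
    return X, mask


def _group_term_pvalues(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Two-sided p of the group coefficient (column 1) for every column of Y."""
    n, k = X.shape
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = n - k
    sigma2 = (resid ** 2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, beta[1] / se, np.inf * np.sign(beta[1]))
    return 2.0 * stats.t.sf(np.abs(tval), dof)


def region_group_test(suvr_column, cohort: CohortTable, groups: tuple[str, str]) -> float:
    """ANCOVA p-value of the group term for a single region.

    Fits ``suvr ~ group + age + sex`` on the subjects of the two groups and
    returns the two-sided p of the group indicator (partial F on 1 df).
    """
    X, mask = _ancova_design(cohort, groups)
    y = np.asarray(suvr_column, dtype=float)[mask]
    return float(_group_term_pvalues(y[:, None], X)[0])


@dataclass(frozen=True)
class ContrastTable:
    """Per-region contrast results plus summary counts."""

    table: pd.DataFrame          # label, compartment, hemisphere, p_raw, p_fdr, percent_diff, significant
    q: float
    groups: tuple[str, str]

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    @property
    def significant_labels(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "label"])

    @property
    def hemisphere_tally(self) -> dict[str, int]:
        sig = self.table[self.table["significant"]]
        return {
            "R": int((sig["hemisphere"] == "R").sum()),
            "L": int((sig["hemisphere"] == "L").sum()),
        }


def build_contrast_table(
    early: SuvrMatrix,
    cohort: CohortTable,
    q: float = 0.01,
    groups: tuple[str, str] = ("FOURRT", "HC"),
    atlas: RegionAtlas | None = None,
) -> ContrastTable:
    """Test all regions, correct by BH-FDR and assemble the contrast table.

    Percent differences are computed on raw (covariate-unadjusted) group
    means relative to the second group of ``groups``.
    """
    atlas = atlas or load_atlas()
    aligned = align_cohort(early, cohort)
    X, mask = _ancova_design(aligned.cohort, groups)
    Y = aligned.matrix.values.to_numpy(dtype=float)[mask]
    p_raw = _group_term_pvalues(Y, X)
    p_fdr, reject = benjamini_hochberg(p_raw, q)

    grp = aligned.cohort.table.loc[mask, "group"].to_numpy()
    mean_a = Y[grp == groups[0]].mean(axis=0)
    mean_b = Y[grp == groups[1]].mean(axis=0)
    pct = 100.0 * (mean_a - mean_b) / mean_b

    labels = aligned.matrix.region_labels
    df = pd.DataFrame({
        "label": labels,
        "compartment": [atlas.compartment_of(lab) for lab in labels],
        "hemisphere": [atlas.hemisphere_of(lab) for lab in labels],
        "p_raw": p_raw,
        "p_fdr": p_fdr,
        "percent_diff": pct,
        "significant": reject,
    })
    df = df.sort_values(
        ["significant", "percent_diff"],
        key=lambda s: s.abs() if s.name == "percent_diff" else s,
        ascending=[False, False],
    ).reset_index(drop=True)
    return ContrastTable(table=df, q=q, groups=groups)
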