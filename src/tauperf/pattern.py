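"""Disease-pattern expression scores from PCA with varimax rotation.

The pattern-expression pipeline condenses a subjects x regions SUVr matrix
into a single disease-relatedness score per subject:

1. regions whose absolute Pearson correlation with every other region stays
   below 0.3 are discarded (weak linear relationship);
2. sampling adequacy is summarized by the Kaiser-Meyer-Olkin measure and
   Bartlett's test of sphericity (reported, never gating);
3. the correlation matrix of the training set is eigendecomposed, components
   with eigenvalue > 1.0 are retained, and their loadings varimax-rotated;
4. component scores follow the regression method (score coefficients
   ``R^+ . rotated_loadings`` applied to training-standardized data);
5. a diagnostic regression (logistic by default) of the binary disease
   indicator on the component scores yields per-component weights, and the
   expression score is the weighted sum of a subject's component scores.

External cohorts are projected with the training standardization, score
coefficients and weights, so the score is a fixed linear functional of new
data.  The combined perfusion+tau score is the plain sum of the two
phase-specific scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression


# ---------------------------------------------------------------------------
# variable screening and sampling adequacy
# ---------------------------------------------------------------------------

def correlation_filter(X: pd.DataFrame, threshold: float = 0.3,
                       rule: str = "max_abs") -> list[str]:
    """Labels of columns passing the inter-region correlation screen.

    A column is retained when its |Pearson r| with at least one other column
    reaches ``threshold`` (``rule='max_abs'``), or when its mean |r| with the
    others does (``rule='mean_abs'``).  Zero-variance columns are excluded
    with a warning before correlations are formed.
    """
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need at least 3 subjects and 2 regions")
    if rule not in ("max_abs", "mean_abs"):
        raise ValueError(f"unknown filter rule {rule!r}")
    variances = X.var(axis=0, ddof=1)
    degenerate = list(variances.index[variances == 0])
    if degenerate:
        warnings.warn(f"excluding zero-variance region(s): {degenerate}", stacklevel=2)
        X = X.drop(columns=degenerate)
        if X.shape[1] < 2:
            raise ValueError("fewer than 2 regions with variance remain")
    r = np.corrcoef(X.to_numpy(dtype=float), rowvar=False)
    np.fill_diagonal(r, 0.0)
    absr = np.abs(r)
    if rule == "max_abs":
        stat = absr.max(axis=0)
    else:
        stat = absr.sum(axis=0) / (absr.shape[0] - 1)
    return [lab for lab, s in zip(X.columns, stat) if s >= threshold]


def kmo_measure(X) -> float:
    """Overall Kaiser-Meyer-Olkin measure of sampling adequacy.

    With correlations ``r_ij`` and anti-image partial correlations
    ``q_ij = -inv_ij / sqrt(inv_ii inv_jj)`` from the inverse correlation
    matrix, KMO = sum r^2 / (sum r^2 + sum q^2) over off-diagonal pairs.
    """
    arr = np.asarray(X, dtype=float)
    r = np.corrcoef(arr, rowvar=False)
    try:
        r_inv = np.linalg.inv(r)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "correlation matrix is singular; apply the correlation filter or "
            "regularize before computing KMO"
        ) from exc
    d = np.sqrt(np.outer(np.diag(r_inv), np.diag(r_inv)))
    q = -r_inv / d
    off = ~np.eye(r.shape[0], dtype=bool)
    r2 = (r[off] ** 2).sum()
    q2 = (q[off] ** 2).sum()
    return float(r2 / (r2 + q2))


def bartlett_sphericity(X) -> dict:
    """Bartlett's test that the correlation matrix is the identity.

    ``chi2 = -(n - 1 - (2p + 5) / 6) * ln det(R)`` with ``p(p-1)/2`` degrees
    of freedom and an upper-tail chi-square p-value.
    """
    arr = np.asarray(X, dtype=float)
    n, p = arr.shape
    r = np.corrcoef(arr, rowvar=False)
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise ValueError("correlation matrix has non-positive determinant")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    return {"chi2": float(chi2), "df": int(df), "p": float(stats.chi2.sf(chi2, df))}


# ---------------------------------------------------------------------------
# varimax rotation
# ---------------------------------------------------------------------------

def _varimax_criterion(L: np.ndarray) -> float:
    sq = L ** 2
    p = L.shape[0]
    return float((sq ** 2).sum() - (sq.sum(axis=0) ** 2).sum() / p)


def varimax(loadings: np.ndarray, kaiser_normalize: bool = True,
            tol: float = 1e-6, max_sweeps: int = 500) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation by pairwise planar rotations.

    Maximizes the variance of squared loadings per component over orthogonal
    rotations, with Kaiser row normalization.  Returns ``(rotated, rotation)``
    with ``loadings @ rotation == rotated``; a single column is returned
    unchanged.  Raises if the criterion has not converged (relative gain
    below ``tol``) within ``max_sweeps`` sweeps.
    """
    L = np.array(loadings, dtype=float)
    p, k = L.shape
    if k == 1:
        return L, np.eye(1)
    comm = np.sqrt((L ** 2).sum(axis=1))
    if kaiser_normalize:
        nz = comm > 0
        L[nz] = L[nz] / comm[nz, None]
    R = np.eye(k)
    v_old = _varimax_criterion(L)
    for sweep in range(1, max_sweeps + 1):
        for a in range(k - 1):
            for b in range(a + 1, k):
                x, y = L[:, a], L[:, b]
                u = x ** 2 - y ** 2
                w = 2.0 * x * y
                A, B = u.sum(), w.sum()
                num = 2.0 * (u * w).sum() - 2.0 * A * B / p
                den = (u ** 2 - w ** 2).sum() - (A ** 2 - B ** 2) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-15:
                    continue
                c, s = np.cos(phi), np.sin(phi)
                L[:, a], L[:, b] = c * x + s * y, -s * x + c * y
                R[:, [a, b]] = R[:, [a, b]] @ np.array([[c, -s], [s, c]])
        v_new = _varimax_criterion(L)
        if v_new - v_old <= tol * max(1.0, abs(v_old)):
            break
        v_old = v_new
    else:
        raise RuntimeError(f"varimax did not converge within {max_sweeps} sweeps")
    if kaiser_normalize:
        L[nz] = L[nz] * comm[nz, None]
        L[~nz] = 0.0
    return L, R


# ---------------------------------------------------------------------------
# model fitting and scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatternModel:
    """Trained pattern-expression model (standardization, loadings, weights)."""

    phase: str
    retained_labels: tuple[str, ...]
    mean: np.ndarray                # per retained region, training mean
    sd: np.ndarray                  # per retained region, training SD (ddof=1)
    eigenvalues: np.ndarray         # all eigenvalues of the correlation matrix
    rotated_loadings: np.ndarray    # regions x retained components
    score_coefficients: np.ndarray  # regions x retained components
    weights: np.ndarray             # per retained component, diagnostic regression
    intercept: float
    kmo: float | None
    bartlett: dict | None

    @property
    def n_components(self) -> int:
        return self.rotated_loadings.shape[1]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "phase": self.phase,
            "retained_labels": list(self.retained_labels),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "rotated_loadings": self.rotated_loadings.tolist(),
            "score_coefficients": self.score_coefficients.tolist(),
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "kmo": self.kmo,
            "bartlett": self.bartlett,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PatternModel":
        if isinstance(source, Path) or (len(str(source)) < 4096 and Path(str(source)).exists()):
            text = Path(source).read_text()
        else:
            text = str(source)
        d = json.loads(text)
        return cls(
            phase=d["phase"],
            retained_labels=tuple(d["retained_labels"]),
            mean=np.array(d["mean"]),
            sd=np.array(d["sd"]),
            eigenvalues=np.array(d["eigenvalues"]),
            rotated_loadings=np.array(d["rotated_loadings"]),
            score_coefficients=np.array(d["score_coefficients"]),
            weights=np.array(d["weights"]),
            intercept=d["intercept"],
            kmo=d["kmo"],
            bartlett=d["bartlett"],
        )


def _orient_columns(L: np.ndarray) -> np.ndarray:
    """Flip column signs so each component's largest |loading| is positive."""
    flip = np.sign(L[np.abs(L).argmax(axis=0), np.arange(L.shape[1])])
    flip[flip == 0] = 1.0
    return L * flip


def fit_pattern_model(
    X: pd.DataFrame,
    labels: np.ndarray,
    phase: str = "EARLY",
    regression: str = "logistic",
) -> PatternModel:
    """Fit the pattern-expression model on training data.

    Parameters
    ----------
    X
        Training subjects x retained regions (post correlation filter).
    labels
        Binary disease indicator (1 = target disease) per training subject.
    regression
        ``'logistic'`` (default) or ``'linear'`` (linear-probability fit) for
        the component-weighting regression.
    """
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("labels must contain both classes coded 0/1")
    if regression not in ("logistic", "linear"):
        raise ValueError(f"unknown regression {regression!r}")

    arr = X.to_numpy(dtype=float)
    n, p = arr.shape
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [lab for lab, s in zip(X.columns, sd) if s == 0]
        raise ValueError(f"zero-variance region(s) in training data: {bad}")
    Z = (arr - mean) / sd
    R = (Z.T @ Z) / (n - 1)

    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    retained = eigval > 1.0 + 1e-10   # tolerance guards the exact-identity case
    if not retained.any():
        raise ValueError("no components retained (all eigenvalues <= 1.0)")
    lam = eigval[retained]
    V = _orient_columns(eigvec[:, retained])
    loadings = V * np.sqrt(lam)

    rotated, _ = varimax(loadings)
    # order rotated components by explained variance, largest first
    ssl = (rotated ** 2).sum(axis=0)
    comp_order = np.argsort(ssl)[::-1]
    rotated = _orient_columns(rotated[:, comp_order])

    # regression-method component scores; pseudo-inverse handles the
    # subjects < regions case where R is rank deficient (rotated loadings lie
    # in the span of the non-null eigenvectors, so the scores are exact)
    coeffs = np.linalg.pinv(R, rcond=1e-10) @ rotated
    scores = Z @ coeffs

    if regression == "logistic":
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000)
        clf.fit(scores, y)
        weights = clf.coef_.ravel()
        intercept = float(clf.intercept_[0])
    else:
        design = np.column_stack([np.ones(n), scores])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        intercept, weights = float(beta[0]), beta[1:]

    try:
        kmo = kmo_measure(arr)
    except np.linalg.LinAlgError:
        kmo = None
    try:
        bartlett = bartlett_sphericity(arr)
    except ValueError:
        bartlett = None

    return PatternModel(
        phase=phase,
        retained_labels=tuple(X.columns),
        mean=mean, sd=sd, eigenvalues=eigval,
        rotated_loadings=rotated,
        score_coefficients=coeffs,
        weights=np.asarray(weights, dtype=float),
        intercept=intercept,
        kmo=kmo, bartlett=bartlett,
    )


def component_scores(X_new: pd.DataFrame, model: PatternModel) -> np.ndarray:
    """Component scores of new subjects under the training standardization."""
    missing = [lab for lab in model.retained_labels if lab not in X_new.columns]
    if missing:
        raise ValueError(f"missing retained region(s): {missing}")
    arr = X_new[list(model.retained_labels)].to_numpy(dtype=float)
    Z = (arr - model.mean) / model.sd
    return Z @ model.score_coefficients


def score_subjects(X_new: pd.DataFrame, model: PatternModel) -> pd.Series:
    """Pattern-expression score per subject: weighted sum of component scores.

    The regression intercept is omitted: it shifts every subject equally and
    cannot change any rank-based downstream quantity.
    """
    scores = component_scores(X_new, model)
    return pd.Series(scores @ model.weights, index=X_new.index, name=f"score_{model.phase.lower()}")


def combine_scores(perfusion, tau):
    """Combined perfusion+tau expression score: the plain sum."""
    return perfusion + tau


def combine_scores_standardized(perfusion: pd.Series, tau: pd.Series,
                                ref_perfusion: pd.Series, ref_tau: pd.Series):
    """Sum of z-scores, each standardized on a reference (training) sample."""
    zp = (perfusion - ref_perfusion.mean()) / ref_perfusion.std(ddof=1)
    zt = (tau - ref_tau.mean()) / ref_tau.std(ddof=1)
    return zp + zt
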