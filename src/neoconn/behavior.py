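"""Outcome preprocessing and the covariate-adjusted association layer.

Behavioural raw scores (CBCL-style internalizing/externalizing problem
counts) are first residualized on corrected age at follow-up and
standardized; all subsequent associations use these age-adjusted scores.
Associations with clinical, environmental and network features are
partial Spearman rank correlations (rank-transform everything, partial
out the ranked covariates by least squares, correlate the residuals),
with Benjamini-Hochberg FDR correction within explicit test families.
Group comparisons across heart-lesion subgroups use the tie-corrected
Kruskal-Wallis H test, suited to the uneven subgroup sizes.

Also provided: CBCL T-score banding (normal < 60, borderline 60-63,
clinical > 63) and the radiological brain-injury grading rules (white
matter injury graded by focus count/size; an overall none-mild vs
moderate-severe rating).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from statsmodels.stats.multitest import multipletests

__all__ = [
    "age_adjust",
    "partial_spearman",
    "PartialCorrelationResult",
    "fdr_adjust",
    "kruskal_wallis",
    "band_tscore",
    "band_counts",
    "classify_wmi",
    "overall_injury",
]


def age_adjust(scores, ages) -> pd.DataFrame:
    """Standardized residuals of raw scores regressed on corrected age.

    Parameters are aligned per subject (same order); subjects with a
    missing score or age are dropped from the fit and absent from the
    output.  Returns a frame with columns raw_score, age, age_adjusted;
    the adjusted column has sample mean 0 and SD 1 over the fitted
    subjects.  An all-residuals-zero fit (scores exactly linear in age)
    is flagged via the ``zero_variance`` attribute and reported as 0s.
    """
    s = pd.Series(np.asarray(scores, float))
    a = pd.Series(np.asarray(ages, float))
    keep = s.notna() & a.notna()
    s, a = s[keep], a[keep]
    if len(s) < 3:
        raise ValueError("need at least 3 subjects with score and age")
    if a.std() == 0:
        raise ValueError("corrected age is constant; regression is rank-deficient")
    X = np.column_stack([np.ones(len(a)), a.to_numpy()])
    beta, *_ = np.linalg.lstsq(X, s.to_numpy(), rcond=None)
    resid = s.to_numpy() - X @ beta
    sd = resid.std(ddof=1)
    zero_variance = sd < 1e-12 * max(1.0, np.abs(s).max())
    adjusted = np.zeros_like(resid) if zero_variance else (resid - resid.mean()) / sd
    out = pd.DataFrame(
        {"raw_score": s.to_numpy(), "age": a.to_numpy(), "age_adjusted": adjusted},
        index=s.index,
    )
    out.attrs["zero_variance"] = bool(zero_variance)
    return out


@dataclass
class PartialCorrelationResult:
    x: str
    y: str
    partial_rho: float
    p_value: float
    n_used: int
    covariates: tuple
    p_fdr: float | None = None


def _rank(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v, method="average")


def partial_spearman(
    x, y, covariates=None, x_name: str = "x", y_name: str = "y"
) -> PartialCorrelationResult:
    """Partial Spearman rank correlation of x and y given covariates.

    Implementation: average-rank transform x, y and each covariate over
    complete cases, residualize the ranked x and y on the ranked
    covariates (with intercept) by least squares, and Pearson-correlate
    the residuals.  The p-value uses the t approximation with
    n - 2 - k degrees of freedom (k covariates).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    covs = [np.asarray(c, float) for c in (covariates or [])]
    mask = np.isfinite(x) & np.isfinite(y)
    for c in covs:
        mask &= np.isfinite(c)
    k = len(covs)
    n = int(mask.sum())
    if n < k + 3:
        raise ValueError(f"need at least {k + 3} complete cases, have {n}")
    rx, ry = _rank(x[mask]), _rank(y[mask])
    Z = np.column_stack([np.ones(n)] + [_rank(c[mask]) for c in covs])
    rx_res = rx - Z @ np.linalg.lstsq(Z, rx, rcond=None)[0]
    ry_res = ry - Z @ np.linalg.lstsq(Z, ry, rcond=None)[0]
    sx, sy = rx_res.std(), ry_res.std()
    if sx < 1e-12 or sy < 1e-12:
        raise ValueError("zero variance after rank residualization")
    rho = float(np.clip((rx_res * ry_res).mean() / (sx * sy), -1.0, 1.0))
    df = n - 2 - k
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho**2))
        p = float(2 * stats.t.sf(abs(t), df))
    return PartialCorrelationResult(
        x=x_name, y=y_name, partial_rho=rho, p_value=p, n_used=n,
        covariates=tuple(f"c{i}" for i in range(k)),
    )


def fdr_adjust(p_values, family=None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, within families.

    ``family`` optionally groups the tests; adjustment is applied
    independently within each group.  Input order is preserved.
    """
    p = np.asarray(p_values, float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    if family is None:
        return multipletests(p, method="fdr_bh")[1] if p.size else p.copy()
    family = np.asarray(family)
    out = np.empty_like(p)
    for f in pd.unique(family):
        idx = np.flatnonzero(family == f)
        out[idx] = multipletests(p[idx], method="fdr_bh")[1]
    return out


def kruskal_wallis(scores, group_labels) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value."""
    scores = np.asarray(scores, float)
    labels = np.asarray(group_labels)
    keep = np.isfinite(scores)
    scores, labels = scores[keep], labels[keep]
    groups = [scores[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if np.ptp(scores) == 0:
        # every observation identical: H is 0 by definition
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def band_tscore(t: float) -> str:
    """CBCL band: normal (T < 60), borderline (60 <= T <= 63), clinical (T > 63)."""
    if t < 60:
        return "normal"
    if t <= 63:
        return "borderline"
    return "clinical"


def band_counts(t_scores) -> dict:
    """Band membership counts for a vector of T-scores."""
    counts = {"normal": 0, "borderline": 0, "clinical": 0}
    for t in np.asarray(t_scores, float):
        counts[band_tscore(t)] += 1
    return counts


def classify_wmi(foci_count: int, max_focus_mm: float = 0.0) -> str:
    """Grade white matter injury from lesion focus count and largest size.

    severe: more than 10 foci; moderate: 4-10 foci, or any focus larger
    than 2 mm; mild: 1-3 foci all at most 2 mm; normal: no foci.
    """
    if foci_count < 0 or max_focus_mm < 0:
        raise ValueError("counts and sizes must be nonnegative")
    if foci_count == 0:
        return "normal"
    if foci_count > 10:
        return "severe"
    if foci_count > 3 or max_focus_mm > 2:
        return "moderate"
    return "mild"


def overall_injury(
    wmi_class: str, cerebellar_hemorrhage_mm: float = 0.0, ivh_present: bool = False
) -> str:
    """Overall brain-injury rating: none_mild vs moderate_severe.

    moderate_severe iff the WMI grade is moderate or severe, or a
    cerebellar haemorrhage exceeds 2 mm; intraventricular haemorrhage and
    small cerebellar haemorrhage stay in the none_mild group.
    """
    if wmi_class not in {"normal", "mild", "moderate", "severe"}:
        raise ValueError(f"unknown WMI class {wmi_class!r}")
    del ivh_present  # IVH alone never escalates the rating
    if wmi_class in {"moderate", "severe"} or cerebellar_hemorrhage_mm > 2:
        return "moderate_severe"
    return "none_mild"
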