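"""Subject-level cohort statistics.

Covers every test the analysis pipeline runs on the manifest and the
overlap tables: the >=8% methylation dichotomization, median split of
the continuous percentage, Pearson chi-square on 2x2 tables (no
continuity correction), pooled-variance two-sample t, Pearson and
first-order partial correlation, a multivariate (Wilks' lambda)
repeated-measures ANOVA over network overlap profiles, and Bonferroni
correction.

Conventions
-----------
* chi-square is the uncorrected Pearson statistic (df=1 upper tail).
* the two-sample t pools variances (Student); Welch is available by
  flag.
* partial correlation uses the first-order formula
  r_xy.z = (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2))
  with a t transform on n-3 degrees of freedom.
* median-split ties go to the low group (deterministic, logged).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

METHYLATION_CUTOFF = 8.0  # percent; >= cutoff is "methylated"


@dataclass
class StatResult:
    """One hypothesis test: statistic, df, p, optional corrected p."""

    test_name: str
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    n: int
    p_corrected: float | None = None
    family_size: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of [0,1]: {self.p_value}")
        if self.p_corrected is not None and self.p_corrected < self.p_value:
            raise ValueError("corrected p cannot be below the raw p")

    def as_row(self) -> dict:
        df = self.df
        return {
            "test": self.test_name,
            "n": self.n,
            "statistic": self.statistic,
            "df": df if np.isscalar(df) else "/".join(str(d) for d in df),
            "p": self.p_value,
            "p_corrected": self.p_corrected,
            "family_size": self.family_size,
        }


# ---------------------------------------------------------------------------
# Dichotomization
# ---------------------------------------------------------------------------


def classify_methylation(pct: float, cutoff: float = METHYLATION_CUTOFF) -> str:
    """``methylated`` iff the methylation percentage is >= ``cutoff`` (inclusive)."""
    if not (0.0 <= pct <= 100.0):
        raise ValueError(f"methylation percentage out of [0,100]: {pct}")
    return "methylated" if pct >= cutoff else "unmethylated"


def classify_methylation_series(pcts: Sequence[float], cutoff: float = METHYLATION_CUTOFF):
    """Vectorized :func:`classify_methylation`; NaN maps to None (missing)."""
    out = []
    for p in np.asarray(pcts, dtype=float):
        out.append(None if np.isnan(p) else classify_methylation(float(p), cutoff))
    return out


def median_split(values: Sequence[float]) -> tuple[np.ndarray, np.ndarray, float]:
    """Split at the sample median; ties are assigned to the low group.

    Returns ``(high, low, cutoff)`` where ``high`` holds the values
    strictly above the median. A degenerate split (all values equal)
    leaves one group empty and emits a warning rather than raising.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("median_split needs at least two values")
    cutoff = float(np.median(v))
    high = v[v > cutoff]
    low = v[v <= cutoff]
    n_ties = int(np.sum(v == cutoff))
    if n_ties:
        logger.info("median_split: %d value(s) equal to the median assigned to the low group", n_ties)
    if high.size == 0 or low.size == 0:
        warnings.warn("median_split produced an empty group (all values identical?)", stacklevel=2)
    return high, low, cutoff


# ---------------------------------------------------------------------------
# Group tests
# ---------------------------------------------------------------------------


def chi_square_2x2(table: Sequence[Sequence[int]]) -> StatResult:
    """Pearson chi-square on a 2x2 table, without continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got {t.shape}")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must hold nonnegative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: a marginal total is zero")
    res = sps.chi2_contingency(t, correction=False)
    return StatResult(
        test_name="chi_square_2x2",
        statistic=float(res.statistic),
        df=1.0,
        p_value=float(res.pvalue),
        n=int(t.sum()),
    )


def two_sample_t(
    x: Sequence[float],
    y: Sequence[float],
    two_tailed: bool = True,
    equal_var: bool = True,
) -> StatResult:
    """Two-sample t-test; pooled variance (Student) by default."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if x.mean() == y.mean():
            df = x.size + y.size - 2
            return StatResult("two_sample_t", 0.0, float(df), 1.0, int(x.size + y.size))
        raise ValueError("zero pooled variance with unequal means: t undefined")
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    p = float(res.pvalue)
    if not two_tailed:
        p = p / 2.0 if res.statistic > 0 else 1.0 - p / 2.0
    return StatResult(
        test_name="two_sample_t" if equal_var else "welch_t",
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=p,
        n=int(x.size + y.size),
    )


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------


def pearson_r(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Pearson correlation with a two-tailed t-transform p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("pearson_r needs n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("pearson_r undefined for a constant variable")
    res = sps.pearsonr(x, y)
    return StatResult(
        test_name="pearson_r",
        statistic=float(res.statistic),
        df=float(x.size - 2),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def partial_r(x: Sequence[float], y: Sequence[float], z: Sequence[float]) -> StatResult:
    """First-order partial correlation of x and y controlling for z.

    Equivalent to correlating the residuals of x and y after removing
    the linear effect of z; p via t = r sqrt((n-3)/(1-r^2)) on n-3 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = x.size
    if not (y.size == n and z.size == n):
        raise ValueError("x, y, z must have equal length")
    if n < 4:
        raise ValueError("partial_r needs n >= 4")
    for name, v in (("x", x), ("y", y), ("z", z)):
        if v.std() == 0:
            raise ValueError(f"partial_r undefined: {name} is constant")
    r_xy = float(np.corrcoef(x, y)[0, 1])
    r_xz = float(np.corrcoef(x, z)[0, 1])
    r_yz = float(np.corrcoef(y, z)[0, 1])
    if abs(r_xz) >= 1.0 - 1e-12 or abs(r_yz) >= 1.0 - 1e-12:
        raise ValueError("partial_r undefined: a control correlation is +/-1")
    denom_sq = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if denom_sq <= 0.0:
        raise ValueError("partial_r undefined: a control correlation is +/-1")
    r = (r_xy - r_xz * r_yz) / np.sqrt(denom_sq)
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 3
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return StatResult(test_name="partial_r", statistic=r, df=float(df), p_value=p, n=int(n))


# ---------------------------------------------------------------------------
# Repeated-measures MANOVA (Wilks' lambda)
# ---------------------------------------------------------------------------


@dataclass
class RMAnovaResult:
    """Multivariate repeated-measures ANOVA output.

    ``condition`` tests whether the within-subject profile is flat
    (lesions distributed unequally across networks); ``interaction``
    — present when a between-subject covariate is supplied — tests
    whether the profile depends on the covariate.
    """

    condition: StatResult
    interaction: StatResult | None = None


def _difference_contrasts(k: int) -> np.ndarray:
    """Orthonormal k x (k-1) within-subject difference contrasts."""
    c = np.zeros((k, k - 1))
    for j in range(k - 1):
        c[j, j] = 1.0
        c[j + 1, j] = -1.0
    q, _ = np.linalg.qr(c)
    return q


def _wilks_f(e: np.ndarray, h: np.ndarray, m: int, df_err: int) -> tuple[float, float, tuple[float, float], float]:
    """Wilks lambda for a single-df hypothesis and its exact F.

    For one hypothesis degree of freedom the transform
    F = ((1 - L)/L) * (df_err - m + 1)/m  with df (m, df_err - m + 1)
    is exact.
    """
    det_e = np.linalg.det(e)
    det_eh = np.linalg.det(e + h)
    if det_eh == 0.0 or not np.isfinite(det_e / det_eh):
        raise np.linalg.LinAlgError("singular contrast-score covariance")
    lam = float(det_e / det_eh)
    if lam <= 0.0:
        raise np.linalg.LinAlgError("singular contrast-score covariance")
    df2 = df_err - m + 1
    if df2 < 1:
        raise ValueError("too few subjects for the multivariate test")
    f = (1.0 - lam) / lam * df2 / m
    p = float(sps.f.sf(f, m, df2))
    return lam, float(f), (float(m), float(df2)), p


def rm_anova_wilks(
    measures: np.ndarray,
    between: Sequence[float] | None = None,
) -> RMAnovaResult:
    """Multivariate repeated-measures ANOVA on an n x k profile matrix.

    The k within-subject conditions (e.g. per-network overlap ratios)
    are reduced to k-1 orthonormal difference-contrast scores. The
    condition effect tests a zero mean contrast vector via Wilks'
    lambda = det(E)/det(E+H) converted to an exact F on
    (k-1, n-k+1) df. With ``between`` (a per-subject covariate, e.g.
    methylation status coded 0/1), the condition x covariate
    interaction is tested by the same statistic on the contrast scores
    regressed on the covariate, F on (k-1, n-k) df.
    """
    y = np.asarray(measures, dtype=float)
    if y.ndim != 2:
        raise ValueError("measures must be an n x k matrix")
    n, k = y.shape
    if k < 2:
        raise ValueError("need at least two within-subject conditions")
    if n <= k - 1:
        raise ValueError(f"need n > k-1 subjects (n={n}, k={k})")
    c = _difference_contrasts(k)
    d = y @ c  # n x (k-1) contrast scores
    m = k - 1

    dbar = d.mean(axis=0)
    resid = d - dbar
    e = resid.T @ resid
    h = n * np.outer(dbar, dbar)
    _, f, df, p = _wilks_f(e, h, m, df_err=n - 1)
    condition = StatResult("rm_anova_condition", f, df, p, n)

    interaction = None
    if between is not None:
        x = np.asarray(between, dtype=float)
        if x.size != n:
            raise ValueError("between covariate length must equal n subjects")
        if x.std() == 0:
            raise ValueError("between covariate is constant")
        xc = x - x.mean()
        sxx = float(xc @ xc)
        beta = (xc @ d) / sxx  # (k-1,)
        fitted = dbar + np.outer(xc, beta)
        resid2 = d - fitted
        e2 = resid2.T @ resid2
        h2 = sxx * np.outer(beta, beta)
        _, f2, df2, p2 = _wilks_f(e2, h2, m, df_err=n - 2)
        interaction = StatResult("rm_anova_condition_by_covariate", f2, df2, p2, n)
    return RMAnovaResult(condition=condition, interaction=interaction)


# ---------------------------------------------------------------------------
# Multiple comparisons
# ---------------------------------------------------------------------------


def bonferroni(
    p_values: Sequence[float], family_size: int | None = None
) -> tuple[np.ndarray, float]:
    """Bonferroni correction: p*m clipped at 1, and the adjusted alpha 0.05/m."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0,1]")
    m = len(p) if family_size is None else int(family_size)
    if m < len(p):
        raise ValueError("family_size cannot be smaller than the number of p-values")
    corrected = np.minimum(1.0, p * m)
    return corrected, 0.05 / m


def involvement_percentages(counts: dict[str, int], n_subjects: int) -> dict[str, float]:
    """Involvement frequencies as percentages of the cohort size."""
    if n_subjects <= 0:
        raise ValueError("n_subjects must be positive")
    return {name: 100.0 * c / n_subjects for name, c in counts.items()}
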