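"""Cohort statistics for severity-grouped wave-intensity studies.

Implements the statistical toolkit used to relate pulmonary-regurgitation
(PR) severity to aortic wave-intensity and hemodynamic outcomes:

* PR severity binning (none / mild / moderate / severe) from the
  regurgitant fraction;
* standard derived ventricular indices (stroke volume, ejection fraction,
  cardiac index) from BSA-indexed volumes;
* four-group comparisons by the Kruskal–Wallis test with Dunn's post hoc
  pairwise z-tests on mean ranks (tie-corrected; raw and
  Bonferroni-adjusted p-values both reported);
* Pearson chi-squared tests for categorical variables;
* ordinary-least-squares regression (one code path for univariate and
  multivariable models);
* two-sample t-test power via the noncentral t distribution, plus the
  inverse problem (minimal n for a target power).

Wave-speed variables automatically exclude subjects whose velocity trace
was computationally rectified (conduction-abnormality cases): those beats
contribute wave-intensity observations but not wave-speed ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DomainError, InsufficientDataError

SEVERITIES = ("none", "mild", "moderate", "severe")

#: variables whose cohort statistics must exclude rectified-velocity beats
WAVE_SPEED_VARIABLES = frozenset(
    {"c", "c_m_per_s", "wave_speed", "D_mmhg", "D_e-3_per_mmHg",
     "distensibility"}
)


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's demographics, volumetry and severity grouping."""

    subject_id: str
    age: float                  # years
    sex: str                    # "M" | "F"
    bsa: float                  # m²
    hr: float                   # beats/min
    pr_pct: float               # regurgitant fraction, %
    lv_edvi: float              # mL/m²
    lv_esvi: float              # mL/m²
    rv_edvi: float
    rv_esvi: float
    adjusted: bool = False
    severity: str = field(init=False)
    lv_sv: float = field(init=False)    # mL
    lv_ef: float = field(init=False)    # %
    lv_ci: float = field(init=False)    # L/min/m²

    def __post_init__(self):
        if not (0 <= self.pr_pct <= 100):
            raise DomainError("PR% must lie in [0, 100]")
        if self.lv_edvi < self.lv_esvi or self.lv_esvi < 0:
            raise DomainError("require EDVi >= ESVi >= 0")
        object.__setattr__(self, "severity", pr_group(self.pr_pct))
        sv, ef, ci = derived_indices(self.lv_edvi, self.lv_esvi,
                                     self.bsa, self.hr)
        object.__setattr__(self, "lv_sv", sv)
        object.__setattr__(self, "lv_ef", ef)
        object.__setattr__(self, "lv_ci", ci)


def pr_group(pr_pct: float) -> str:
    """Severity bin from the pulmonary regurgitant fraction.

    0% → none; (0, 20)% → mild; [20, 40)% → moderate; ≥ 40% → severe.
    """
    if not (0 <= pr_pct <= 100) or not np.isfinite(pr_pct):
        raise DomainError(f"PR% must lie in [0, 100], got {pr_pct}")
    if pr_pct == 0:
        return "none"
    if pr_pct < 20:
        return "mild"
    if pr_pct < 40:
        return "moderate"
    return "severe"


def derived_indices(
    edvi: float, esvi: float, bsa: float, hr: float
) -> tuple[float, float, float]:
    """Stroke volume (mL), ejection fraction (%), cardiac index (L/min/m²)
    from BSA-indexed volumes.

    SV = (EDVi − ESVi)·BSA;  EF = 100·(EDVi − ESVi)/EDVi;
    CI = SV·HR/(1000·BSA).
    """
    if edvi < esvi or esvi < 0:
        raise DomainError("require EDVi >= ESVi >= 0")
    if bsa <= 0 or hr <= 0:
        raise DomainError("BSA and HR must be positive")
    if edvi == 0:
        if esvi == 0:
            raise DomainError("EF undefined for EDVi = 0")
    sv = (edvi - esvi) * bsa
    ef = 100.0 * (edvi - esvi) / edvi if edvi > 0 else np.nan
    ci = sv * hr / (1000.0 * bsa)
    return float(sv), float(ef), float(ci)


# ---------------------------------------------------------------------------
# Group comparisons


def dunn_test(groups: list[np.ndarray]) -> np.ndarray:
    """Dunn's post hoc pairwise z-tests on mean ranks, tie-corrected.

    Returns the symmetric matrix of raw two-sided p-values (diagonal 1).
    The z statistic for groups i, j is

        z = (R̄_i − R̄_j) / sqrt( S² · (1/n_i + 1/n_j) )

    with S² = (N(N+1)/12) − ΣT/(12(N−1)) and ΣT = Σ(t³ − t) over tie
    groups of size t in the pooled sample.
    """
    k = len(groups)
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    sizes = [len(g) for g in groups]
    mean_ranks = []
    start = 0
    for n in sizes:
        mean_ranks.append(np.mean(ranks[start : start + n]))
        start += n
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    s2 = N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1))
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(s2 * (1.0 / sizes[i] + 1.0 / sizes[j]))
            if se == 0:
                pij = 1.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / se
                pij = 2.0 * stats.norm.sf(abs(z))
            p[i, j] = p[j, i] = pij
    return p


@dataclass(frozen=True)
class GroupComparison:
    """Four-group comparison of one variable."""

    variable: str
    group_names: tuple[str, ...]
    n: tuple[int, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    statistic: float            # Kruskal–Wallis H
    p_value: float
    dunn_raw: pd.DataFrame      # pairwise raw p
    dunn_adjusted: pd.DataFrame  # Bonferroni over the pairwise family
    degenerate: bool = False
    excluded_adjusted: int = 0


def group_compare(
    table: pd.DataFrame,
    variable: str,
    group_col: str = "severity",
    adjusted_col: str = "adjusted",
) -> GroupComparison:
    """Kruskal–Wallis + Dunn comparison of ``variable`` across severity groups.

    Wave-speed variables (wave speed, distensibility) automatically drop
    subjects with rectified velocity traces before testing.
    """
    df = table
    excluded = 0
    if variable in WAVE_SPEED_VARIABLES and adjusted_col in df.columns:
        excluded = int(df[adjusted_col].sum())
        df = df[~df[adjusted_col].astype(bool)]
    df = df[np.isfinite(df[variable].astype(float))]
    names = [g for g in SEVERITIES if g in set(df[group_col])]
    names += sorted(set(df[group_col]) - set(SEVERITIES))
    groups = [df.loc[df[group_col] == g, variable].to_numpy(float)
              for g in names]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise InsufficientDataError(
            "need >= 2 groups with >= 2 observations each"
        )
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        k = len(groups)
        ones = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
        return GroupComparison(
            variable=variable,
            group_names=tuple(names),
            n=tuple(len(g) for g in groups),
            means=tuple(float(np.mean(g)) for g in groups),
            sds=tuple(float(np.std(g, ddof=1)) for g in groups),
            statistic=0.0,
            p_value=1.0,
            dunn_raw=ones,
            dunn_adjusted=ones.copy(),
            degenerate=True,
            excluded_adjusted=excluded,
        )
    H, p = stats.kruskal(*groups)
    raw = dunn_test(groups)
    m = len(groups) * (len(groups) - 1) // 2
    adj = np.minimum(raw * m, 1.0)
    np.fill_diagonal(adj, 1.0)
    return GroupComparison(
        variable=variable,
        group_names=tuple(names),
        n=tuple(len(g) for g in groups),
        means=tuple(float(np.mean(g)) for g in groups),
        sds=tuple(float(np.std(g, ddof=1)) for g in groups),
        statistic=float(H),
        p_value=float(p),
        dunn_raw=pd.DataFrame(raw, index=names, columns=names),
        dunn_adjusted=pd.DataFrame(adj, index=names, columns=names),
        excluded_adjusted=excluded,
    )


def chi_square(
    table: pd.DataFrame,
    variable: str,
    group_col: str = "severity",
) -> tuple[float, float, pd.DataFrame]:
    """Pearson chi-squared test of independence between severity group and
    a categorical variable. Zero-margin rows/columns are dropped with a
    warning. Returns (statistic, p, contingency table)."""
    ct = pd.crosstab(table[group_col], table[variable])
    keep_r = ct.sum(axis=1) > 0
    keep_c = ct.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("dropping zero-margin rows/columns from the "
                      "contingency table", stacklevel=2)
        ct = ct.loc[keep_r, keep_c]
    if ct.shape[0] < 2 or ct.shape[1] < 2:
        raise InsufficientDataError("contingency table must be >= 2x2")
    res = stats.chi2_contingency(ct.to_numpy(), correction=False)
    return float(res.statistic), float(res.pvalue), ct


# ---------------------------------------------------------------------------
# Regression


@dataclass(frozen=True)
class RegressionReport:
    """OLS fit of a wave-intensity outcome on clinical predictors."""

    outcome: str
    predictors: tuple[str, ...]
    coefficients: pd.Series     # includes 'const'
    p_values: pd.Series
    r_squared: float
    n: int
    multivariable: bool
    fitted: object = None       # underlying statsmodels results

    def summary(self) -> str:
        head = "multivariable" if self.multivariable else "univariate"
        lines = [
            f"OLS ({head}): {self.outcome} ~ {' + '.join(self.predictors)}",
            f"n = {self.n},  R² = {self.r_squared:.3f}",
        ]
        for name in self.coefficients.index:
            lines.append(
                f"  {name:<16} beta = {self.coefficients[name]: .4g}   "
                f"p = {self.p_values[name]:.4g}"
            )
        return "\n".join(lines)


def regress(
    table: pd.DataFrame, outcome: str, predictors: list[str]
) -> RegressionReport:
    """Ordinary least squares of ``outcome`` on ``predictors``.

    Univariate and multivariable analyses share this one code path; sex is
    coded M=1/F=0 when passed as a predictor. Collinear predictors raise a
    rank-deficiency error naming the offending columns.
    """
    df = table[[outcome, *predictors]].copy()
    if "sex" in predictors:
        df["sex"] = (df["sex"] == "M").astype(float)
    df = df.astype(float).dropna()
    n = len(df)
    if n <= len(predictors) + 1:
        raise InsufficientDataError(
            f"n={n} too small for {len(predictors)} predictors"
        )
    X = sm.add_constant(df[predictors].to_numpy())
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(df[predictors])
        raise DomainError(f"collinear predictors: {', '.join(bad)}")
    fit = sm.OLS(df[outcome].to_numpy(), X).fit()
    names = ["const", *predictors]
    return RegressionReport(
        outcome=outcome,
        predictors=tuple(predictors),
        coefficients=pd.Series(fit.params, index=names),
        p_values=pd.Series(fit.pvalues, index=names),
        r_squared=float(fit.rsquared),
        n=n,
        multivariable=len(predictors) > 1,
        fitted=fit,
    )


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    """Columns implicated in a rank deficiency (smallest-singular-vector
    support, plus constant columns)."""
    bad = [c for c in X.columns if np.ptp(X[c].to_numpy(float)) == 0]
    M = sm.add_constant(X.to_numpy(float))
    _, s, vt = np.linalg.svd(M)
    null_dim = M.shape[1] - np.linalg.matrix_rank(M)
    for row in vt[len(s) - null_dim :] if null_dim else []:
        for i, w in enumerate(row[1:]):  # skip the constant column
            if abs(w) > 1e-8 and X.columns[i] not in bad:
                bad.append(X.columns[i])
    return bad or list(X.columns)


# ---------------------------------------------------------------------------
# Power analysis


def t_power(
    mean1: float,
    mean2: float,
    sd1: float,
    sd2: float,
    n_per_group: int,
    alpha: float = 0.05,
) -> float:
    """Power of the two-sided pooled-variance two-sample t-test.

    Uses the noncentral t distribution with noncentrality
    δ = (μ1 − μ2)/(σ_p·√(2/n)), σ_p² = (sd1² + sd2²)/2, df = 2n − 2.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise DomainError("sds must be positive")
    if n_per_group < 2:
        raise DomainError("need n >= 2 per group")
    if not (0 < alpha < 1):
        raise DomainError("alpha must lie in (0, 1)")
    df = 2 * n_per_group - 2
    sp = np.sqrt((sd1**2 + sd2**2) / 2.0)
    ncp = (mean1 - mean2) / (sp * np.sqrt(2.0 / n_per_group))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    power = stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)
    return float(power)


def required_n(
    mean1: float,
    mean2: float,
    sd1: float,
    sd2: float,
    target_power: float = 0.90,
    alpha: float = 0.05,
    n_max: int = 100_000,
) -> int:
    """Smallest per-group n achieving the target power (companion to
    :func:`t_power`)."""
    if not (0 < target_power < 1):
        raise DomainError("target power must lie in (0, 1)")
    if mean1 == mean2:
        raise DomainError("no detectable difference: power never exceeds alpha")
    for n in range(2, n_max + 1):
        if t_power(mean1, mean2, sd1, sd2, n, alpha) >= target_power:
            return n
    raise InsufficientDataError(f"target power not reached by n={n_max}")
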