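"""Repeatability, pre/post and dimensionality-reduction statistics.

Implements the study's statistics layer: Stata-convention percentiles,
intraclass correlation ICC(A,k) (two-way model, absolute agreement, mean of
k ratings) with parametric or bootstrap confidence intervals, regression
velocity adjustment, session/group comparisons (Kruskal-Wallis,
repeated-measures ANOVA, Mann-Whitney), random-intercept linear mixed
models for pre/post contrasts, and a correlation PCA with correlation
pruning, KMO sampling adequacy and Bartlett's sphericity test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import BASELINE_SESSIONS, StudyTable, ValidationError

__all__ = [
    "median_iqr", "percentile",
    "ICCResult", "icc_ak", "population_icc_ak",
    "velocity_adjust", "compare_groups", "compare_sessions",
    "LMMResult", "fit_prepost_lmm",
    "prune_correlated", "kmo", "bartlett_sphericity",
    "PCAResult", "pca_correlation", "pca_pipeline",
]


# ---------------------------------------------------------------------------
# Percentiles
# ---------------------------------------------------------------------------

def percentile(values, p: float, convention: str = "stata") -> float:
    """Percentile of a sample.

    stata: with h = n*p/100, the average of order statistics h and h+1 when h
    is integral, otherwise order statistic ceil(h) (the convention of the
    study's statistics software; it reproduces the published medians).
    linear: ordinary linear interpolation between order statistics.
    """
    v = np.sort(np.asarray(values, dtype=float))
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValidationError("percentile of an empty sample")
    n = v.size
    if convention == "linear":
        return float(np.percentile(v, p))
    if convention != "stata":
        raise ValueError(f"unknown percentile convention {convention!r}")
    h = n * p / 100.0
    if np.isclose(h, np.round(h)):
        i = int(np.round(h))
        if i <= 0:
            return float(v[0])
        if i >= n:
            return float(v[-1])
        return float(0.5 * (v[i - 1] + v[i]))
    return float(v[min(int(np.ceil(h)), n) - 1])


def median_iqr(values, convention: str = "stata") -> tuple[float, float, float]:
    """(median, q1, q3) of a sample under the chosen percentile convention."""
    return (
        percentile(values, 50, convention),
        percentile(values, 25, convention),
        percentile(values, 75, convention),
    )


# ---------------------------------------------------------------------------
# ICC(A,k)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    method: str
    n_subjects: int
    k_raters: int
    mean_squares: dict = field(default_factory=dict)


def _mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares (rows=subjects, columns=raters/sessions)."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_err = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def _icc_ak_point(x: np.ndarray) -> float:
    n, k = x.shape
    msr, msc, mse = _mean_squares(x)
    denom = msr + (msc - mse) / n
    if denom == 0:
        raise ValidationError("ICC undefined: zero between-subject and error variance")
    return (msr - mse) / denom


def _sb(icc1: float, k: int) -> float:
    """Spearman-Brown step-up from a single-rating to a mean-of-k ICC."""
    return k * icc1 / (1 + (k - 1) * icc1)


def _parametric_ci_ak(x: np.ndarray, alpha: float) -> tuple[float, float]:
    """F-based CI for ICC(A,k): single-rating absolute-agreement bounds with
    Satterthwaite degrees of freedom, stepped up by Spearman-Brown."""
    n, k = x.shape
    msr, msc, mse = _mean_squares(x)
    icc1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    a = k * icc1 / (n * (1 - icc1)) if icc1 < 1 else np.inf
    b = 1 + k * icc1 * (n - 1) / (n * (1 - icc1)) if icc1 < 1 else np.inf
    if not np.isfinite(a):
        return 1.0, 1.0
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num / den if den > 0 else (n - 1) * (k - 1)
    f_u = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_l = sps.f.ppf(1 - alpha / 2, v, n - 1)
    low1 = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
    up1 = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
    return _sb(low1, k), _sb(up1, k)


def icc_ak(
    data,
    ci_method: str = "parametric",
    n_boot: int = 2000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> ICCResult:
    """ICC for absolute agreement of the mean of k ratings, two-way model.

    ``data`` is a subjects x raters matrix (e.g. animals x baseline
    sessions).  Rows with missing cells are dropped with a warning.  The
    bootstrap CI resamples subjects with replacement (percentile method)
    and requires a seed for reproducibility.
    """
    x = np.asarray(pd.DataFrame(data), dtype=float)
    complete = np.all(np.isfinite(x), axis=1)
    if not complete.all():
        warnings.warn(f"dropping {int((~complete).sum())} subject(s) with missing cells")
        x = x[complete]
    n, k = x.shape
    if k < 2:
        raise ValidationError("ICC needs at least 2 raters/sessions")
    if n < 3:
        raise ValidationError("ICC needs at least 3 subjects")
    icc = _icc_ak_point(x)
    msr, msc, mse = _mean_squares(x)
    if ci_method == "parametric":
        lo, hi = _parametric_ci_ak(x, alpha)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_boot):
            xb = x[rng.integers(0, n, size=n)]
            try:
                boots.append(_icc_ak_point(xb))
            except ValidationError:
                continue
        lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        lo, hi = min(lo, icc), max(hi, icc)  # percentile CI contains the estimate
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return ICCResult(
        icc=float(icc), ci_low=float(lo), ci_high=float(hi), method=ci_method,
        n_subjects=n, k_raters=k,
        mean_squares={"msr": msr, "msc": msc, "mse": mse},
    )


def population_icc_ak(sigma_subject: float, sigma_rater: float,
                      sigma_error: float, k: int) -> float:
    """Closed-form population ICC(A,k) from variance components."""
    s2 = sigma_subject ** 2
    return s2 / (s2 + (sigma_rater ** 2 + sigma_error ** 2) / k)


# ---------------------------------------------------------------------------
# Velocity adjustment
# ---------------------------------------------------------------------------

def velocity_adjust(
    table: StudyTable,
    measure: str,
    velocity_measure: str = "mean_forward_velocity",
) -> StudyTable:
    """Regress a measure on walking velocity and keep residual + grand mean.

    A single slope is fitted across all (animal, session, limb) cells in the
    analysis set; the velocity covariate is the trial-global value of the
    matching (animal, session).  With (near-)constant velocity the slope is
    undefined and the measure is returned unadjusted with a warning.
    """
    df = table.df.copy()
    m = df["measure"] == measure
    vel = (df[df["measure"] == velocity_measure]
           .set_index(["animal", "session"])["value"])
    if vel.empty:
        raise ValidationError(f"velocity measure {velocity_measure!r} absent from table")
    sub = df[m]
    v = vel.reindex(pd.MultiIndex.from_frame(sub[["animal", "session"]])).to_numpy()
    y = sub["value"].to_numpy(dtype=float)
    ok = np.isfinite(v) & np.isfinite(y)
    if np.std(v[ok]) < 1e-12:
        warnings.warn("constant velocity: slope undefined, measure left unadjusted")
        return StudyTable(df)
    slope, intercept = np.polyfit(v[ok], y[ok], 1)
    adj = y.copy()
    adj[ok] = y[ok] - (intercept + slope * v[ok]) + y[ok].mean()
    df.loc[m, "value"] = adj
    return StudyTable(df)


# ---------------------------------------------------------------------------
# Session / group comparisons
# ---------------------------------------------------------------------------

def compare_groups(groups: list, design: str) -> tuple[float, float]:
    """Test statistic and p-value comparing independent (or repeated) samples.

    kruskal_wallis: ties-corrected H (asymptotic chi-square p).
    mann_whitney: exact U for small untied samples, otherwise normal
    approximation with ties correction (two-sided).
    rm_anova: one-way repeated measures F across columns of equal length.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in groups):
        raise ValidationError("empty group in comparison")
    if design == "kruskal_wallis":
        res = sps.kruskal(*groups)
        return float(res.statistic), float(res.pvalue)
    if design == "mann_whitney":
        if len(groups) != 2:
            raise ValidationError("Mann-Whitney compares exactly 2 groups")
        res = sps.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    if design == "rm_anova":
        lengths = {g.size for g in groups}
        if len(lengths) != 1:
            raise ValidationError("repeated-measures ANOVA needs balanced groups")
        x = np.column_stack(groups)  # subjects x conditions
        n, k = x.shape
        grand = x.mean()
        ss_cond = n * np.sum((x.mean(axis=0) - grand) ** 2)
        ss_subj = k * np.sum((x.mean(axis=1) - grand) ** 2)
        ss_tot = np.sum((x - grand) ** 2)
        ss_err = ss_tot - ss_cond - ss_subj
        df1, df2 = k - 1, (n - 1) * (k - 1)
        f = (ss_cond / df1) / (ss_err / df2)
        return float(f), float(sps.f.sf(f, df1, df2))
    raise ValueError(f"unknown design {design!r}")


def compare_sessions(
    table: StudyTable,
    measure: str,
    design: str = "kruskal_wallis",
    sessions=BASELINE_SESSIONS,
    limb: str | None = None,
) -> tuple[float, float]:
    """Compare a measure across sessions (paired by animal for rm_anova)."""
    df = table.df
    df = df[df["measure"] == measure]
    if limb is not None:
        df = df[df["limb"] == limb]
    wide = df.pivot_table(index="animal", columns="session", values="value")
    missing = [s for s in sessions if s not in wide.columns]
    if missing:
        raise ValidationError(f"sessions absent from table: {missing}")
    wide = wide[list(sessions)].dropna()
    groups = [wide[s].to_numpy() for s in sessions]
    return compare_groups(groups, design)


# ---------------------------------------------------------------------------
# Pre/post linear mixed models
# ---------------------------------------------------------------------------

@dataclass
class LMMResult:
    measure: str
    fixed_effects: pd.DataFrame  # term, estimate, se, ci_low, ci_high, p
    animal_variance: float
    residual_variance: float
    contrasts: pd.DataFrame      # limb, estimate, se, ci_low, ci_high, p
    converged: bool
    adjusted_for_velocity: bool = False

    def contrast(self, limb: str) -> pd.Series:
        row = self.contrasts[self.contrasts["limb"] == limb]
        if row.empty:
            raise KeyError(limb)
        return row.iloc[0]


def _collapse_prepost(
    table: StudyTable,
    measure: str,
    limbs,
    baseline_sessions,
    post_session: str,
    velocity_measure: str | None,
) -> pd.DataFrame:
    df = table.df
    rows = []
    vel = None
    if velocity_measure is not None:
        vel = (df[df["measure"] == velocity_measure]
               .groupby(["animal", "session"])["value"].mean())
    sub = df[(df["measure"] == measure) & (df["limb"].isin(limbs))]
    for (animal, limb), grp in sub.groupby(["animal", "limb"]):
        per_sess = grp.groupby("session")["value"].mean()
        base = per_sess.reindex(list(baseline_sessions)).dropna()
        if base.empty or post_session not in per_sess.index:
            continue
        for time, value, sessions in (
            (0, float(base.mean()), list(base.index)),
            (1, float(per_sess[post_session]), [post_session]),
        ):
            row = {"animal": animal, "limb": limb, "time": time, "value": value}
            if vel is not None:
                row["velocity"] = float(np.mean([vel.get((animal, s), np.nan)
                                                 for s in sessions]))
            rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValidationError(f"no complete pre/post cells for measure {measure!r}")
    return out


def fit_prepost_lmm(
    table: StudyTable,
    measure: str,
    limbs=("FL_L", "FL_R"),
    adjust_velocity: bool = False,
    group: dict | None = None,
    baseline_sessions=BASELINE_SESSIONS,
    post_session: str = "D3",
    velocity_measure: str = "mean_forward_velocity",
) -> LMMResult:
    """Random-intercept mixed model for the pre/post change in one measure.

    The pre value is the mean of the baseline sessions per animal and limb
    (sessions themselves are the mean of their trials).  Fixed effects are
    time (pre=0, post=1), side (left=0, right=1) and their interaction, with
    an optional velocity covariate; the random intercept is per animal (REML
    fit, normal-approximation p-values).  Per-limb post-minus-pre contrasts
    are returned with 95% CIs.

    ``group`` (animal -> label) replaces the time term with a two-level
    group effect on the pre/post-collapsed data, for between-group analyses
    (sex, infarct-size class); contrasts then estimate the group difference
    per limb.
    """
    import statsmodels.formula.api as smf

    data = _collapse_prepost(
        table, measure, limbs, baseline_sessions, post_session,
        velocity_measure if adjust_velocity else None,
    )
    sides = sorted({l.rsplit("_", 1)[1] for l in limbs})
    data["side"] = [l.rsplit("_", 1)[1] for l in data["limb"]]
    data["side01"] = (data["side"] == "R").astype(float)

    if group is not None:
        data["grp"] = data["animal"].map(group)
        if data["grp"].isna().any():
            raise ValidationError("group mapping does not cover all animals")
        levels = sorted(data["grp"].unique())
        if len(levels) != 2:
            raise ValidationError(f"group term needs 2 levels, got {levels}")
        data = data[data["time"] == 0] if (data["time"] == 0).all() else data
        data["eff"] = (data["grp"] == levels[1]).astype(float)
        eff_name = f"group[{levels[1]}-{levels[0]}]"
    else:
        data["eff"] = data["time"].astype(float)
        eff_name = "time[post-pre]"

    formula = "value ~ eff + side01 + eff:side01"
    if adjust_velocity:
        formula += " + velocity"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data["animal"])
        fit = model.fit(reml=True)
    converged = bool(getattr(fit, "converged", True))
    animal_var = float(max(fit.cov_re.iloc[0, 0], 0.0))
    resid_var = float(fit.scale)
    if animal_var <= 1e-12:
        warnings.warn("singular fit: animal variance estimated as zero")

    params = fit.params
    cov = fit.cov_params()
    fe_terms = [t for t in params.index if t != "Group Var"]
    z = sps.norm.ppf(0.975)
    fe = pd.DataFrame({
        "term": [_pretty_term(t, eff_name) for t in fe_terms],
        "estimate": [float(params[t]) for t in fe_terms],
        "se": [float(np.sqrt(cov.loc[t, t])) for t in fe_terms],
    })
    fe["ci_low"] = fe["estimate"] - z * fe["se"]
    fe["ci_high"] = fe["estimate"] + z * fe["se"]
    fe["p"] = 2 * sps.norm.sf(np.abs(fe["estimate"] / fe["se"]))

    rows = []
    for limb in limbs:
        side01 = 1.0 if limb.endswith("_R") else 0.0
        vec = pd.Series(0.0, index=params.index)
        vec["eff"] = 1.0
        if "eff:side01" in vec.index:
            vec["eff:side01"] = side01
        est = float(vec @ params)
        se = float(np.sqrt(vec @ cov.to_numpy() @ vec))
        rows.append({
            "limb": limb, "estimate": est, "se": se,
            "ci_low": est - z * se, "ci_high": est + z * se,
            "p": float(2 * sps.norm.sf(abs(est / se))) if se > 0 else np.nan,
        })
    contrasts = pd.DataFrame(rows)
    return LMMResult(
        measure=measure, fixed_effects=fe,
        animal_variance=animal_var, residual_variance=resid_var,
        contrasts=contrasts, converged=converged,
        adjusted_for_velocity=adjust_velocity,
    )


def _pretty_term(term: str, eff_name: str) -> str:
    return {
        "Intercept": "intercept",
        "eff": eff_name,
        "side01": "side[R-L]",
        "eff:side01": f"{eff_name}:side[R-L]",
        "velocity": "velocity",
    }.get(term, term)


# ---------------------------------------------------------------------------
# Correlation pruning, KMO, Bartlett, PCA
# ---------------------------------------------------------------------------

def prune_correlated(
    data: pd.DataFrame, r_threshold: float = 0.85
) -> tuple[pd.DataFrame, list[dict]]:
    """Iteratively drop one member of each |r| > threshold variable pair.

    Of the offending pair the variable with the larger mean absolute
    correlation to all other variables is removed (ties toward the
    later column).  Returns the reduced table and a removal log.
    """
    df = data.copy()
    if df.shape[1] < 2:
        raise ValidationError("need at least 2 variables")
    log: list[dict] = []
    while df.shape[1] >= 2:
        corr = df.corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        aa = np.abs(corr)
        i, j = np.unravel_index(np.argmax(aa), aa.shape)
        if aa[i, j] <= r_threshold:
            break
        cols = list(df.columns)
        mean_i = aa[i].sum() / (len(cols) - 1)
        mean_j = aa[j].sum() / (len(cols) - 1)
        if np.isclose(mean_i, mean_j):
            drop = max(i, j)
        else:
            drop = i if mean_i > mean_j else j
        log.append({
            "pair": (cols[min(i, j)], cols[max(i, j)]),
            "r": float(corr[i, j]),
            "removed": cols[drop],
        })
        df = df.drop(columns=[cols[drop]])
    return df, log


def kmo(corr: np.ndarray | pd.DataFrame) -> tuple[pd.Series, float]:
    """Kaiser-Meyer-Olkin sampling adequacy, per variable and overall.

    Computed from squared correlations and squared anti-image partial
    correlations.  For an identity correlation matrix both sums are zero;
    the 0/0 case is defined as 0 (no common variance).
    """
    R = pd.DataFrame(corr)
    names = list(R.columns)
    r = R.to_numpy(dtype=float)
    try:
        rinv = np.linalg.inv(r)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            "singular correlation matrix; prune collinear variables first"
        ) from exc
    d = np.sqrt(np.outer(np.diag(rinv), np.diag(rinv)))
    partial = -rinv / d
    np.fill_diagonal(partial, 0.0)
    r0 = r.copy()
    np.fill_diagonal(r0, 0.0)
    num = (r0 ** 2).sum(axis=0)
    den = num + (partial ** 2).sum(axis=0)
    per_var = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    tot_num = (r0 ** 2).sum()
    tot_den = tot_num + (partial ** 2).sum()
    overall = float(tot_num / tot_den) if tot_den > 0 else 0.0
    return pd.Series(per_var, index=names), overall


def bartlett_sphericity(corr: np.ndarray | pd.DataFrame, n: int) -> tuple[float, int, float]:
    """Bartlett's test that the correlation matrix is the identity.

    chi2 = -(n - 1 - (2p + 5)/6) * ln det(R), df = p(p-1)/2.
    """
    r = np.asarray(pd.DataFrame(corr), dtype=float)
    p = r.shape[0]
    if n <= p:
        raise ValidationError("Bartlett's test needs more observations than variables")
    det = np.linalg.det(r)
    if det <= 0:
        raise ValidationError("non-positive correlation determinant")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * np.log(det)
    df = p * (p - 1) // 2
    return float(chi2), int(df), float(sps.chi2.sf(chi2, df))


@dataclass
class PCAResult:
    retained_variables: list[str]
    kmo_per_variable: pd.Series
    kmo_overall: float
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    eigenvalues: np.ndarray
    n_components: int
    pct_variance: np.ndarray
    cumulative_pct: np.ndarray
    loadings: pd.DataFrame  # variables x PC1..PCp (unit-norm eigenvectors)
    scores: pd.DataFrame | None = None
    pruned: list[dict] = field(default_factory=list)
    kmo_excluded: list[dict] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"PCA on {len(self.retained_variables)} variables",
            f"  KMO overall: {self.kmo_overall:.3f}",
            f"  Bartlett chi2({self.bartlett_df}) = {self.bartlett_chi2:.1f}, "
            f"p = {self.bartlett_p:.2e}",
            f"  components with eigenvalue > 1: {self.n_components}",
            f"  % variance: {np.round(self.pct_variance[:self.n_components], 1)}",
            f"  cumulative: {self.cumulative_pct[self.n_components - 1]:.1f}%",
        ]
        return "\n".join(lines)


def pca_correlation(
    data: pd.DataFrame,
    sign_anchor: str | None = None,
) -> PCAResult:
    """Principal components of the correlation matrix.

    Components are ordered by eigenvalue; loadings are the unit-norm
    eigenvectors, with each component's sign flipped so the anchor variable
    (default: the first column) loads non-negatively on PC1 and each later
    component's largest-magnitude loading is positive.  Percent variance is
    eigenvalue / p x 100; components are retained while eigenvalue > 1.
    """
    df = pd.DataFrame(data)
    if df.isna().any().any():
        raise ValidationError("missing cells in PCA input (no imputation performed)")
    if df.shape[1] < 2 or df.shape[0] < 3:
        raise ValidationError("PCA needs >= 2 variables and >= 3 observations")
    names = list(df.columns)
    R = df.corr()
    evals, evecs = np.linalg.eigh(R.to_numpy())
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # sign convention
    anchor_idx = names.index(sign_anchor) if sign_anchor is not None else 0
    if evecs[anchor_idx, 0] < 0:
        evecs[:, 0] *= -1
    for c in range(1, evecs.shape[1]):
        if evecs[np.argmax(np.abs(evecs[:, c])), c] < 0:
            evecs[:, c] *= -1
    p = len(names)
    pct = evals / p * 100.0
    n_comp = int(np.sum(evals > 1.0))
    try:
        chi2, dfree, pval = bartlett_sphericity(R, len(df))
    except ValidationError:  # rank-deficient input: the test is undefined
        chi2, dfree, pval = np.nan, p * (p - 1) // 2, np.nan
    try:
        per_var, overall = kmo(R)
    except ValidationError:
        per_var = pd.Series(np.nan, index=names)
        overall = np.nan
    z = (df - df.mean()) / df.std(ddof=1)
    scores = pd.DataFrame(
        z.to_numpy() @ evecs, index=df.index,
        columns=[f"PC{i + 1}" for i in range(p)],
    )
    return PCAResult(
        retained_variables=names,
        kmo_per_variable=per_var,
        kmo_overall=overall,
        bartlett_chi2=chi2, bartlett_df=dfree, bartlett_p=pval,
        eigenvalues=evals,
        n_components=n_comp,
        pct_variance=pct,
        cumulative_pct=np.cumsum(pct),
        loadings=pd.DataFrame(evecs, index=names,
                              columns=[f"PC{i + 1}" for i in range(p)]),
        scores=scores,
    )


def pca_pipeline(
    data: pd.DataFrame,
    r_threshold: float = 0.85,
    kmo_threshold: float = 0.5,
    sign_anchor: str | None = None,
) -> PCAResult:
    """Correlation pruning, iterative KMO screening, then correlation PCA.

    Variable pairs with |r| above ``r_threshold`` are pruned first; then the
    variable with the lowest per-variable KMO below ``kmo_threshold`` is
    dropped and the KMO recomputed, repeating until all variables pass.
    Both exclusion steps are logged on the result.
    """
    df, prune_log = prune_correlated(pd.DataFrame(data), r_threshold)
    kmo_log: list[dict] = []
    while df.shape[1] > 2:
        per_var, _ = kmo(df.corr())
        worst = per_var.idxmin()
        if per_var[worst] >= kmo_threshold:
            break
        kmo_log.append({"variable": worst, "kmo": float(per_var[worst])})
        df = df.drop(columns=[worst])
    anchor = sign_anchor if sign_anchor in df.columns else None
    res = pca_correlation(df, sign_anchor=anchor)
    res.pruned = prune_log
    res.kmo_excluded = kmo_log
    return res
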