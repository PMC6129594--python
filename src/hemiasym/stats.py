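"""Group and hemisphere statistics for connectome laterality studies.

The central model is a repeated-measures GLM with hemisphere as a
two-level within-subject factor, group (patients vs controls) between
subjects, their interaction, and age, gender and age-by-gender as
covariates.  A two-level within factor admits an exact sum/difference
decomposition:

* the between-subject (group) effect is the least-squares regression of
  the subject mean (L + R)/2 on group plus covariates;
* the hemisphere main effect and the group-by-hemisphere interaction
  come from regressing the within-subject difference R - L on an
  intercept, group and covariates — the intercept tests the hemisphere
  effect and the group coefficient tests the interaction.

This is algebraically identical to the mixed-model ANOVA for two
levels, and every F reported is the square of the corresponding
regression t with (1, residual) degrees of freedom.

Coding: age is mean-centered, gender and group are effect-coded
(+1/2 / -1/2) so the difference-regression intercept estimates the
grand hemisphere effect, and the age-by-gender product is formed after
centering.

Post hoc tests are pooled-variance two-sample t (df = n1 + n2 - 2) for
group differences and paired t for hemisphere differences.  Asymmetry
scores get a one-sample t against zero within each group and a
univariate ANCOVA (same covariates) for group differences.  Regional
families use Bonferroni correction; correlations between regional
asymmetry and symptom severity are partial correlations (Pearson and
Spearman) within the patient group, left uncorrected as exploratory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "build_design",
    "glm_group_by_hemisphere",
    "one_sample_t",
    "two_sample_t",
    "paired_t",
    "ancova_on_as",
    "bonferroni",
    "partial_correlation",
    "chi_square_counts",
    "run_statistics",
]

logger = logging.getLogger(__name__)


@dataclass
class StatResult:
    """One named statistical effect."""

    effect: str
    statistic_type: str  # 't', 'F' or 'r'
    value: float
    df: tuple[float, ...] | float
    p: float
    n: int
    corrected: bool = False
    correction_method: str = ""
    family_size: int = 1
    metric: str = ""

    def row(self) -> dict:
        df = self.df if isinstance(self.df, tuple) else (self.df,)
        return {
            "effect": self.effect,
            "metric": self.metric,
            "statistic": self.statistic_type,
            "value": self.value,
            "df1": df[0],
            "df2": df[1] if len(df) > 1 else np.nan,
            "p": self.p,
            "n": self.n,
            "corrected": self.corrected,
            "correction": self.correction_method,
            "family_size": self.family_size,
        }


# ---------------------------------------------------------------------------
# design matrix

def build_design(cohort: pd.DataFrame) -> pd.DataFrame:
    """Covariate design from the cohort table.

    Returns a frame indexed like ``cohort`` with columns ``group_ec``
    (BD = +1/2, NC = -1/2), ``age_c`` (mean-centered), ``gender_ec``
    (M = +1/2, F = -1/2) and ``age_x_gender`` (product of the centered
    and effect-coded columns).
    """
    required = {"group", "age", "gender"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if cohort[["age", "gender", "group"]].isna().any().any():
        raise ValueError("missing covariate values in cohort table")
    group = cohort["group"].map({"BD": 0.5, "NC": -0.5})
    if group.isna().any():
        raise ValueError("group labels must be 'BD' or 'NC'")
    gender = cohort["gender"].map({"M": 0.5, "F": -0.5})
    if gender.isna().any():
        raise ValueError("gender labels must be 'M' or 'F'")
    age_c = cohort["age"].astype(float) - cohort["age"].astype(float).mean()
    return pd.DataFrame(
        {
            "group_ec": group.astype(float),
            "age_c": age_c,
            "gender_ec": gender.astype(float),
            "age_x_gender": age_c * gender.astype(float),
        },
        index=cohort.index,
    )


def _ols_t(y: np.ndarray, X: np.ndarray, names: list[str]) -> dict[str, tuple]:
    """Per-coefficient t-tests of an OLS fit; raises on rank deficiency.

    Returns {name: (t, df_resid, p, beta)}.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # identify collinear columns by checking rank drop on removal
        bad = [names[j] for j in range(k)
               if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    if n <= k:
        raise ValueError(f"too few observations ({n}) for {k} parameters")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - k
    sigma2 = resid @ resid / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    out = {}
    for j, name in enumerate(names):
        if se[j] == 0:
            t = 0.0 if beta[j] == 0 else np.sign(beta[j]) * np.inf
        else:
            t = beta[j] / se[j]
        p = 2 * sps.t.sf(abs(t), df) if np.isfinite(t) else 0.0
        out[name] = (float(t), df, float(p), float(beta[j]))
    return out


def glm_group_by_hemisphere(
    left: np.ndarray,
    right: np.ndarray,
    design: pd.DataFrame,
    metric: str = "",
) -> dict[str, StatResult]:
    """Repeated-measures GLM for one metric measured in both hemispheres.

    ``left`` and ``right`` are per-subject values aligned with
    ``design`` (from :func:`build_design`).  Missing pairs are dropped
    listwise.  Returns StatResults keyed ``group``, ``hemisphere`` and
    ``group_x_hemisphere``, each an F with (1, residual) df and, for
    the two difference-based effects, F = t² exactly.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    D = design.to_numpy(dtype=float)
    keep = np.isfinite(left) & np.isfinite(right) & np.isfinite(D).all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("%s: %d subjects dropped (missing values)", metric, n_dropped)
    left, right, D = left[keep], right[keep], D[keep]
    n = left.size
    if "group_ec" not in design.columns:
        raise ValueError("design must contain a 'group_ec' column")
    ones = np.ones((n, 1))
    X = np.hstack([ones, D])
    names = ["intercept"] + list(design.columns)

    mean_y = (left + right) / 2.0
    diff_y = right - left

    between = _ols_t(mean_y, X, names)
    within = _ols_t(diff_y, X, names)

    def as_f(effect: str, t_df_p) -> StatResult:
        t, df, p, _ = t_df_p
        return StatResult(
            effect=effect,
            statistic_type="F",
            value=t * t,
            df=(1.0, float(df)),
            p=p,
            n=n,
            metric=metric,
        )

    return {
        "group": as_f("group", between["group_ec"]),
        "hemisphere": as_f("hemisphere", within["intercept"]),
        "group_x_hemisphere": as_f("group_x_hemisphere", within["group_ec"]),
    }


# ---------------------------------------------------------------------------
# t-tests

def one_sample_t(values, mu0: float = 0.0, metric: str = "",
                 effect: str = "AS_vs_zero") -> StatResult:
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        raise ValueError("one-sample t requires at least 2 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance; t undefined")
    t = (x.mean() - mu0) / (sd / np.sqrt(n))
    p = 2 * sps.t.sf(abs(t), n - 1)
    return StatResult(effect=effect, statistic_type="t", value=float(t),
                      df=float(n - 1), p=float(p), n=n, metric=metric)


def two_sample_t(a, b, metric: str = "", effect: str = "group_diff") -> StatResult:
    """Pooled-variance Student t (df = n1 + n2 - 2), not Welch."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("two-sample t requires at least 2 observations per group")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        raise ValueError("zero pooled variance; t undefined")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * sps.t.sf(abs(t), df)
    return StatResult(effect=effect, statistic_type="t", value=float(t),
                      df=float(df), p=float(p), n=n1 + n2, metric=metric)


def paired_t(x, y, metric: str = "", effect: str = "hemisphere_diff") -> StatResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired t requires equal-length samples")
    keep = np.isfinite(x) & np.isfinite(y)
    res = one_sample_t(x[keep] - y[keep], 0.0, metric=metric, effect=effect)
    return res


# ---------------------------------------------------------------------------
# ANCOVA on asymmetry scores

def ancova_on_as(
    as_values, cohort: pd.DataFrame, design: pd.DataFrame | None = None,
    metric: str = "",
) -> StatResult:
    """Group F-test on asymmetry scores adjusting for the covariates."""
    if design is None:
        design = build_design(cohort)
    y = np.asarray(as_values, dtype=float)
    D = design.to_numpy(dtype=float)
    keep = np.isfinite(y) & np.isfinite(D).all(axis=1)
    y, D = y[keep], D[keep]
    n = y.size
    if "group_ec" not in design.columns:
        raise ValueError("design must contain a 'group_ec' column")
    X = np.hstack([np.ones((n, 1)), D])
    names = ["intercept"] + list(design.columns)
    res = _ols_t(y, X, names)
    t, df, p, _ = res["group_ec"]
    return StatResult(effect="AS_group_diff", statistic_type="F", value=t * t,
                      df=(1.0, float(df)), p=p, n=n, metric=metric)


def bonferroni(p_values, alpha: float = 0.05, m: int | None = None):
    """Family-wise correction: significant iff p < alpha / m.

    Returns ``(mask, adjusted_p, threshold)`` where ``adjusted_p`` is
    ``min(1, m * p)``.  ``m`` defaults to the number of tests.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("family size must be positive")
    threshold = alpha / m
    return p < threshold, np.minimum(1.0, m * p), threshold


# ---------------------------------------------------------------------------
# partial correlation

def partial_correlation(
    x, y, covariates=None, method: str = "pearson", metric: str = ""
) -> StatResult:
    """Correlation of x and y after removing covariates from both.

    Spearman rank-transforms x and y (and the covariates) first, then
    residualizes and correlates, so both variants treat the two sides
    symmetrically.  df = n - 2 - n_covariates.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        C = np.empty((x.size, 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    keep = np.isfinite(x) & np.isfinite(y) & np.isfinite(C).all(axis=1)
    x, y, C = x[keep], y[keep], C[keep]
    n = x.size
    k = C.shape[1]
    if n <= k + 2:
        raise ValueError(f"need more than {k + 2} complete observations, have {n}")
    if method == "spearman":
        x = sps.rankdata(x)
        y = sps.rankdata(y)
        C = np.column_stack([sps.rankdata(c) for c in C.T]) if k else C
    X = np.hstack([np.ones((n, 1)), C])
    rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
    ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    # residual scale relative to the input scale, so an exact linear
    # dependence is caught despite floating-point rounding
    tol_x = 1e-10 * max(1.0, float(np.abs(x).max()))
    tol_y = 1e-10 * max(1.0, float(np.abs(y).max()))
    if rx.std() <= tol_x or ry.std() <= tol_y:
        raise ValueError("constant input after residualization")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    t = r * np.sqrt(df / max(1e-300, 1 - r * r))
    p = 2 * sps.t.sf(abs(t), df)
    return StatResult(effect=f"correlation_{method}", statistic_type="r",
                      value=r, df=float(df), p=float(p), n=n, metric=metric)


def chi_square_counts(table) -> StatResult:
    """Pearson chi-square on a contingency table, no continuity correction."""
    obs = np.asarray(table, dtype=float)
    chi2, p, dof, _ = sps.chi2_contingency(obs, correction=False)
    return StatResult(effect="chi_square", statistic_type="F", value=float(chi2),
                      df=float(dof), p=float(p), n=int(obs.sum()))


# ---------------------------------------------------------------------------
# full battery

GLOBAL_AS_ORDER = ["Eg", "Eloc", "Cp", "Lp", "gamma", "lambda", "sigma"]


def _pivot_metric(asym: pd.DataFrame, cohort: pd.DataFrame):
    """Align asymmetry rows to cohort subject order per metric."""
    by_metric = {}
    order = cohort["subject_id"].tolist()
    for metric, sub in asym.groupby("metric"):
        sub = sub.set_index("subject_id").reindex(order)
        by_metric[metric] = sub
    return by_metric


def run_statistics(
    asym: pd.DataFrame,
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    regional_correction: str = "bonferroni",
) -> dict[str, pd.DataFrame]:
    """The full statistical battery on a cohort's asymmetry table.

    Returns long-format frames: ``glm_global`` and ``glm_nodal``
    (group / hemisphere / interaction F per metric), ``as_tests``
    (per-group one-sample t on AS plus the group ANCOVA),
    ``posthoc`` (paired and two-sample t, emitted when the matching
    omnibus effect clears its threshold) and ``correlations`` (partial
    Pearson and Spearman of nodal AS with YMRS and HAMD in patients).
    Regional families are Bonferroni-corrected over the number of
    regions; global tests use the plain alpha.
    """
    design = build_design(cohort)
    by_metric = _pivot_metric(asym, cohort)
    metrics = list(by_metric)
    global_metrics = [m for m in GLOBAL_AS_ORDER if m in metrics]
    nodal_metrics = sorted(m for m in metrics if m.startswith("Enodal:"))
    n_regions = len(nodal_metrics)

    is_bd = (cohort["group"] == "BD").to_numpy()

    glm_rows: dict[str, list] = {"global": [], "nodal": []}
    as_rows = []
    posthoc_rows = []

    for metric in global_metrics + nodal_metrics:
        sub = by_metric[metric]
        kind = "nodal" if metric.startswith("Enodal:") else "global"
        family = n_regions if kind == "nodal" else 1
        threshold = alpha / family

        left = sub["x_left"].to_numpy(dtype=float)
        right = sub["x_right"].to_numpy(dtype=float)
        as_vals = sub["AS"].to_numpy(dtype=float)

        glm = glm_group_by_hemisphere(left, right, design, metric=metric)
        for res in glm.values():
            res.corrected = kind == "nodal" and regional_correction == "bonferroni"
            res.correction_method = regional_correction if res.corrected else ""
            res.family_size = family
            glm_rows[kind].append(res.row())

        # one-sample t on AS within each group; skip degenerate slices
        for gname, gmask in (("BD", is_bd), ("NC", ~is_bd)):
            vals = as_vals[gmask]
            vals = vals[np.isfinite(vals)]
            if vals.size >= 2 and vals.std(ddof=1) > 0:
                res = one_sample_t(vals, 0.0, metric=metric,
                                   effect=f"AS_vs_zero_{gname}")
                res.corrected = kind == "nodal"
                res.correction_method = regional_correction if res.corrected else ""
                res.family_size = family
                as_rows.append(res.row())
            else:
                logger.warning("metric %s group %s: AS degenerate, t skipped",
                               metric, gname)
        try:
            res = ancova_on_as(as_vals, cohort, design, metric=metric)
            res.corrected = kind == "nodal"
            res.correction_method = regional_correction if res.corrected else ""
            res.family_size = family
            as_rows.append(res.row())
        except ValueError as exc:
            logger.warning("metric %s: ANCOVA skipped (%s)", metric, exc)

        # post hoc, conditional on the omnibus GLM
        if glm["hemisphere"].p < threshold:
            posthoc_rows.append(
                paired_t(right, left, metric=metric,
                         effect="hemisphere_paired_all").row()
            )
        if glm["group"].p < threshold:
            mean_lr = (left + right) / 2.0
            posthoc_rows.append(
                two_sample_t(mean_lr[is_bd], mean_lr[~is_bd], metric=metric,
                             effect="group_two_sample").row()
            )
        if glm["group_x_hemisphere"].p < threshold:
            for gname, gmask in (("BD", is_bd), ("NC", ~is_bd)):
                try:
                    posthoc_rows.append(
                        paired_t(right[gmask], left[gmask], metric=metric,
                                 effect=f"hemisphere_paired_{gname}").row()
                    )
                except ValueError:
                    pass

    # correlations: patients only, nodal AS vs clinical scores
    corr_rows = []
    bd = cohort[is_bd]
    bd_design = pd.DataFrame(
        {
            "age_c": bd["age"].astype(float) - bd["age"].astype(float).mean(),
            "gender_ec": bd["gender"].map({"M": 0.5, "F": -0.5}).astype(float),
        },
        index=bd.index,
    )
    bd_design["age_x_gender"] = bd_design["age_c"] * bd_design["gender_ec"]
    covs = bd_design.to_numpy()
    for metric in nodal_metrics:
        sub = by_metric[metric]
        as_bd = sub["AS"].to_numpy(dtype=float)[is_bd]
        for score in ("ymrs", "hamd"):
            if score not in bd.columns:
                continue
            clin = bd[score].to_numpy(dtype=float)
            for method in ("pearson", "spearman"):
                try:
                    res = partial_correlation(as_bd, clin, covs, method=method,
                                              metric=metric)
                except ValueError as exc:
                    logger.warning("correlation %s/%s/%s skipped (%s)",
                                   metric, score, method, exc)
                    continue
                row = res.row()
                row["clinical_score"] = score.upper()
                corr_rows.append(row)

    def frame(rows: list) -> pd.DataFrame:
        return pd.DataFrame(rows) if rows else pd.DataFrame(
            columns=["effect", "metric", "statistic", "value", "df1", "df2",
                     "p", "n", "corrected", "correction", "family_size"]
        )

    correlations = frame(corr_rows)
    if "clinical_score" not in correlations.columns:
        correlations["clinical_score"] = pd.Series(dtype=str)
    return {
        "glm_global": frame(glm_rows["global"]),
        "glm_nodal": frame(glm_rows["nodal"]),
        "as_tests": frame(as_rows),
        "posthoc": frame(posthoc_rows),
        "correlations": correlations,
    }
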