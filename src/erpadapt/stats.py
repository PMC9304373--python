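"""Inferential layer: repeated-measures models, planned contrasts, effect sizes.

ERP scores are analyzed as a condition (FF, FC, CC, CF) by electrode site
(left, midline, right) repeated-measures design.  For complete balanced data
the model is the classical two-way within-subject decomposition, testing each
effect against its own subject-interaction stratum.  With missing cells (e.g.
conditions dropped for too few epochs) or a covariate, the 12-cell response is
fit as a multivariate normal with unstructured covariance by EM over the
observed cells, and effects are tested with Wald F statistics using an
approximate (possibly fractional) denominator df.

Planned pairwise comparisons are paired t tests reported uncorrected, with
Cohen's d for dependent means defined as mean(diff) / sd(diff).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContrastResult",
    "ModelFit",
    "paired_contrast",
    "one_sample",
    "planned_comparisons",
    "fit_condition_model",
    "PLANNED",
]

CONDITIONS = ("FF", "FC", "CC", "CF")
SITES = ("left", "midline", "right")

#: the three planned comparisons: face sensitivity and the two
#: category-specific repetition (release-from-adaptation) effects
PLANNED = (
    ("sensitivity_FF_vs_CC", "FF", "CC"),
    ("specificity_human_FC_vs_FF", "FC", "FF"),
    ("specificity_cat_CF_vs_CC", "CF", "CC"),
)


@dataclass(frozen=True)
class ContrastResult:
    """Paired (or one-sample) mean difference with t, p, and Cohen's d."""

    name: str
    mean_diff_uV: float
    sd_diff_uV: float
    n: int
    t: float
    df: int
    p: float
    d: float


@dataclass
class ModelFit:
    """Fitted repeated-measures model: F table and estimated marginal means."""

    dependent: str
    method: str  # 'rm_anova' or 'unstructured_em'
    anova: pd.DataFrame  # effect, df1, df2, F, p
    emmeans: pd.Series  # per condition
    cell_means: pd.DataFrame  # condition x site
    n_subjects: int
    covariate: str | None = None
    covariate_slope: float | None = None


def paired_contrast(a: np.ndarray, b: np.ndarray, name: str = "a_vs_b") -> ContrastResult:
    """Paired t test of per-subject values ``a`` against ``b``.

    Pairs with either side missing are dropped.  d = mean(a-b)/sd(a-b);
    t = mean / (sd/sqrt(n)); two-sided p on n-1 df.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    diff = a[keep] - b[keep]
    n = diff.size
    if n < 2:
        raise ValueError("fewer than 2 complete pairs")
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        t = 0.0 if mean == 0.0 else np.inf * np.sign(mean)
        d = t
        p = 1.0 if mean == 0.0 else 0.0
    else:
        t = mean / (sd / np.sqrt(n))
        d = mean / sd
        p = 2.0 * sps.t.sf(abs(t), n - 1)
    return ContrastResult(name, mean, sd, n, float(t), n - 1, float(p), float(d))


def one_sample(values: np.ndarray, name: str = "vs_baseline") -> ContrastResult:
    """One-sample t test of values against zero (e.g., amplitude above baseline)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    return paired_contrast(v, np.zeros_like(v), name=name)


def _subject_condition_values(
    table: pd.DataFrame, value_col: str, component: str | None = None
) -> pd.DataFrame:
    t = table
    if component is not None and "component" in t:
        t = t[t["component"] == component]
    # collapse electrode sites within subject x condition
    return (
        t.groupby(["subject", "condition"])[value_col].mean().unstack("condition")
    )


def planned_comparisons(
    table: pd.DataFrame, value_col: str = "amplitude", component: str | None = "N"
) -> list[ContrastResult]:
    """The three planned pairwise condition comparisons, uncorrected.

    ``table`` is a tidy frame with subject, condition and the value column
    (site-level rows are collapsed by subject-condition means first).
    Returns sensitivity (FF - CC) and the two release-from-adaptation
    contrasts (FC - FF and CF - CC).
    """
    wide = _subject_condition_values(table, value_col, component)
    out = []
    for name, x, y in PLANNED:
        a = wide[x] if x in wide else pd.Series(np.nan, index=wide.index)
        b = wide[y] if y in wide else pd.Series(np.nan, index=wide.index)
        n_complete = int((~(a.isna() | b.isna())).sum())
        if n_complete < 2:  # condition unavailable (e.g. too few epochs)
            out.append(
                ContrastResult(name, np.nan, np.nan, n_complete,
                               np.nan, max(n_complete - 1, 0), np.nan, np.nan)
            )
            continue
        out.append(paired_contrast(a.to_numpy(), b.to_numpy(), name=name))
    return out


# ---------------------------------------------------------------------------
# repeated-measures model


def _rm_anova_complete(Y: np.ndarray) -> pd.DataFrame:
    """Classical two-way within-subject ANOVA on (n, a, b) complete data."""
    n, a, b = Y.shape
    gm = Y.mean()
    s_i = Y.mean(axis=(1, 2))
    c_j = Y.mean(axis=(0, 2))
    e_k = Y.mean(axis=(0, 1))
    sc = Y.mean(axis=2)
    se = Y.mean(axis=1)
    ce = Y.mean(axis=0)

    ss_c = n * b * np.sum((c_j - gm) ** 2)
    ss_e = n * a * np.sum((e_k - gm) ** 2)
    ss_ce = n * np.sum((ce - c_j[:, None] - e_k[None, :] + gm) ** 2)
    ss_cs = b * np.sum((sc - s_i[:, None] - c_j[None, :] + gm) ** 2)
    ss_es = a * np.sum((se - s_i[:, None] - e_k[None, :] + gm) ** 2)
    resid = (
        Y
        - sc[:, :, None]
        - se[:, None, :]
        - ce[None, :, :]
        + s_i[:, None, None]
        + c_j[None, :, None]
        + e_k[None, None, :]
        - gm
    )
    ss_r = np.sum(resid**2)

    rows = []
    for effect, ss, df1, ss_err, df2 in (
        ("condition", ss_c, a - 1, ss_cs, (a - 1) * (n - 1)),
        ("electrode", ss_e, b - 1, ss_es, (b - 1) * (n - 1)),
        ("condition:electrode", ss_ce, (a - 1) * (b - 1), ss_r, (a - 1) * (b - 1) * (n - 1)),
    ):
        F = (ss / df1) / (ss_err / df2)
        rows.append((effect, float(df1), float(df2), float(F), float(sps.f.sf(F, df1, df2))))
    return pd.DataFrame(rows, columns=["effect", "df1", "df2", "F", "p"])


def _em_mvnorm(Y: np.ndarray, max_iter: int = 200, tol: float = 1e-8):
    """ML mean/covariance of row-wise multivariate normal data with NaNs."""
    n, p = Y.shape
    mu = np.nanmean(Y, axis=0)
    var = np.nanvar(Y, axis=0, ddof=0)
    var = np.where(var > 0, var, 1.0)
    Sigma = np.diag(var)
    obs_masks = ~np.isnan(Y)
    for _ in range(max_iter):
        sum_y = np.zeros(p)
        sum_yy = np.zeros((p, p))
        for i in range(n):
            o = obs_masks[i]
            y = Y[i].copy()
            cov_add = np.zeros((p, p))
            if not o.all():
                m = ~o
                Soo = Sigma[np.ix_(o, o)]
                Smo = Sigma[np.ix_(m, o)]
                solve = np.linalg.solve(Soo, (y[o] - mu[o]))
                y[m] = mu[m] + Smo @ solve
                cond_cov = Sigma[np.ix_(m, m)] - Smo @ np.linalg.solve(Soo, Smo.T)
                cov_add[np.ix_(m, m)] = cond_cov
            sum_y += y
            sum_yy += np.outer(y, y) + cov_add
        mu_new = sum_y / n
        Sigma_new = sum_yy / n - np.outer(mu_new, mu_new)
        # keep symmetric positive semidefinite with a tiny ridge
        Sigma_new = (Sigma_new + Sigma_new.T) / 2 + 1e-10 * np.eye(p)
        if np.max(np.abs(mu_new - mu)) < tol and np.max(np.abs(Sigma_new - Sigma)) < tol:
            mu, Sigma = mu_new, Sigma_new
            break
        mu, Sigma = mu_new, Sigma_new
    # information-based covariance of the mean estimate
    info = np.zeros((p, p))
    for i in range(n):
        o = obs_masks[i]
        inv = np.linalg.inv(Sigma[np.ix_(o, o)])
        info[np.ix_(o, o)] += inv
    V = np.linalg.inv(info)
    return mu, Sigma, V, obs_masks


def _effect_contrasts(a: int, b: int) -> dict[str, np.ndarray]:
    """Contrast matrices over the a*b cell-mean vector (condition-major)."""
    Ia, Ib = np.eye(a), np.eye(b)
    one_a, one_b = np.ones((1, a)) / a, np.ones((1, b)) / b
    Da = np.diff(Ia, axis=0)  # (a-1, a) successive differences
    Db = np.diff(Ib, axis=0)
    return {
        "condition": np.kron(Da, one_b),
        "electrode": np.kron(one_a, Db),
        "condition:electrode": np.kron(Da, Db),
    }


def fit_condition_model(
    table: pd.DataFrame,
    dependent: str = "amplitude",
    covariate: str | None = None,
    component: str | None = "N",
) -> ModelFit:
    """Repeated-measures fit of condition x electrode effects on an ERP score.

    ``table`` is tidy with columns subject, condition, roi, and the dependent
    column; missing cells are allowed.  Complete balanced data without a
    covariate is analyzed with the classical within-subject decomposition;
    otherwise an EM fit of the 12-cell multivariate normal with unstructured
    covariance is used and effects are Wald F tests with an approximate
    denominator df.  A covariate (e.g. number of averaged epochs) is removed
    by pooled within-cell regression before modelling.
    """
    t = table
    if component is not None and "component" in t:
        t = t[t["component"] == component]
    t = t[["subject", "condition", "roi", dependent] + ([covariate] if covariate else [])]
    # conditions/sites with no observations at all are dropped from the model
    conds = [c for c in CONDITIONS if c in set(t["condition"])]
    sites = [s for s in SITES if s in set(t["roi"])]
    if len(conds) < 2 or len(sites) < 2:
        raise np.linalg.LinAlgError(
            "singular fit: need at least 2 observed conditions and 2 sites"
        )
    cells = [(c, s) for c in conds for s in sites]
    wide = t.pivot_table(index="subject", columns=["condition", "roi"], values=dependent)
    wide = wide.reindex(columns=pd.MultiIndex.from_tuples(cells))
    Y = wide.to_numpy(dtype=float)
    n_obs_per_subject = (~np.isnan(Y)).sum(axis=1)
    if np.sum(n_obs_per_subject >= 2) < 2:
        raise np.linalg.LinAlgError(
            "singular fit: need at least 2 subjects with at least 2 observed cells"
        )

    slope = None
    if covariate is not None:
        cov_wide = t.pivot_table(index="subject", columns=["condition", "roi"], values=covariate)
        cov_wide = cov_wide.reindex(columns=pd.MultiIndex.from_tuples(cells))
        X = cov_wide.to_numpy(dtype=float)
        # pooled within-cell regression (covariate centered per cell)
        xc = X - np.nanmean(X, axis=0, keepdims=True)
        yc = Y - np.nanmean(Y, axis=0, keepdims=True)
        num = np.nansum(xc * yc)
        den = np.nansum(xc * xc)
        slope = float(num / den) if den > 0 else 0.0
        Y = Y - slope * np.where(np.isnan(xc), 0.0, xc)

    a, b = len(conds), len(sites)
    complete = not np.isnan(Y).any()
    if complete and covariate is None:
        anova = _rm_anova_complete(Y.reshape(-1, a, b))
        mu = Y.mean(axis=0)
        method = "rm_anova"
    else:
        mu, Sigma, V, obs = _em_mvnorm(Y)
        rows = []
        L_all = _effect_contrasts(a, b)
        for effect, L in L_all.items():
            q = L.shape[0]
            est = L @ mu
            W = float(est @ np.linalg.solve(L @ V @ L.T, est))
            # fractional denominator df from effective per-subject completeness
            w = n_obs_per_subject / (a * b)
            df2 = max((w.sum() ** 2) / np.sum(w**2) - 1.0, q + 1e-6)
            F = W / q
            rows.append((effect, float(q), float(df2), float(F), float(sps.f.sf(F, q, df2))))
        anova = pd.DataFrame(rows, columns=["effect", "df1", "df2", "F", "p"])
        method = "unstructured_em"

    cell = pd.DataFrame(
        np.asarray(mu).reshape(a, b), index=list(conds), columns=list(sites)
    )
    emmeans = cell.mean(axis=1)
    emmeans.name = dependent
    if covariate is not None:
        method += "+covariate"
    return ModelFit(
        dependent=dependent,
        method=method,
        anova=anova,
        emmeans=emmeans,
        cell_means=cell,
        n_subjects=Y.shape[0],
        covariate=covariate,
        covariate_slope=slope,
    )
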