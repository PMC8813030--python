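"""Covariate-adjusted group inference, FDR control, and partial correlation.

Edge- and metric-level group effects are tested with a linear model
``y ~ intercept + group dummies + age + sex + education + mean FD`` and an
F-test of the group dummies (full vs reduced model), with Benjamini-
Hochberg FDR across features.  Non-normal outcomes use Kruskal-Wallis with
Dunn/Bonferroni post-hocs.  Associations with cognition are partial
Pearson correlations after residualizing both variables on the nuisance
covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupTestResult",
    "PartialCorrResult",
    "covariate_matrix",
    "covariate_adjust",
    "group_ftest_batch",
    "group_glm_ftest",
    "fdr_bh",
    "kruskal_wallis",
    "posthoc_dunn_bonferroni",
    "partial_correlation",
    "demographics_table",
]

#: Nuisance covariates used throughout, in fixed column order.
COVARIATE_COLUMNS = ("age", "sex", "education", "mean_fd")


@dataclass
class GroupTestResult:
    feature_id: str
    statistic: float
    p: float
    q: float = float("nan")
    group_means: dict[str, float] = field(default_factory=dict)
    test_name: str = "group_glm_ftest"


@dataclass
class PartialCorrResult:
    x_name: str
    y_name: str
    r: float
    p: float
    df: int
    covariate_names: list[str] = field(default_factory=list)


def covariate_matrix(meta: pd.DataFrame) -> np.ndarray:
    """Numeric nuisance-covariate matrix (age, sex 0/1, education, mean FD).

    Sex is coded M=0, F=1; an already-numeric sex column passes through.
    """
    cols = []
    for name in COVARIATE_COLUMNS:
        col = meta[name]
        if name == "sex" and col.dtype == object:
            col = col.map({"M": 0.0, "F": 1.0})
            if col.isna().any():
                raise ValueError("sex column must contain only 'M'/'F'")
        cols.append(np.asarray(col, dtype=float))
    return np.column_stack(cols)


def _design(covariates: np.ndarray | None, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
    if covariates.shape[0] != n:
        covariates = covariates.T
    return np.column_stack([np.ones(n), covariates])


def covariate_adjust(
    y: np.ndarray, covariates: np.ndarray | None
) -> np.ndarray:
    """Least-squares residuals of y on an intercept plus covariates.

    ``y`` may be a vector or an (n, m) matrix of features in columns.
    """
    y = np.asarray(y, dtype=float)
    x = _design(covariates, y.shape[0])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def _rss(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of each column of y on design x (via QR)."""
    q, _ = np.linalg.qr(x)
    fitted_ss = np.sum((q.T @ y) ** 2, axis=0)
    return np.sum(y**2, axis=0) - fitted_ss


def group_ftest_batch(
    y: np.ndarray,
    groups: np.ndarray,
    covariates: np.ndarray | None = None,
    feature_ids: list[str] | None = None,
    q_fdr: float = 0.05,
) -> pd.DataFrame:
    """Covariate-adjusted group F-test for many features at once.

    ``y`` is (n_subjects, n_features); the same design (intercept + group
    dummies + covariates) is shared by all features, so full- and reduced-
    model residual sums of squares are computed by projection.  Returns a
    tidy frame with F, p, BH-adjusted q, rejection flag at ``q_fdr``, and
    covariate-adjusted group means.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[0] != np.asarray(groups).shape[0]:
        y = y.T
    n, m = y.shape
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups).tolist())
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    dummies = np.column_stack(
        [(groups == lev).astype(float) for lev in levels[1:]]
    )
    x_red = _design(covariates, n)
    x_full = np.column_stack([x_red, dummies])
    df_group = dummies.shape[1]
    df_resid = n - x_full.shape[1]
    if df_resid <= 0:
        raise ValueError("not enough subjects for the design")

    rss_full = _rss(x_full, y)
    rss_red = _rss(x_red, y)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = ((rss_red - rss_full) / df_group) / (rss_full / df_resid)
    f = np.where(rss_full <= 0, 0.0, f)
    f = np.maximum(f, 0.0)
    p = sps.f.sf(f, df_group, df_resid)
    p = np.where(f == 0, 1.0, p)  # degenerate zero-variance features
    reject, q = fdr_bh(p, q=q_fdr)

    adj = covariate_adjust(y, covariates) + y.mean(axis=0)
    if feature_ids is None:
        feature_ids = [f"feature{i}" for i in range(m)]
    out = pd.DataFrame({
        "feature_id": feature_ids,
        "F": f,
        "p": p,
        "q": q,
        "reject": reject,
    })
    for lev in levels:
        out[f"mean_{lev}"] = adj[groups == lev].mean(axis=0)
    return out


def group_glm_ftest(
    y: np.ndarray,
    groups: np.ndarray,
    covariates: np.ndarray | None = None,
    feature_id: str = "feature",
) -> GroupTestResult:
    """Single-feature covariate-adjusted group F-test."""
    res = group_ftest_batch(
        np.asarray(y, dtype=float).reshape(-1, 1),
        groups, covariates, feature_ids=[feature_id],
    )
    row = res.iloc[0]
    means = {
        c.removeprefix("mean_"): float(row[c])
        for c in res.columns if c.startswith("mean_")
    }
    return GroupTestResult(
        feature_id=feature_id,
        statistic=float(row["F"]),
        p=float(row["p"]),
        q=float(row["q"]),
        group_means=means,
    )


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject mask, adjusted p-values)."""
    pvals = np.asarray(pvals, dtype=float)
    reject, p_adj, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject, p_adj


def kruskal_wallis(y: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Rank-based H test across groups (ties-corrected, chi-square p).

    Identical values in every group give H = 0, p = 1.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    samples = [y[groups == lev] for lev in pd.unique(groups)]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if np.all(y == y[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*samples)
    return float(h), float(p)


def posthoc_dunn_bonferroni(y: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Dunn pairwise rank z-tests with Bonferroni-multiplied p-values.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)), where
    T is the tie correction sum(t^3 - t) / (12 (N - 1)); two-sided normal
    p-values are multiplied by the number of pairs and capped at 1.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups).tolist())
    ranks = sps.rankdata(y)
    n = y.size
    _, tie_counts = np.unique(y, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    n_pairs = len(levels) * (len(levels) - 1) // 2
    rows = []
    for a in range(len(levels)):
        for b in range(a + 1, len(levels)):
            ga, gb = levels[a], levels[b]
            ra = ranks[groups == ga].mean()
            rb = ranks[groups == gb].mean()
            na = int((groups == ga).sum())
            nb = int((groups == gb).sum())
            se = np.sqrt(var_base * (1.0 / na + 1.0 / nb))
            z = (ra - rb) / se if se > 0 else 0.0
            p_raw = 2.0 * sps.norm.sf(abs(z))
            rows.append({
                "group_a": ga, "group_b": gb, "z": z,
                "p_raw": p_raw,
                "p_bonferroni": min(1.0, n_pairs * p_raw),
            })
    return pd.DataFrame(rows)


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    x_name: str = "x",
    y_name: str = "y",
    covariate_names: list[str] | None = None,
) -> PartialCorrResult:
    """Pearson correlation of covariate-adjusted residuals.

    The t-based p-value uses df = n - 2 - k for k covariates.  With no
    covariates this reduces to the plain Pearson correlation and p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    k = 0
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        k = cov.shape[1]
        rx = covariate_adjust(x, cov)
        ry = covariate_adjust(y, cov)
    else:
        rx, ry = x - x.mean(), y - y.mean()
    df = n - 2 - k
    if df < 1:
        raise ValueError("not enough observations for partial correlation")
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return PartialCorrResult(
        x_name=x_name, y_name=y_name, r=r, p=p, df=df,
        covariate_names=list(covariate_names or []),
    )


def demographics_table(
    meta: pd.DataFrame,
    continuous: tuple[str, ...] = ("age", "education"),
    categorical: tuple[str, ...] = ("sex",),
    clinical_continuous: tuple[str, ...] = (),
    patient_groups: tuple[str, ...] = ("LTLE", "RTLE"),
    chi2_correction: bool = False,
) -> pd.DataFrame:
    """Cohort characteristics table with the matching omnibus test per row.

    Continuous demographics: per-group mean +/- SD and one-way ANOVA across
    all groups.  Categorical: per-group counts and a chi-square test.
    Clinical continuous features: two-sample t-test restricted to the
    patient groups.
    """
    groups = sorted(meta["group"].unique().tolist())
    rows = []
    for name in continuous:
        samples = [meta.loc[meta["group"] == g, name].to_numpy(float)
                   for g in groups]
        if all(np.all(s == samples[0][0]) for s in samples):
            f, p = 0.0, 1.0
        else:
            f, p = sps.f_oneway(*samples)
        row = {"feature": name, "test": "anova",
               "statistic": float(f), "p": float(p)}
        for g, s in zip(groups, samples):
            row[g] = f"{s.mean():.2f} +/- {s.std(ddof=1):.2f}"
        rows.append(row)
    for name in categorical:
        table = pd.crosstab(meta[name], meta["group"])
        if table.to_numpy().min() == table.to_numpy().max() and table.shape[0] == 1:
            chi2, p = 0.0, 1.0
        else:
            chi2, p, _, _ = sps.chi2_contingency(
                table.to_numpy(), correction=chi2_correction
            )
        row = {"feature": name, "test": "chi2",
               "statistic": float(chi2), "p": float(p)}
        for g in groups:
            counts = table[g] if g in table else pd.Series(dtype=int)
            row[g] = "/".join(str(int(v)) for v in counts)
        rows.append(row)
    for name in clinical_continuous:
        present = [g for g in patient_groups if g in groups]
        if len(present) != 2:
            continue
        a = meta.loc[meta["group"] == present[0], name].to_numpy(float)
        b = meta.loc[meta["group"] == present[1], name].to_numpy(float)
        t, p = sps.ttest_ind(a, b)
        row = {"feature": name, "test": "ttest",
               "statistic": float(t), "p": float(p)}
        row[present[0]] = f"{a.mean():.2f} +/- {a.std(ddof=1):.2f}"
        row[present[1]] = f"{b.mean():.2f} +/- {b.std(ddof=1):.2f}"
        rows.append(row)
    return pd.DataFrame(rows)
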