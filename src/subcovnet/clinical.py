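"""Subject-level statistics: composite scores, navigation subgrouping,
ANOVA/ANCOVA with LSD post hoc, exact count tests, partial correlation,
and Benjamini-Hochberg FDR.

Composite cognitive scores are mean z-scores over the tests of a domain
(z over the full analyzed sample; completion-time tests sign-flipped so
higher always means better).  The navigation composite is the
standardized mean distance error over all egocentric and allocentric
trials, *not* sign-flipped: higher = worse navigation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: cognitive test -> (domain, higher_is_better)
DEFAULT_DOMAIN_MAP: dict[str, tuple[str, bool]] = {
    "avlt_immediate": ("memory", True),
    "avlt_short_delayed": ("memory", True),
    "avlt_long_delayed": ("memory", True),
    "avlt_cued": ("memory", True),
    "avlt_recognition": ("memory", True),
    "tmt_a": ("executive", False),  # completion time
    "tmt_b": ("executive", False),
    "sdmt": ("executive", True),
    "cdt": ("executive", True),
    "aft": ("language", True),
    "bnt": ("language", True),
}

EGO_TRIAL_COLUMNS = tuple(f"ego_trial_{i}" for i in range(1, 9))
ALLO_TRIAL_COLUMNS = tuple(f"allo_trial_{i}" for i in range(1, 9))


@dataclass
class StatResult:
    """One test statistic with its p-value and optional adjuncts."""

    name: str  # "F" | "chi2" | "t" | "r" | "p_exact"
    statistic: float
    df: tuple[float, ...] | None
    p: float
    p_adjusted: float | None = None
    group_means: dict[str, float] | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# composites and subgrouping
# ---------------------------------------------------------------------------


def _zscore(x: np.ndarray, label: str) -> np.ndarray:
    sd = np.std(x, ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError(f"test {label!r} has zero variance; cannot standardize")
    return (x - np.mean(x)) / sd


def composite_zscores(
    cohort: pd.DataFrame,
    domain_map: dict[str, tuple[str, bool]] | None = None,
) -> pd.DataFrame:
    """Per-subject composite z-scores for memory/executive/language and
    the navigation distance-error composite.

    Each raw score is standardized over the full sample (ddof=1),
    sign-flipped when higher is worse, and averaged within its domain.
    Navigation = standardized mean distance error over the 16 trials,
    left unflipped (higher error = worse performance).
    """
    dmap = DEFAULT_DOMAIN_MAP if domain_map is None else domain_map
    missing = [t for t in dmap if t not in cohort.columns]
    if missing:
        raise ValueError(f"cohort lacks cognitive test columns: {missing}")
    domains: dict[str, list[np.ndarray]] = {}
    for test, (domain, higher_better) in dmap.items():
        z = _zscore(cohort[test].to_numpy(dtype=float), test)
        domains.setdefault(domain, []).append(z if higher_better else -z)
    out = pd.DataFrame(index=cohort.index)
    for domain, zs in domains.items():
        out[domain] = np.mean(zs, axis=0)
    trial_cols = [c for c in EGO_TRIAL_COLUMNS + ALLO_TRIAL_COLUMNS if c in cohort.columns]
    if trial_cols:
        mean_err = cohort[list(trial_cols)].to_numpy(dtype=float).mean(axis=1)
        out["navigation"] = _zscore(mean_err, "navigation distance error")
    return out


def split_scd_by_score(
    cohort: pd.DataFrame,
    score: pd.Series | np.ndarray,
    scd_mask: pd.Series | np.ndarray | None = None,
    lower_is_better: bool = True,
    odd_rule: str | None = None,
) -> pd.Series:
    """Symmetric median split of the SCD subjects into G-SCD / B-SCD.

    Subjects are ranked by ``score`` (ascending when lower is better);
    the better half is labeled ``G-SCD``, the worse half ``B-SCD``.
    Boundary ties are resolved by stable input order and logged.  An odd
    SCD count raises unless ``odd_rule`` is ``"extra_good"`` or
    ``"extra_bad"``.
    """
    if scd_mask is None:
        scd_mask = cohort["group"].isin(["SCD", "G-SCD", "B-SCD"])
    scd_mask = np.asarray(scd_mask, dtype=bool)
    s = np.asarray(score, dtype=float)
    if s.shape[0] != len(cohort):
        raise ValueError("score must align with the cohort rows")
    if np.isnan(s[scd_mask]).any():
        raise ValueError("missing grouping score for some SCD subjects")
    n_scd = int(scd_mask.sum())
    if n_scd < 2:
        raise ValueError(f"need at least 2 SCD subjects to split, got {n_scd}")
    half, rem = divmod(n_scd, 2)
    if rem:
        if odd_rule == "extra_good":
            half += 1
        elif odd_rule != "extra_bad":
            raise ValueError(
                f"odd SCD count ({n_scd}): pass odd_rule='extra_good' or 'extra_bad'"
            )
    key = s[scd_mask] if lower_is_better else -s[scd_mask]
    order = np.argsort(key, kind="stable")
    ranks = np.empty(n_scd, dtype=int)
    ranks[order] = np.arange(n_scd)
    sorted_key = key[order]
    if half < n_scd and sorted_key[half - 1] == sorted_key[half]:
        logger.warning(
            "median-split tie at the G-SCD/B-SCD boundary (score %g); "
            "resolved by stable input order",
            sorted_key[half],
        )
    labels = pd.Series(cohort["group"].to_numpy(), index=cohort.index, dtype=object)
    scd_idx = np.flatnonzero(scd_mask)
    labels.iloc[scd_idx[ranks < half]] = "G-SCD"
    labels.iloc[scd_idx[ranks >= half]] = "B-SCD"
    return labels


# ---------------------------------------------------------------------------
# classical tests
# ---------------------------------------------------------------------------


def oneway_anova(values: np.ndarray, groups: np.ndarray) -> StatResult:
    """One-way ANOVA F test across the unique group labels."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in pd.unique(groups)]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if all(np.var(s, ddof=1) == 0 for s in samples):
        raise ValueError("zero within-group variance in every group")
    f, p = stats.f_oneway(*samples)
    k = len(samples)
    n = sum(len(s) for s in samples)
    means = {str(g): float(values[groups == g].mean()) for g in pd.unique(groups)}
    return StatResult("F", float(f), (k - 1, n - k), float(p), group_means=means)


def chi_square_test(table: np.ndarray | pd.DataFrame) -> StatResult:
    """Pearson chi-square without continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin")
    chi2, p, dof, _ = stats.chi2_contingency(t, correction=False)
    return StatResult("chi2", float(chi2), (float(dof),), float(p))


def fisher_exact_two_tailed(
    table: np.ndarray, rule: str = "sum-small-p", rel_tol: float = 1e-7
) -> StatResult:
    """Two-tailed Fisher's exact test for a 2x2 table.

    Default rule sums, over all tables with the observed margins, the
    hypergeometric probabilities not exceeding that of the observed table
    (with relative tolerance ``rel_tol`` on the comparison).  The
    "doubling" rule (twice the smaller one-sided p, capped at 1) is
    available as an alternative.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table must be 2x2 with non-negative integer counts")
    a = int(t[0, 0])
    r1 = int(t[0].sum())
    c1 = int(t[:, 0].sum())
    n = int(t.sum())
    dist = stats.hypergeom(n, r1, c1)
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    probs = dist.pmf(support)
    p_obs = dist.pmf(a)
    if rule == "sum-small-p":
        p = float(probs[probs <= p_obs * (1 + rel_tol)].sum())
    elif rule == "doubling":
        lower = float(probs[support <= a].sum())
        upper = float(probs[support >= a].sum())
        p = 2.0 * min(lower, upper)
    else:
        raise ValueError("rule must be 'sum-small-p' or 'doubling'")
    p = float(min(p, 1.0))
    return StatResult("p_exact", p, None, p, extras={"odds_table": t.tolist()})


def two_sample_t(a: np.ndarray, b: np.ndarray) -> StatResult:
    """Pooled-variance two-sample t test, two-tailed."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 observations")
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        if a.mean() == b.mean():
            return StatResult("t", 0.0, (float(na + nb - 2),), 1.0)
        raise ValueError("zero pooled variance with unequal means")
    tstat, p = stats.ttest_ind(a, b, equal_var=True)
    return StatResult("t", float(tstat), (float(na + nb - 2),), float(p))


# ---------------------------------------------------------------------------
# ANCOVA, LSD post hoc, partial correlation
# ---------------------------------------------------------------------------


@dataclass
class AncovaFit:
    """Least-squares fit of outcome ~ group + covariates (internal)."""

    groups: list[str]
    design: np.ndarray
    beta: np.ndarray
    xtx_inv: np.ndarray
    mse: float
    df_resid: int
    covariate_means: np.ndarray
    result: StatResult


def _encode_covariates(covariates: pd.DataFrame | np.ndarray | None) -> np.ndarray:
    if covariates is None:
        return np.empty((0, 0))
    if isinstance(covariates, pd.DataFrame):
        cols = []
        for c in covariates.columns:
            col = covariates[c]
            if col.dtype == object or str(col.dtype) == "category":
                codes, _ = pd.factorize(col)
                cols.append(codes.astype(float))
            else:
                cols.append(col.to_numpy(dtype=float))
        return np.column_stack(cols) if cols else np.empty((len(covariates), 0))
    C = np.asarray(covariates, dtype=float)
    return C.reshape(len(C), -1)


def ancova_group_effect(
    values: np.ndarray,
    groups: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> AncovaFit:
    """One-way ANCOVA: F for the group factor adjusting for covariates.

    F = ((SSE_reduced - SSE_full) / (k - 1)) / MSE_full, where the full
    model is outcome ~ intercept + group dummies + covariates and the
    reduced model drops the group dummies.  Covariate-adjusted group
    means (evaluated at the covariate sample means) are attached.
    """
    y = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    k = len(levels)
    if k < 2:
        raise ValueError("need >= 2 groups")
    C = _encode_covariates(covariates)
    if C.size == 0:
        C = np.empty((len(y), 0))
    if len(C) != len(y):
        raise ValueError("covariates must align with values")
    dummies = np.column_stack([(groups == g).astype(float) for g in levels[1:]])
    X_full = np.column_stack([np.ones(len(y)), dummies, C])
    X_red = np.column_stack([np.ones(len(y)), C])
    rank = np.linalg.matrix_rank(X_full)
    if rank < X_full.shape[1]:
        # name the offending columns for the error message
        names = ["intercept"] + [f"group[{g}]" for g in levels[1:]] + [
            f"covariate[{i}]" for i in range(C.shape[1])
        ]
        r = np.linalg.qr(X_full, mode="r")
        bad = [names[i] for i in np.flatnonzero(np.abs(np.diag(r)) < 1e-10)]
        raise ValueError(f"design matrix is rank deficient (collinear: {bad})")

    beta, _, _, _ = np.linalg.lstsq(X_full, y, rcond=None)
    resid = y - X_full @ beta
    sse_full = float(resid @ resid)
    beta_r, _, _, _ = np.linalg.lstsq(X_red, y, rcond=None)
    resid_r = y - X_red @ beta_r
    sse_red = float(resid_r @ resid_r)
    df_resid = len(y) - X_full.shape[1]
    if df_resid < 1:
        raise ValueError("not enough residual degrees of freedom")
    mse = sse_full / df_resid
    tol = 1e-12 * (float(y @ y) + 1.0)
    delta = max(sse_red - sse_full, 0.0)
    if sse_full < tol:
        # exact fit: no residual variance left; the group factor either
        # explains nothing beyond the covariates (F = 0) or is degenerate
        if delta < tol:
            f, p, mse = 0.0, 1.0, 0.0
        else:
            raise ValueError("zero residual variance with a nonzero group effect")
    else:
        f = delta / (k - 1) / mse
        p = float(stats.f.sf(f, k - 1, df_resid))

    cbar = C.mean(axis=0) if C.shape[1] else np.empty(0)
    adj_means = {}
    for g in levels:
        x = np.concatenate([[1.0], [(g == h) for h in levels[1:]], cbar])
        adj_means[str(g)] = float(x @ beta)
    result = StatResult(
        "F", float(f), (k - 1, df_resid), p, group_means=adj_means
    )
    return AncovaFit(
        groups=[str(g) for g in levels],
        design=X_full,
        beta=beta,
        xtx_inv=np.linalg.pinv(X_full.T @ X_full),
        mse=mse,
        df_resid=df_resid,
        covariate_means=cbar,
        result=result,
    )


def lsd_posthoc(fit: AncovaFit) -> dict[tuple[str, str], StatResult]:
    """Least-significant-difference pairwise comparisons of adjusted means.

    For each group pair, t = (adjusted mean difference) / SE from the
    full-model MSE; two-tailed p with no multiplicity correction (LSD by
    definition leaves the pairwise p-values unadjusted).
    """
    k = len(fit.groups)
    ncov = fit.covariate_means.size
    out: dict[tuple[str, str], StatResult] = {}
    for i in range(k):
        for j in range(i + 1, k):
            c = np.zeros(1 + (k - 1) + ncov)
            if i > 0:
                c[i] = 1.0
            if j > 0:
                c[j] = -1.0
            diff = float(c @ fit.beta)
            se = math.sqrt(float(c @ fit.xtx_inv @ c) * fit.mse)
            t = diff / se
            p = 2.0 * float(stats.t.sf(abs(t), fit.df_resid))
            out[(fit.groups[i], fit.groups[j])] = StatResult(
                "t", t, (float(fit.df_resid),), p, extras={"diff": diff, "se": se}
            )
    return out


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: pd.DataFrame | np.ndarray | None = None
) -> StatResult:
    """Pearson correlation of x and y after residualizing both on the
    covariates (plus intercept); p from t = r sqrt((n-2-k)/(1-r^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    C = _encode_covariates(covariates)
    if C.size == 0:
        C = np.empty((len(x), 0))
    ncov = C.shape[1]
    n = len(x)
    if n <= ncov + 2:
        raise ValueError(f"need n > {ncov + 2} observations, got {n}")
    design = np.column_stack([np.ones(n), C])
    bx, *_ = np.linalg.lstsq(design, x, rcond=None)
    by, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ bx
    ry = y - design @ by
    if np.std(rx) <= 1e-10 * (np.std(x) + 1) or np.std(ry) <= 1e-10 * (np.std(y) + 1):
        raise ValueError("constant residuals; partial correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - ncov
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
        t = math.inf if r > 0 else -math.inf
    else:
        t = r * math.sqrt(df / (1 - r * r))
        p = 2.0 * float(stats.t.sf(abs(t), df))
    return StatResult("r", r, (float(df),), p, extras={"t": t})


def fdr_adjust(p_values: np.ndarray, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method != "bh":
        raise ValueError("only the Benjamini-Hochberg ('bh') method is implemented")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q
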