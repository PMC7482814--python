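"""Feature selection and differential/association statistics on SUI profiles.

The two-group test is an empirical-Bayes moderated t: per-tandem residual
variances are shrunk toward a common value by moment-matching a scaled-F
model for the sample variances, adding ``d0`` prior degrees of freedom.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

SHORTENED = "shortened"
LENGTHENED = "lengthened"


def cv_rank_select(sui: pd.DataFrame, top_fraction: float = 0.25) -> list[str]:
    """Top tandems by absolute coefficient of variation of SUI.

    ``CV_t = sd_t / |mean_t|`` (sample sd).  Exactly
    ``floor(top_fraction * n)`` tandems are returned, ranked descending by
    CV with ties broken by tandem id.  A mean of exactly 0 gives infinite
    CV (maximally variable).
    """
    if sui.shape[1] < 2:
        raise ValueError("need at least 2 samples for a CV")
    mean = sui.mean(axis=1)
    sd = sui.std(axis=1, ddof=1)
    with np.errstate(divide="ignore"):
        cv = (sd / mean.abs()).to_numpy()
    zero = mean.to_numpy() == 0
    if zero.any():
        logger.info("CV ranking: %d tandems with mean 0 set to +inf", zero.sum())
        cv = np.where(zero, np.inf, cv)
    order = pd.DataFrame({"cv": cv, "tid": sui.index.astype(str)}).sort_values(
        ["cv", "tid"], ascending=[False, True], kind="mergesort"
    )
    k = int(top_fraction * len(sui))
    return list(order["tid"].iloc[:k])


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match d0 and s0^2 for the scaled-F model of sample variances.

    Works on ``e = log s^2`` corrected for the known finite-df bias; the
    excess spread of ``e`` over ``trigamma(df/2)`` determines the prior
    degrees of freedom ``d0`` (infinite if there is no excess spread).
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-300)
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    G = len(e)
    e_var = ((e - e_mean) ** 2).sum() / (G - 1) if G > 1 else 0.0
    excess = e_var - polygamma(1, df / 2.0)
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0_sq)


def moderated_two_group_test(
    sui: pd.DataFrame,
    labels: pd.Series,
    group_a: str | None = None,
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-group t-test per tandem.

    ``labels`` assigns each sample column to one of two groups; ``group_a``
    names the group whose mean enters positively in ``dsui`` (default: the
    lexicographically larger level, so "tumor" vs "normal" reports
    tumor - normal).  Returns a DataFrame with per-tandem group means,
    dsui, moderated t, raw p and BH-adjusted q.

    ``d0_override`` pins the prior degrees of freedom (0 recovers the
    ordinary pooled t; inf uses the common variance only).
    """
    labels = labels.loc[list(sui.columns)]
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    if group_a is None:
        group_a = levels[1]
    group_b = [l for l in levels if l != group_a][0]
    a_cols = list(labels.index[labels == group_a])
    b_cols = list(labels.index[labels == group_b])
    n1, n2 = len(a_cols), len(b_cols)
    if min(n1, n2) < 2:
        raise ValueError("need >= 2 samples per group")
    df_resid = n1 + n2 - 2
    if df_resid < 1:
        raise ValueError("zero residual degrees of freedom")

    A = sui[a_cols].to_numpy(dtype=float)
    B = sui[b_cols].to_numpy(dtype=float)
    m1, m2 = A.mean(axis=1), B.mean(axis=1)
    ss = ((A - m1[:, None]) ** 2).sum(axis=1) + ((B - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid

    if d0_override is None:
        d0, s0_sq = _fit_f_dist(s2, df_resid)
    else:
        d0 = float(d0_override)
        _, s0_sq = _fit_f_dist(s2, df_resid) if d0 != 0 else (0.0, 0.0)

    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_tilde = s2
        df_total = df_resid
    else:
        s2_tilde = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (m1 - m2) / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "tandem_id": sui.index.astype(str),
            f"mean_{group_a}": m1,
            f"mean_{group_b}": m2,
            "dsui": m1 - m2,
            "t": t,
            "p": p,
            "q": q,
        }
    ).set_index("tandem_id")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_direction(
    results: pd.DataFrame, dsui_min: float = 0.2, q_max: float = 0.05
) -> pd.DataFrame:
    """Label shortening / lengthening events at the reporting thresholds.

    Shortened: ``dsui >= dsui_min`` and ``q <= q_max``; lengthened:
    ``dsui <= -dsui_min`` and ``q <= q_max``; otherwise no call.
    """
    out = results.copy()
    direction = np.full(len(out), "", dtype=object)
    sig = out["q"].to_numpy() <= q_max
    direction[(out["dsui"].to_numpy() >= dsui_min) & sig] = SHORTENED
    direction[(out["dsui"].to_numpy() <= -dsui_min) & sig] = LENGTHENED
    out["direction"] = direction
    return out


def sui_expression_correlation(
    sui: pd.DataFrame,
    expression: pd.DataFrame,
    tandem_gene: pd.Series,
    seed: int = 0,
) -> tuple[pd.Series, dict]:
    """Pearson r between SUI and gene expression, with a bimodality summary.

    Each tandem is matched to its gene's expression row; r is computed
    across shared samples.  A 2-component Gaussian mixture (EM, 10 seeded
    restarts) summarizes the r distribution: component means and weights.
    """
    shared = [s for s in sui.columns if s in expression.columns]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples")
    rs = {}
    for tid in sui.index:
        gene = tandem_gene.get(tid)
        if gene is None or gene not in expression.index:
            continue
        x = sui.loc[tid, shared].to_numpy(dtype=float)
        y = expression.loc[gene, shared].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            rs[tid] = np.nan
            continue
        rs[tid] = float(np.corrcoef(x, y)[0, 1])
    r = pd.Series(rs, name="pearson_r")
    finite = r.dropna().to_numpy()
    summary: dict = {"n": int(len(finite))}
    if len(finite) >= 4:
        gm = GaussianMixture(n_components=2, n_init=10, random_state=seed)
        gm.fit(finite.reshape(-1, 1))
        order = np.argsort(gm.means_.ravel())
        summary["component_means"] = [float(m) for m in gm.means_.ravel()[order]]
        summary["component_weights"] = [float(w) for w in gm.weights_[order]]
    return r, summary


def iqr_variance_summary(
    sui: pd.DataFrame,
    groups: pd.Series,
    subset: list[str] | None = None,
    iqr_min: float = 0.8,
) -> pd.Series:
    """Percentage of tandems with SUI IQR >= ``iqr_min``, per sample group.

    IQR uses linear-interpolation (type-7) quantiles.  ``subset`` restricts
    the tandems considered (e.g. clinically actionable genes).
    """
    if subset is not None:
        if len(subset) == 0:
            raise ValueError("empty tandem subset")
        sui = sui.loc[[t for t in subset if t in sui.index]]
    groups = groups.loc[[s for s in sui.columns if s in groups.index]]
    out = {}
    for g in sorted(groups.unique()):
        cols = list(groups.index[groups == g])
        if len(cols) < 4:
            warnings.warn(f"group {g!r} has < 4 samples; IQR summary unstable")
        vals = sui[cols].to_numpy(dtype=float)
        q75, q25 = np.percentile(vals, [75, 25], axis=1)
        out[g] = 100.0 * float(np.mean((q75 - q25) >= iqr_min))
    return pd.Series(out, name=f"pct_iqr_ge_{iqr_min}")


def composition_percentages(
    counts: dict[str, int], total: int | None = None, decimals: int = 1
) -> dict[str, float]:
    """Percent composition of category counts, rounded for reporting."""
    tot = total if total is not None else sum(counts.values())
    if tot <= 0:
        raise ValueError("total must be positive")
    return {k: round(100.0 * v / tot, decimals) for k, v in counts.items()}
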