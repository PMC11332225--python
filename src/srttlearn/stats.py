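"""Statistical battery: ANOVAs, Tukey pairwise tests, effect sizes, Bayes factors.

One-way between-subjects ANOVA with eta-squared and a noncentral-F confidence
interval; mixed (between x within) ANOVA with Mauchly's sphericity test and
Greenhouse-Geisser df correction; Tukey HSD pairwise comparisons with Hedges'
g (noncentral-t CI); one-sample t tests; the default JZS Bayes factor for t
statistics (Cauchy prior, scale sqrt(2)/2, exact quadrature); BIC-approximated
Bayes factors for nested (mixed) linear models; and the moderated regression
relating micro-offline to macro-offline gains with young adults as reference
group.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
from scipy import integrate, optimize, stats

DEFAULT_JZS_SCALE = math.sqrt(2) / 2


@dataclass
class AnovaResult:
    effect: str
    F: float
    df1: float
    df2: float
    p: float
    eta2: float | None = None
    partial_eta2: float | None = None
    eta2_ci: tuple[float, float] | None = None
    epsilon_gg: float | None = None
    sphericity_p: float | None = None
    gg_applied: bool = False
    bf10: float | None = None

    @property
    def trend(self) -> bool:
        """Non-significant trend flag: 0.05 < p < 0.1."""
        return 0.05 < self.p < 0.1


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    mean_diff: float
    tukey_p: float
    hedges_g: float
    g_ci_95: tuple[float, float]
    bf10: float | None = None


# ---------------------------------------------------------------------------
# noncentrality helpers
# ---------------------------------------------------------------------------

def _ncf_lambda_bounds(F: float, df1: float, df2: float, conf: float = 0.95) -> tuple[float, float]:
    """Confidence bounds on the noncentrality of an observed F (Steiger-style)."""
    alpha = 1.0 - conf
    fobs = max(F, 0.0)

    def cdf(lam):
        return stats.ncf.cdf(fobs, df1, df2, lam)

    def solve(target):
        if cdf(0.0) <= target:
            return 0.0
        hi = 1.0
        while cdf(hi) > target:
            hi *= 2.0
            if hi > 1e7:
                return hi
        return optimize.brentq(lambda lam: cdf(lam) - target, 0.0, hi, xtol=1e-8)

    lam_lo = solve(1.0 - alpha / 2.0)
    lam_hi = solve(alpha / 2.0)
    return lam_lo, lam_hi


def _eta2_ci(F: float, df1: float, df2: float, conf: float = 0.95) -> tuple[float, float]:
    lam_lo, lam_hi = _ncf_lambda_bounds(F, df1, df2, conf)
    n = df1 + df2 + 1.0
    return (lam_lo / (lam_lo + n), lam_hi / (lam_hi + n))


# ---------------------------------------------------------------------------
# one-way ANOVA
# ---------------------------------------------------------------------------

def _split_groups(values, groups) -> dict[str, np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups).tolist(), key=str)
    out = {str(g): values[groups == g] for g in labels}
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in out.items():
        if len(v) < 2:
            raise ValueError(f"group {g} has fewer than 2 values")
    return out


def one_way_anova(values, groups, compute_bf: bool = True) -> AnovaResult:
    """Classical between-subjects one-way ANOVA with eta-squared and its CI.

    ``F = MSB/MSW``; ``eta2 = SSB/SST``; the 95% CI on eta-squared comes from
    inverting the noncentral-F distribution; BF10 compares the group model
    against the intercept-only null via the BIC approximation.
    """
    by = _split_groups(values, groups)
    allv = np.concatenate(list(by.values()))
    n, k = len(allv), len(by)
    grand = allv.mean()
    ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in by.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in by.values())
    sst = ssb + ssw
    if sst <= 0:
        raise ValueError("zero total variance: F undefined")
    df1, df2 = k - 1, n - k
    if ssw == 0:
        raise ValueError("zero within-group variance: F undefined")
    F = (ssb / df1) / (ssw / df2)
    p = stats.f.sf(F, df1, df2)
    eta2 = ssb / sst
    bf = None
    if compute_bf:
        y = allv
        g_labels = np.concatenate([[g] * len(v) for g, v in by.items()])
        X = pd.get_dummies(pd.Series(g_labels), drop_first=True, dtype=float).to_numpy()
        bf = _bic_bf(y, np.column_stack([np.ones(n), X]), np.ones((n, 1)))
    return AnovaResult(
        effect="group",
        F=float(F),
        df1=float(df1),
        df2=float(df2),
        p=float(p),
        eta2=float(eta2),
        eta2_ci=_eta2_ci(F, df1, df2),
        epsilon_gg=None,
        bf10=bf,
    )


# ---------------------------------------------------------------------------
# mixed ANOVA
# ---------------------------------------------------------------------------

def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    within: str,
    between: str,
    subject: str,
    gg_alpha: float = 0.05,
    compute_bf: bool = True,
) -> list[AnovaResult]:
    """Mixed ANOVA (one between-, one within-subject factor).

    Requires a complete balanced-within design (every subject measured at
    every within level); incomplete participants must be removed upstream
    (listwise deletion). The Greenhouse-Geisser epsilon multiplies the
    within/interaction dfs whenever Mauchly's test rejects sphericity at
    ``gg_alpha`` (and the within factor has more than 2 levels; with m = 2
    sphericity holds and epsilon = 1 analytically). Per-effect BF10 values
    use the BIC approximation on linear mixed models with a subject random
    intercept; the null model is the subject random effect alone.
    """
    d = data[[subject, between, within, dv]].copy()
    if d[dv].isna().any():
        raise ValueError("missing values in dv: apply listwise deletion upstream")
    pivot = d.pivot_table(index=subject, columns=within, values=dv, aggfunc="count")
    if pivot.isna().any().any() or (pivot != 1).any().any():
        raise ValueError(
            "incomplete or duplicated cells: every subject needs exactly one "
            "value per within level (listwise-delete incomplete subjects upstream)"
        )
    if d.groupby(subject)[between].nunique().max() > 1:
        raise ValueError("subjects must be nested within between-groups")

    levels = sorted(pd.unique(d[within]).tolist(), key=str)
    m = len(levels)
    if m == 1:
        res = one_way_anova(d[dv], d[between], compute_bf=compute_bf)
        res.effect = between
        return [res]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.mixed_anova(
            data=d, dv=dv, within=within, between=between, subject=subject,
            correction=True, effsize="np2",
        )
    aov = aov.set_index("Source")
    wrow = aov.loc[within]

    if m == 2:
        eps, spher_p = 1.0, None
    else:
        eps = float(wrow["eps"])
        spher_p = float(wrow["p_spher"]) if np.isfinite(wrow["p_spher"]) else None
    apply_gg = m > 2 and spher_p is not None and spher_p < gg_alpha

    results = []
    for label, key in ((between, between), (within, within), ("interaction", "Interaction")):
        row = aov.loc[key]
        F = float(row["F"])
        df1, df2 = float(row["DF1"]), float(row["DF2"])
        if apply_gg and key != between:
            df1, df2 = df1 * eps, df2 * eps
        p = float(stats.f.sf(F, df1, df2))
        results.append(
            AnovaResult(
                effect=label,
                F=F,
                df1=df1,
                df2=df2,
                p=p,
                partial_eta2=float(row["np2"]),
                eta2_ci=_eta2_ci(F, df1, df2),
                epsilon_gg=eps if key != between else None,
                sphericity_p=spher_p if key != between else None,
                gg_applied=apply_gg and key != between,
            )
        )

    if compute_bf:
        y = d[dv].to_numpy(dtype=float)
        groups = d[subject].to_numpy()
        Xb = pd.get_dummies(d[between].astype(str), drop_first=True, dtype=float).to_numpy()
        Xw = pd.get_dummies(d[within].astype(str), drop_first=True, dtype=float).to_numpy()
        Xi = np.column_stack([Xb[:, i] * Xw[:, j] for i in range(Xb.shape[1]) for j in range(Xw.shape[1])])
        ones = np.ones((len(y), 1))
        both = np.column_stack([ones, Xb, Xw])
        bic_b = _mixed_bic(y, np.column_stack([ones, Xw]), groups)
        bic_w = _mixed_bic(y, np.column_stack([ones, Xb]), groups)
        bic_bw = _mixed_bic(y, both, groups)
        bic_full = _mixed_bic(y, np.column_stack([both, Xi]), groups)
        results[0].bf10 = _bf_from_bics(bic_b, bic_bw)
        results[1].bf10 = _bf_from_bics(bic_w, bic_bw)
        results[2].bf10 = _bf_from_bics(bic_bw, bic_full)
    return results


def _bf_from_bics(bic_reduced: float, bic_full: float) -> float:
    """BF10 = exp((BIC_reduced - BIC_full)/2), kept finite."""
    return float(math.exp(min((bic_reduced - bic_full) / 2.0, 700.0)))


def _mixed_bic(y, X, groups) -> float:
    # random-intercept variances near the boundary can break one optimizer's
    # Hessian inversion; fall through a chain before giving up
    last: Exception | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "bfgs", "cg", "powell"):
            try:
                fit = sm.MixedLM(y, X, groups=groups).fit(reml=False, method=method)
                return float(fit.bic)
            except Exception as e:  # LinAlgError, convergence failures
                last = e
    raise RuntimeError(f"mixed-model fit failed: {last}")


def _bic_bf(y, X_full, X_reduced) -> float:
    full = sm.OLS(y, X_full).fit()
    red = sm.OLS(y, X_reduced).fit()
    return _bf_from_bics(float(red.bic), float(full.bic))


# ---------------------------------------------------------------------------
# pairwise comparisons and effect sizes
# ---------------------------------------------------------------------------

def hedges_g(a, b, conf: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Small-sample corrected standardized mean difference with noncentral-t CI.

    ``g = J * (mean_a - mean_b) / s_pooled`` with ``J = 1 - 3/(4*df - 1)``,
    ``df = n_a + n_b - 2``. The CI inverts the noncentral-t distribution of
    the two-sample t statistic.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each sample needs n >= 2")
    df = na + nb - 2
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df
    diff = a.mean() - b.mean()
    if sp2 == 0:
        if diff == 0:
            return 0.0, (0.0, 0.0)
        raise ValueError("zero pooled variance with unequal means: infinite effect")
    J = 1.0 - 3.0 / (4.0 * df - 1.0)
    d = diff / math.sqrt(sp2)
    g = J * d
    ntilde = na * nb / (na + nb)
    tval = d * math.sqrt(ntilde)

    def solve(target):
        # ncp bound: nct.cdf(t; df, ncp) == target
        f = lambda ncp: stats.nct.cdf(tval, df, ncp) - target
        lo, hi = tval - 2.0, tval + 2.0
        while f(lo) < 0:
            lo -= 5.0
        while f(hi) > 0:
            hi += 5.0
        return optimize.brentq(f, lo, hi, xtol=1e-8)

    alpha = 1.0 - conf
    ncp_lo = solve(1.0 - alpha / 2.0)
    ncp_hi = solve(alpha / 2.0)
    ci = (J * ncp_lo / math.sqrt(ntilde), J * ncp_hi / math.sqrt(ntilde))
    return float(g), (float(ci[0]), float(ci[1]))


def tukey_pairwise(values, groups, compute_bf: bool = True) -> list[PairwiseResult]:
    """Tukey HSD pairwise comparisons over all unordered group pairs.

    p-values come from the studentized-range distribution with the pooled
    within-group mean square; each pair also carries Hedges' g with its 95%
    CI and a JZS BF10 computed from the pair's two-sample t statistic.
    """
    by = _split_groups(values, groups)
    labels = list(by.keys())
    res = stats.tukey_hsd(*[by[g] for g in labels])
    out = []
    for i, j in itertools.combinations(range(len(labels)), 2):
        a, b = by[labels[i]], by[labels[j]]
        g, ci = hedges_g(a, b)
        bf = None
        if compute_bf:
            t, _ = stats.ttest_ind(a, b)
            bf = jzs_bf_ttest(float(t), len(a), len(b))
        out.append(
            PairwiseResult(
                group_a=labels[i],
                group_b=labels[j],
                mean_diff=float(a.mean() - b.mean()),
                tukey_p=float(res.pvalue[i, j]),
                hedges_g=g,
                g_ci_95=ci,
                bf10=bf,
            )
        )
    return out


def one_sample_t(values, mu0: float = 0.0) -> tuple[float, int, float, float]:
    """Two-sided one-sample t test; returns (t, df, p, Hedges-corrected g)."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 2:
        raise ValueError("need n >= 2")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation")
    t = (v.mean() - mu0) / (sd / math.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    J = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = J * (v.mean() - mu0) / sd
    return float(t), df, float(p), float(g)


# ---------------------------------------------------------------------------
# Bayes factors
# ---------------------------------------------------------------------------

def jzs_bf_ttest(t: float, n1: int, n2: int | None = None, r_scale: float = DEFAULT_JZS_SCALE) -> float:
    """Default JZS Bayes factor (BF10) for a t statistic.

    Cauchy prior with scale ``r_scale`` on the standardized effect,
    marginalised by exact one-dimensional quadrature over the inverse-gamma
    mixing variable. ``n2 = None`` gives the one-sample form. BF10 > 1 favors
    a nonzero effect.
    """
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    if n2 is None:
        neff, nu = float(n1), n1 - 1
    else:
        neff, nu = n1 * n2 / (n1 + n2), n1 + n2 - 2
    if nu < 1:
        raise ValueError("not enough observations")
    r2 = r_scale**2
    t2 = t * t

    def log_null():
        return -(nu + 1) / 2.0 * math.log1p(t2 / nu)

    def integrand(g):
        c = 1.0 + neff * g * r2
        return (
            c**-0.5
            * (1.0 + t2 / (c * nu)) ** (-(nu + 1) / 2.0)
            * (2.0 * math.pi) ** -0.5
            * g**-1.5
            * math.exp(-1.0 / (2.0 * g))
        )

    alt, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    return float(alt / math.exp(log_null()))


def bf_model_comparison(
    data: pd.DataFrame,
    dv: str,
    full_terms: list[str],
    reduced_terms: list[str],
    subject: str | None = None,
) -> float:
    """BIC-approximated BF10 for nested linear models.

    Terms are column names; ``a:b`` denotes the elementwise interaction of
    the (dummy-encoded) columns. With ``subject`` given, both models carry a
    subject random intercept (fit by ML); this mirrors specifying the null
    model as the random effect of subjects in repeated-measures designs.
    """
    if not set(reduced_terms) <= set(full_terms):
        raise ValueError("reduced model terms must be a subset of the full model terms")

    def encode(term: str) -> np.ndarray:
        parts = term.split(":")
        mats = []
        for pcol in parts:
            col = data[pcol]
            if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
                mats.append(pd.get_dummies(col.astype(str), drop_first=True, dtype=float).to_numpy())
            else:
                mats.append(col.to_numpy(dtype=float).reshape(-1, 1))
        X = mats[0]
        for m2 in mats[1:]:
            X = np.column_stack([X[:, i] * m2[:, j] for i in range(X.shape[1]) for j in range(m2.shape[1])])
        return X

    y = data[dv].to_numpy(dtype=float)
    ones = np.ones((len(y), 1))

    def design(terms):
        mats = [ones] + [encode(tm) for tm in terms]
        return np.column_stack(mats)

    Xf, Xr = design(full_terms), design(reduced_terms)
    if np.linalg.matrix_rank(Xf) < Xf.shape[1]:
        raise ValueError("rank-deficient design (constant or collinear predictor)")
    if subject is not None:
        groups = data[subject].to_numpy()
        bic_f = _mixed_bic(y, Xf, groups)
        bic_r = _mixed_bic(y, Xr, groups)
        return float(np.exp((bic_r - bic_f) / 2.0))
    return _bic_bf(y, Xf, Xr)


# ---------------------------------------------------------------------------
# moderated regression: micro-offline -> macro-offline, by age group
# ---------------------------------------------------------------------------

def moderated_regression(
    macro, micro, groups, reference: str = "YA"
) -> tuple[pd.DataFrame, float]:
    """OLS of macro-offline gains on micro-offline gains moderated by group.

    The model contains the micro-offline slope, dummy-coded main effects for
    every non-reference group, and group x micro interaction terms, so each
    interaction coefficient is the slope difference between that group and
    the reference (young adults by default). Returns the coefficient table
    (term, b, se, t, p) and the BIC-approximated BF10 for the interaction
    block as a whole.
    """
    df = pd.DataFrame({"macro": macro, "micro": micro, "group": groups}).dropna()
    labels = [g for g in pd.unique(df["group"]) if g != reference]
    if reference not in set(df["group"]):
        raise ValueError(f"reference group {reference!r} absent")
    if df["micro"].nunique() < 2:
        raise ValueError("rank-deficient design: micro predictor is constant")
    y = df["macro"].to_numpy(dtype=float)
    x = df["micro"].to_numpy(dtype=float)
    cols = {"intercept": np.ones(len(df)), "micro": x}
    for g in labels:
        dummy = (df["group"] == g).to_numpy(dtype=float)
        cols[f"group[{g}]"] = dummy
        cols[f"group[{g}]:micro"] = dummy * x
    X = np.column_stack(list(cols.values()))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design")
    fit = sm.OLS(y, X).fit()
    table = pd.DataFrame(
        {
            "term": list(cols.keys()),
            "b": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    ).reset_index(drop=True)
    n_inter = len(labels)
    bf = _bf_from_bics(float(sm.OLS(y, X[:, : X.shape[1] - n_inter]).fit().bic), float(fit.bic))
    return table, bf
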