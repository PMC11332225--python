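"""Age-trajectory curve fitting with AIC model selection.

Five candidate forms relate a learning/consolidation measure to age within
one of the two sampled windows (7-35 or 55-75 years; the windows are always
fitted separately): linear ``a + b*x``, quadratic ``a + b*x + c*x**2``, power
``a * x**b``, single exponential ``a * exp(b*x)`` and double exponential
``a*exp(b*x) + c*exp(d*x)``. Polynomial forms are solved in closed form;
the nonlinear forms use multi-start least squares with a fixed seed. The
form with the lowest Gaussian AIC, ``n*ln(rss/n) + 2*(n_params + 1)`` (the
error variance counts as a parameter, consistently across forms), wins; ties
break toward fewer parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

FORMS = ("linear", "quadratic", "power", "exp1", "exp2")
_N_PARAMS = {"linear": 2, "quadratic": 3, "power": 2, "exp1": 2, "exp2": 4}


@dataclass
class FitResult:
    form: str
    params: tuple[float, ...]
    rss: float
    r2: float
    aic: float
    F: float
    df1: int
    df2: int
    p: float
    n: int
    converged: bool = True
    age_range: str | None = None

    @property
    def vertex(self) -> float | None:
        """Quadratic stationary point -b/(2c); age of peak/trough performance."""
        if self.form != "quadratic":
            return None
        a, b, c = self.params
        return -b / (2.0 * c) if c != 0 else None

    def predict(self, x) -> np.ndarray:
        return _predict(self.form, np.asarray(self.params, dtype=float), np.asarray(x, dtype=float))


def _safe_exp(z):
    return np.exp(np.clip(z, -700.0, 700.0))


def _predict(form: str, p: np.ndarray, x: np.ndarray) -> np.ndarray:
    if form in ("exp1", "exp2", "power"):
        with np.errstate(over="ignore", invalid="ignore"):
            return _predict_unchecked(form, p, x)
    return _predict_unchecked(form, p, x)


def _predict_unchecked(form: str, p: np.ndarray, x: np.ndarray) -> np.ndarray:
    if form == "linear":
        return p[0] + p[1] * x
    if form == "quadratic":
        return p[0] + p[1] * x + p[2] * x * x
    if form == "power":
        return p[0] * np.power(x, p[1])
    if form == "exp1":
        return p[0] * _safe_exp(p[1] * x)
    if form == "exp2":
        return p[0] * _safe_exp(p[1] * x) + p[2] * _safe_exp(p[3] * x)
    raise ValueError(f"unknown form {form!r}")


def _starts(form: str, x, y, rng: np.random.Generator, n_starts: int) -> list[np.ndarray]:
    ybar = float(np.mean(y))
    yamp = float(np.std(y)) or abs(ybar) or 1.0
    starts = []
    if form == "power":
        # log-log moment start when signs allow, plus random starts
        if np.all(y > 0):
            b0, loga0 = np.polyfit(np.log(x), np.log(y), 1)
            starts.append(np.array([math.exp(loga0), b0]))
        for _ in range(n_starts):
            starts.append(np.array([rng.normal(ybar, yamp), rng.uniform(-2.0, 2.0)]))
    elif form == "exp1":
        if np.all(y > 0):
            b0, loga0 = np.polyfit(x, np.log(y), 1)
            starts.append(np.array([math.exp(loga0), b0]))
        for _ in range(n_starts):
            starts.append(np.array([rng.normal(ybar, yamp), rng.uniform(-0.3, 0.3)]))
    elif form == "exp2":
        for _ in range(2 * n_starts):
            starts.append(
                np.array(
                    [
                        rng.normal(ybar, yamp),
                        rng.uniform(-0.3, 0.3),
                        rng.normal(0.0, yamp),
                        rng.uniform(-0.3, 0.3),
                    ]
                )
            )
    return starts


def fit_curve(x, y, form: str, seed: int = 0, n_starts: int = 8) -> FitResult:
    """Least-squares fit of one candidate form.

    Polynomial forms are exact; power/exponential forms run multi-start
    nonlinear least squares (deterministic given ``seed``). A form that fails
    to converge from every start is returned with ``converged=False`` and is
    excluded from model selection rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    npar = _N_PARAMS[form]
    n = len(x)
    if n < npar + 2:
        raise ValueError(f"need at least {npar + 2} points for {form}")
    if form in ("power",) and np.any(x <= 0):
        raise ValueError("power form requires x > 0")

    params, converged = None, False
    if form in ("linear", "quadratic"):
        deg = 1 if form == "linear" else 2
        coefs = np.polyfit(x, y, deg)
        params = coefs[::-1]  # ascending order: intercept first
        converged = True
    else:
        rng = np.random.default_rng(seed)
        best_rss = np.inf
        for p0 in _starts(form, x, y, rng, n_starts):
            try:
                sol = optimize.least_squares(
                    lambda p: _predict(form, p, x) - y, p0, method="lm", max_nfev=5000
                )
            except Exception:
                continue
            if not np.all(np.isfinite(sol.x)):
                continue
            rss_c = float(np.sum(sol.fun**2))
            if rss_c < best_rss:
                best_rss, params, converged = rss_c, sol.x, True

    if not converged:
        return FitResult(form, (), math.inf, -math.inf, math.inf, math.nan, 0, 0, math.nan, n, False)

    resid = y - _predict(form, np.asarray(params, dtype=float), x)
    rss = float(np.sum(resid**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / sst if sst > 0 else 1.0
    aic = n * math.log(max(rss, 1e-300) / n) + 2.0 * (npar + 1)
    df1, df2 = npar - 1, n - npar
    if rss > 0 and df1 > 0:
        F = ((sst - rss) / df1) / (rss / df2)
        pval = float(stats.f.sf(F, df1, df2))
    else:
        F, pval = math.inf, 0.0
    return FitResult(
        form=form,
        params=tuple(float(v) for v in params),
        rss=rss,
        r2=float(r2),
        aic=float(aic),
        F=float(F),
        df1=df1,
        df2=df2,
        p=pval,
        n=n,
    )


def select_best_fit(
    x, y, forms: tuple[str, ...] = FORMS, seed: int = 0, age_range: str | None = None
) -> tuple[FitResult, list[FitResult]]:
    """Fit every candidate form and pick the converged one with minimal AIC.

    Returns ``(best, ranking)`` with the ranking sorted by AIC (ties broken
    toward fewer parameters). Raises if no form converges.
    """
    fits = []
    for form in forms:
        try:
            fits.append(fit_curve(x, y, form, seed=seed))
        except ValueError:
            continue
    ok = [f for f in fits if f.converged]
    if not ok:
        raise RuntimeError("no candidate form converged")
    ranking = sorted(ok, key=lambda f: (round(f.aic, 9), _N_PARAMS[f.form]))
    best = ranking[0]
    if age_range is not None:
        for f in fits:
            f.age_range = age_range
    return best, ranking
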