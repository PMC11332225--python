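"""A priori power analysis for fixed-effects and repeated-measures ANOVA.

Implements the G*Power conventions: the test statistic under the alternative
follows a noncentral F distribution with noncentrality lambda = f^2 * N for a
one-way design; repeated-measures designs scale lambda by the number of
repeated measurements m and the correlation rho among them —
``m / (1 + (m-1)*rho)`` for the between-groups effect and ``m / (1 - rho)``
for within and interaction effects.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

_RM_EFFECTS = ("between", "within", "interaction")


@dataclass
class PowerDesign:
    design: str
    f: float
    k: int
    m: int
    rho: float
    alpha: float
    N: int
    lam: float
    df1: float
    df2: float
    power: float


def _power(lam: float, df1: float, df2: float, alpha: float) -> float:
    fcrit = stats.f.isf(alpha, df1, df2)
    if lam == 0:  # central case: scipy's ncf is unreliable at nc = 0
        return float(alpha)
    return float(stats.ncf.sf(fcrit, df1, df2, lam))


def power_oneway(f: float, k: int, N: int, alpha: float = 0.05) -> PowerDesign:
    """Power of a one-way, k-group fixed-effects ANOVA at Cohen's f."""
    if f < 0:
        raise ValueError("f must be >= 0")
    if N <= k:
        raise ValueError("N must exceed the number of groups")
    lam = f * f * N
    df1, df2 = k - 1, N - k
    return PowerDesign("oneway", f, k, 1, 0.0, alpha, N, lam, df1, df2, _power(lam, df1, df2, alpha))


def power_repeated(
    f: float, k: int, m: int, rho: float, N: int, alpha: float = 0.05, effect: str = "interaction"
) -> PowerDesign:
    """Power of a k-group x m-measurement repeated-measures ANOVA effect.

    ``effect`` selects the between-groups, within, or group-x-measurement
    interaction test; ``rho`` is the assumed correlation among the repeated
    measurements. ``m = 1`` with ``rho = 0`` collapses to the one-way formula.
    """
    if effect not in _RM_EFFECTS:
        raise ValueError(f"effect must be one of {_RM_EFFECTS}")
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must be in [0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    if N <= k:
        raise ValueError("N must exceed the number of groups")
    if m == 1:
        base = power_oneway(f, k, N, alpha)
        return PowerDesign(f"rm_{effect}", f, k, m, rho, alpha, N, base.lam, base.df1, base.df2, base.power)
    if effect == "between":
        lam = f * f * N * m / (1.0 + (m - 1) * rho)
        df1, df2 = k - 1, N - k
    else:
        lam = f * f * N * m / (1.0 - rho)
        if effect == "within":
            df1, df2 = (m - 1), (N - k) * (m - 1)
        else:
            df1, df2 = (k - 1) * (m - 1), (N - k) * (m - 1)
    return PowerDesign(f"rm_{effect}", f, k, m, rho, alpha, N, lam, df1, df2, _power(lam, df1, df2, alpha))


def required_sample_size(
    design: str,
    f: float,
    k: int,
    target_power: float,
    alpha: float = 0.05,
    m: int = 1,
    rho: float = 0.0,
    effect: str = "interaction",
    max_n: int = 100_000,
) -> PowerDesign:
    """Smallest total N (multiple of k, equal groups) reaching the target power."""
    if not (alpha < target_power < 1.0):
        raise ValueError("target power must lie in (alpha, 1)")
    N = 2 * k
    while N <= max_n:
        pd_ = (
            power_oneway(f, k, N, alpha)
            if design == "oneway"
            else power_repeated(f, k, m, rho, N, alpha, effect)
        )
        if pd_.power >= target_power:
            return pd_
        N += k
    raise ValueError(f"target power {target_power} unreachable below N = {max_n}")
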