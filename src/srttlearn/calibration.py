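"""Monte-Carlo calibration and recovery studies for the simulated cohorts.

These routines re-run the generator -> preprocessing -> measures -> statistics
chain over many seeds to check that (a) the between-group test holds its
nominal type-I error when every group shares the same generating parameters,
(b) planted macro-offline gains are recovered without bias and reliably
detected, and (c) a planted quadratic age trajectory of sequence-specific
learning is re-selected by AIC with the correct peak age. Each study
generates only the runs its measure consumes, which keeps hundreds of
replicates affordable without changing the study conditions (group sizes,
generating parameters) themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .measures import learning_magnitude, macro_offline_gains
from .preprocess import baseline_normalize, flag_rt_outliers, summarize_blocks
from .simulate import CohortConfig, null_cohort_config, simulate_cohort
from .stats import mixed_anova
from .trajectories import select_best_fit

_MACRO_RUNS = ("pre_random", "post_test", "retest_seq")
_LM_RUNS = ("pre_random", "post_test", "post_random")


def _macro_seq_long(cfg: CohortConfig, seed: int) -> pd.DataFrame:
    """Simulate, preprocess, and return sequential macro gains in long form."""
    trials, _ = simulate_cohort(cfg, seed=seed, runs=_MACRO_RUNS)
    flagged = flag_rt_outliers(trials)
    norm = baseline_normalize(summarize_blocks(flagged))
    macro = macro_offline_gains(norm.blocks)
    meta = trials.drop_duplicates("participant_id")[["participant_id", "group"]]
    d = macro.merge(meta, on="participant_id").dropna(subset=["macro_seq_5h", "macro_seq_24h"])
    return d.melt(
        id_vars=["participant_id", "group"],
        value_vars=["macro_seq_5h", "macro_seq_24h"],
        var_name="period",
        value_name="value",
    )


def _group_effect_p(long: pd.DataFrame) -> float:
    res = mixed_anova(
        long, dv="value", within="period", between="group", subject="participant_id",
        compute_bf=False,
    )
    return next(r for r in res if r.effect == "group").p


@dataclass
class CalibrationResult:
    n_seeds: int
    rejections: int

    @property
    def rate(self) -> float:
        return self.rejections / self.n_seeds


def type_i_error_calibration(
    n_seeds: int = 500, n_per_group: int = 27, alpha: float = 0.05, seed: int = 0
) -> CalibrationResult:
    """Rejection rate of the group effect under the all-groups-equal null.

    Every group draws its parameters from the young-adult distributions, so
    the between-group effect on the sequential macro-offline gains is null by
    construction; a calibrated test rejects at ~alpha.
    """
    cfg = null_cohort_config(experiment=2, n_per_group=n_per_group)
    rej = 0
    for i in range(n_seeds):
        long = _macro_seq_long(cfg, seed=(seed + 7919 * i) % (2**31))
        if _group_effect_p(long) < alpha:
            rej += 1
    return CalibrationResult(n_seeds=n_seeds, rejections=rej)


@dataclass
class RecoveryResult:
    mae: float  # mean absolute error of group-mean macro_seq_24h vs truth
    detected: int  # seeds in which the group effect was detected
    n_seeds: int


def macro_gain_recovery(
    n_seeds: int = 20, n_per_group: int = 27, alpha: float = 0.05, seed: int = 0
) -> RecoveryResult:
    """Recovery of the planted group-mean 24 h macro-offline gains.

    Uses the default experiment-2 generator (e.g. children 0.12 vs young
    adults 0.05 normalized units at 24 h); reports the mean absolute error of
    the estimated group means against the group-level generating means and
    how often the group x offline-period ANOVA detects the group effect.
    """
    cfg = CohortConfig(experiment=2, n_per_group=n_per_group)
    truth_means = {g: cfg.group_params[g]["gain_24h"][0] for g in cfg.group_params}
    errs, detected = [], 0
    for i in range(n_seeds):
        s = (seed + 104729 * i) % (2**31)
        long = _macro_seq_long(cfg, seed=s)
        if _group_effect_p(long) < alpha:
            detected += 1
        g24 = (
            long[long["period"] == "macro_seq_24h"].groupby("group")["value"].mean()
        )
        errs.extend(abs(g24[g] - truth_means[g]) for g in truth_means)
    return RecoveryResult(mae=float(np.mean(errs)), detected=detected, n_seeds=n_seeds)


@dataclass
class TrajectoryResult:
    quadratic_selected: int
    n_seeds: int
    vertices: list[float]  # vertex of the quadratic fit, per seed

    @property
    def selection_rate(self) -> float:
        return self.quadratic_selected / self.n_seeds

    @property
    def median_vertex(self) -> float:
        return float(np.median(self.vertices))


def trajectory_recovery(
    n_seeds: int = 50, n_total: int = 98, seed: int = 0
) -> TrajectoryResult:
    """Recovery of a planted quadratic learning-magnitude age trajectory.

    Continuous-age cohorts (ages uniform on 7-35) carry
    ``seq_amp(age) = 0.10 - 0.0002 (age - 24)^2``; the learning magnitude is a
    monotone transform of seq_amp at fixed age, so its expected trajectory
    peaks at exactly the planted vertex. Reports how often AIC selects the
    quadratic form and the fitted peak ages.
    """
    cfg = CohortConfig(experiment=1, continuous_age=True, n_total=n_total)
    n_quad, vertices = 0, []
    from .trajectories import fit_curve

    for i in range(n_seeds):
        s = (seed + 15485863 * i) % (2**31)
        trials, _ = simulate_cohort(cfg, seed=s, runs=_LM_RUNS)
        flagged = flag_rt_outliers(trials)
        norm = baseline_normalize(summarize_blocks(flagged))
        lm = learning_magnitude(norm.blocks, 1).dropna()
        meta = trials.drop_duplicates("participant_id").set_index("participant_id")["age"]
        ages = meta.reindex(lm.index).to_numpy()
        best, _ = select_best_fit(ages, lm.to_numpy(), seed=s % 1000)
        if best.form == "quadratic":
            n_quad += 1
            vertices.append(best.vertex)
        else:
            vertices.append(fit_curve(ages, lm.to_numpy(), "quadratic").vertex)
    return TrajectoryResult(quadratic_selected=n_quad, n_seeds=n_seeds, vertices=vertices)
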