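"""Synthetic SRTT cohort generator with exportable ground truth.

Generates keypress-level data for the single-session learning experiment
(experiment 1) and the three-session consolidation experiment (experiment 2)
so that every downstream stage — trial exclusion, baseline normalization,
learning magnitude, micro-online/offline gains, macro-offline gains, the
statistical battery — can be tested against known generating parameters.

Generative model (per participant)
----------------------------------
Expected performance is written on the *normalized* scale (1 = pre-learning
random baseline). Familiarization and the pre-learning random run sit exactly
at baseline. From training onset, block-level learning follows two saturating
exponentials — a general task-familiarization component indexed by the
cumulative analyzed block ``t`` and a sequence-specific component indexed by
the cumulative sequential block ``b`` — plus a linear within-block drift
across the six sequence repetitions (positive = slowing, i.e. reactive
inhibition) and a step improvement at each completed inter-block rest
interval (micro-offline consolidation):

    h(t, b, r, J) = exp(-general_amp * (1 - exp(-general_rate * t))
                        - [seq] * seq_amp * (1 - exp(-seq_rate * b))
                        + within_drift * (r - 1) - micro_jump * J)

Retest runs in sessions 2 (5 h) and 3 (24 h) are frozen at the state of their
session-1 counterpart run (post-test / post-random) and shifted by the
session's macro-offline gain on the normalized scale:

    expected_norm = h - gain_5h * [session 2] - gain_24h * [session 3]

Observed RTs are lognormal around the expectation,
``rt = baseline_rt * expected_norm * exp(N(0, noise_sd))``, with probability
``outlier_rate`` multiplied by a Uniform(outlier_scale_range) factor to plant
the extreme trials the 3-SD exclusion rule is meant to catch. Accuracy is
Bernoulli(acc_p); an incorrect response is uniform over the 7 non-target keys.

With zero noise and no contamination the preprocessing + measures pipeline
recovers the planted macro-offline gains and the closed-form learning
magnitude exactly (see :func:`expected_norm_rt`).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .schema import (
    AGE_RANGES,
    BLOCKS_PER_RUN,
    GROUPS,
    REPS_PER_BLOCK,
    SEQ_LEN,
    SEQUENCE,
    SESSION_RUNS,
    TRIALS_PER_BLOCK,
    classify_age,
    sessions_for_experiment,
)

__all__ = [
    "GroundTruth",
    "CohortConfig",
    "DEFAULT_GROUP_PARAMS",
    "sequence_order",
    "expected_norm_rt",
    "simulate_participant",
    "simulate_cohort",
    "null_cohort_config",
]

#: Bounds applied when drawing per-participant parameters from group-level
#: normal distributions (keeps every GroundTruth valid).
_PARAM_BOUNDS = {
    "baseline_rt": (100.0, 5000.0),
    "general_amp": (0.0, 1.0),
    "general_rate": (1e-6, 5.0),
    "seq_amp": (0.0, 1.0),
    "seq_rate": (1e-6, 5.0),
    "within_drift": (-0.05, 0.05),
    "micro_jump": (0.0, 0.05),
    "gain_5h": (-0.5, 0.5),
    "gain_24h": (-0.5, 0.5),
    "acc_p": (0.5, 1.0),
    "noise_sd": (0.0, 1.0),
    "outlier_rate": (0.0, 0.49),
}

#: Group-level (mean, sd) defaults. These are fabricated generating values,
#: chosen so the simulated cohort reproduces the *ordinal* pattern of the
#: study populations (slower baselines at both ends of the lifespan, smaller
#: sequence-specific learning in children, larger 5 h/24 h offline gains in
#: children, a 24 h deficit in older adults, high stable accuracy, ~2%
#: extreme-RT contamination). Every entry is config-overridable.
DEFAULT_GROUP_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "CH": {
        "baseline_rt": (650.0, 60.0),
        "general_amp": (0.13, 0.02),
        "general_rate": (0.25, 0.05),
        "seq_amp": (0.06, 0.03),
        "seq_rate": (0.35, 0.05),
        "within_drift": (0.002, 0.001),
        "micro_jump": (0.006, 0.002),
        "gain_5h": (0.05, 0.06),
        "gain_24h": (0.12, 0.06),
        "acc_p": (0.94, 0.02),
        "noise_sd": (0.15, 0.02),
        "outlier_rate": (0.02, 0.0),
    },
    "AD": {
        "baseline_rt": (480.0, 50.0),
        "general_amp": (0.10, 0.02),
        "general_rate": (0.25, 0.05),
        "seq_amp": (0.10, 0.03),
        "seq_rate": (0.35, 0.05),
        "within_drift": (0.002, 0.001),
        "micro_jump": (0.005, 0.002),
        "gain_5h": (0.04, 0.06),
        "gain_24h": (0.07, 0.06),
        "acc_p": (0.95, 0.02),
        "noise_sd": (0.13, 0.02),
        "outlier_rate": (0.02, 0.0),
    },
    "YA": {
        "baseline_rt": (420.0, 45.0),
        "general_amp": (0.08, 0.02),
        "general_rate": (0.25, 0.05),
        "seq_amp": (0.10, 0.03),
        "seq_rate": (0.35, 0.05),
        "within_drift": (0.002, 0.001),
        "micro_jump": (0.004, 0.002),
        "gain_5h": (0.00, 0.06),
        "gain_24h": (0.05, 0.06),
        "acc_p": (0.96, 0.02),
        "noise_sd": (0.12, 0.02),
        "outlier_rate": (0.02, 0.0),
    },
    "OA": {
        "baseline_rt": (550.0, 55.0),
        "general_amp": (0.08, 0.02),
        "general_rate": (0.25, 0.05),
        "seq_amp": (0.09, 0.03),
        "seq_rate": (0.35, 0.05),
        "within_drift": (0.002, 0.001),
        "micro_jump": (0.004, 0.002),
        "gain_5h": (0.00, 0.06),
        "gain_24h": (-0.02, 0.06),
        "acc_p": (0.95, 0.02),
        "noise_sd": (0.13, 0.02),
        "outlier_rate": (0.02, 0.0),
    },
}

DEFAULT_OUTLIER_SCALE: tuple[float, float] = (3.0, 8.0)


@dataclass
class GroundTruth:
    """Generating parameters for one participant."""

    participant_id: str
    group: str
    age: float
    experiment: int
    baseline_rt: float
    general_amp: float
    general_rate: float
    seq_amp: float
    seq_rate: float
    within_drift: float
    micro_jump: float
    gain_5h: float
    gain_24h: float
    acc_p: float
    noise_sd: float
    outlier_rate: float
    outlier_scale_range: tuple[float, float] = DEFAULT_OUTLIER_SCALE
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.acc_p <= 1.0):
            raise ValueError(f"acc_p must be in (0, 1], got {self.acc_p}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.outlier_rate < 1.0):
            raise ValueError("outlier_rate must be in [0, 1)")
        if self.general_rate < 0 or self.seq_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.baseline_rt <= 0:
            raise ValueError("baseline_rt must be positive")
        lo, hi = self.outlier_scale_range
        if not (0 < lo <= hi):
            raise ValueError("outlier_scale_range must be 0 < lo <= hi")


@dataclass
class CohortConfig:
    """Study-design + group-parameter configuration for a simulated cohort.

    In the default group mode, ``n_per_group`` participants are drawn per age
    group with ages uniform in the group's operational window (CH 7-12, AD
    13-17, YA 18-35, OA 55-75). In continuous-age mode (``continuous_age``),
    ``n_total`` ages are drawn uniformly over ``age_window`` and the
    sequence-specific amplitude becomes a quadratic function of age,
    ``seq_amp(age) = peak_amp - curvature * (age - vertex_age)**2`` (floored
    at 0.005), to exercise the age-trajectory recovery path.
    """

    experiment: int = 1
    n_per_group: int = 32
    group_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {g: dict(DEFAULT_GROUP_PARAMS[g]) for g in GROUPS}
    )
    outlier_scale_range: tuple[float, float] = DEFAULT_OUTLIER_SCALE
    seed: int = 12345
    continuous_age: bool = False
    n_total: int = 98
    age_window: tuple[float, float] = (7.0, 35.0)
    seq_amp_peak: float = 0.12
    seq_amp_curvature: float = 0.00039
    seq_amp_vertex: float = 24.0

    def validate(self) -> None:
        if self.experiment not in (1, 2):
            raise ValueError("experiment must be 1 or 2")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.continuous_age and self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        for g in self.group_params:
            if g not in GROUPS:
                raise ValueError(f"unknown group {g}")


def null_cohort_config(experiment: int = 2, n_per_group: int = 27, **kw) -> CohortConfig:
    """A cohort in which every group shares the young-adult parameter means.

    Ages still differ across groups, but no generating parameter depends on
    group membership, so every between-group contrast is null by construction
    (used for type-I-error calibration).
    """
    params = {g: dict(DEFAULT_GROUP_PARAMS["YA"]) for g in GROUPS}
    return CohortConfig(experiment=experiment, n_per_group=n_per_group, group_params=params, **kw)


def sequence_order(variant: str, n_trials: int, rng: np.random.Generator, prev_last: int | None = None) -> np.ndarray:
    """Emit a target sequence of length ``n_trials`` (multiple of 8).

    ``sequential`` tiles the fixed 8-element cycle; ``pseudorandom`` draws a
    fresh permutation of 1..8 for every 8-trial window, re-drawing whenever
    the window would open with the previous window's closing target (so no
    target ever repeats on consecutive trials, window and block boundaries
    included). ``prev_last`` carries that constraint across calls.
    """
    if n_trials % SEQ_LEN != 0:
        raise ValueError(f"n_trials must be a multiple of {SEQ_LEN}, got {n_trials}")
    if variant == "sequential":
        return np.tile(SEQUENCE, n_trials // SEQ_LEN)
    if variant != "pseudorandom":
        raise ValueError(f"unknown variant {variant!r}")
    out = np.empty(n_trials, dtype=np.int64)
    last = prev_last
    base = np.arange(1, SEQ_LEN + 1)
    for w in range(n_trials // SEQ_LEN):
        while True:
            perm = rng.permutation(base)
            if perm[0] != last:
                break
        out[w * SEQ_LEN : (w + 1) * SEQ_LEN] = perm
        last = perm[-1]
    return out


# ---------------------------------------------------------------------------
# Design indexing: cumulative block index t (general learning), cumulative
# sequential block index b, completed rest intervals J since training onset.
# Retest runs are frozen at their session-1 counterpart.
# ---------------------------------------------------------------------------

def _design_indices(run: str, block: int) -> tuple[int, int | None, int]:
    """(t, b, J) for a session-1 run/block; retests map to their counterpart."""
    if run in ("familiarization", "pre_random"):
        return 0, None, 0
    if run in ("training",):
        return block, block, block - 1
    if run in ("post_test", "retest_seq"):
        return 16 + block, 16 + block, 15 + block
    if run in ("post_random", "retest_random"):
        return 20 + block, None, 19 + block
    raise ValueError(f"unknown run {run!r}")


def expected_norm_rt(gt: GroundTruth, session: int, run: str, block: int, repetition: int) -> float:
    """Closed-form expected normalized RT for one repetition window.

    This is the generator's own mean function and serves as the independent
    oracle for the measures pipeline: in the zero-noise limit every block and
    repetition mean produced downstream equals this value exactly.
    """
    if run in ("familiarization", "pre_random"):
        # pre-learning baseline: flat by construction, so the normalizing
        # divisor is exactly 1 in the noise-free limit
        return 1.0
    t, b, J = _design_indices(run, block)
    log_h = -gt.general_amp * (1.0 - math.exp(-gt.general_rate * t))
    if b is not None:
        log_h -= gt.seq_amp * (1.0 - math.exp(-gt.seq_rate * b))
    log_h += gt.within_drift * (repetition - 1) - gt.micro_jump * J
    h = math.exp(log_h)
    gain = gt.gain_5h if session == 2 else gt.gain_24h if session == 3 else 0.0
    return max(h - gain, 0.05)


def _runs_for(experiment: int, runs: tuple[str, ...] | None):
    plan = []
    for session in sessions_for_experiment(experiment):
        for run in SESSION_RUNS[session]:
            if runs is None or run in runs:
                plan.append((session, run, BLOCKS_PER_RUN[run]))
    return plan


def _participant_columns(
    gt: GroundTruth, rng: np.random.Generator, runs: tuple[str, ...] | None
) -> dict[str, np.ndarray]:
    """Raw column arrays for one participant (cheap to batch into a cohort)."""
    plan = _runs_for(gt.experiment, runs)
    acc: dict[str, list[np.ndarray]] = {
        k: [] for k in ("session", "run", "block", "trial", "target", "response", "correct", "rt_ms", "repetition")
    }
    for session, run, n_blocks in plan:
        n = n_blocks * TRIALS_PER_BLOCK
        if run in ("training", "post_test", "retest_seq"):
            targets = sequence_order("sequential", n, rng)
        else:
            targets = sequence_order("pseudorandom", n, rng)
        block = np.repeat(np.arange(1, n_blocks + 1), TRIALS_PER_BLOCK)
        trial = np.tile(np.arange(1, TRIALS_PER_BLOCK + 1), n_blocks)
        repetition = (trial - 1) // SEQ_LEN + 1

        # expected norm depends only on (block, repetition): evaluate the
        # closed form on that small grid and broadcast to trials
        grid = np.array(
            [
                [expected_norm_rt(gt, session, run, bl, rp) for rp in range(1, REPS_PER_BLOCK + 1)]
                for bl in range(1, n_blocks + 1)
            ]
        )
        mean_norm = grid[block - 1, repetition - 1]
        rt = gt.baseline_rt * mean_norm * np.exp(rng.normal(0.0, gt.noise_sd, n))
        is_outlier = rng.random(n) < gt.outlier_rate
        scales = rng.uniform(*gt.outlier_scale_range, n)
        rt = np.where(is_outlier, rt * scales, rt)

        correct = rng.random(n) < gt.acc_p
        wrong = ((targets - 1 + rng.integers(1, SEQ_LEN, n)) % SEQ_LEN) + 1
        response = np.where(correct, targets, wrong)

        acc["session"].append(np.full(n, session, dtype=np.int64))
        acc["run"].append(np.full(n, run, dtype=object))
        acc["block"].append(block)
        acc["trial"].append(trial)
        acc["target"].append(targets)
        acc["response"].append(response)
        acc["correct"].append(correct)
        acc["rt_ms"].append(rt)
        acc["repetition"].append(repetition)
    return {k: np.concatenate(v) for k, v in acc.items()}


def _columns_to_frame(cols: dict[str, np.ndarray], meta: dict[str, np.ndarray]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "participant_id": meta["participant_id"],
            "group": meta["group"],
            "age": meta["age"],
            "experiment": meta["experiment"],
            **{k: cols[k] for k in ("session", "run", "block", "trial", "target")},
            "response": pd.array(cols["response"], dtype="Int64"),
            "correct": cols["correct"],
            "rt_ms": cols["rt_ms"],
            "repetition": cols["repetition"],
        }
    )
    return df


def simulate_participant(
    gt: GroundTruth,
    rng: np.random.Generator | None = None,
    runs: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Generate the keypress-level trial table for one participant.

    ``runs`` optionally restricts generation to a subset of run types (the
    full session layout is the default); row counts follow the design
    arithmetic (experiment 1: 29 blocks = 1392 trials; experiment 2: 45
    blocks = 2160 trials).
    """
    gt.validate()
    if rng is None:
        rng = np.random.default_rng(gt.seed)
    cols = _participant_columns(gt, rng, runs)
    n = len(cols["rt_ms"])
    meta = {
        "participant_id": np.full(n, gt.participant_id, dtype=object),
        "group": np.full(n, gt.group, dtype=object),
        "age": np.full(n, gt.age),
        "experiment": np.full(n, gt.experiment, dtype=np.int64),
    }
    return _columns_to_frame(cols, meta)


def _draw_params(spec: dict[str, tuple[float, float]], rng: np.random.Generator) -> dict[str, float]:
    out = {}
    for name, (mean, sd) in spec.items():
        val = mean if sd == 0 else rng.normal(mean, sd)
        lo, hi = _PARAM_BOUNDS[name]
        out[name] = float(np.clip(val, lo, hi))
    return out


def _participant_gt(
    cfg: CohortConfig, index: int, group: str, age: float, seed: int
) -> tuple[GroundTruth, np.random.Generator]:
    child = np.random.SeedSequence(entropy=seed, spawn_key=(index,))
    rng = np.random.default_rng(child)
    params = _draw_params(cfg.group_params[group], rng)
    if cfg.continuous_age:
        amp = cfg.seq_amp_peak - cfg.seq_amp_curvature * (age - cfg.seq_amp_vertex) ** 2
        params["seq_amp"] = max(amp, 0.005)
    gt = GroundTruth(
        participant_id=f"P{index + 1:03d}",
        group=group,
        age=float(age),
        experiment=cfg.experiment,
        outlier_scale_range=cfg.outlier_scale_range,
        seed=int(child.generate_state(1)[0] % (2**31)),
        **params,
    )
    return gt, rng


def simulate_cohort(
    cfg: CohortConfig,
    seed: int | None = None,
    runs: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort; returns (trial table, ground-truth table).

    Output is a pure function of ``(cfg, seed)``: each participant gets a
    child random stream derived deterministically from the master seed and
    the participant index, so the same seed reproduces the cohort
    bit-identically.
    """
    cfg.validate()
    master = cfg.seed if seed is None else int(seed)
    age_rng = np.random.default_rng(np.random.SeedSequence(entropy=master, spawn_key=(2**20,)))

    roster: list[tuple[str, float]] = []
    if cfg.continuous_age:
        lo, hi = cfg.age_window
        ages = age_rng.uniform(lo, hi, cfg.n_total)
        roster = [(classify_age(a), float(a)) for a in ages]
    else:
        for group in GROUPS:
            lo, hi = AGE_RANGES[group]
            ages = age_rng.uniform(lo, hi, cfg.n_per_group)
            roster.extend((group, float(a)) for a in ages)

    per_cols, per_meta, gt_rows = [], [], []
    for idx, (group, age) in enumerate(roster):
        gt, rng = _participant_gt(cfg, idx, group, age, master)
        cols = _participant_columns(gt, rng, runs)
        n = len(cols["rt_ms"])
        per_cols.append(cols)
        per_meta.append(
            {
                "participant_id": np.full(n, gt.participant_id, dtype=object),
                "group": np.full(n, gt.group, dtype=object),
                "age": np.full(n, gt.age),
                "experiment": np.full(n, gt.experiment, dtype=np.int64),
            }
        )
        row = asdict(gt)
        row["outlier_scale_lo"], row["outlier_scale_hi"] = row.pop("outlier_scale_range")
        gt_rows.append(row)

    cols = {k: np.concatenate([c[k] for c in per_cols]) for k in per_cols[0]}
    meta = {k: np.concatenate([m[k] for m in per_meta]) for k in per_meta[0]}
    trials = _columns_to_frame(cols, meta)
    truth = pd.DataFrame(gt_rows)
    return trials, truth
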