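"""Trial exclusion, block aggregation and baseline normalization.

Trials are excluded when their RT lies more than ``k`` (default 3) standard
deviations above or below the participant's mean RT for that block; block
summaries average RT over included correct presses and express accuracy as
the percentage of included presses that were correct; both measures are then
divided by the participant's mean over the four pre-learning random blocks,
so 1.0 = baseline performance on every normalized scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BLOCK_KEYS = ["participant_id", "session", "run", "block"]
_META = ["group", "age", "experiment"]


def flag_rt_outliers(trials: pd.DataFrame, k: float = 3.0) -> pd.DataFrame:
    """Add an ``excluded`` flag: RT outside mean ± k·SD of its 48-trial block.

    The bounds are computed once, from all 48 trials of the block (correct
    and incorrect alike, sample SD), so re-running on already-flagged data is
    a no-op. A zero-SD block excludes nothing.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    out = trials.copy()
    grp = out.groupby(BLOCK_KEYS, sort=False)["rt_ms"]
    m = grp.transform("mean")
    s = grp.transform("std")  # ddof=1; NaN for single-trial blocks
    dev = (out["rt_ms"] - m).abs()
    out["excluded"] = (dev > k * s).fillna(False) & (s > 0).fillna(False)
    return out


def exclusion_rates(trials: pd.DataFrame) -> tuple[pd.Series, float]:
    """Per-participant exclusion percentage and its cohort mean.

    Familiarization trials are not analyzed and do not enter the rates.
    """
    t = trials[trials["run"] != "familiarization"]
    per = t.groupby("participant_id")["excluded"].mean() * 100.0
    return per, float(per.mean())


def summarize_blocks(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-block performance summaries over included trials.

    ``mean_rt_correct`` averages RT over included *correct* presses (missing,
    never 0, when a block has none); ``accuracy_pct`` is 100 x correct
    included / included. Familiarization is dropped (not analyzed).
    """
    t = trials[trials["run"] != "familiarization"].copy()
    inc = ~t["excluded"]
    t["_inc"] = inc
    t["_inc_corr"] = inc & t["correct"]
    t["_rt_inc_corr"] = np.where(t["_inc_corr"], t["rt_ms"], np.nan)
    g = t.groupby(BLOCK_KEYS + _META, sort=True, as_index=False).agg(
        mean_rt_correct=("_rt_inc_corr", "mean"),
        n_included=("_inc", "sum"),
        n_excluded=("excluded", "sum"),
        _n_inc_corr=("_inc_corr", "sum"),
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        g["accuracy_pct"] = 100.0 * g["_n_inc_corr"] / g["n_included"].where(g["n_included"] > 0)
    return g.drop(columns=["_n_inc_corr"])


@dataclass
class NormalizedBlocks:
    """Block summaries with norm fields, per-participant baselines, and drops."""

    blocks: pd.DataFrame
    baselines: pd.DataFrame  # participant_id, rt_base, acc_base
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (participant, reason)


def participant_baselines(blocks: pd.DataFrame) -> pd.DataFrame:
    """Mean RT / accuracy over the four session-1 pre-learning random blocks."""
    pre = blocks[(blocks["run"] == "pre_random") & (blocks["session"] == 1)]
    agg = pre.groupby("participant_id").agg(
        rt_base=("mean_rt_correct", "mean"),
        acc_base=("accuracy_pct", "mean"),
        _n=("mean_rt_correct", "count"),
    )
    agg["_n_blocks"] = pre.groupby("participant_id").size()
    return agg.reset_index()


def baseline_normalize(blocks: pd.DataFrame, raw_mode: bool = False) -> NormalizedBlocks:
    """Divide every block measure by the participant's pre-random baseline.

    Participants lacking four usable pre-random blocks are dropped with a
    logged reason (mirroring replacement of unusable participants). With
    ``raw_mode`` the norm fields simply copy the raw ones (the supplementary
    non-normalized analysis path).
    """
    base = participant_baselines(blocks)
    bad = base[(base["_n"] < 4) | (base["_n_blocks"] != 4)]
    missing_entirely = set(blocks["participant_id"]) - set(base["participant_id"])
    dropped = [(p, "missing/incomplete pre_random baseline") for p in bad["participant_id"]]
    dropped += [(p, "no pre_random run") for p in sorted(missing_entirely)]
    keep = base[~base["participant_id"].isin(bad["participant_id"])]

    out = blocks.merge(keep[["participant_id", "rt_base", "acc_base"]], on="participant_id", how="inner")
    if raw_mode:
        out["norm_rt"] = out["mean_rt_correct"]
        out["norm_acc"] = out["accuracy_pct"]
    else:
        out["norm_rt"] = out["mean_rt_correct"] / out["rt_base"]
        out["norm_acc"] = out["accuracy_pct"] / out["acc_base"]
    return NormalizedBlocks(
        blocks=out.drop(columns=["rt_base", "acc_base"]),
        baselines=keep.drop(columns=["_n", "_n_blocks"]).reset_index(drop=True),
        dropped=dropped,
    )
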