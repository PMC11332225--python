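"""Per-participant learning and consolidation measures.

Sign conventions: every measure here is oriented so that *positive = better*
for an RT outcome where lower is better. Learning magnitude is
``(R - S) / R`` with ``S`` the mean normalized RT of the sequential
test/retest run and ``R`` the same-session random run; micro-online gains are
first minus last repetition of a block; micro-offline gains are last
repetition of block n minus first repetition of block n+1; macro-offline
gains are end-of-training test minus retest. Group-difference statistics
(F, p, |g|) are invariant to this orientation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .schema import SEQUENTIAL_RUNS, REPS_PER_BLOCK

TRAINING_BLOCKS = 16


def repetition_means(
    trials: pd.DataFrame, baselines: pd.DataFrame, raw_mode: bool = False
) -> pd.DataFrame:
    """Mean normalized RT per 8-press sequence repetition window.

    Uses included correct presses of sequential runs only; trial RTs are
    normalized by the participant's pre-random baseline mean (or left raw in
    ``raw_mode``). Empty windows are simply absent (missingness propagates).
    """
    t = trials[trials["run"].isin(SEQUENTIAL_RUNS) & trials["correct"] & ~trials["excluded"]]
    t = t.merge(baselines[["participant_id", "rt_base"]], on="participant_id", how="inner")
    t = t.copy()
    t["norm_rt"] = t["rt_ms"] if raw_mode else t["rt_ms"] / t["rt_base"]
    out = (
        t.groupby(["participant_id", "session", "run", "block", "repetition"], as_index=False)
        .agg(norm_rt=("norm_rt", "mean"))
        .sort_values(["participant_id", "session", "run", "block", "repetition"])
        .reset_index(drop=True)
    )
    return out


def micro_gains(rep_means: pd.DataFrame) -> pd.DataFrame:
    """Micro-online and micro-offline gains across the 16 training blocks.

    Returns a long table (participant_id, idx, micro_online, micro_offline):
    ``micro_online[n] = rep1(n) - rep6(n)`` for n = 1..16 and
    ``micro_offline[n] = rep6(n) - rep1(n+1)`` for n = 1..15 (NaN at idx 16).
    Missing repetition means propagate as missing gains. The gains telescope:
    their grand total equals rep1(block 1) - rep6(block 16) on complete data.
    """
    tr = rep_means[(rep_means["run"] == "training") & (rep_means["session"] == 1)]
    wide = tr.pivot_table(
        index="participant_id", columns=["block", "repetition"], values="norm_rt", aggfunc="first"
    )
    rows = []
    for pid, row in wide.iterrows():
        rep1 = {b: row.get((b, 1), np.nan) for b in range(1, TRAINING_BLOCKS + 1)}
        rep6 = {b: row.get((b, REPS_PER_BLOCK), np.nan) for b in range(1, TRAINING_BLOCKS + 1)}
        for n in range(1, TRAINING_BLOCKS + 1):
            online = rep1[n] - rep6[n]
            offline = rep6[n] - rep1[n + 1] if n < TRAINING_BLOCKS else np.nan
            rows.append((pid, n, online, offline))
    return pd.DataFrame(rows, columns=["participant_id", "idx", "micro_online", "micro_offline"])


def _run_mean(blocks: pd.DataFrame, session: int, run: str) -> pd.Series:
    sel = blocks[(blocks["session"] == session) & (blocks["run"] == run)]
    counts = sel.groupby("participant_id")["norm_rt"].count()
    means = sel.groupby("participant_id")["norm_rt"].mean()
    # a run mean is only usable if all 4 blocks are present and non-missing
    return means.where(counts == 4)


def learning_magnitude(blocks: pd.DataFrame, session: int = 1) -> pd.Series:
    """Sequence-specific learning magnitude, per participant.

    ``lm = (R - S) / R`` where S is the mean normalized RT over the session's
    four sequential test (session 1) or retest (sessions 2/3) blocks and R
    the mean over the same-session random blocks; positive values mean the
    practiced sequence is performed faster than random material.
    """
    if session == 1:
        s_run, r_run = "post_test", "post_random"
    elif session in (2, 3):
        s_run, r_run = "retest_seq", "retest_random"
    else:
        raise ValueError("session must be 1, 2 or 3")
    s_bar = _run_mean(blocks, session, s_run)
    r_bar = _run_mean(blocks, session, r_run)
    s_bar, r_bar = s_bar.align(r_bar)
    return ((r_bar - s_bar) / r_bar).rename(f"lm_session{session}")


def macro_offline_gains(blocks: pd.DataFrame) -> pd.DataFrame:
    """Macro-offline gains over the 5 h and 24 h intervals, per participant.

    ``macro_seq_s = mean(post_test, session 1) - mean(retest_seq, session s)``
    and analogously for the random variant; positive = faster at retest. A
    missing session leaves that gain missing (participants are excluded only
    from contrasts involving the affected runs).
    """
    pt = _run_mean(blocks, 1, "post_test")
    pr = _run_mean(blocks, 1, "post_random")
    out = pd.DataFrame(index=pt.index.union(pr.index))
    for s, label in ((2, "5h"), (3, "24h")):
        rs = _run_mean(blocks, s, "retest_seq")
        rr = _run_mean(blocks, s, "retest_random")
        out[f"macro_seq_{label}"] = pt.reindex(out.index) - rs.reindex(out.index)
        out[f"macro_rand_{label}"] = pr.reindex(out.index) - rr.reindex(out.index)
    out.index.name = "participant_id"
    return out.reset_index()


def offline_lm_change(lm: pd.Series, lm_5h: pd.Series, lm_24h: pd.Series) -> pd.DataFrame:
    """Offline change in learning magnitude: retest LM minus session-1 LM."""
    df = pd.DataFrame({"lm": lm, "lm_5h": lm_5h, "lm_24h": lm_24h})
    df["d_lm_5h"] = df["lm_5h"] - df["lm"]
    df["d_lm_24h"] = df["lm_24h"] - df["lm"]
    return df[["d_lm_5h", "d_lm_24h"]]


def derive_measures(
    blocks: pd.DataFrame,
    trials: pd.DataFrame,
    baselines: pd.DataFrame,
    raw_mode: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the per-participant measure table and the long micro table.

    Returns ``(measures, micro)`` where measures has one row per participant
    (lm, lm_5h/lm_24h and their offline changes when sessions 2/3 exist,
    block-averaged micro gains, macro-offline gains) and micro is the long
    per-block gain table from :func:`micro_gains`.
    """
    reps = repetition_means(trials, baselines, raw_mode=raw_mode)
    micro = micro_gains(reps)

    meta = blocks.drop_duplicates("participant_id").set_index("participant_id")[["group", "age", "experiment"]]
    m = meta.copy()
    m["lm"] = learning_magnitude(blocks, 1)
    have_retest = (blocks["run"] == "retest_seq").any()
    if have_retest:
        m["lm_5h"] = learning_magnitude(blocks, 2)
        m["lm_24h"] = learning_magnitude(blocks, 3)
        m[["d_lm_5h", "d_lm_24h"]] = offline_lm_change(m["lm"], m["lm_5h"], m["lm_24h"])
        macro = macro_offline_gains(blocks).set_index("participant_id")
        m = m.join(macro)
    agg = micro.groupby("participant_id")[["micro_online", "micro_offline"]].mean()
    m["micro_online_mean"] = agg["micro_online"]
    m["micro_offline_mean"] = agg["micro_offline"]
    m.index.name = "participant_id"
    return m.reset_index(), micro
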