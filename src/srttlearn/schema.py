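"""Trial-table schema for the 8-choice serial reaction time task (SRTT).

The pipeline's ingestion contract is one CSV row per keypress. A practice
block holds 48 presses (six traversals of an 8-element pattern); stimuli
follow either the fixed deterministic sequence or a pseudorandom order in
which every 8-trial window contains each of the eight locations exactly once
and no location repeats on consecutive trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Fixed deterministic stimulus sequence (keys 1..8 = left pinky .. right pinky).
SEQUENCE: tuple[int, ...] = (4, 7, 3, 8, 6, 2, 5, 1)

SEQ_LEN = 8
TRIALS_PER_BLOCK = 48
REPS_PER_BLOCK = TRIALS_PER_BLOCK // SEQ_LEN  # 6

RUNS = (
    "familiarization",
    "pre_random",
    "training",
    "post_test",
    "post_random",
    "retest_seq",
    "retest_random",
)
SEQUENTIAL_RUNS = ("training", "post_test", "retest_seq")
RANDOM_RUNS = ("familiarization", "pre_random", "post_random", "retest_random")

#: Number of blocks making up each run.
BLOCKS_PER_RUN = {
    "familiarization": 1,
    "pre_random": 4,
    "training": 16,
    "post_test": 4,
    "post_random": 4,
    "retest_seq": 4,
    "retest_random": 4,
}

#: Runs per session, in task order. Session 1 is shared by both experiments;
#: sessions 2 (5 h) and 3 (24 h) exist only in the consolidation experiment.
SESSION_RUNS = {
    1: ("familiarization", "pre_random", "training", "post_test", "post_random"),
    2: ("retest_seq", "retest_random"),
    3: ("retest_seq", "retest_random"),
}

GROUPS = ("CH", "AD", "YA", "OA")

#: Operational age windows (years) per group: children, adolescents, young
#: adults, older adults. The study sampled nobody between 35 and 55.
AGE_RANGES = {"CH": (7, 12), "AD": (13, 17), "YA": (18, 35), "OA": (55, 75)}

COLUMNS = (
    "participant_id",
    "group",
    "age",
    "experiment",
    "session",
    "run",
    "block",
    "trial",
    "target",
    "response",
    "correct",
    "rt_ms",
    "repetition",
)


class SchemaError(ValueError):
    """A trial-table file violates the column contract."""


class TrialParseError(ValueError):
    """Rows of a trial-table file could not be parsed."""

    def __init__(self, message: str, rows: list[int]):
        super().__init__(message)
        self.rows = rows


def classify_age(age: float) -> str:
    """Map an age in years to its group label; raises outside the sampled windows.

    Decimal ages use contiguous half-open brackets (a 12.7-year-old is a
    child, a 17.4-year-old an adolescent).
    """
    if 7 <= age < 13:
        return "CH"
    if 13 <= age < 18:
        return "AD"
    if 18 <= age <= 35:
        return "YA"
    if 55 <= age <= 75:
        return "OA"
    raise ValueError(f"age {age} is outside the sampled windows 7-35 and 55-75")


def sessions_for_experiment(experiment: int) -> tuple[int, ...]:
    return (1,) if experiment == 1 else (1, 2, 3)


def _coerce_types(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["participant_id"] = df["participant_id"].astype(str)
    df["group"] = df["group"].astype(str)
    df["run"] = df["run"].astype(str)
    df["age"] = pd.to_numeric(df["age"])
    for col in ("experiment", "session", "block", "trial", "target", "repetition"):
        df[col] = pd.to_numeric(df[col]).astype("int64")
    df["response"] = pd.to_numeric(df["response"], errors="raise").astype("Int64")
    if df["correct"].dtype == object:
        df["correct"] = (
            df["correct"].astype(str).str.strip().str.lower().map({"true": True, "false": False})
        )
    df["correct"] = df["correct"].astype(bool)
    return df


def read_trial_table(path) -> pd.DataFrame:
    """Read a keypress-level trial table from CSV.

    Raises :class:`SchemaError` if a required column is missing and
    :class:`TrialParseError` (listing the offending 0-based row indices) if
    ``rt_ms`` values are not numeric; unparseable rows are never dropped
    silently.
    """
    df = pd.read_csv(path)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    rt = pd.to_numeric(df["rt_ms"], errors="coerce")
    bad = df.index[rt.isna() & df["rt_ms"].notna()].tolist()
    if bad or rt.isna().any():
        bad = sorted(set(bad) | set(df.index[rt.isna()].tolist()))
        raise TrialParseError(f"non-numeric rt_ms in rows {bad[:20]}", bad)
    df["rt_ms"] = rt.astype(float)
    return _coerce_types(df[list(COLUMNS)])


def write_trial_table(df: pd.DataFrame, path) -> None:
    """Write a trial table to CSV (UTF-8, comma delimited, fixed column order)."""
    df[list(COLUMNS)].to_csv(path, index=False)


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_trial_table`: violations are content, not errors."""

    errors: list[tuple[str, str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.errors

    def add_error(self, rule: str, location: str, message: str) -> None:
        self.errors.append((rule, location, message))

    def add_warning(self, rule: str, location: str, message: str) -> None:
        self.warnings.append((rule, location, message))

    def rules_violated(self) -> set[str]:
        return {r for r, _, _ in self.errors}


def _loc(pid, session, run, block=None) -> str:
    s = f"{pid}/s{session}/{run}"
    return s if block is None else f"{s}/b{block}"


def validate_trial_table(t: pd.DataFrame) -> ValidationReport:
    """Check every trial-table invariant; returns a report, never raises.

    Rules: column domains, the 7-35/55-75 age windows, 48-trial blocks with
    ``repetition == ceil(trial/8)``, per-run block counts, the fixed target
    cycle in sequential blocks, the windowed-permutation/no-consecutive-repeat
    structure of pseudorandom runs, and ``correct <=> response == target``.
    """
    rep = ValidationReport()

    if not t["group"].isin(GROUPS).all():
        bad = sorted(set(t.loc[~t["group"].isin(GROUPS), "group"]))
        rep.add_error("column-domain", "group", f"unknown group label(s) {bad}")
    if not t["run"].isin(RUNS).all():
        bad = sorted(set(t.loc[~t["run"].isin(RUNS), "run"]))
        rep.add_error("column-domain", "run", f"unknown run label(s) {bad}")
    for col, lo, hi in (
        ("session", 1, 3),
        ("trial", 1, TRIALS_PER_BLOCK),
        ("target", 1, SEQ_LEN),
        ("repetition", 1, REPS_PER_BLOCK),
        ("experiment", 1, 2),
    ):
        if not t[col].between(lo, hi).all():
            rep.add_error("column-domain", col, f"values outside [{lo}, {hi}]")
    resp = t["response"]
    if not resp.dropna().between(1, SEQ_LEN).all():
        rep.add_error("column-domain", "response", "responses outside 1..8")
    if not (t["rt_ms"] > 0).all():
        rep.add_error("column-domain", "rt_ms", "non-positive response times")

    # Age windows: 36-54 (and anything outside 7-75) was never sampled.
    per_p = t.drop_duplicates("participant_id")
    for _, row in per_p.iterrows():
        a = row["age"]
        if not ((7 <= a <= 35) or (55 <= a <= 75)):
            rep.add_error(
                "age-window", str(row["participant_id"]), f"age {a} outside 7-35 / 55-75"
            )
        elif row["group"] in AGE_RANGES and classify_age(a) != row["group"]:
            rep.add_warning(
                "group-age",
                str(row["participant_id"]),
                f"age {a} maps to group {classify_age(a)}, not {row['group']}",
            )

    # Block-level structure.
    for (pid, session, run, block), blk in t.groupby(
        ["participant_id", "session", "run", "block"], sort=True
    ):
        loc = _loc(pid, session, run, block)
        if len(blk) != TRIALS_PER_BLOCK:
            rep.add_error("block-size", loc, f"{len(blk)} trials, expected {TRIALS_PER_BLOCK}")
            continue
        blk = blk.sort_values("trial")
        if not (blk["trial"].to_numpy() == np.arange(1, TRIALS_PER_BLOCK + 1)).all():
            rep.add_error("block-size", loc, "trial indices are not 1..48")
            continue
        expected_rep = np.ceil(blk["trial"].to_numpy() / SEQ_LEN).astype(int)
        if not (blk["repetition"].to_numpy() == expected_rep).all():
            rep.add_error("repetition-index", loc, "repetition != ceil(trial/8)")
        targets = blk["target"].to_numpy()
        if run in SEQUENTIAL_RUNS:
            if not np.array_equal(targets, np.tile(SEQUENCE, REPS_PER_BLOCK)):
                rep.add_error("sequence-order", loc, "targets do not cycle 4-7-3-8-6-2-5-1")
        else:
            for w in range(REPS_PER_BLOCK):
                win = targets[w * SEQ_LEN : (w + 1) * SEQ_LEN]
                if set(win) != set(range(1, SEQ_LEN + 1)):
                    rep.add_error(
                        "random-window", loc, f"window {w + 1} is not a permutation of 1..8"
                    )
        mism = blk["correct"].to_numpy() != (
            blk["response"].to_numpy(dtype=object) == blk["target"].to_numpy(dtype=object)
        )
        if mism.any():
            rep.add_error("correct-consistency", loc, "correct != (response == target)")

    # Run-level structure: block counts and no consecutive repeats across a
    # pseudorandom run (window boundaries included).
    for (pid, session, run), g in t.groupby(["participant_id", "session", "run"], sort=True):
        loc = _loc(pid, session, run)
        blocks = sorted(g["block"].unique())
        want = BLOCKS_PER_RUN.get(run)
        if want is not None and blocks != list(range(1, want + 1)):
            rep.add_error("run-structure", loc, f"blocks {blocks}, expected 1..{want}")
        if run in SESSION_RUNS[1] and session != 1:
            rep.add_error("run-structure", loc, f"run {run} only occurs in session 1")
        if run in ("retest_seq", "retest_random") and session == 1:
            rep.add_error("run-structure", loc, f"run {run} only occurs in sessions 2/3")
        if run not in SEQUENTIAL_RUNS:
            seq = g.sort_values(["block", "trial"])["target"].to_numpy()
            if (seq[1:] == seq[:-1]).any():
                rep.add_error("random-repeat", loc, "target repeats on consecutive trials")

    return rep
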