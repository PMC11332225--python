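"""End-to-end orchestration: simulate/load -> qc -> derive -> stats -> curves -> report."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import measures as meas
from . import preprocess as prep
from .config import PipelineConfig
from .schema import read_trial_table, validate_trial_table, write_trial_table
from .simulate import CohortConfig, simulate_cohort
from .stats import (
    AnovaResult,
    mixed_anova,
    moderated_regression,
    one_sample_t,
    one_way_anova,
    tukey_pairwise,
)
from .trajectories import select_best_fit

log = logging.getLogger("srttlearn")

AGE_WINDOWS = {"7-35": (7.0, 35.0), "55-75": (55.0, 75.0)}


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    return obj


def _complete_long(df: pd.DataFrame, subject: str, within: str, value: str) -> pd.DataFrame:
    """Listwise-delete subjects missing any within-level (mixed ANOVA contract)."""
    wide = df.pivot_table(index=subject, columns=within, values=value, aggfunc="first")
    keep = wide.dropna().index
    dropped = sorted(set(wide.index) - set(keep))
    if dropped:
        log.info("listwise deletion of %d participant(s) with incomplete cells", len(dropped))
    return df[df[subject].isin(keep)]


def _block_mixed(blocks, run, dv, gg_alpha, compute_bf):
    d = blocks[(blocks["session"] == 1) & (blocks["run"] == run)][
        ["participant_id", "group", "block", dv]
    ].rename(columns={dv: "value"})
    d["block"] = d["block"].astype(str).str.zfill(2)
    d = _complete_long(d.dropna(subset=["value"]), "participant_id", "block", "value")
    return mixed_anova(
        d, dv="value", within="block", between="group", subject="participant_id",
        gg_alpha=gg_alpha, compute_bf=compute_bf,
    )


def _fit_windows(mdf: pd.DataFrame, col: str, seed: int) -> dict:
    out = {}
    for label, (lo, hi) in AGE_WINDOWS.items():
        sel = mdf[(mdf["age"] >= lo) & (mdf["age"] <= hi)].dropna(subset=[col])
        if len(sel) < 8:
            continue
        best, ranking = select_best_fit(
            sel["age"].to_numpy(), sel[col].to_numpy(), seed=seed, age_range=label
        )
        out[label] = {"best": best, "ranking": ranking}
    return out


def run_statistics(
    blocks: pd.DataFrame,
    measures_df: pd.DataFrame,
    micro: pd.DataFrame,
    experiment: int,
    gg_alpha: float = 0.05,
    compute_bf: bool = True,
) -> dict:
    """The full inferential battery for one experiment's normalized measures."""
    out: dict = {}

    # learning dynamics: group x block mixed ANOVAs on RT and accuracy
    for run in ("training", "post_test"):
        for dv, tag in (("norm_rt", "rt"), ("norm_acc", "acc")):
            out[f"{run}_{tag}"] = _block_mixed(blocks, run, dv, gg_alpha, compute_bf)

    # sequence-specific learning magnitude
    mm = measures_df.dropna(subset=["lm"])
    out["lm_group"] = one_way_anova(mm["lm"], mm["group"], compute_bf=compute_bf)
    out["lm_pairwise"] = tukey_pairwise(mm["lm"], mm["group"], compute_bf=compute_bf)
    out["lm_vs_zero"] = {
        g: dict(zip(("t", "df", "p", "g"), one_sample_t(sub["lm"], 0.0)))
        for g, sub in mm.groupby("group")
    }
    # follow-up: group effect on the post-learning random run itself
    pr = blocks[(blocks["session"] == 1) & (blocks["run"] == "post_random")]
    pr_mean = pr.groupby(["participant_id", "group"], as_index=False)["norm_rt"].mean()
    out["post_random_group"] = one_way_anova(pr_mean["norm_rt"], pr_mean["group"], compute_bf=compute_bf)

    # micro-online / micro-offline mixed ANOVAs
    micro_m = micro.merge(measures_df[["participant_id", "group"]], on="participant_id")
    for col, maxidx in (("micro_online", 16), ("micro_offline", 15)):
        d = micro_m[micro_m["idx"] <= maxidx][["participant_id", "group", "idx", col]].rename(
            columns={col: "value"}
        )
        d["idx"] = d["idx"].astype(str).str.zfill(2)
        d = _complete_long(d.dropna(subset=["value"]), "participant_id", "idx", "value")
        out[col] = mixed_anova(
            d, dv="value", within="idx", between="group", subject="participant_id",
            gg_alpha=gg_alpha, compute_bf=compute_bf,
        )

    if experiment == 2:
        for variant in ("seq", "rand"):
            cols = [f"macro_{variant}_5h", f"macro_{variant}_24h"]
            d = measures_df[["participant_id", "group"] + cols].dropna()
            long = d.melt(
                id_vars=["participant_id", "group"], var_name="period", value_name="value"
            )
            long["period"] = long["period"].str.replace(f"macro_{variant}_", "", regex=False)
            out[f"macro_{variant}"] = mixed_anova(
                long, dv="value", within="period", between="group", subject="participant_id",
                gg_alpha=gg_alpha, compute_bf=compute_bf,
            )
            for period in ("5h", "24h"):
                col = f"macro_{variant}_{period}"
                dd = measures_df.dropna(subset=[col])
                out[f"{col}_group"] = one_way_anova(dd[col], dd["group"], compute_bf=compute_bf)
                out[f"{col}_pairwise"] = tukey_pairwise(dd[col], dd["group"], compute_bf=compute_bf)
                out[f"{col}_vs_zero"] = {
                    g: dict(zip(("t", "df", "p", "g"), one_sample_t(sub[col], 0.0)))
                    for g, sub in dd.groupby(by="group")
                    if len(sub) >= 2
                }
        # micro-offline -> macro-offline moderated regressions (YA reference)
        for period in ("5h", "24h"):
            col = f"macro_seq_{period}"
            dd = measures_df.dropna(subset=[col, "micro_offline_mean"])
            table, bf = moderated_regression(dd[col], dd["micro_offline_mean"], dd["group"])
            simple = one_way_slope(dd["micro_offline_mean"], dd[col])
            out[f"micro_to_macro_{period}"] = {
                "coefficients": table,
                "interaction_bf10": bf,
                "simple_slope": simple,
            }
    return out


def one_way_slope(x, y) -> dict:
    """Simple linear regression slope of y on x (b, t, p)."""
    import statsmodels.api as sm

    X = np.column_stack([np.ones(len(x)), np.asarray(x, dtype=float)])
    fit = sm.OLS(np.asarray(y, dtype=float), X).fit()
    return {"b": float(fit.params[1]), "t": float(fit.tvalues[1]), "p": float(fit.pvalues[1])}


def _fmt_anova(r: AnovaResult) -> str:
    s = f"F({r.df1:.3f}, {r.df2:.3f}) = {r.F:.3f}, p = {r.p:.4g}"
    if r.partial_eta2 is not None:
        s += f", partial eta2 = {r.partial_eta2:.3f}"
    if r.eta2 is not None:
        s += f", eta2 = {r.eta2:.3f}"
    if r.eta2_ci is not None:
        s += f", 95% CI [{r.eta2_ci[0]:.3f}, {r.eta2_ci[1]:.3f}]"
    if r.gg_applied:
        s += f" (GG eps = {r.epsilon_gg:.3f})"
    if r.bf10 is not None:
        s += f", BF10 = {r.bf10:.4g}"
    if r.trend:
        s += "  [non-significant trend, 0.05 < p < 0.1]"
    return s


def render_report(stats_out: dict, fits_out: dict, meta: dict) -> str:
    lines = ["# SRTT analysis report", ""]
    lines += [f"- {k}: {v}" for k, v in meta.items()]
    lines.append("")
    for key, val in stats_out.items():
        lines.append(f"## {key}")
        if isinstance(val, AnovaResult):
            lines.append(f"- {val.effect}: {_fmt_anova(val)}")
        elif isinstance(val, list) and val and isinstance(val[0], AnovaResult):
            lines += [f"- {r.effect}: {_fmt_anova(r)}" for r in val]
        elif isinstance(val, list):  # pairwise
            for pr in val:
                lines.append(
                    f"- {pr.group_a} vs {pr.group_b}: diff = {pr.mean_diff:.4f}, "
                    f"Tukey p = {pr.tukey_p:.4g}, g = {pr.hedges_g:.3f} "
                    f"[{pr.g_ci_95[0]:.3f}, {pr.g_ci_95[1]:.3f}]"
                    + (f", BF10 = {pr.bf10:.4g}" if pr.bf10 is not None else "")
                )
        elif isinstance(val, dict) and "coefficients" in val:
            tab = val["coefficients"]
            for _, row in tab.iterrows():
                lines.append(
                    f"- {row['term']}: b = {row['b']:.4f}, t = {row['t']:.3f}, p = {row['p']:.4g}"
                )
            lines.append(f"- interaction block BF10 = {val['interaction_bf10']:.4g}")
            lines.append(f"- simple slope: {val['simple_slope']}")
        elif isinstance(val, dict):
            for g, st in val.items():
                lines.append(
                    f"- {g}: t({st['df']}) = {st['t']:.3f}, p = {st['p']:.4g}, g = {st['g']:.3f}"
                )
        lines.append("")
    for col, windows in fits_out.items():
        lines.append(f"## age trajectory: {col}")
        for label, res in windows.items():
            b = res["best"]
            extra = f", vertex = {b.vertex:.1f} y" if b.form == "quadratic" else ""
            lines.append(
                f"- {label}: best = {b.form}, R2 = {b.r2:.3f}, "
                f"F({b.df1}, {b.df2}) = {b.F:.3f}, p = {b.p:.4g}, AIC = {b.aic:.2f}{extra}"
            )
        lines.append("")
    return "\n".join(lines)


def run_pipeline(cfg: PipelineConfig, seed: int | None = None, outdir: str | None = None) -> dict:
    """Run every stage; returns the report bundle and writes artifacts.

    Deterministic given (cfg, seed). Any stage error aborts with the failing
    stage named; partial outputs stay on disk with a MANIFEST marking
    incompleteness.
    """
    cfg.validate()
    seed = cfg.seed if seed is None else int(seed)
    out = Path(outdir if outdir is not None else cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"complete": False, "stages": [], "seed": seed}
    bundle: dict = {}
    t0 = time.time()

    def stage(name):
        manifest["stages"].append(name)
        log.info("stage: %s", name)

    try:
        stage("ingest")
        if cfg.input is not None:
            trials = read_trial_table(cfg.input)
            truth = None
        else:
            sim = cfg.simulate or CohortConfig(
                experiment=cfg.experiment, n_per_group=32 if cfg.experiment == 1 else 27
            )
            trials, truth = simulate_cohort(sim, seed=seed)
            write_trial_table(trials, out / "trials.csv")
            truth.to_csv(out / "ground_truth.csv", index=False)
        log.info("ingested %d trials from %d participants", len(trials), trials["participant_id"].nunique())

        stage("validate")
        report = validate_trial_table(trials)
        if not report.is_valid:
            raise ValueError(f"trial table invalid: {report.errors[:5]} ...")

        stage("qc")
        flagged = prep.flag_rt_outliers(trials, k=cfg.k_sd)
        per_rate, cohort_rate = prep.exclusion_rates(flagged)
        flagged[flagged["excluded"]].to_csv(out / "exclusions.csv", index=False)
        log.info("cohort exclusion rate: %.2f%%", cohort_rate)

        stage("summarize")
        blocks = prep.summarize_blocks(flagged)
        norm = prep.baseline_normalize(blocks, raw_mode=cfg.raw_mode)
        for pid, reason in norm.dropped:
            log.warning("dropped participant %s: %s", pid, reason)
        norm.blocks.to_csv(out / "blocks.csv", index=False)

        stage("derive")
        measures_df, micro = meas.derive_measures(
            norm.blocks, flagged, norm.baselines, raw_mode=cfg.raw_mode
        )
        measures_df.to_csv(out / "measures.csv", index=False)
        micro.to_csv(out / "micro.csv", index=False)

        stage("stats")
        stats_out = run_statistics(
            norm.blocks, measures_df, micro, cfg.experiment,
            gg_alpha=cfg.gg_alpha, compute_bf=cfg.compute_bf,
        )
        (out / "stats.json").write_text(json.dumps(_jsonable(stats_out), indent=1))

        stage("curves")
        fits_out = {}
        fit_cols = ["lm", "micro_online_mean", "micro_offline_mean"]
        if cfg.experiment == 2:
            fit_cols += ["macro_seq_5h", "macro_seq_24h"]
        for col in fit_cols:
            windows = _fit_windows(measures_df, col, seed)
            if windows:
                fits_out[col] = windows
        (out / "fits.json").write_text(json.dumps(_jsonable(fits_out), indent=1))

        stage("report")
        meta = {
            "experiment": cfg.experiment,
            "participants": int(trials["participant_id"].nunique()),
            "trials": int(len(trials)),
            "cohort_exclusion_rate_pct": round(cohort_rate, 3),
            "raw_mode": cfg.raw_mode,
            "seed": seed,
        }
        report_md = render_report(stats_out, fits_out, meta)
        (out / "report.md").write_text(report_md)

        bundle = {
            "trials": trials,
            "ground_truth": truth,
            "blocks": norm.blocks,
            "baselines": norm.baselines,
            "measures": measures_df,
            "micro": micro,
            "stats": stats_out,
            "fits": fits_out,
            "exclusion_rate_pct": cohort_rate,
            "exclusion_rate_per_participant": per_rate,
            "report_md": report_md,
            "runtime_s": time.time() - t0,
        }
        manifest["complete"] = True
        return bundle
    except Exception as e:
        manifest["error"] = f"stage {manifest['stages'][-1]!r} failed: {e}"
        raise
    finally:
        manifest["runtime_s"] = round(time.time() - t0, 2)
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=1))
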