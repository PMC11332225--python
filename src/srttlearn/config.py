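"""Pipeline configuration: a small typed YAML surface with strict keys."""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

from .simulate import CohortConfig


class ConfigError(ValueError):
    """Unknown key or out-of-range value in a pipeline configuration."""


@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    Exactly one of ``input`` (path to a trial-table CSV) or ``simulate``
    (cohort generation parameters) drives a run; ``k_sd`` is the trial
    exclusion threshold in block-level standard deviations; ``raw_mode``
    switches the supplementary non-normalized analysis path; ``gg_alpha`` is
    the Mauchly-test level that triggers the Greenhouse-Geisser correction.
    """

    experiment: int = 1
    input: str | None = None
    simulate: CohortConfig | None = None
    k_sd: float = 3.0
    raw_mode: bool = False
    gg_alpha: float = 0.05
    compute_bf: bool = True
    outdir: str = "results"
    seed: int = 12345
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.experiment not in (1, 2):
            raise ConfigError(f"experiment must be 1 or 2, got {self.experiment}")
        if self.k_sd <= 0:
            raise ConfigError(f"k_sd must be positive, got {self.k_sd}")
        if not (0.0 < self.gg_alpha < 1.0):
            raise ConfigError("gg_alpha must be in (0, 1)")
        if self.input is not None and self.simulate is not None:
            raise ConfigError("give either an input path or a simulate block, not both")


_COHORT_KEYS = {f.name for f in fields(CohortConfig)}
_PIPELINE_KEYS = {f.name for f in fields(PipelineConfig)}


def _cohort_from_dict(d: dict) -> CohortConfig:
    unknown = set(d) - _COHORT_KEYS
    if unknown:
        raise ConfigError(f"unknown simulate key(s): {sorted(unknown)}")
    kw = dict(d)
    if "group_params" in kw:
        kw["group_params"] = {
            g: {p: tuple(v) for p, v in params.items()} for g, params in kw["group_params"].items()
        }
    for tup_key in ("outlier_scale_range", "age_window"):
        if tup_key in kw:
            kw[tup_key] = tuple(kw[tup_key])
    cfg = CohortConfig(**kw)
    try:
        cfg.validate()
    except ValueError as e:
        raise ConfigError(str(e)) from e
    return cfg


def config_from_dict(d: dict | None) -> PipelineConfig:
    d = dict(d or {})
    unknown = set(d) - _PIPELINE_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
    if d.get("simulate") is not None:
        d["simulate"] = _cohort_from_dict(d["simulate"])
    cfg = PipelineConfig(**d)
    cfg.validate()
    return cfg


def read_config(path) -> PipelineConfig:
    """Parse a YAML pipeline configuration; empty files yield all defaults.

    Unknown keys raise :class:`ConfigError`; out-of-range values (for
    instance a non-positive exclusion threshold) raise as well.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    return config_from_dict(raw)
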