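"""Configuration objects shared by every pipeline stage.

Two frozen dataclasses carry all tunables: :class:`EloConfig` for the
rating engine (k factor, start rating, expectation scale, replacement
detection threshold) and :class:`AnalysisConfig` for the downstream
statistics (percentile cuts, focal group size, pre-calving window,
diel period length).  ``load_config`` reads a flat YAML key/value file
and applies defaults for every missing key.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import yaml

#: Spread of the normal-CDF winning expectation, the convention of the
#: animal-dominance Elo literature: p = Phi(rating_diff / (200 * sqrt(2))).
DEFAULT_EXPECTATION_SCALE = 200.0 * math.sqrt(2.0)


class ConfigError(ValueError):
    """Raised for invalid or non-positive configuration values."""


@dataclass(frozen=True)
class EloConfig:
    """Parameters of the sequential rating update.

    k is the maximum number of points transferable per replacement;
    every cow enters the group at ``start_rating``.  ``threshold_seconds``
    is the inter-visit gap that defines an agonistic replacement; it is
    carried here so one object records the full dominance pipeline.
    """

    k: float = 20.0
    start_rating: float = 1000.0
    expectation_scale: float = DEFAULT_EXPECTATION_SCALE
    threshold_seconds: float = 26.0

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ConfigError(f"k must be positive, got {self.k}")
        if not self.start_rating > 0:
            raise ConfigError(f"start_rating must be positive, got {self.start_rating}")
        if not self.expectation_scale > 0:
            raise ConfigError(
                f"expectation_scale must be positive, got {self.expectation_scale}"
            )
        if self.threshold_seconds < 0:
            raise ConfigError(
                f"threshold_seconds must be non-negative, got {self.threshold_seconds}"
            )


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings for extreme-group selection and the statistical battery."""

    elo: EloConfig = field(default_factory=EloConfig)
    lower_quantile: float = 0.15
    upper_quantile: float = 0.85
    n_per_group: int = 12
    window_days: int = 7
    period_hours: int = 3

    def __post_init__(self) -> None:
        if not (0.0 < self.lower_quantile < self.upper_quantile < 1.0):
            raise ConfigError(
                "quantiles must satisfy 0 < lower < upper < 1, got "
                f"{self.lower_quantile}/{self.upper_quantile}"
            )
        if self.n_per_group < 1:
            raise ConfigError(f"n_per_group must be >= 1, got {self.n_per_group}")
        if self.window_days < 1:
            raise ConfigError(f"window_days must be >= 1, got {self.window_days}")
        if self.period_hours < 1 or 24 % self.period_hours != 0:
            raise ConfigError(
                f"period_hours must divide 24, got {self.period_hours}"
            )


_ELO_KEYS = {"k", "start_rating", "expectation_scale", "threshold_seconds"}
_ANALYSIS_KEYS = {
    "lower_quantile",
    "upper_quantile",
    "n_per_group",
    "window_days",
    "period_hours",
}


def load_config(path=None, **overrides) -> AnalysisConfig:
    """Build an :class:`AnalysisConfig` from a YAML file plus overrides.

    All keys are optional; keys may be given flat (``k: 10``) in the file.
    Keyword overrides take precedence over the file.  Unknown keys raise
    :class:`ConfigError` so typos never silently fall back to defaults.
    """
    values: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path!r} must contain a mapping")
        values.update(loaded)
    values.update(overrides)

    unknown = set(values) - _ELO_KEYS - _ANALYSIS_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")

    try:
        elo = EloConfig(**{k: v for k, v in values.items() if k in _ELO_KEYS})
        return AnalysisConfig(
            elo=elo, **{k: v for k, v in values.items() if k in _ANALYSIS_KEYS}
        )
    except TypeError as exc:  # e.g. a list where a number belongs
        raise ConfigError(str(exc)) from exc


def config_as_dict(cfg: AnalysisConfig) -> dict:
    """Flat dict of every setting, for provenance records and run logs."""
    out = {f.name: getattr(cfg.elo, f.name) for f in fields(EloConfig)}
    for f in fields(AnalysisConfig):
        if f.name != "elo":
            out[f.name] = getattr(cfg, f.name)
    return out
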