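"""Simulation and pipeline configuration models.

All knobs of the synthetic tweet stream live in :class:`SimulationConfig`.
The generator emulates an eight-year Japanese tweet corpus at desk scale:
monthly volume with a long-term decline and month-of-year seasonality, a
marker-token subpopulation used for pseudo-baseline sampling, small
per-attitude rates of touch-desire / touch-avoidance posts, multinomial
target-word distributions that may shift after the outbreak month, and
contamination (exact-duplicate bot posts, URL posts, noisy targets).
"""

from __future__ import annotations

import math
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .errors import ConfigurationError

ATTITUDES = ("desire", "avoidance")

#: month-of-year multiplicative factors (January first), geometric mean 1.
#: Winter months run high with a pronounced January peak and a February dip,
#: mimicking the observed ~11% January-to-February drop in touch-attitude
#: proportions; values are normalised in the validator.
DEFAULT_SEASONAL_RAW = (1.10, 0.98, 0.99, 1.00, 1.01, 0.97, 0.98, 1.00, 1.01, 1.02, 1.03, 1.06)


def _geonormalise(factors: tuple[float, ...]) -> tuple[float, ...]:
    g = math.exp(sum(math.log(f) for f in factors) / len(factors))
    return tuple(f / g for f in factors)


def default_target_distribution(words: list[str]) -> dict[str, float]:
    """Zipf-like probabilities over a sorted word list (rank 1 most common)."""
    ranks = np.arange(1, len(words) + 1, dtype=float)
    w = 1.0 / ranks
    w /= w.sum()
    return dict(zip(sorted(words), w))


class Contamination(BaseModel):
    """Rates of records the exclusion cascade must remove."""

    model_config = ConfigDict(frozen=True)

    duplicate: float = Field(default=0.05, ge=0.0, le=1.0)
    url: float = Field(default=0.10, ge=0.0, le=1.0)
    noisy_target: float = Field(default=0.30, ge=0.0, le=1.0)


class SimulationConfig(BaseModel):
    model_config = ConfigDict(frozen=True, validate_default=True)

    start_month: str = "2013-02"
    n_months: int = Field(default=96, ge=1)
    base_volume: float = Field(default=100_000.0, ge=0.0)
    #: total fractional change of volume and attitude rates over six years,
    #: applied exponentially per month; -0.238 mirrors the observed 23.8%
    #: decline of touch-desire proportions between 2013 and 2019
    trend: float = Field(default=-0.238, gt=-1.0)
    seasonal_factors: tuple[float, ...] = DEFAULT_SEASONAL_RAW
    #: probability a post contains the high-frequency marker token whose
    #: window-sampled count forms the pseudo-baseline denominator
    marker_prevalence: float = Field(default=0.9, gt=0.0, lt=1.0)
    attitude_rate: dict[str, float] = Field(
        default_factory=lambda: {"desire": 0.020, "avoidance": 0.006}
    )
    #: probability an attitude post carries an extractable target word
    target_presence: float = Field(default=0.25, ge=0.0, le=1.0)
    outbreak_month: str = "2020-02"
    effect_overall: float = Field(default=1.0, ge=0.0)
    effect_waves: tuple[float, float, float] = (1.0, 1.0, 1.0)
    target_distribution_pre: Optional[dict[str, float]] = None
    target_distribution_post: Optional[dict[str, float]] = None
    contamination: Contamination = Field(default_factory=Contamination)
    count_model: Literal["poisson", "negative_binomial"] = "poisson"
    #: negative-binomial overdispersion (variance = mu + nb_alpha * mu^2)
    nb_alpha: float = Field(default=0.1, gt=0.0)
    timezone: str = "Asia/Tokyo"
    seed: int = 0

    # ------------------------------------------------------------------ #

    @field_validator("start_month", "outbreak_month")
    @classmethod
    def _valid_month(cls, v: str) -> str:
        try:
            pd.Period(v, freq="M")
        except Exception as exc:  # pragma: no cover - pandas message varies
            raise ValueError(f"not a calendar month: {v!r}") from exc
        return v

    @field_validator("seasonal_factors")
    @classmethod
    def _valid_season(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if len(v) != 12:
            raise ValueError("seasonal_factors must have length 12")
        if any(f <= 0 for f in v):
            raise ValueError("seasonal_factors must all be > 0")
        return _geonormalise(tuple(float(f) for f in v))

    @field_validator("attitude_rate")
    @classmethod
    def _valid_rates(cls, v: dict[str, float]) -> dict[str, float]:
        for att, r in v.items():
            if att not in ATTITUDES:
                raise ValueError(f"unknown attitude {att!r}")
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"attitude_rate[{att!r}] must be in [0,1], got {r}")
        return {att: float(v.get(att, 0.0)) for att in ATTITUDES}

    @model_validator(mode="after")
    def _valid_distributions(self) -> "SimulationConfig":
        for name in ("target_distribution_pre", "target_distribution_post"):
            dist = getattr(self, name)
            if dist is None:
                continue
            vals = np.asarray(list(dist.values()), dtype=float)
            if (vals < 0).any():
                raise ValueError(f"{name} has negative entries")
            if abs(vals.sum() - 1.0) > 1e-12:
                raise ValueError(f"{name} must sum to 1 within 1e-12, got {vals.sum()!r}")
        return self

    # ------------------------------------------------------------------ #

    @property
    def months(self) -> pd.PeriodIndex:
        return pd.period_range(self.start_month, periods=self.n_months, freq="M")

    def monthly_trend_factor(self, month: pd.Period) -> float:
        """Exponential trend factor relative to the simulation start."""
        years = (month.ordinal - pd.Period(self.start_month, "M").ordinal) / 12.0
        return float((1.0 + self.trend) ** (years / 6.0))

    def seasonal_factor(self, month: pd.Period) -> float:
        return self.seasonal_factors[month.month - 1]

    def wave_of(self, month: pd.Period) -> int | None:
        """Outbreak wave index (1..3) of a calendar month, or None.

        Wave 1 spans outbreak months 0-4 (Feb-Jun), wave 2 months 5-9
        (Jul-Nov), wave 3 months 10-11 (Dec-Jan).
        """
        lag = month.ordinal - pd.Period(self.outbreak_month, "M").ordinal
        if lag < 0 or lag > 11:
            return None
        return 1 if lag <= 4 else (2 if lag <= 9 else 3)

    def effect_multiplier(self, month: pd.Period) -> float:
        wave = self.wave_of(month)
        if wave is None:
            return 1.0
        return self.effect_overall * self.effect_waves[wave - 1]

    def expected_volume(self, month: pd.Period) -> float:
        return self.base_volume * self.monthly_trend_factor(month) * self.seasonal_factor(month)

    def attitude_rate_at(self, attitude: str, month: pd.Period) -> float:
        """Per-post probability of the attitude, with trend, seasonality and
        any injected post-outbreak effect applied."""
        r = (
            self.attitude_rate[attitude]
            * self.monthly_trend_factor(month)
            * self.seasonal_factor(month)
            * self.effect_multiplier(month)
        )
        if r > 1.0:
            raise ConfigurationError(
                f"attitude_rate[{attitude!r}] exceeds 1 in {month} after trend/effects"
            )
        return r

    def target_distribution_at(self, month: pd.Period, words: list[str]) -> dict[str, float]:
        pre = self.target_distribution_pre or default_target_distribution(words)
        post = self.target_distribution_post or pre
        outbreak = pd.Period(self.outbreak_month, "M")
        return post if month >= outbreak else pre

    # -- YAML round trip ------------------------------------------------ #

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.model_validate(raw)


def validate_config(raw: dict) -> SimulationConfig:
    """Validate a raw mapping, raising :class:`ConfigurationError` naming the
    offending field."""
    try:
        return SimulationConfig.model_validate(raw)
    except Exception as exc:
        raise ConfigurationError(str(exc)) from exc
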