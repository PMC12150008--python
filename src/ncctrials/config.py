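"""Schema-validated configuration for simulation, fitting and studies.

A config file is flat YAML or JSON.  Minimal example::

    K: 4
    d: 250
    n_arm: 250

Defaults fill in everything else (``alpha=0.025``, ``sigma=1``,
``n_reps=10000``, ``psi=1``, ...).  Unknown keys and type or range
violations are rejected with a message listing every problem at once.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .design import PlatformDesign, build_design
from .study import Scenario

__all__ = ["Config", "ConfigError", "LamScheme", "load_config", "expand_scenarios"]


class ConfigError(ValueError):
    """Invalid configuration file."""


class LamScheme(BaseModel):
    """Per-arm assignment of the trend strength ``x``: arms in ``arms`` get
    ``x * multiplier``, all other arms (control included) get zero."""

    model_config = ConfigDict(extra="forbid")

    arms: list[int] = Field(min_length=1)
    multipliers: list[float] | None = None

    @model_validator(mode="after")
    def _check(self) -> "LamScheme":
        if self.multipliers is not None and len(self.multipliers) != len(self.arms):
            raise ValueError("multipliers must match arms in length")
        return self

    def expand(self, x: float, K: int) -> tuple[float, ...]:
        mult = self.multipliers or [1.0] * len(self.arms)
        lam = [0.0] * (K + 1)
        for arm, m in zip(self.arms, mult):
            if not 1 <= arm <= K:
                raise ConfigError(f"lam_scheme arm {arm} outside 1..{K}")
            lam[arm] = x * m
        return tuple(lam)


class Config(BaseModel):
    """Flat configuration covering design, trend, generative and study keys."""

    model_config = ConfigDict(extra="forbid")

    # --- design
    K: int = Field(ge=1)
    d: int | None = Field(default=None, ge=0)
    schedule: list[int] | None = None
    n_arm: int = Field(default=250, ge=1)
    clength: int = Field(default=100, ge=1)
    # --- time trend
    pattern: Literal["linear", "stepwise", "inverted_u", "seasonal"] | None = None
    lam: float | list[float] = 0.0
    lam_grid: list[float] | None = None
    lam_scheme: Literal["equal"] | LamScheme = "equal"
    Np: int | None = Field(default=None, ge=1)
    psi: float = Field(default=1.0, gt=0)
    # --- generative
    eta0: float = 0.0
    theta: float | list[float] = 0.25
    sigma: float = Field(default=1.0, gt=0)
    # --- study
    M: int | None = Field(default=None, ge=1)
    models: list[str] = ["fixed-period", "ttest-pooled", "ttest-separate"]
    hypothesis: Literal["null", "alternative", "both"] = "both"
    n_reps: int = Field(default=10_000, ge=1)
    alpha: float = Field(default=0.025, gt=0, lt=1)
    seed: int = 1
    name: str = "scenario"

    @model_validator(mode="after")
    def _check(self) -> "Config":
        if self.d is None and self.schedule is None:
            raise ValueError("one of 'd' or 'schedule' is required")
        if self.d is not None and self.schedule is not None:
            raise ValueError("'d' and 'schedule' are mutually exclusive")
        return self

    # -- expansion helpers ---------------------------------------------------

    @property
    def evaluated_arm(self) -> int:
        return self.M if self.M is not None else self.K

    def to_design(self) -> PlatformDesign:
        sched = self.d if self.schedule is None else self.schedule
        return build_design(self.K, sched, self.n_arm, self.clength)

    def theta_vector(self, null: bool = False) -> tuple[float, ...]:
        if null:
            return (0.0,) * self.K
        if isinstance(self.theta, list):
            if len(self.theta) != self.K:
                raise ConfigError(f"theta needs K={self.K} entries")
            return tuple(self.theta)
        return (float(self.theta),) * self.K

    def lam_vector(self, x: float) -> tuple[float, ...]:
        if self.lam_scheme == "equal":
            return (float(x),) * (self.K + 1)
        return self.lam_scheme.expand(x, self.K)

    def scenario(self, lam_x: float | None = None, null: bool = False) -> Scenario:
        """Single scenario; ``lam_x`` overrides the configured strength."""
        if lam_x is None:
            if isinstance(self.lam, list):
                if len(self.lam) != self.K + 1:
                    raise ConfigError(f"lam needs K+1={self.K + 1} entries")
                lam = tuple(float(v) for v in self.lam)
            else:
                lam = self.lam_vector(float(self.lam))
        else:
            lam = self.lam_vector(lam_x)
        suffix = "null" if null else "alt"
        tag = "" if lam_x is None else f"_lam{lam_x:g}"
        return Scenario(
            name=f"{self.name}_{self.pattern or 'notrend'}{tag}_{suffix}",
            design=self.to_design(),
            M=self.evaluated_arm,
            theta=self.theta_vector(null=null),
            pattern=self.pattern,
            lam=lam if self.pattern is not None else (),
            Np=self.Np,
            psi=self.psi,
            eta0=self.eta0,
            sigma=self.sigma,
            alpha=self.alpha,
        )


def expand_scenarios(cfg: Config) -> list[Scenario]:
    """Cross the strength grid with the hypothesis setting."""
    nulls = {"null": [True], "alternative": [False], "both": [True, False]}[
        cfg.hypothesis
    ]
    xs: list[float | None] = (
        [None] if cfg.lam_grid is None else [float(x) for x in cfg.lam_grid]
    )
    return [cfg.scenario(lam_x=x, null=h) for x in xs for h in nulls]


def load_config(path: str | Path, **overrides) -> Config:
    """Load and validate a YAML or JSON config file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return Config(**raw)
    except ValidationError as exc:
        issues = "; ".join(
            f"{'.'.join(str(p) for p in e['loc']) or '<root>'}: {e['msg']}"
            for e in exc.errors()
        )
        raise ConfigError(f"invalid config {path}: {issues}") from exc
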