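"""Run configuration: parameter container, validation, YAML round-trip.

A :class:`Config` fully determines a simulation session (together with the
seed it contains).  Defaults are the healthy-control configuration used for
the single-agent simulations: k=0.1, m=1.3, c=8, w0=0.5, z=0.4,
lambda_min=2, lambda_max=50, alpha=3, beta=1, y=0.8, 200 trials with a
reversal at trial 100.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional

import yaml

__all__ = ["Config", "ConfigError"]


class ConfigError(ValueError):
    """Raised for missing files, parse failures and out-of-range values."""


def _check(cond: bool, key: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"config key '{key}': {msg}")


@dataclass
class Config:
    # environment
    y: float = 0.8                 # P(neutral | correct response)
    n_trials: int = 200
    reversal_trial: int = 100      # trials >= this index use the flipped map

    # agent generative model
    c: float = 8.0                 # baseline stress sensitivity (preference magnitude)
    z: float = 0.4                 # Pavlovian belief of reaching the neutral state
    alpha: float = 3.0             # action precision
    beta: float = 1.0              # prior policy-precision parameter (gamma = 1/beta)
    init_scale: float = 1.0        # total initial Dirichlet concentration per column
    gamma: Optional[float] = None  # policy precision; None -> 1/beta

    # learning
    k: float = 0.1                 # stress weight on the aversive learning-rate boost
    g: float = 5.0                 # decay-logistic gradient (nats^-1)
    m: float = 1.3                 # decay-logistic midpoint (belief-decay threshold)
    lambda_min: float = 2.0
    lambda_max: float = 50.0

    # controllability
    w0: float = 0.5                # controllability threshold (logistic midpoint)
    g_w: float = 4.0               # controllability-logistic gradient
    controllability_enabled: bool = True
    # False (default): c_eff modulates only the outcome-valence learning
    # rate, and policies are evaluated with the baseline c.  True: c_eff
    # also feeds back into the preferences used for policy evaluation on
    # the same trial (one fixed-point sweep).
    controllability_same_trial: bool = False

    # SAPE: condition the policy posterior on the taken action before the
    # pre-outcome BMA (True) or use the pre-action posterior (False)
    sape_post_action: bool = True

    # replication
    n_replicates: int = 50
    base_seed: int = 0

    def __post_init__(self) -> None:
        _check(0.0 <= self.y <= 1.0, "y", f"must be a probability, got {self.y}")
        _check(self.n_trials >= 0, "n_trials", "must be >= 0")
        _check(
            0 <= self.reversal_trial <= self.n_trials,
            "reversal_trial",
            f"must lie in [0, n_trials={self.n_trials}], got {self.reversal_trial}",
        )
        _check(self.c >= 1.0, "c", f"must be >= 1 (c_eff = c^(1-w) in [1, c]), got {self.c}")
        _check(0.0 <= self.z <= 1.0, "z", f"must be a probability, got {self.z}")
        _check(self.alpha >= 0.0, "alpha", "must be >= 0")
        _check(self.beta > 0.0, "beta", "must be > 0")
        _check(self.init_scale > 0.0, "init_scale", "must be > 0")
        if self.gamma is not None:
            _check(self.gamma > 0.0, "gamma", "must be > 0 when given")
        _check(self.k >= 0.0, "k", f"must be >= 0, got {self.k}")
        _check(self.g > 0.0, "g", "must be > 0")
        _check(self.m >= 0.0, "m", "must be >= 0")
        _check(self.lambda_min > 0.0, "lambda_min", "must be > 0")
        _check(
            self.lambda_max >= self.lambda_min,
            "lambda_max",
            f"must be >= lambda_min={self.lambda_min}, got {self.lambda_max}",
        )
        _check(0.0 <= self.w0 <= 1.0, "w0", f"must lie in [0, 1], got {self.w0}")
        _check(self.g_w > 0.0, "g_w", "must be > 0")
        _check(self.n_replicates >= 1, "n_replicates", "must be >= 1")
        _check(int(self.base_seed) == self.base_seed and self.base_seed >= 0,
               "base_seed", "must be a nonnegative integer")

    @property
    def policy_precision(self) -> float:
        """Policy precision gamma; fixed at 1/beta unless overridden."""
        return self.gamma if self.gamma is not None else 1.0 / self.beta

    def replace(self, **kwargs: Any) -> "Config":
        """Return a validated copy with the given fields replaced."""
        return dataclasses.replace(self, **kwargs)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "Config":
        if not isinstance(data, dict):
            raise ConfigError(f"expected a mapping of config keys, got {type(data).__name__}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
        try:
            return cls(**data)
        except TypeError as exc:  # pragma: no cover - defensive
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        try:
            data = yaml.safe_load(path.read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"could not parse {path}: {exc}") from exc
        if data is None:  # empty file -> all defaults
            data = {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        data = self.to_dict()
        # YAML has no NaN-safe convention we rely on; gamma=None round-trips as null
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    def validate_finite(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and not math.isfinite(v):
                raise ConfigError(f"config key '{f.name}': must be finite, got {v}")
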