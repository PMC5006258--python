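"""Trial design configuration.

All design constants of the adaptive trial live in one dataclass: arm count,
burn-in size, interim cadence, decision thresholds, utility weight, and the
Dirichlet priors of the outcome and conditional transition models. Defaults
are the four-arm design: 80-patient burn-in (20 per arm) plus 20 spare
slots, 400-patient cap, quarterly (13-week) adaptations, early-success
threshold 0.925 and loser threshold 0.01 on the posterior probability of
being the best arm.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

from .errors import ConfigError

_TRIPLE_FIELDS = ("outcome_prior", "eff_prior", "noeff_prior")


@dataclass(frozen=True)
class TrialConfig:
    n_arms: int = 4
    burn_in_n: int = 80
    burn_in_spare: int = 20
    max_n: int = 400
    adaptation_interval_weeks: float = 13.0
    success_threshold: float = 0.925
    loser_threshold: float = 0.01
    utility_weight: float = 0.75
    outcome_prior: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    eff_prior: tuple[float, float, float] = (1.0, 7.0, 2.0)
    noeff_prior: tuple[float, float, float] = (1.0, 2.0, 7.0)
    visit_weeks: tuple[int, ...] = (4, 8, 12)
    n_draws: int = 10_000
    m_imputations: int = 20
    block_size: int = 100
    seed: int | None = None
    #: optional unblinded arm-code → drug-name mapping; blinded reports use A, B, C, ...
    arm_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_arms < 2:
            raise ConfigError("need at least two arms")
        if self.burn_in_n % self.n_arms:
            raise ConfigError("burn_in_n must be divisible by n_arms")
        if self.burn_in_spare % self.n_arms:
            raise ConfigError("burn_in_spare must be divisible by n_arms")
        if not 0 < self.loser_threshold < self.success_threshold < 1:
            raise ConfigError(
                "need 0 < loser_threshold < success_threshold < 1, got "
                f"{self.loser_threshold} / {self.success_threshold}"
            )
        if self.max_n < self.burn_in_n:
            raise ConfigError("max_n must be at least burn_in_n")
        if self.utility_weight < 0:
            raise ConfigError("utility_weight must be nonnegative")
        for name in _TRIPLE_FIELDS:
            triple = getattr(self, name)
            if len(triple) != 3 or any(c <= 0 for c in triple):
                raise ConfigError(f"{name} must be three positive concentrations")
        if self.n_draws < 1 or self.m_imputations < 1 or self.block_size < 1:
            raise ConfigError("n_draws, m_imputations and block_size must be >= 1")
        if self.arm_names is not None and len(self.arm_names) != self.n_arms:
            raise ConfigError("arm_names must list one name per arm")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        for name in _TRIPLE_FIELDS + ("visit_weeks",):
            d[name] = list(d[name])
        if d["arm_names"] is not None:
            d["arm_names"] = list(d["arm_names"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrialConfig":
        d = dict(d)
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for name in _TRIPLE_FIELDS + ("visit_weeks",):
            if name in d:
                d[name] = tuple(d[name])
        if d.get("arm_names") is not None:
            d["arm_names"] = tuple(d["arm_names"])
        return cls(**d)

    def with_(self, **kwargs) -> "TrialConfig":
        """Copy with fields replaced."""
        return replace(self, **kwargs)

    def config_hash(self) -> str:
        """SHA-256 of the canonical JSON form (versioning/audit anchor)."""
        canon = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canon.encode()).hexdigest()

    def blinded_labels(self) -> tuple[str, ...]:
        """Generic arm codes (A, B, C, ...) used in blinded reports."""
        return tuple(chr(ord("A") + i) for i in range(self.n_arms))
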