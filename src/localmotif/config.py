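"""Run configuration: spans, kernel widths, thresholds, sample counts, seeds."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .regions import DEFAULT_PDEP_THRESHOLDS, DEFAULT_PIND_THRESHOLD


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    span_start: int = -3000
    span_end: int = 2000
    x_start: int = -2000
    x_stop: int = 1000
    kernel_shape: str = "gaussian"
    half_widths: list[int] = field(default_factory=lambda: [10, 20, 50, 100, 200])
    p_dep_thresholds: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_PDEP_THRESHOLDS)
    )
    p_ind_threshold: float = DEFAULT_PIND_THRESHOLD
    p_ori_threshold: float = 0.01
    n_samples_local: int = 25000
    n_samples_ori: int = 10000
    k_min: int = 2
    k_max: int = 10
    kmeans_restarts: int = 100
    kmeans_max_iter: int = 100
    kstar_reps: int = 1000
    strong_fraction: float = 0.85
    weak_fraction: float = 0.70
    seed: int = 1

    def validate(self) -> None:
        missing = [h for h in self.half_widths if h not in self.p_dep_thresholds]
        if missing:
            raise ConfigError(
                f"no P_dep threshold configured for half-width(s) {missing}"
            )
        if not (self.span_start < self.x_start < self.x_stop <= self.span_end):
            raise ConfigError(
                "need span_start < x_start < x_stop <= span_end "
                f"(got span [{self.span_start},{self.span_end}), "
                f"scored [{self.x_start},{self.x_stop}])"
            )
        if not (2 <= self.k_min <= self.k_max <= 10):
            raise ConfigError("k range must satisfy 2 <= k_min <= k_max <= 10")
        if not (0 < self.weak_fraction < self.strong_fraction <= 1):
            raise ConfigError("need 0 < weak_fraction < strong_fraction <= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "p_dep_thresholds" in raw:
            raw["p_dep_thresholds"] = {
                int(k): float(v) for k, v in raw["p_dep_thresholds"].items()
            }
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
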