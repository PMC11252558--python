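"""Pipeline configuration: serializable parameters with a stable digest.

The digest (sha256 of the canonical JSON form) is embedded in every
numerical output so runs can be matched to the exact parameters that
produced them; two runs with equal digests produce byte-identical bundles.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .synthetic import CohortSpec


@dataclass
class PipelineConfig:
    """All tunable parameters of the end-to-end analysis."""

    cohort: dict = field(default_factory=lambda: CohortSpec().to_dict())
    bands: tuple[str, ...] = ("alpha", "theta")
    target_rate: float = 500.0
    epoch_length: float = 2.0
    edge_trim: float = 1.0
    bootstrap_fraction: float = 0.2
    bootstrap_repeats: int = 5
    sparsity: float = 0.2
    hhse_bin_width: float = 0.5
    hhse_freq_range: tuple[float, float] = (1.0, 30.0)
    hhse_sd_tol: float = 0.2
    hhse_max_sifts: int = 10
    hhse_channels: tuple[str, ...] | None = None  # None = all channels
    outer_folds: int = 10
    inner_folds: int = 5
    c_grid: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3)
    select_features: bool = True
    global_normalization: bool = False
    n_permutations: int = 0  # 0 disables the permutation test
    reject_ptp: float | None = None  # epoch-rejection stub threshold, off by default
    seed: int = 0

    def __post_init__(self) -> None:
        from .recording import BANDS

        unknown = [b for b in self.bands if b not in BANDS]
        if unknown:
            raise ValueError(f"unknown band name(s): {unknown}")
        if "alpha" not in self.bands or "theta" not in self.bands:
            raise ValueError("the analysis requires at least the alpha and theta bands")
        if not 0.0 < self.sparsity <= 1.0:
            raise ValueError(f"sparsity must lie in (0, 1], got {self.sparsity}")
        if not 0.0 < self.bootstrap_fraction <= 1.0:
            raise ValueError("bootstrap_fraction must lie in (0, 1]")
        for name in ("epoch_length", "target_rate", "hhse_bin_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.edge_trim < 0:
            raise ValueError("edge_trim must be non-negative")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("outer_folds and inner_folds must be at least 2")
        CohortSpec.from_dict(self.cohort)  # validates

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec.from_dict(self.cohort)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bands"] = list(self.bands)
        d["hhse_freq_range"] = list(self.hhse_freq_range)
        d["c_grid"] = list(self.c_grid)
        d["hhse_channels"] = (
            list(self.hhse_channels) if self.hhse_channels is not None else None
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("bands", "hhse_freq_range", "c_grid", "hhse_channels"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def digest(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2, sort_keys=True)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=True)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


def desk_config(seed: int = 0, **overrides) -> PipelineConfig:
    """Smoke-run configuration: a small cohort and fold counts its size permits."""
    from .synthetic import desk_spec

    params = dict(
        cohort=desk_spec(seed=seed).to_dict(),
        target_rate=250.0,
        edge_trim=0.5,
        outer_folds=3,
        inner_folds=2,
        c_grid=(1e-2, 1.0, 1e2),
        select_features=False,
        seed=seed,
    )
    params.update(overrides)
    return PipelineConfig(**params)
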