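"""Analysis configuration: spline settings, priors, MCMC controls.

Loaded from / dumped to YAML; every run writes the resolved config next to
its outputs so analyses are reproducible from the output directory alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml


@dataclass
class PriorSpec:
    """Priors: Laplace(0, lambda) on every penalized coefficient with a shared
    Gamma(a, b) hyperprior on the intensity lambda; diffuse Normal(0, sd) on
    the intercept; Dirichlet(1,...,1) on haplotype frequencies; flat on the
    inbreeding coefficient over its valid range."""

    gamma_shape: float = 20.0
    gamma_rate: float = 20.0
    beta0_sd: float = 10.0

    def __post_init__(self):
        if self.gamma_shape <= 0 or self.gamma_rate <= 0:
            raise ValueError("gamma hyperprior parameters must be positive")


@dataclass
class MCMCSettings:
    iterations: int = 50_000
    burn_in: int = 10_000
    thinning: int = 10
    seed: int = 0
    target_acceptance: float = 0.35
    adapt_interval: int = 50
    initial_scale: float = 0.2
    # diagnostics / unusual-run toggles
    update_frequencies: bool = True
    update_inbreeding: bool = True
    update_intensity: bool = True
    likelihood_enabled: bool = True
    fixed_intensity: float = 1.0  # used when update_intensity is False

    def __post_init__(self):
        if not 0 < self.burn_in < self.iterations:
            raise ValueError("need 0 < burn_in < iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def n_samples(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning


@dataclass
class AnalysisConfig:
    """Block definition, spline knots, reporting grid, MCMC and priors."""

    block_snps: list[str] | None = None
    anchor_snp: str | None = None
    flank: int = 2
    interior_knots: tuple[float, ...] = (40.0, 60.0)
    boundary_knots: tuple[float, float] = (20.0, 100.0)
    spline_order: int = 4
    age_grid: tuple[float, ...] = tuple(float(a) for a in range(25, 100, 5))
    significance_age_window: tuple[float, float] | None = None
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    prior: PriorSpec = field(default_factory=PriorSpec)

    def __post_init__(self):
        lo, hi = self.boundary_knots
        ik = self.interior_knots
        if ik and not (lo < min(ik) and max(ik) < hi):
            raise ValueError("boundary knots must strictly contain interior knots")
        if any(a < lo or a > hi for a in self.age_grid):
            raise ValueError("age grid must lie within the boundary knots")

    def validate_ages(self, ages: np.ndarray) -> None:
        lo, hi = self.boundary_knots
        ages = np.asarray(ages, dtype=float)
        if ages.size and (ages.min() < lo or ages.max() > hi):
            raise ValueError(
                f"observed ages [{ages.min()}, {ages.max()}] fall outside "
                f"the boundary knots [{lo}, {hi}]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["interior_knots"] = list(self.interior_knots)
        d["boundary_knots"] = list(self.boundary_knots)
        d["age_grid"] = list(self.age_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "mcmc" in d and isinstance(d["mcmc"], dict):
            d["mcmc"] = MCMCSettings(**d["mcmc"])
        if "prior" in d and isinstance(d["prior"], dict):
            d["prior"] = PriorSpec(**d["prior"])
        for key in ("interior_knots", "boundary_knots", "age_grid",
                    "significance_age_window"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
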