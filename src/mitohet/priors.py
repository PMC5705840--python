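"""Prior distributions for the model parameters.

The source study's exact priors are not published, so the defaults here are
weakly informative and support-respecting: uniform on the bounded fractions
(h_star on its (0, 0.9) domain, the sigmoid midpoint h0 on (0, 1)) and
log-uniform over generous positive ranges for every scale/rate parameter.
All defaults can be overridden per parameter.

Sampling happens in a transformed space in which each default prior is flat:
positive parameters are sampled as logarithms, bounded fractions as-is.
Each prior therefore exposes both its natural-space density and the density
in its sampling coordinate (including the Jacobian).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import PARAM_NAMES

__all__ = ["Uniform", "LogUniform", "HalfNormal", "PriorSpec", "default_priors"]


@dataclass(frozen=True)
class Uniform:
    """Flat prior on (lo, hi); sampling coordinate is the value itself."""

    lo: float
    hi: float

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError(f"require lo < hi, got ({self.lo}, {self.hi})")

    log_scale = False

    def logpdf(self, x: float) -> float:
        return -np.log(self.hi - self.lo) if self.lo < x < self.hi else -np.inf

    def logpdf_transformed(self, y: float) -> float:
        return self.logpdf(y)

    def transform(self, x: float) -> float:
        return x

    def untransform(self, y: float) -> float:
        return y

    @property
    def transformed_bounds(self) -> tuple[float, float]:
        return (self.lo, self.hi)

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.uniform(self.lo, self.hi))

    def typical(self) -> float:
        return 0.5 * (self.lo + self.hi)


@dataclass(frozen=True)
class LogUniform:
    """Scale-invariant prior p(x) ∝ 1/x on (lo, hi); sampled as log(x)."""

    lo: float
    hi: float

    def __post_init__(self):
        if not 0 < self.lo < self.hi:
            raise ValueError(f"require 0 < lo < hi, got ({self.lo}, {self.hi})")

    log_scale = True

    def logpdf(self, x: float) -> float:
        if not self.lo < x < self.hi:
            return -np.inf
        return -np.log(x) - np.log(np.log(self.hi / self.lo))

    def logpdf_transformed(self, y: float) -> float:
        # uniform in y = log x
        lo, hi = np.log(self.lo), np.log(self.hi)
        return -np.log(hi - lo) if lo < y < hi else -np.inf

    def transform(self, x: float) -> float:
        return float(np.log(x))

    def untransform(self, y: float) -> float:
        return float(np.exp(y))

    @property
    def transformed_bounds(self) -> tuple[float, float]:
        return (float(np.log(self.lo)), float(np.log(self.hi)))

    def sample(self, rng: np.random.Generator) -> float:
        return float(np.exp(rng.uniform(np.log(self.lo), np.log(self.hi))))

    def typical(self) -> float:
        return float(np.sqrt(self.lo * self.hi))


@dataclass(frozen=True)
class HalfNormal:
    """Half-normal prior on x > 0 with the given scale; sampled as log(x)."""

    scale: float

    def __post_init__(self):
        if not self.scale > 0:
            raise ValueError(f"scale must be positive, got {self.scale}")

    log_scale = True

    def logpdf(self, x: float) -> float:
        if x <= 0:
            return -np.inf
        return (
            0.5 * np.log(2.0 / np.pi)
            - np.log(self.scale)
            - x**2 / (2.0 * self.scale**2)
        )

    def logpdf_transformed(self, y: float) -> float:
        # p(y) = p(x) |dx/dy| = p(e^y) e^y
        return self.logpdf(np.exp(y)) + y

    def transform(self, x: float) -> float:
        return float(np.log(x))

    def untransform(self, y: float) -> float:
        return float(np.exp(y))

    @property
    def transformed_bounds(self) -> tuple[float, float]:
        return (-np.inf, np.inf)

    def sample(self, rng: np.random.Generator) -> float:
        return float(np.abs(rng.normal(0.0, self.scale)))

    def typical(self) -> float:
        return self.scale * np.sqrt(2.0 / np.pi)


Prior = Uniform | LogUniform | HalfNormal


class PriorSpec:
    """Per-parameter priors for the 12 adjustable model parameters."""

    def __init__(self, priors: dict[str, Prior]):
        missing = set(PARAM_NAMES) - set(priors)
        extra = set(priors) - set(PARAM_NAMES)
        if missing or extra:
            raise ValueError(f"prior spec mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        self._priors = {name: priors[name] for name in PARAM_NAMES}

    def __getitem__(self, name: str) -> Prior:
        return self._priors[name]

    def items(self):
        return self._priors.items()

    def replace(self, **overrides: Prior) -> "PriorSpec":
        merged = dict(self._priors)
        for name, prior in overrides.items():
            if name not in merged:
                raise ValueError(f"unknown parameter {name!r}")
            merged[name] = prior
        return PriorSpec(merged)

    # --- sampling-space helpers -------------------------------------------

    def transform(self, values) -> np.ndarray:
        return np.array([p.transform(v) for (_, p), v in zip(self.items(), values)])

    def untransform(self, coords) -> np.ndarray:
        return np.array([p.untransform(c) for (_, p), c in zip(self.items(), coords)])

    def log_prior_transformed(self, coords) -> float:
        total = 0.0
        for (_, prior), c in zip(self.items(), coords):
            lp = prior.logpdf_transformed(c)
            if not np.isfinite(lp):
                return -np.inf
            total += lp
        return total

    def log_prior(self, values) -> float:
        total = 0.0
        for (_, prior), v in zip(self.items(), values):
            lp = prior.logpdf(v)
            if not np.isfinite(lp):
                return -np.inf
            total += lp
        return total

    def transformed_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        los, his = zip(*(p.transformed_bounds for _, p in self.items()))
        return np.array(los), np.array(his)

    def typical_point(self) -> np.ndarray:
        """Prior-typical values in natural space (midpoint / geometric mean)."""
        return np.array([p.typical() for _, p in self.items()])

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return np.array([p.sample(rng) for _, p in self.items()])

    def describe(self) -> dict[str, str]:
        return {name: repr(prior) for name, prior in self.items()}


def default_priors() -> PriorSpec:
    """Documented default priors (the published study's are unavailable)."""
    wide = LogUniform(1e-2, 1e2)
    return PriorSpec(
        {
            "beta": wide,
            "k_mRNA": wide,
            "k_m": LogUniform(0.1, 100.0),
            "h0": Uniform(0.0, 1.0),
            "delta_p": wide,
            "c1": wide,
            "m2": wide,
            "h_star": Uniform(0.0, 0.9),
            "k_o": wide,
            "k_g": wide,
            "k_gr": wide,
            "k_p": wide,
        }
    )
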