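"""Parameter containers for the heteroplasmy bioenergetics model.

The mechanistic model has 12 adjustable parameters.  The total mtDNA copy
number ``N`` is held fixed (normalized to 1), and the post-changepoint
glycolysis intercept ``c2 = c1 - m2*h_star`` is derived by continuity, so
neither counts as adjustable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import yaml

__all__ = ["ModelParameters", "FixedConstants", "PARAM_NAMES"]


@dataclass(frozen=True)
class ModelParameters:
    """The 12 adjustable parameters of the supply/demand model.

    Attributes
    ----------
    beta : float
        Mitochondrial transcription rate (normalized units).
    k_mRNA : float
        Maximal ETC mRNA degradation rate; the high-degradation plateau of
        the sigmoid at low heteroplasmy.
    k_m : float
        Steepness of the degradation sigmoid (dimensionless).
    h0 : float
        Midpoint heteroplasmy of the degradation sigmoid, in [0, 1].
    delta_p : float
        ETC protein degradation rate.
    c1 : float
        Baseline glycolysis mRNA level (constant branch).
    m2 : float
        Glycolysis induction slope above the critical heteroplasmy.
    h_star : float
        Critical heteroplasmy, the changepoint where glycolysis is induced;
        restricted to (0, 0.9) because the model domain excludes h = 1.
    k_o : float
        OXPHOS weight in the power-supply sum.
    k_g : float
        Glycolysis weight in the power-supply sum.
    k_gr : float
        Growth constant; growth rate is k_gr / volume.
    k_p : float
        Respiratory capacity per unit ETC protein.
    """

    beta: float
    k_mRNA: float
    k_m: float
    h0: float
    delta_p: float
    c1: float
    m2: float
    h_star: float
    k_o: float
    k_g: float
    k_gr: float
    k_p: float

    def __post_init__(self) -> None:
        positive = ("beta", "k_mRNA", "delta_p", "c1", "k_o", "k_g", "k_gr", "k_p")
        for name in positive:
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"parameter {name!r} must be strictly positive, got {value}")
        if not 0 < self.h_star < 0.9:
            raise ValueError(f"h_star must lie in (0, 0.9), got {self.h_star}")
        if not 0 <= self.h0 <= 1:
            raise ValueError(f"h0 must lie in [0, 1], got {self.h0}")

    @property
    def c2(self) -> float:
        """Post-changepoint glycolysis intercept, derived by continuity."""
        return self.c1 - self.m2 * self.h_star

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, mapping: dict[str, float]) -> "ModelParameters":
        extra = set(mapping) - set(PARAM_NAMES)
        if extra:
            raise ValueError(f"unknown parameter(s): {sorted(extra)}")
        return cls(**{k: float(mapping[k]) for k in PARAM_NAMES})

    def to_array(self) -> "list[float]":
        return [getattr(self, name) for name in PARAM_NAMES]

    @classmethod
    def from_array(cls, values) -> "ModelParameters":
        if len(values) != len(PARAM_NAMES):
            raise ValueError(f"expected {len(PARAM_NAMES)} values, got {len(values)}")
        return cls(**dict(zip(PARAM_NAMES, map(float, values))))

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def save(self, path: str | Path) -> None:
        """Round-trip the parameter set as a flat JSON or YAML mapping."""
        path = Path(path)
        text = (
            yaml.safe_dump(self.to_dict(), sort_keys=False)
            if path.suffix in (".yml", ".yaml")
            else json.dumps(self.to_dict(), indent=2)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "ModelParameters":
        path = Path(path)
        mapping = yaml.safe_load(path.read_text())
        return cls.from_dict(mapping)

    def __iter__(self) -> Iterator[float]:
        return iter(self.to_array())


PARAM_NAMES: tuple[str, ...] = tuple(f.name for f in dataclasses.fields(ModelParameters))


@dataclass(frozen=True)
class FixedConstants:
    """Constants held fixed during inference.

    N is the total mtDNA copy number; it shows no systematic heteroplasmy
    dependence in cybrid data and is set to 1 after normalization without
    loss of generality.
    """

    N: float = 1.0

    def __post_init__(self) -> None:
        if not self.N > 0:
            raise ValueError(f"N must be strictly positive, got {self.N}")
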