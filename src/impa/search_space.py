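"""Bounded mixed-type hyperparameter search spaces.

The optimizer moves in a continuous box.  Each dimension of that box is
one hyperparameter; ``log_continuous`` dimensions are represented in
log10 coordinates so that, e.g., a learning-rate range spanning four
orders of magnitude is searched uniformly on the exponent.  ``decode``
maps a raw optimizer position back to a concrete classifier
configuration (rounding integer dimensions, exponentiating log ones).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import yaml

__all__ = [
    "DimensionSpec",
    "SearchSpace",
    "ClassifierConfig",
    "default_space",
    "sample_uniform",
    "decode",
    "clamp",
]

_KINDS = ("continuous", "log_continuous", "integer")


@dataclass(frozen=True)
class DimensionSpec:
    """One bounded hyperparameter dimension.

    ``lower`` and ``upper`` are always on the natural (decoded) scale;
    the optimizer-coordinate bounds of a ``log_continuous`` dimension
    are their log10.
    """

    name: str
    kind: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown dimension kind {self.kind!r}; expected one of {_KINDS}")
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: lower bound {self.lower} must be < upper {self.upper}")
        if self.kind == "log_continuous" and self.lower <= 0:
            raise ValueError(f"{self.name}: log_continuous bounds must be strictly positive")
        if self.kind == "integer" and not (
            float(self.lower).is_integer() and float(self.upper).is_integer()
        ):
            raise ValueError(f"{self.name}: integer dimension bounds must be whole numbers")

    @property
    def opt_lower(self) -> float:
        """Lower bound in optimizer coordinates."""
        return math.log10(self.lower) if self.kind == "log_continuous" else float(self.lower)

    @property
    def opt_upper(self) -> float:
        return math.log10(self.upper) if self.kind == "log_continuous" else float(self.upper)

    def decode_scalar(self, x: float) -> float | int:
        """Map one optimizer coordinate to the natural scale."""
        x = min(max(x, self.opt_lower), self.opt_upper)
        if self.kind == "log_continuous":
            return 10.0**x
        if self.kind == "integer":
            # round half away from zero, then clamp
            r = math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1)
            return int(min(max(r, self.lower), self.upper))
        return x


@dataclass(frozen=True)
class SearchSpace:
    """Ordered collection of dimensions; the box the optimizer searches."""

    dims: tuple[DimensionSpec, ...]

    def __post_init__(self) -> None:
        if len(self.dims) < 1:
            raise ValueError("a search space needs at least one dimension")
        names = [d.name for d in self.dims]
        if len(set(names)) != len(names):
            raise ValueError("dimension names must be unique")
        object.__setattr__(self, "dims", tuple(self.dims))

    @property
    def dim(self) -> int:
        return len(self.dims)

    def __len__(self) -> int:
        return self.dim

    def __iter__(self) -> Iterator[DimensionSpec]:
        return iter(self.dims)

    def __getitem__(self, name: str) -> DimensionSpec:
        for d in self.dims:
            if d.name == name:
                return d
        raise KeyError(name)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lb, ub) arrays in optimizer coordinates."""
        lb = np.array([d.opt_lower for d in self.dims])
        ub = np.array([d.opt_upper for d in self.dims])
        return lb, ub

    # -- YAML round-trip -------------------------------------------------
    def to_yaml(self) -> str:
        entries = [
            {"name": d.name, "kind": d.kind, "lower": float(d.lower), "upper": float(d.upper)}
            for d in self.dims
        ]
        return yaml.safe_dump(entries, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SearchSpace":
        entries = yaml.safe_load(text)
        return cls(tuple(DimensionSpec(**e) for e in entries))


@dataclass(frozen=True)
class ClassifierConfig:
    """The eight optimized hyperparameters of the fine-tuned classifier.

    Learning rate, batch size, the three dropout rates of the three
    dropout layers and the unit counts of the first three dense layers.
    The training epoch budget is fixed, not searched.
    """

    learning_rate: float
    batch_size: int
    dropout_rates: tuple[float, float, float]
    dense_units: tuple[int, int, int]
    epochs: int = 30

    def __post_init__(self) -> None:
        if not (1e-7 - 1e-12 <= self.learning_rate <= 1e-3 + 1e-12):
            raise ValueError(f"learning_rate {self.learning_rate} outside [1e-7, 1e-3]")
        if not 1 <= self.batch_size <= 64:
            raise ValueError(f"batch_size {self.batch_size} outside [1, 64]")
        for r in self.dropout_rates:
            if not 0.1 - 1e-12 <= r <= 0.9 + 1e-12:
                raise ValueError(f"dropout rate {r} outside [0.1, 0.9]")
        for u in self.dense_units:
            if not 50 <= u <= 500:
                raise ValueError(f"dense unit count {u} outside [50, 500]")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    def as_dict(self) -> dict:
        return {
            "learning_rate": self.learning_rate,
            "batch_size": self.batch_size,
            "dropout_rates": list(self.dropout_rates),
            "dense_units": list(self.dense_units),
            "epochs": self.epochs,
        }


def default_space() -> SearchSpace:
    """The 8-dimensional CNN fine-tuning space.

    Learning rate 1e-7..1e-3 (log scale), batch size 1..64, three
    dropout rates 0.1..0.9, three dense-layer widths 50..500 — in that
    fixed order.
    """
    return SearchSpace(
        (
            DimensionSpec("learning_rate", "log_continuous", 1e-7, 1e-3),
            DimensionSpec("batch_size", "integer", 1, 64),
            DimensionSpec("dropout_rate_1", "continuous", 0.1, 0.9),
            DimensionSpec("dropout_rate_2", "continuous", 0.1, 0.9),
            DimensionSpec("dropout_rate_3", "continuous", 0.1, 0.9),
            DimensionSpec("dense_units_1", "integer", 50, 500),
            DimensionSpec("dense_units_2", "integer", 50, 500),
            DimensionSpec("dense_units_3", "integer", 50, 500),
        )
    )


def sample_uniform(space: SearchSpace, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` positions uniformly in the optimizer box.

    Each entry is lb_i + q * (ub_i - lb_i) with q ~ U[0, 1]; for
    log-scaled dimensions the box bounds are already log10, so the draw
    is uniform on the exponent.
    """
    if n < 1:
        raise ValueError(f"sample count must be >= 1, got {n}")
    lb, ub = space.bounds()
    q = rng.uniform(size=(n, space.dim))
    return lb + q * (ub - lb)


def clamp(positions: np.ndarray, space: SearchSpace) -> np.ndarray:
    """Project positions onto the box [lb, ub] (optimizer coordinates)."""
    positions = np.asarray(positions, dtype=float)
    if positions.shape[-1] != space.dim:
        raise ValueError(f"expected {space.dim} columns, got {positions.shape[-1]}")
    lb, ub = space.bounds()
    return np.clip(positions, lb, ub)


def decode(position: Sequence[float], space: SearchSpace) -> ClassifierConfig:
    """Decode a raw optimizer position into a :class:`ClassifierConfig`.

    The position must come from (or be clamped to) the default 8-D
    space layout produced by :func:`default_space`.
    """
    position = np.asarray(position, dtype=float).ravel()
    if position.size != space.dim:
        raise ValueError(f"position has {position.size} entries, space has {space.dim}")
    vals = [d.decode_scalar(x) for d, x in zip(space.dims, position)]
    return ClassifierConfig(
        learning_rate=float(vals[0]),
        batch_size=int(vals[1]),
        dropout_rates=(float(vals[2]), float(vals[3]), float(vals[4])),
        dense_units=(int(vals[5]), int(vals[6]), int(vals[7])),
    )
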