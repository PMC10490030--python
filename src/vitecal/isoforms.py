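"""Core currency of the package: the eight vitamin E isoforms.

Vitamin E is not a single compound but a family of eight naturally occurring
isoforms — α-, β-, γ-, δ-tocopherol and α-, β-, γ-, δ-tocotrienol — that
differ in chromanol-ring methylation and side-chain saturation, and hence in
biological activity.  Every quantity this package moves around (content of a
food per 100 g, content of one portion, daily intake of a respondent) is a
vector of these eight masses plus manufacturer-added vitamin E, in mg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from enum import Enum

import numpy as np

from .errors import ValidationError

#: The eight natural isoforms, tocopherols first, in canonical order.
ISOFORMS: tuple[str, ...] = (
    "alpha_t",
    "beta_t",
    "gamma_t",
    "delta_t",
    "alpha_t3",
    "beta_t3",
    "gamma_t3",
    "delta_t3",
)

TOCOPHEROLS: tuple[str, ...] = ISOFORMS[:4]
TOCOTRIENOLS: tuple[str, ...] = ISOFORMS[4:]

#: Isoforms plus the manufacturer-fortification column.
COMPONENTS: tuple[str, ...] = ISOFORMS + ("added_vit_e",)

#: Pretty labels for reports.
ISOFORM_LABELS: dict[str, str] = {
    "alpha_t": "α-tocopherol",
    "beta_t": "β-tocopherol",
    "gamma_t": "γ-tocopherol",
    "delta_t": "δ-tocopherol",
    "alpha_t3": "α-tocotrienol",
    "beta_t3": "β-tocotrienol",
    "gamma_t3": "γ-tocotrienol",
    "delta_t3": "δ-tocotrienol",
    "added_vit_e": "added vitamin E",
    "sum_t": "sum of tocopherols",
    "sum_t3": "sum of tocotrienols",
    "total": "total of vitamin E isoforms",
    "alpha_te": "α-tocopherol equivalents",
}


class FoodGroup(str, Enum):
    """The eight food-product categories of the instrument."""

    VEGETABLES = "vegetables"
    FRUIT = "fruit and fruit products"
    LEGUMES = "legumes and legume products"
    NUTS = "nuts and oilseeds"
    FATS = "fats"
    CEREALS = "cereals"
    FISH = "fish and fish products"
    SNACKS = "snacks and others"

    @classmethod
    def parse(cls, value: "str | FoodGroup") -> "FoodGroup":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise ValidationError(
                f"unknown food group {value!r}; expected one of "
                + ", ".join(g.value for g in cls)
            ) from None


@dataclass(frozen=True)
class IsoformVector:
    """Masses (mg) of the eight isoforms plus added vitamin E.

    Supports componentwise addition and nonnegative scalar multiplication,
    which is all the intake arithmetic needs: contents scale linearly with
    portion mass and with portions per day, and intakes add over foods.
    """

    alpha_t: float = 0.0
    beta_t: float = 0.0
    gamma_t: float = 0.0
    delta_t: float = 0.0
    alpha_t3: float = 0.0
    beta_t3: float = 0.0
    gamma_t3: float = 0.0
    delta_t3: float = 0.0
    added_vit_e: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                raise ValidationError(f"{f.name} must be a number, got {v!r}")
            v = float(v)
            if not math.isfinite(v):
                raise ValidationError(f"{f.name} must be finite, got {v!r}")
            if v < 0:
                raise ValidationError(f"{f.name} must be >= 0, got {v!r}")
            object.__setattr__(self, f.name, v)

    # -- algebra ---------------------------------------------------------
    def __add__(self, other: "IsoformVector") -> "IsoformVector":
        if not isinstance(other, IsoformVector):
            return NotImplemented
        return IsoformVector(
            **{c: getattr(self, c) + getattr(other, c) for c in COMPONENTS}
        )

    def __mul__(self, scalar: float) -> "IsoformVector":
        if not isinstance(scalar, (int, float)) or isinstance(scalar, bool):
            return NotImplemented
        if scalar < 0:
            raise ValidationError("isoform masses cannot be scaled by a negative factor")
        return IsoformVector(**{c: getattr(self, c) * scalar for c in COMPONENTS})

    __rmul__ = __mul__

    # -- conversions -----------------------------------------------------
    def as_array(self) -> np.ndarray:
        """Components in :data:`COMPONENTS` order, shape (9,)."""
        return np.array([getattr(self, c) for c in COMPONENTS], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "IsoformVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(COMPONENTS),):
            raise ValidationError(f"expected shape ({len(COMPONENTS)},), got {arr.shape}")
        return cls(**dict(zip(COMPONENTS, arr.tolist())))

    @classmethod
    def zero(cls) -> "IsoformVector":
        return cls()

    # -- derived sums ----------------------------------------------------
    @property
    def sum_tocopherols(self) -> float:
        return sum(getattr(self, c) for c in TOCOPHEROLS)

    @property
    def sum_tocotrienols(self) -> float:
        return sum(getattr(self, c) for c in TOCOTRIENOLS)

    @property
    def total_isoforms(self) -> float:
        """Total of the eight natural isoforms (added vitamin E excluded)."""
        return self.sum_tocopherols + self.sum_tocotrienols

    def isclose(self, other: "IsoformVector", rel: float = 1e-9, abs_: float = 1e-12) -> bool:
        return all(
            math.isclose(getattr(self, c), getattr(other, c), rel_tol=rel, abs_tol=abs_)
            for c in COMPONENTS
        )
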