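"""The intake engine: FFQ answers → daily vitamin E isoform intakes.

For each line item the daily number of portions is the weekly serving
count divided by 7; the item's daily contribution is that portion count
times the per-portion isoform content derived from the composition
database.  Contributions accumulate in instrument order (fixed order, so
outputs are bit-reproducible) into a per-respondent daily vector, a
per-food-group breakdown, tocopherol/tocotrienol sums, and α-tocopherol
equivalents (α-TE).

α-TE expresses total vitamin E activity relative to α-tocopherol via
fixed activity coefficients:

    α-TE = 1.0·αT + 0.4·βT + 0.1·γT + 0.01·δT
         + 0.3·αT3 + 0.05·βT3 + 0.01·γT3 + 0.0·δT3   [mg/day]

δ-tocotrienol carries weight 0 by default (it is conventionally dropped
from the equivalence formula, its activity being negligible); the weight
is configurable for users following a different convention.  Manufacturer-
added vitamin E is, by default, counted in α-TE with weight 1 (it is
supplemented as α-tocopherol forms).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .composition import CompositionDB, content_per_portion
from .errors import DomainError, SchemaError, ValidationError, VitECalError
from .ffq import FFQInstrument, FFQResponse
from .isoforms import COMPONENTS, ISOFORMS, FoodGroup, IsoformVector

#: Derived columns appended after the 9 components in intake tables.
DERIVED_COLUMNS: tuple[str, ...] = ("sum_t", "sum_t3", "total", "alpha_te")
INTAKE_COLUMNS: tuple[str, ...] = ("respondent_id", "sex") + COMPONENTS + DERIVED_COLUMNS


@dataclass(frozen=True)
class ConversionWeights:
    """Activity coefficients turning an isoform vector into mg α-TE."""

    w_alpha_t: float = 1.0
    w_beta_t: float = 0.4
    w_gamma_t: float = 0.1
    w_delta_t: float = 0.01
    w_alpha_t3: float = 0.3
    w_beta_t3: float = 0.05
    w_gamma_t3: float = 0.01
    w_delta_t3: float = 0.0
    fold_added_as_alpha: bool = True

    def __post_init__(self) -> None:
        for iso in ISOFORMS:
            if getattr(self, f"w_{iso}") < 0:
                raise ValidationError(f"weight w_{iso} must be >= 0")

    def weight_for(self, isoform: str) -> float:
        return getattr(self, f"w_{isoform}")

    def with_overrides(self, overrides: Mapping[str, float]) -> "ConversionWeights":
        """New weights with ``{'delta_t3': 0.01, ...}``-style overrides applied."""
        kwargs = {}
        for key, value in overrides.items():
            name = key if key.startswith("w_") or key == "fold_added_as_alpha" else f"w_{key}"
            if name != "fold_added_as_alpha" and name not in {f"w_{i}" for i in ISOFORMS}:
                raise ValidationError(f"unknown weight override {key!r}")
            kwargs[name] = value
        return replace(self, **kwargs)


def alpha_te(v: IsoformVector, weights: ConversionWeights = ConversionWeights()) -> float:
    """mg α-tocopherol equivalents of an isoform vector."""
    total = sum(weights.weight_for(iso) * getattr(v, iso) for iso in ISOFORMS)
    if weights.fold_added_as_alpha:
        total += v.added_vit_e
    return total


def daily_portions(servings_per_week: float, recall_period_days: int = 7) -> float:
    """Average portions per day from a weekly serving count."""
    if not (servings_per_week >= 0):
        raise DomainError(f"servings_per_week must be >= 0, got {servings_per_week}")
    return servings_per_week / recall_period_days


def item_daily_intake(portions_per_day: float, per_portion: IsoformVector) -> IsoformVector:
    """Daily isoform intake (mg) from one line item."""
    if not (portions_per_day >= 0):
        raise DomainError(f"portions_per_day must be >= 0, got {portions_per_day}")
    return per_portion * portions_per_day


@dataclass(frozen=True)
class IntakeResult:
    """Per-respondent daily intake: isoform vector, group breakdown, sums, α-TE."""

    respondent_id: str
    daily: IsoformVector
    by_group: Mapping[FoodGroup, IsoformVector]
    sum_tocopherols: float
    sum_tocotrienols: float
    total_isoforms: float
    alpha_te: float
    sex: str | None = None

    def as_row(self) -> dict:
        row: dict = {"respondent_id": self.respondent_id, "sex": self.sex}
        row.update({c: getattr(self.daily, c) for c in COMPONENTS})
        row["sum_t"] = self.sum_tocopherols
        row["sum_t3"] = self.sum_tocotrienols
        row["total"] = self.total_isoforms
        row["alpha_te"] = self.alpha_te
        return row


def respondent_intake(
    response: FFQResponse,
    instrument: FFQInstrument,
    db: CompositionDB,
    weights: ConversionWeights = ConversionWeights(),
) -> IntakeResult:
    """Daily vitamin E intake of one respondent.

    Items the respondent did not answer (possible only under a permissive
    response policy) contribute zero.  Lookup failures are re-raised with
    the respondent id attached.
    """
    daily = IsoformVector.zero()
    by_group: dict[FoodGroup, IsoformVector] = {}
    for item in instrument.items:
        servings = response.servings_per_week.get(item.item_id, 0.0)
        try:
            per_portion = content_per_portion(item, db)
        except VitECalError as exc:
            raise type(exc)(f"respondent {response.respondent_id!r}, item {item.item_id!r}: {exc}") from exc
        contrib = item_daily_intake(
            daily_portions(servings, instrument.recall_period_days), per_portion
        )
        daily = daily + contrib
        by_group[item.group] = by_group.get(item.group, IsoformVector.zero()) + contrib
    return IntakeResult(
        respondent_id=response.respondent_id,
        daily=daily,
        by_group=by_group,
        sum_tocopherols=daily.sum_tocopherols,
        sum_tocotrienols=daily.sum_tocotrienols,
        total_isoforms=daily.total_isoforms,
        alpha_te=alpha_te(daily, weights),
        sex=response.sex,
    )


def cohort_intake(
    responses: Sequence[FFQResponse],
    instrument: FFQInstrument,
    db: CompositionDB,
    weights: ConversionWeights = ConversionWeights(),
) -> list[IntakeResult]:
    """Daily intakes for a whole cohort, in input order."""
    return [respondent_intake(r, instrument, db, weights) for r in responses]


# ---------------------------------------------------------------------------
# Intake-table I/O
# ---------------------------------------------------------------------------


def intake_table(results: Iterable[IntakeResult]) -> pd.DataFrame:
    """Tabulate results: one row per respondent, full internal precision."""
    return pd.DataFrame([r.as_row() for r in results], columns=list(INTAKE_COLUMNS))


def write_intake_table(
    results: Iterable[IntakeResult] | pd.DataFrame,
    dest: str | Path,
    *,
    sep: str = ",",
    decimals: int | None = None,
) -> Path:
    """Write an intake table; optional rounding applies only here, never upstream."""
    dest = Path(dest)
    df = results if isinstance(results, pd.DataFrame) else intake_table(results)
    if decimals is not None:
        df = df.round(decimals)
    df.to_csv(dest, sep=sep, index=False)
    return dest


def read_intake_table(source: str | Path, *, sep: str | None = None) -> pd.DataFrame:
    """Read an intake table written by :func:`write_intake_table`."""
    source = Path(source)
    df = pd.read_csv(source, sep=sep, engine="python" if sep is None else "c",
                     dtype={"respondent_id": str})
    required = [c for c in INTAKE_COLUMNS if c != "sex"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"intake table {source} is missing column(s): {', '.join(missing)}")
    return df


def write_intake_json(results: Iterable[IntakeResult], dest: str | Path) -> Path:
    """Machine-readable alternative to the delimited intake table."""
    dest = Path(dest)
    payload = []
    for r in results:
        entry = r.as_row()
        entry["by_group"] = {
            g.value: {c: getattr(v, c) for c in COMPONENTS} for g, v in r.by_group.items()
        }
        payload.append(entry)
    dest.write_text(json.dumps(payload, indent=2, ensure_ascii=False), encoding="utf-8")
    return dest
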