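"""Food-composition database: isoform contents per 100 g of edible portion.

Mirrors the "product group database" side of the calculator: one row per
food product, one column per isoform (mg/100 g) plus manufacturer-added
vitamin E.  Contents are stored per 100 g — the food-composition-table
standard — and converted to per-portion amounts at query time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DefinitionError, DomainError, FoodLookupError, SchemaError, ValidationError
from .isoforms import COMPONENTS, FoodGroup, IsoformVector

logger = logging.getLogger(__name__)

#: Column order of the delimited composition-table format.
COMPOSITION_COLUMNS: tuple[str, ...] = ("food_id", "name", "group") + COMPONENTS


@dataclass(frozen=True)
class FoodItem:
    """One food product with its isoform content per 100 g."""

    food_id: str
    name: str
    group: FoodGroup
    content_per_100g: IsoformVector

    def __post_init__(self) -> None:
        if not self.food_id:
            raise ValidationError("food_id must be nonempty")
        object.__setattr__(self, "group", FoodGroup.parse(self.group))


@dataclass
class CompositionDB:
    """Lookup table of :class:`FoodItem` keyed by ``food_id``."""

    items: dict[str, FoodItem] = field(default_factory=dict)
    provenance: str = ""

    @classmethod
    def from_items(cls, items: Iterable[FoodItem], provenance: str = "") -> "CompositionDB":
        db = cls(provenance=provenance)
        for item in items:
            db.add(item)
        return db

    def add(self, item: FoodItem) -> None:
        if item.food_id in self.items:
            raise ValidationError(f"duplicate food_id {item.food_id!r}")
        self.items[item.food_id] = item

    def __len__(self) -> int:
        return len(self.items)

    def __contains__(self, food_id: str) -> bool:
        return food_id in self.items

    def __iter__(self) -> Iterator[FoodItem]:
        return iter(self.items.values())

    def __getitem__(self, food_id: str) -> FoodItem:
        try:
            return self.items[food_id]
        except KeyError:
            raise FoodLookupError(f"food_id {food_id!r} not found in composition database") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CompositionDB):
            return NotImplemented
        return self.items == other.items


def load_composition(
    source: str | Path,
    *,
    sep: str | None = None,
    blank_to_zero: bool = False,
    provenance: str | None = None,
) -> CompositionDB:
    """Load a delimited composition table (comma or tab, auto-detected).

    Parameters
    ----------
    source
        Path to a UTF-8 delimited text file with columns
        ``food_id, name, group, alpha_t, ..., delta_t3, added_vit_e``
        (contents in mg/100 g, decimal point).
    sep
        Field separator; ``None`` auto-detects comma vs tab.
    blank_to_zero
        Permissive mode: empty isoform cells become 0 with a logged
        warning instead of raising.  Off by default because silent zeros
        bias intake estimates downward.
    """
    source = Path(source)
    if not source.exists():
        raise FileNotFoundError(source)
    df = pd.read_csv(source, sep=sep, engine="python" if sep is None else "c", dtype={"food_id": str})
    missing = [c for c in COMPOSITION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"composition table {source} is missing column(s): {', '.join(missing)}")

    items: list[FoodItem] = []
    for _, row in df.iterrows():
        fid = str(row["food_id"])
        values: dict[str, float] = {}
        for comp in COMPONENTS:
            v = row[comp]
            if pd.isna(v):
                if blank_to_zero:
                    logger.warning("composition: blank %s for %s mapped to 0", comp, fid)
                    v = 0.0
                else:
                    raise ValidationError(f"missing {comp} for food_id {fid!r} (use blank_to_zero to map blanks to 0)")
            v = float(v)
            if v < 0:
                raise ValidationError(f"negative {comp} = {v} for food_id {fid!r}")
            values[comp] = v
        items.append(
            FoodItem(
                food_id=fid,
                name=str(row["name"]),
                group=FoodGroup.parse(row["group"]),
                content_per_100g=IsoformVector(**values),
            )
        )
    return CompositionDB.from_items(
        items, provenance=provenance if provenance is not None else f"loaded from {source.name}"
    )


def write_composition(db: CompositionDB, dest: str | Path, *, sep: str = ",") -> Path:
    """Write a database back to the delimited composition-table format."""
    dest = Path(dest)
    rows = []
    for item in db:
        row = {"food_id": item.food_id, "name": item.name, "group": item.group.value}
        row.update({c: getattr(item.content_per_100g, c) for c in COMPONENTS})
        rows.append(row)
    pd.DataFrame(rows, columns=list(COMPOSITION_COLUMNS)).to_csv(dest, sep=sep, index=False)
    return dest


def content_per_portion(item, db: CompositionDB) -> IsoformVector:
    """Isoform content (mg) of one portion of an instrument line item.

    A line item may pool several member foods ("almonds/sunflower seeds");
    its per-portion content is the unweighted mean of the members'
    per-100 g contents scaled by portion mass:

        content = mean_over_members(content_per_100g) * portion_g / 100
    """
    member_ids: Sequence[str] = item.member_food_ids
    if not member_ids:
        raise DefinitionError(f"instrument item {item.item_id!r} has no member foods")
    total = IsoformVector.zero()
    for fid in member_ids:
        total = total + db[fid].content_per_100g
    mean = total * (1.0 / len(member_ids))
    return mean * (item.portion_g / 100.0)


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------

#: Median content (mg/100 g) per food group used by the fixture generator.
#: Magnitudes follow what food-composition tables show: oils and nuts are
#: tocopherol-rich; whole-grain cereals carry the tocotrienols (β-T3
#: dominant, wheat-like); fried snacks pick up γ-tocopherol and palm-oil
#: tocotrienols; vegetables, fruit and fish contribute little.
GROUP_CONTENT_MEDIANS: dict[FoodGroup, dict[str, float]] = {
    FoodGroup.VEGETABLES: {"alpha_t": 1.0, "beta_t": 0.03, "gamma_t": 0.3, "delta_t": 0.04,
                           "alpha_t3": 0.01, "beta_t3": 0.01, "gamma_t3": 0.01, "delta_t3": 0.002},
    FoodGroup.FRUIT: {"alpha_t": 0.8, "beta_t": 0.02, "gamma_t": 0.3, "delta_t": 0.03,
                      "alpha_t3": 0.01, "beta_t3": 0.005, "gamma_t3": 0.005, "delta_t3": 0.001},
    FoodGroup.LEGUMES: {"alpha_t": 0.5, "beta_t": 0.05, "gamma_t": 2.5, "delta_t": 0.3,
                        "alpha_t3": 0.02, "beta_t3": 0.01, "gamma_t3": 0.02, "delta_t3": 0.005},
    FoodGroup.NUTS: {"alpha_t": 15.0, "beta_t": 0.3, "gamma_t": 9.0, "delta_t": 0.7,
                     "alpha_t3": 0.1, "beta_t3": 0.03, "gamma_t3": 0.05, "delta_t3": 0.01},
    FoodGroup.FATS: {"alpha_t": 20.0, "beta_t": 0.5, "gamma_t": 18.0, "delta_t": 1.5,
                     "alpha_t3": 0.2, "beta_t3": 0.05, "gamma_t3": 0.15, "delta_t3": 0.02},
    FoodGroup.CEREALS: {"alpha_t": 0.5, "beta_t": 0.25, "gamma_t": 0.6, "delta_t": 0.06,
                        "alpha_t3": 0.9, "beta_t3": 3.8, "gamma_t3": 0.7, "delta_t3": 0.08},
    FoodGroup.FISH: {"alpha_t": 1.8, "beta_t": 0.02, "gamma_t": 0.3, "delta_t": 0.05,
                     "alpha_t3": 0.01, "beta_t3": 0.005, "gamma_t3": 0.005, "delta_t3": 0.001},
    FoodGroup.SNACKS: {"alpha_t": 3.0, "beta_t": 0.1, "gamma_t": 6.0, "delta_t": 0.8,
                       "alpha_t3": 0.6, "beta_t3": 0.4, "gamma_t3": 2.2, "delta_t3": 0.12},
}

#: Lognormal spread (sigma of log) of fixture contents around the group median.
_FIXTURE_SIGMA = 0.5


#: Beverages (juices, plant drinks) are mostly water; their per-100 g
#: contents sit far below the solid foods of their group.
_BEVERAGE_DILUTION = 0.05


def _draw_content(rng: np.random.Generator, group: FoodGroup, food_id: str = "") -> IsoformVector:
    medians = GROUP_CONTENT_MEDIANS[group]
    values = {iso: medians[iso] * float(rng.lognormal(0.0, _FIXTURE_SIGMA)) for iso in medians}
    if "juice" in food_id or "drink" in food_id:
        values = {iso: v * _BEVERAGE_DILUTION for iso, v in values.items()}
    # Occasional fortified margarine/snack product.
    if group in (FoodGroup.FATS, FoodGroup.SNACKS) and rng.random() < 0.15:
        values["added_vit_e"] = float(rng.uniform(1.0, 12.0))
    return IsoformVector(**values)


def make_fixture_db(seed: int, n_items: int = 41) -> CompositionDB:
    """Deterministic synthetic composition database spread over all 8 groups.

    Useful for tests and demos when no user composition table is at hand;
    contents are drawn lognormally around group-typical medians, so oils
    and nuts are isoform-rich and vegetables low.
    """
    if n_items < 1:
        raise DomainError(f"n_items must be >= 1, got {n_items}")
    rng = np.random.default_rng(seed)
    groups = list(FoodGroup)
    items = []
    for i in range(n_items):
        group = groups[i % len(groups)]
        items.append(
            FoodItem(
                food_id=f"food_{i:03d}",
                name=f"synthetic {group.value} item {i}",
                group=group,
                content_per_100g=_draw_content(rng, group),
            )
        )
    return CompositionDB.from_items(items, provenance=f"synthetic fixture (seed={seed}, n={n_items})")


def fixture_db_for_instrument(seed: int, instrument=None) -> CompositionDB:
    """Synthetic composition database covering every member food of an instrument.

    Generates one :class:`FoodItem` per distinct ``member_food_id`` (67 for
    the built-in instrument), with group-realistic magnitudes, so the whole
    pipeline runs end-to-end without any external data.
    """
    if instrument is None:
        from .ffq import builtin_instrument

        instrument = builtin_instrument()
    rng = np.random.default_rng(seed)
    items: list[FoodItem] = []
    seen: set[str] = set()
    for ffq_item in instrument.items:
        for fid in ffq_item.member_food_ids:
            if fid in seen:
                continue
            seen.add(fid)
            items.append(
                FoodItem(
                    food_id=fid,
                    name=fid.replace("_", " "),
                    group=ffq_item.group,
                    content_per_100g=_draw_content(rng, ffq_item.group, fid),
                )
            )
    return CompositionDB.from_items(
        items, provenance=f"synthetic fixture for instrument (seed={seed}, n={len(items)})"
    )
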