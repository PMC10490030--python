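"""The semiquantitative vitamin E FFQ instrument and respondent responses.

The instrument is a fixed list of 41 line items in 8 food groups, each with
a standard portion (g or mL) and a household measure.  Several line items
pool multiple foods ("almonds/sunflower seeds"); the full enumeration of
member foods comes to 67 products.  Respondents report their usual number
of servings per week per line item; fractional answers are allowed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import pandas as pd
import yaml

from .errors import SchemaError, ValidationError
from .isoforms import FoodGroup

logger = logging.getLogger(__name__)

Sex = Literal["female", "male"]
SEXES: tuple[str, ...] = ("female", "male")


@dataclass(frozen=True)
class FFQItem:
    """One line item of the instrument."""

    item_id: str
    label: str
    group: FoodGroup
    portion_g: float
    unit: str = "g"  # "g" or "mL"; mL is treated numerically as g (density ~1)
    household_measure: str = ""
    member_food_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.label:
            raise ValidationError(f"item {self.item_id!r}: label must be nonempty")
        if self.portion_g <= 0:
            raise ValidationError(f"item {self.item_id!r}: portion must be > 0, got {self.portion_g}")
        if self.unit not in ("g", "mL"):
            raise ValidationError(f"item {self.item_id!r}: unit must be 'g' or 'mL'")
        object.__setattr__(self, "group", FoodGroup.parse(self.group))
        object.__setattr__(self, "member_food_ids", tuple(self.member_food_ids))


@dataclass(frozen=True)
class FFQInstrument:
    """An ordered list of FFQ items with a recall normalisation period."""

    items: tuple[FFQItem, ...]
    recall_period_days: int = 7
    note: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate item_id(s): {', '.join(dup)}")
        if self.recall_period_days <= 0:
            raise ValidationError("recall_period_days must be > 0")

    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    def __getitem__(self, item_id: str) -> FFQItem:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def groups(self) -> tuple[FoodGroup, ...]:
        seen: list[FoodGroup] = []
        for it in self.items:
            if it.group not in seen:
                seen.append(it.group)
        return tuple(seen)

    def member_food_ids(self) -> tuple[str, ...]:
        out: list[str] = []
        for it in self.items:
            for fid in it.member_food_ids:
                if fid not in out:
                    out.append(fid)
        return tuple(out)


@dataclass(frozen=True)
class FFQResponse:
    """One respondent's answers: servings per week for every line item."""

    respondent_id: str
    sex: str
    servings_per_week: Mapping[str, float] = field(default_factory=dict)
    completeness: float = 1.0

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be 'female' or 'male', got {self.sex!r}")
        spw = dict(self.servings_per_week)
        for item_id, v in spw.items():
            if not (v >= 0):  # also rejects NaN
                raise ValidationError(
                    f"respondent {self.respondent_id!r}: servings for {item_id!r} must be >= 0, got {v}"
                )
        object.__setattr__(self, "servings_per_week", spw)


# ---------------------------------------------------------------------------
# Built-in instrument
# ---------------------------------------------------------------------------

_V = FoodGroup.VEGETABLES
_FR = FoodGroup.FRUIT
_L = FoodGroup.LEGUMES
_N = FoodGroup.NUTS
_FA = FoodGroup.FATS
_C = FoodGroup.CEREALS
_FI = FoodGroup.FISH
_S = FoodGroup.SNACKS

# (item_id, label, group, portion, unit, household measure, member foods)
_BUILTIN_ITEMS: tuple[tuple, ...] = (
    ("brassicas", "Broccoli/brussels sprouts/kale/asparagus/leeks", _V, 100, "g",
     "2/3 cup; 2 handfuls of leaves", ("broccoli", "brussels_sprouts", "kale", "asparagus", "leeks")),
    ("carrots_parsley_root", "Carrots/parsley root", _V, 100, "g", "2/3 cup",
     ("carrots", "parsley_root")),
    ("green_peas_tomatoes", "Green peas/tomatoes", _V, 100, "g", "2/3 cup",
     ("green_peas", "tomatoes")),
    ("beetroot_pumpkin_peppers", "Beetroot/beet greens/pumpkin/red peppers/turnip", _V, 100, "g",
     "2/3 cup; 2 handfuls of leaves", ("beetroot", "beet_greens", "pumpkin", "red_peppers", "turnip")),
    ("leafy_salads", "Lettuce/romaine lettuce/spinach/chicory/rucola", _V, 100, "g",
     "2/3 cup; 2 handfuls", ("lettuce", "romaine_lettuce", "spinach", "chicory", "rucola")),
    ("corn", "Corn", _V, 20, "g", "1 tablespoon", ("corn",)),
    ("vegetable_juices", "Carrot juice/multivegetable juices", _V, 200, "mL", "1 cup",
     ("carrot_juice", "multivegetable_juice")),
    ("other_vegetables", "Other vegetables", _V, 100, "g", "2/3 cup; 2 handfuls of leaves",
     ("other_vegetables",)),
    ("kiwifruit", "Kiwifruit", _FR, 100, "g", "2/3 cup", ("kiwifruit",)),
    ("berries", "Raspberries/blackberries/blueberries", _FR, 100, "g", "2/3 cup",
     ("raspberries", "blackberries", "blueberries")),
    ("avocado", "Avocado", _FR, 70, "g", "1/2 medium piece", ("avocado",)),
    ("other_fruit", "Other fruit", _FR, 100, "g", "2/3 cup", ("other_fruit",)),
    ("dry_legume_seeds", "Peas/lentils—dry seeds", _L, 15, "g", "1 tablespoon",
     ("peas_dry", "lentils_dry")),
    ("hummus", "Hummus", _L, 10, "g", "1 teaspoon", ("hummus",)),
    ("pumpkin_seeds", "Pumpkin seeds", _N, 30, "g", "2 tablespoons", ("pumpkin_seeds",)),
    ("linseeds", "Linseeds", _N, 30, "g", "2 tablespoons", ("linseeds",)),
    ("pistachios_pecans", "Pistachios/pecans", _N, 30, "g", "2 tablespoons",
     ("pistachios", "pecans")),
    ("almonds_sunflower_seeds", "Almonds/sunflower seeds", _N, 30, "g", "2 tablespoons",
     ("almonds", "sunflower_seeds")),
    ("almond_drink", "Almond drink", _N, 200, "mL", "1 cup", ("almond_drink",)),
    ("hazelnuts", "Hazelnuts", _N, 30, "g", "2 tablespoons", ("hazelnuts",)),
    ("peanuts", "Peanuts", _N, 30, "g", "2 tablespoons", ("peanuts",)),
    ("pine_nuts", "Pine nuts", _N, 30, "g", "2 tablespoons", ("pine_nuts",)),
    ("other_nuts", "Other nuts, e.g., walnuts, cashews", _N, 30, "g", "2 tablespoons",
     ("walnuts", "cashews")),
    ("canola_oil", "Canola oil", _FA, 10, "g", "1 tablespoon", ("canola_oil",)),
    ("sunflower_oil", "Sunflower oil", _FA, 10, "g", "1 tablespoon", ("sunflower_oil",)),
    ("olive_oil", "Olive oil", _FA, 10, "g", "1 tablespoon", ("olive_oil",)),
    ("grape_seed_oil", "Grape-seed oil", _FA, 10, "g", "1 tablespoon", ("grape_seed_oil",)),
    ("peanut_oil", "Peanut oil", _FA, 10, "g", "1 tablespoon", ("peanut_oil",)),
    ("wheat_germ_oil", "Wheat germ oil", _FA, 10, "g", "1 tablespoon", ("wheat_germ_oil",)),
    ("soybean_oil", "Soybean oil", _FA, 10, "g", "1 tablespoon", ("soybean_oil",)),
    ("coconut_oil", "Coconut oil", _FA, 10, "g", "1 tablespoon", ("coconut_oil",)),
    ("margarine", "Margarine", _FA, 10, "g", "1 tablespoon", ("margarine",)),
    ("mayonnaise", "Mayonnaise", _FA, 10, "g", "1 tablespoon", ("mayonnaise",)),
    ("pesto", "Pesto", _FA, 10, "g", "1 teaspoon", ("pesto",)),
    ("eggs", "Eggs", _FA, 50, "g", "1 piece", ("eggs",)),
    ("wholegrain_cereals", "Wholemeal bread, whole wheat pasta/brown rice/cornflakes", _C, 75, "g",
     "1 slice (bread, 35 g) or 1 cup of dry product (75 g)",
     ("wholemeal_bread", "whole_wheat_pasta", "brown_rice", "cornflakes")),
    # Fish rows list open-ended examples ("e.g., ..."); each maps to one
    # representative member food rather than an exhaustive enumeration.
    ("fresh_fish", "Fresh fish, e.g., salmon, trout, mackerel, herring", _FI, 100, "g", "1 piece",
     ("fresh_fish",)),
    ("canned_fish_in_oil", "Canned fish in oil, e.g., mackerel, tuna, herring, sardines", _FI, 150,
     "g", "1 medium can", ("canned_fish_in_oil",)),
    ("other_fish", "Other fish, e.g., canned fish in water/in tomatoes, flounder, carp, fish fingers",
     _FI, 150, "g", "1 medium can", ("other_fish",)),
    ("dark_chocolate", "Dark chocolate", _S, 5, "g", "1 cube", ("dark_chocolate",)),
    ("chips_crackers_nachos", "Chips/crackers/nachos", _S, 10, "g", "1 handful",
     ("chips", "crackers", "nachos")),
)


def builtin_instrument() -> FFQInstrument:
    """The packaged vitamin E FFQ: 41 line items, 8 food groups, 67 member foods.

    Portions follow the instrument's serving sizes (100 g for most
    vegetables and fruit, 30 g nuts and seeds, 10 g oils, 200 mL juices
    and almond drink, 50 g eggs, 100–150 g fish, 5 g dark chocolate,
    10 g salty snacks, 15 g dry legume seeds).  Servings are asked per
    week, so ``recall_period_days`` is 7.
    """
    items = tuple(
        FFQItem(item_id=i, label=l, group=g, portion_g=float(p), unit=u,
                household_measure=m, member_food_ids=members)
        for (i, l, g, p, u, m, members) in _BUILTIN_ITEMS
    )
    return FFQInstrument(
        items=items,
        recall_period_days=7,
        note="semiquantitative vitamin E FFQ; servings per week, usual diet",
    )


# ---------------------------------------------------------------------------
# Response I/O
# ---------------------------------------------------------------------------

RESPONSE_COLUMNS = ("respondent_id", "sex", "item_id", "servings_per_week")


def load_responses(
    source: str | Path,
    instrument: FFQInstrument,
    *,
    policy: Literal["strict", "permissive"] = "strict",
    sep: str | None = None,
    wide: bool = False,
) -> list[FFQResponse]:
    """Read respondent answers from a delimited text file.

    Long format (default): columns ``respondent_id, sex, item_id,
    servings_per_week``, one row per answered item.  Wide format
    (``wide=True``): one row per respondent, columns ``respondent_id, sex``
    then one column per instrument item_id.

    Under ``strict`` policy every instrument item must be answered; under
    ``permissive``, missing items count as 0 servings with a logged warning
    and a per-respondent completeness fraction below 1.
    """
    source = Path(source)
    if not source.exists():
        raise FileNotFoundError(source)
    df = pd.read_csv(source, sep=sep, engine="python" if sep is None else "c",
                     dtype={"respondent_id": str})
    if wide:
        df = _wide_to_long(df, instrument)
    missing_cols = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"responses table {source} is missing column(s): {', '.join(missing_cols)}")
    return responses_from_frame(df, instrument, policy=policy)


def _wide_to_long(df: pd.DataFrame, instrument: FFQInstrument) -> pd.DataFrame:
    for c in ("respondent_id", "sex"):
        if c not in df.columns:
            raise SchemaError(f"wide responses table is missing column {c!r}")
    value_cols = [c for c in df.columns if c not in ("respondent_id", "sex")]
    long = df.melt(id_vars=["respondent_id", "sex"], value_vars=value_cols,
                   var_name="item_id", value_name="servings_per_week")
    return long.dropna(subset=["servings_per_week"])


def responses_from_frame(
    df: pd.DataFrame,
    instrument: FFQInstrument,
    *,
    policy: Literal["strict", "permissive"] = "strict",
) -> list[FFQResponse]:
    """Validate a long-format answers frame against an instrument."""
    if policy not in ("strict", "permissive"):
        raise ValidationError(f"unknown policy {policy!r}")
    known = set(instrument.item_ids())
    unknown = sorted(set(df["item_id"].astype(str)) - known)
    if unknown:
        raise ValidationError(f"unknown item_id(s) in responses: {', '.join(unknown)}")
    dup = df.duplicated(subset=["respondent_id", "item_id"])
    if dup.any():
        pairs = df.loc[dup, ["respondent_id", "item_id"]].astype(str).agg("×".join, axis=1)
        raise ValidationError(f"duplicate respondent×item row(s): {', '.join(sorted(set(pairs)))}")

    n_items = len(known)
    responses: list[FFQResponse] = []
    for rid, grp in df.groupby("respondent_id", sort=True):
        sexes = set(grp["sex"].astype(str))
        if len(sexes) != 1:
            raise ValidationError(f"respondent {rid!r}: inconsistent sex values {sorted(sexes)}")
        sex = sexes.pop()
        answered = dict(zip(grp["item_id"].astype(str), grp["servings_per_week"].astype(float)))
        neg = sorted(k for k, v in answered.items() if not (v >= 0))
        if neg:
            raise ValidationError(f"respondent {rid!r}: negative/NaN servings for {', '.join(neg)}")
        missing = sorted(known - set(answered))
        if missing:
            if policy == "strict":
                raise ValidationError(
                    f"respondent {rid!r}: missing item(s) under strict policy: {', '.join(missing)}"
                )
            logger.warning("responses: respondent %s missing %d item(s), filled with 0", rid, len(missing))
        completeness = len(answered) / n_items
        full = {iid: answered.get(iid, 0.0) for iid in instrument.item_ids()}
        responses.append(FFQResponse(respondent_id=str(rid), sex=sex,
                                     servings_per_week=full, completeness=completeness))
    return responses


def write_responses(responses: Iterable[FFQResponse], dest: str | Path, *, sep: str = ",") -> Path:
    """Write responses in the long delimited format (load_responses round-trip)."""
    dest = Path(dest)
    rows = [
        {"respondent_id": r.respondent_id, "sex": r.sex, "item_id": iid, "servings_per_week": v}
        for r in responses
        for iid, v in r.servings_per_week.items()
    ]
    pd.DataFrame(rows, columns=list(RESPONSE_COLUMNS)).to_csv(dest, sep=sep, index=False)
    return dest


# ---------------------------------------------------------------------------
# Instrument I/O (user-modified instruments)
# ---------------------------------------------------------------------------


def write_instrument(instrument: FFQInstrument, dest: str | Path) -> Path:
    """Serialise an instrument to YAML for editing/versioning."""
    dest = Path(dest)
    payload = {
        "recall_period_days": instrument.recall_period_days,
        "note": instrument.note,
        "items": [
            {
                "item_id": it.item_id,
                "label": it.label,
                "group": it.group.value,
                "portion_g": it.portion_g,
                "unit": it.unit,
                "household_measure": it.household_measure,
                "member_food_ids": list(it.member_food_ids),
            }
            for it in instrument.items
        ],
    }
    dest.write_text(yaml.safe_dump(payload, allow_unicode=True, sort_keys=False), encoding="utf-8")
    return dest


def load_instrument(source: str | Path) -> FFQInstrument:
    """Load and schema-validate a YAML instrument written by :func:`write_instrument`."""
    source = Path(source)
    payload = yaml.safe_load(source.read_text(encoding="utf-8"))
    if not isinstance(payload, dict) or "items" not in payload:
        raise SchemaError(f"instrument file {source} must be a mapping with an 'items' list")
    items = []
    for raw in payload["items"]:
        missing = [k for k in ("item_id", "label", "group", "portion_g") if k not in raw]
        if missing:
            raise SchemaError(f"instrument item missing key(s): {', '.join(missing)}")
        items.append(
            FFQItem(
                item_id=str(raw["item_id"]),
                label=str(raw["label"]),
                group=FoodGroup.parse(raw["group"]),
                portion_g=float(raw["portion_g"]),
                unit=str(raw.get("unit", "g")),
                household_measure=str(raw.get("household_measure", "")),
                member_food_ids=tuple(raw.get("member_food_ids", ())),
            )
        )
    return FFQInstrument(
        items=tuple(items),
        recall_period_days=int(payload.get("recall_period_days", 7)),
        note=str(payload.get("note", "")),
    )
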