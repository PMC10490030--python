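"""Adequacy of vitamin E intake against dietary reference frameworks.

Three adult reference frameworks are built in:

========  ========  =========  ==============  ======
name      metric    reference  threshold (mg)  UL
========  ========  =========  ==============  ======
NIPH-NIH-NRI  α-TE  AI         10 men / 8 women   300
NIH           α-T   RDA        15 both          1000
EFSA          α-T   AI         13 men / 11 women  300
========  ========  =========  ==============  ======

An intake is classified adequate when it reaches the sex-specific
threshold (``value >= threshold``); the tolerable upper level is
exceeded when ``value > UL`` (strict).  Both boundary conventions are
package choices; the frameworks are silent on ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
import yaml

from .errors import DomainError, SchemaError, ValidationError
from .ffq import SEXES

Metric = Literal["alpha_t", "alpha_te"]


@dataclass(frozen=True)
class DRIFramework:
    """One reference framework: metric, per-sex threshold, upper level."""

    name: str
    metric: Metric
    reference_type: str  # "AI" or "RDA"
    threshold_by_sex: Mapping[str, float]
    ul: float

    def __post_init__(self) -> None:
        if self.metric not in ("alpha_t", "alpha_te"):
            raise ValidationError(f"metric must be alpha_t or alpha_te, got {self.metric!r}")
        thr = dict(self.threshold_by_sex)
        for sex in SEXES:
            if sex not in thr:
                raise ValidationError(f"framework {self.name!r}: missing threshold for {sex!r}")
            if thr[sex] <= 0:
                raise ValidationError(f"framework {self.name!r}: threshold for {sex} must be > 0")
        if self.ul < max(thr.values()):
            raise ValidationError(f"framework {self.name!r}: UL below the intake threshold")
        object.__setattr__(self, "threshold_by_sex", thr)

    def threshold(self, sex: str) -> float:
        try:
            return self.threshold_by_sex[sex]
        except KeyError:
            raise DomainError(f"unknown sex {sex!r}; expected one of {SEXES}") from None


@dataclass(frozen=True)
class AdequacyResult:
    """Classification of one respondent under one framework."""

    respondent_id: str
    framework: str
    status: Literal["adequate", "inadequate"]
    ul_exceeded: bool
    value: float
    sex: str


def builtin_frameworks() -> list[DRIFramework]:
    """The three packaged adult frameworks (see module docstring)."""
    return [
        DRIFramework(
            name="NIPH-NIH-NRI",
            metric="alpha_te",
            reference_type="AI",
            threshold_by_sex={"male": 10.0, "female": 8.0},
            ul=300.0,
        ),
        DRIFramework(
            name="NIH",
            metric="alpha_t",
            reference_type="RDA",
            threshold_by_sex={"male": 15.0, "female": 15.0},
            ul=1000.0,
        ),
        DRIFramework(
            name="EFSA",
            metric="alpha_t",
            reference_type="AI",
            threshold_by_sex={"male": 13.0, "female": 11.0},
            ul=300.0,
        ),
    ]


def classify(
    value: float,
    sex: str,
    framework: DRIFramework,
    respondent_id: str = "",
) -> AdequacyResult:
    """Classify one intake value (mg/day of the framework's metric)."""
    if not (value >= 0):
        raise DomainError(f"intake value must be >= 0, got {value}")
    threshold = framework.threshold(sex)
    return AdequacyResult(
        respondent_id=respondent_id,
        framework=framework.name,
        status="adequate" if value >= threshold else "inadequate",
        ul_exceeded=value > framework.ul,
        value=value,
        sex=sex,
    )


def assess_cohort(
    intake: pd.DataFrame,
    frameworks: Sequence[DRIFramework] | None = None,
) -> list[AdequacyResult]:
    """Classify every respondent of an intake table under every framework.

    ``intake`` needs columns ``respondent_id, sex`` plus each framework's
    metric column (``alpha_t`` / ``alpha_te``).
    """
    frameworks = list(frameworks) if frameworks is not None else builtin_frameworks()
    for col in ("respondent_id", "sex"):
        if col not in intake.columns:
            raise SchemaError(f"intake table is missing column {col!r}")
    results: list[AdequacyResult] = []
    for fw in frameworks:
        if fw.metric not in intake.columns:
            raise SchemaError(f"intake table is missing metric column {fw.metric!r} for {fw.name}")
        for _, row in intake.iterrows():
            results.append(
                classify(float(row[fw.metric]), str(row["sex"]), fw, str(row["respondent_id"]))
            )
    return results


def group_summary(results: Sequence[AdequacyResult]) -> pd.DataFrame:
    """Percentage adequate / inadequate / above-UL per framework.

    Full precision; integer rounding is left to report writers.  The
    adequate and inadequate percentages are exact complements.
    """
    if not results:
        raise DomainError("group_summary needs a nonempty result list")
    rows = []
    by_fw: dict[str, list[AdequacyResult]] = {}
    for r in results:
        by_fw.setdefault(r.framework, []).append(r)
    for fw, rs in by_fw.items():
        n = len(rs)
        n_ad = sum(1 for r in rs if r.status == "adequate")
        n_ul = sum(1 for r in rs if r.ul_exceeded)
        rows.append(
            {
                "framework": fw,
                "n": n,
                "pct_adequate": 100.0 * n_ad / n,
                "pct_inadequate": 100.0 * (n - n_ad) / n,
                "pct_ul_exceeded": 100.0 * n_ul / n,
            }
        )
    return pd.DataFrame(rows, columns=["framework", "n", "pct_adequate", "pct_inadequate", "pct_ul_exceeded"])


def write_adequacy_report(
    results: Sequence[AdequacyResult],
    dest: str | Path,
    *,
    sep: str = ",",
    decimals: int | None = 0,
) -> Path:
    """Write the per-framework percentage summary as delimited text."""
    dest = Path(dest)
    df = group_summary(results)
    if decimals is not None:
        for c in ("pct_adequate", "pct_inadequate", "pct_ul_exceeded"):
            df[c] = df[c].round(decimals)
    df.to_csv(dest, sep=sep, index=False)
    return dest


def write_classifications(results: Sequence[AdequacyResult], dest: str | Path, *, sep: str = ",") -> Path:
    """Write per-respondent classifications as delimited text."""
    dest = Path(dest)
    pd.DataFrame(
        [
            {
                "respondent_id": r.respondent_id,
                "sex": r.sex,
                "framework": r.framework,
                "value": r.value,
                "status": r.status,
                "ul_exceeded": r.ul_exceeded,
            }
            for r in results
        ]
    ).to_csv(dest, sep=sep, index=False)
    return dest


# ---------------------------------------------------------------------------
# User-defined frameworks
# ---------------------------------------------------------------------------


def load_frameworks(source: str | Path) -> list[DRIFramework]:
    """Load framework definitions from a YAML list of mappings."""
    source = Path(source)
    payload = yaml.safe_load(source.read_text(encoding="utf-8"))
    if not isinstance(payload, list):
        raise SchemaError(f"framework file {source} must contain a list")
    out = []
    for raw in payload:
        missing = [k for k in ("name", "metric", "reference_type", "threshold_by_sex", "ul") if k not in raw]
        if missing:
            raise SchemaError(f"framework entry missing key(s): {', '.join(missing)}")
        out.append(
            DRIFramework(
                name=str(raw["name"]),
                metric=raw["metric"],
                reference_type=str(raw["reference_type"]),
                threshold_by_sex={k: float(v) for k, v in raw["threshold_by_sex"].items()},
                ul=float(raw["ul"]),
            )
        )
    return out
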