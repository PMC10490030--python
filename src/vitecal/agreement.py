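"""Method-comparison statistics for paired dietary-assessment data.

Two instruments measuring the same intake (e.g. an FFQ and a 1-day
dietary record) are compared per variable with:

* **Bland–Altman limits of agreement**: for paired values (a_i, b_i) the
  differences d_i = a_i − b_i have bias d̄ and sample SD s (n−1
  denominator); the limits of agreement are d̄ ± k·s with k = 1.96, which
  bound ~95% of differences under normality.  The **Bland–Altman index**
  is the percentage of pairs strictly beyond the limits; ≤5% is read as
  good agreement (≤10% as acceptable).
* **Spearman rank correlation** (midranks for ties, t-approximation
  p-value) — the nonparametric association between the two methods.
* **Mann–Whitney U** (asymptotic two-sided p with tie and continuity
  correction) — whether the two methods' intake distributions differ.
* A **Shapiro–Wilk normality gate** that routes analysis down the
  nonparametric path when either series rejects normality at p ≤ 0.05.

The rank statistics are delegated to scipy.stats; the Bland–Altman
construction is implemented here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError
from .isoforms import ISOFORMS

logger = logging.getLogger(__name__)

#: Variables reported in the method-comparison tables: the eight isoforms,
#: both family sums, and α-TE.
AGREEMENT_VARIABLES: tuple[str, ...] = ISOFORMS + ("sum_t", "sum_t3", "alpha_te")

DEFAULT_K = 1.96
DEFAULT_INDEX_THRESHOLD = 5.0  # percent beyond the LOA tolerated for "good"


@dataclass(frozen=True)
class PairedSample:
    """Aligned per-respondent values from two methods for one variable."""

    respondent_ids: tuple[str, ...]
    values_a: np.ndarray  # method A, e.g. FFQ (mg/day)
    values_b: np.ndarray  # method B, e.g. 1-day record (mg/day)
    label: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.values_a, dtype=float)
        b = np.asarray(self.values_b, dtype=float)
        ids = tuple(str(r) for r in self.respondent_ids)
        if not (len(ids) == a.shape[0] == b.shape[0]):
            raise DomainError("respondent_ids, values_a and values_b must have equal length")
        if a.ndim != 1:
            raise DomainError("paired values must be one-dimensional")
        if len(ids) < 2:
            raise DomainError("a paired sample needs at least 2 pairs")
        object.__setattr__(self, "respondent_ids", ids)
        object.__setattr__(self, "values_a", a)
        object.__setattr__(self, "values_b", b)

    def __len__(self) -> int:
        return len(self.respondent_ids)

    @classmethod
    def from_tables(cls, table_a: pd.DataFrame, table_b: pd.DataFrame, variable: str) -> "PairedSample":
        """Align two intake tables on respondent_id for one variable."""
        a = table_a.set_index("respondent_id")[variable]
        b = table_b.set_index("respondent_id")[variable]
        common = a.index.intersection(b.index)
        if len(common) < 2:
            raise DomainError(f"fewer than 2 respondents common to both tables for {variable!r}")
        return cls(
            respondent_ids=tuple(common),
            values_a=a.loc[common].to_numpy(dtype=float),
            values_b=b.loc[common].to_numpy(dtype=float),
            label=variable,
        )


@dataclass(frozen=True)
class AgreementResult:
    """Bland–Altman summary for one variable."""

    label: str
    n: int
    mean_diff: float  # bias, mean of signed a - b
    sd_diff: float
    lower_loa: float
    upper_loa: float
    n_outside: int
    ba_index_pct: float
    good_agreement: bool
    k: float = DEFAULT_K

    @property
    def n_within(self) -> int:
        return self.n - self.n_outside


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    label: str = ""


@dataclass(frozen=True)
class RankTestResult:
    u_statistic: float
    p_value: float
    n_a: int
    n_b: int
    label: str = ""


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    p_value: float
    normal: bool  # True -> parametric path acceptable


def ba_index_from_counts(n: int, *, n_outside: int | None = None, n_within: int | None = None) -> float:
    """Bland–Altman index (%) from pair counts: 100 × beyond / n."""
    if n <= 0:
        raise DomainError("n must be positive")
    if (n_outside is None) == (n_within is None):
        raise DomainError("give exactly one of n_outside / n_within")
    out = n - n_within if n_outside is None else n_outside
    if not 0 <= out <= n:
        raise DomainError(f"count outside LOA must be in [0, {n}], got {out}")
    return 100.0 * out / n


def bland_altman(
    sample: PairedSample,
    k: float = DEFAULT_K,
    index_threshold: float = DEFAULT_INDEX_THRESHOLD,
) -> AgreementResult:
    """Bland–Altman limits of agreement and index for a paired sample.

    Differences are signed (a − b); the SD uses the n−1 denominator; pairs
    exactly on a limit count as within.  A zero-variance sample yields an
    index of 0 with a warning (every difference equals the bias).
    """
    d = sample.values_a - sample.values_b
    n = len(d)
    mean_diff = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    if sd_diff == 0.0:
        logger.warning("bland_altman(%s): zero variance of differences; index defined as 0", sample.label)
        lower = upper = mean_diff
        n_outside = 0
    else:
        lower = mean_diff - k * sd_diff
        upper = mean_diff + k * sd_diff
        n_outside = int(np.sum((d < lower) | (d > upper)))
    index = 100.0 * n_outside / n
    return AgreementResult(
        label=sample.label,
        n=n,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        lower_loa=lower,
        upper_loa=upper,
        n_outside=n_outside,
        ba_index_pct=index,
        good_agreement=index <= index_threshold,
        k=k,
    )


def spearman(sample: PairedSample) -> CorrelationResult:
    """Spearman rank correlation (midranks for ties, t-approximation p)."""
    n = len(sample)
    if n < 3:
        raise DomainError("spearman needs at least 3 pairs")
    if np.ptp(sample.values_a) == 0 or np.ptp(sample.values_b) == 0:
        logger.warning("spearman(%s): constant series, rho undefined", sample.label)
        return CorrelationResult(rho=float("nan"), p_value=float("nan"), n=n, label=sample.label)
    res = stats.spearmanr(sample.values_a, sample.values_b)
    return CorrelationResult(rho=float(res.statistic), p_value=float(res.pvalue), n=n, label=sample.label)


def mann_whitney(values_a: Sequence[float], values_b: Sequence[float], label: str = "") -> RankTestResult:
    """Mann–Whitney U (U for sample a), asymptotic two-sided p.

    U equals #{a > b} + ½·#{a = b} over all cross pairs; the p-value uses
    the normal approximation with tie and continuity corrections,
    appropriate at cohort scale.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DomainError("both samples must be nonempty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", use_continuity=True)
    return RankTestResult(
        u_statistic=float(res.statistic), p_value=float(res.pvalue),
        n_a=int(a.size), n_b=int(b.size), label=label,
    )


def normality_gate(values: Sequence[float], alpha: float = 0.05) -> NormalityResult:
    """Shapiro–Wilk test; ``normal=False`` routes to the nonparametric path."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise DomainError("Shapiro-Wilk needs at least 3 observations")
    if x.size > 5000:
        logger.warning("normality_gate: n=%d > 5000; Shapiro-Wilk p-value is approximate", x.size)
    stat, p = stats.shapiro(x)
    return NormalityResult(statistic=float(stat), p_value=float(p), normal=bool(p > alpha))


# ---------------------------------------------------------------------------
# Reports and plot data
# ---------------------------------------------------------------------------


def ba_plot_data(sample: PairedSample, result: AgreementResult) -> pd.DataFrame:
    """Per-pair plot coordinates plus constant reference lines.

    Columns: ``respondent_id``, ``mean`` ((a+b)/2, the x-axis),
    ``diff`` (a−b, the y-axis) and the three horizontal references
    ``bias``, ``lower_loa``, ``upper_loa`` repeated on every row so the
    export is self-contained.
    """
    return pd.DataFrame(
        {
            "respondent_id": list(sample.respondent_ids),
            "mean": (sample.values_a + sample.values_b) / 2.0,
            "diff": sample.values_a - sample.values_b,
            "bias": result.mean_diff,
            "lower_loa": result.lower_loa,
            "upper_loa": result.upper_loa,
        }
    )


def write_ba_plot_data(df: pd.DataFrame, dest: str | Path, *, sep: str = ",") -> Path:
    dest = Path(dest)
    df.to_csv(dest, sep=sep, index=False)
    return dest


def read_ba_plot_data(source: str | Path, *, sep: str = ",") -> pd.DataFrame:
    return pd.read_csv(Path(source), sep=sep, dtype={"respondent_id": str})


def agreement_report(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    variables: Sequence[str] = AGREEMENT_VARIABLES,
    k: float = DEFAULT_K,
    index_threshold: float = DEFAULT_INDEX_THRESHOLD,
) -> pd.DataFrame:
    """Method-comparison table across variables.

    One row per variable with the Bland–Altman summary (bias, LOA,
    "x out of n" within count, index %), Spearman rho and p, the
    Mann–Whitney U and p, and the normality gate of both series.
    """
    rows = []
    for var in variables:
        sample = PairedSample.from_tables(table_a, table_b, var)
        ba = bland_altman(sample, k=k, index_threshold=index_threshold)
        rho = spearman(sample)
        mw = mann_whitney(sample.values_a, sample.values_b, label=var)
        norm_a = normality_gate(sample.values_a)
        norm_b = normality_gate(sample.values_b)
        rows.append(
            {
                "variable": var,
                "n": ba.n,
                "bias": ba.mean_diff,
                "sd_diff": ba.sd_diff,
                "lower_loa": ba.lower_loa,
                "upper_loa": ba.upper_loa,
                "n_within": f"{ba.n_within} out of {ba.n}",
                "ba_index_pct": ba.ba_index_pct,
                "good_agreement": ba.good_agreement,
                "spearman_rho": rho.rho,
                "spearman_p": rho.p_value,
                "mannwhitney_u": mw.u_statistic,
                "mannwhitney_p": mw.p_value,
                "normal_a": norm_a.normal,
                "normal_b": norm_b.normal,
            }
        )
    return pd.DataFrame(rows)
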