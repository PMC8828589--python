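"""Two-level percentile classification and selection-strategy evaluation.

Families are classed Low/Medium/High against the 30th/70th percentiles of
wild-type per-plant yield; the same cutoffs class each individual plant,
giving a 3x3 lattice of nine combined categories (e.g. ``ML.HI`` = medium
line mean, high individual).  Three retroactive strategies are compared on
the follow-up multi-location trial: unselected (all lines pooled), line-mean
groups, and the nine line+individual categories, each contrasted against the
wild-type checks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.stats

from . import trial_stats
from ._util import DataError, round_half_up

logger = logging.getLogger(__name__)

CLASSES = ("L", "M", "H")
LINE_GROUPS = ("LL", "ML", "HL")
COMBINED_CATEGORIES = tuple(
    f"{lc}L.{ic}I" for lc in CLASSES for ic in CLASSES
)  # LL.LI ... HL.HI

STRATEGY_UNSELECTED = "unselected"
STRATEGY_LINE = "line_mean"
STRATEGY_LINE_INDIVIDUAL = "line_and_individual"


@dataclass(frozen=True)
class YieldCutoffs:
    """30th/70th percentile thresholds from wild-type per-plant yield."""

    p30: float
    p70: float
    source_n: int = 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.p30) and np.isfinite(self.p70)):
            raise DataError("cutoffs must be finite")
        if self.p30 > self.p70:
            raise DataError(f"p30 ({self.p30}) must not exceed p70 ({self.p70})")


@dataclass(frozen=True)
class CategoryLabel:
    """A selection category: line class, optionally combined with an
    individual class.  Renders as ``ML`` (line-only) or ``ML.HI``."""

    line_class: str
    individual_class: str | None = None

    def __post_init__(self) -> None:
        if self.line_class not in CLASSES:
            raise ValueError(f"line_class must be one of {CLASSES}")
        if self.individual_class is not None and self.individual_class not in CLASSES:
            raise ValueError(f"individual_class must be one of {CLASSES} or None")

    def render(self) -> str:
        if self.individual_class is None:
            return f"{self.line_class}L"
        return f"{self.line_class}L.{self.individual_class}I"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()

    @classmethod
    def parse(cls, text: str) -> "CategoryLabel":
        text = text.strip()
        if "." in text:
            line_part, ind_part = text.split(".", 1)
            if len(line_part) == 2 and line_part[1] == "L" and len(ind_part) == 2 and ind_part[1] == "I":
                return cls(line_part[0], ind_part[0])
        elif len(text) == 2 and text[1] == "L":
            return cls(text[0], None)
        raise ValueError(f"unrecognized category label {text!r}")


def compute_cutoffs(wt_yields, method: str = "linear") -> YieldCutoffs:
    """30th/70th percentiles of wild-type per-plant yields.

    ``method`` is any numpy percentile method; the default is linear
    interpolation between order statistics.
    """
    arr = np.asarray(wt_yields, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise DataError("need at least 2 finite wild-type yields")
    if np.any(arr < 0):
        raise DataError("yields must be non-negative")
    p30, p70 = np.percentile(arr, [30, 70], method=method)
    return YieldCutoffs(p30=float(p30), p70=float(p70), source_n=int(arr.size))


def classify_value(value: float, cutoffs: YieldCutoffs) -> str:
    """L if value < p30; M if p30 <= value <= p70; H if value > p70.

    Boundary values fall in M — both inequalities of the middle band are
    inclusive.
    """
    if not np.isfinite(value):
        raise DataError(f"cannot classify non-finite value {value!r}")
    if value < cutoffs.p30:
        return "L"
    if value > cutoffs.p70:
        return "H"
    return "M"


def classify_population(
    records: pd.DataFrame,
    cutoffs: YieldCutoffs,
    yield_col: str = "yield_g",
    line_col: str = "line_id",
) -> pd.DataFrame:
    """Assign every plant its two-level category.

    Returns a copy of ``records`` with ``line_class`` (from the line's mean
    yield), ``individual_class`` (from the plant's own yield) and the
    rendered ``category`` column.  Lines with no measurable yield are
    excluded with a logged warning.
    """
    for col in (yield_col, line_col):
        if col not in records.columns:
            raise DataError(f"missing required column {col!r}")
    df = records.copy()
    measurable = df[yield_col].notna()
    bad_lines = sorted(set(df.loc[~measurable, line_col]) - set(df.loc[measurable, line_col]))
    if bad_lines:
        logger.warning("excluding %d line(s) with no measured plants: %s", len(bad_lines), bad_lines)
        df = df[~df[line_col].isin(bad_lines)]
    df = df[df[yield_col].notna()]
    line_means = df.groupby(line_col)[yield_col].mean()
    df["line_class"] = df[line_col].map(
        {line: classify_value(m, cutoffs) for line, m in line_means.items()}
    )
    df["individual_class"] = [classify_value(v, cutoffs) for v in df[yield_col]]
    df["category"] = df["line_class"] + "L." + df["individual_class"] + "I"
    return df


def line_categories(
    classified: pd.DataFrame, line_col: str = "line_id"
) -> dict[str, CategoryLabel]:
    """Per-line combined category for lines advanced as whole families.

    Line class comes from the family mean; the individual class is the most
    frequent individual class within the family.  When a specific plant was
    selected to found the next generation, build the mapping from that
    plant's category instead.
    """
    out: dict[str, CategoryLabel] = {}
    for line, sub in classified.groupby(line_col):
        lc = sub["line_class"].iloc[0]
        ic = sub["individual_class"].mode().iloc[0]
        out[str(line)] = CategoryLabel(lc, ic)
    return out


def percent_increase(group_mean: float, ref_mean: float, ndigits: int | None = 1) -> float:
    """100 * (group - reference) / reference, rounded half-up to one decimal."""
    if ref_mean <= 0:
        raise DataError("reference mean must be positive")
    pct = 100.0 * (group_mean - ref_mean) / ref_mean
    return round_half_up(pct, ndigits) if ndigits is not None else pct


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _group_result(
    strategy: str,
    group: str,
    env: str,
    epi: pd.DataFrame,
    wt: pd.DataFrame,
    yield_col: str,
    line_col: str,
) -> dict:
    n_lines = epi[line_col].nunique()
    n_plots = len(epi)
    wt_mean = float(wt[yield_col].mean())
    if n_plots == 0:
        return dict(
            strategy=strategy, group=group, environment_id=env, n_lines=0, n_plots=0,
            group_mean_yield=np.nan, wt_mean_yield=wt_mean, percent_increase=np.nan,
            p_value=np.nan, significance="", estimable=False,
        )
    gmean = float(epi[yield_col].mean())
    if n_plots >= 2 and len(wt) >= 2 and (epi[yield_col].std() > 0 or wt[yield_col].std() > 0):
        p = float(scipy.stats.ttest_ind(epi[yield_col], wt[yield_col], equal_var=False).pvalue)
    else:
        p = np.nan
    return dict(
        strategy=strategy, group=group, environment_id=env, n_lines=n_lines,
        n_plots=n_plots, group_mean_yield=gmean, wt_mean_yield=wt_mean,
        percent_increase=percent_increase(gmean, wt_mean),
        p_value=p, significance=_stars(p), estimable=True,
    )


def evaluate_strategies(
    f3_plots: pd.DataFrame,
    category_of_line: Mapping[str, CategoryLabel | str],
    environment_id: str,
    yield_col: str = "yield_kg_ha_std",
    line_col: str = "line_id",
    cohort_col: str = "cohort",
    wt_cohort: str = "WT",
    means: str = "raw",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare the three selection strategies against wild type in one location.

    Returns one row per (strategy, group): the pooled unselected group, the
    three line-mean groups and the nine combined categories.  ``means='raw'``
    uses arithmetic plot means with a Welch contrast (this is the arithmetic
    that reproduces the headline percent gains); ``means='lsmeans'`` fits the
    mixed model with group as the genotype term and block random.  Epi lines
    absent from ``category_of_line`` are dropped with a warning; empty groups
    are flagged not-estimable rather than dropped.
    """
    if means not in ("raw", "lsmeans"):
        raise ValueError("means must be 'raw' or 'lsmeans'")
    df = f3_plots[f3_plots["environment_id"].astype(str) == str(environment_id)].copy()
    if df.empty:
        raise DataError(f"no plots for environment {environment_id!r}")
    wt = df[df[cohort_col] == wt_cohort]
    if wt.empty:
        raise DataError(f"no wild-type plots in environment {environment_id!r}")
    epi = df[df[cohort_col] != wt_cohort].copy()

    cats = {
        str(k): (v if isinstance(v, CategoryLabel) else CategoryLabel.parse(str(v)))
        for k, v in category_of_line.items()
    }
    unmapped = sorted(set(epi[line_col].astype(str)) - set(cats))
    if unmapped:
        warnings.warn(
            f"dropping {len(unmapped)} line(s) with no category mapping: {unmapped[:5]}...",
            stacklevel=2,
        )
        epi = epi[~epi[line_col].astype(str).isin(unmapped)]
    epi["_line_group"] = [cats[str(l)].line_class + "L" for l in epi[line_col]]
    epi["_category"] = [cats[str(l)].render() for l in epi[line_col]]

    rows = [
        _group_result(
            STRATEGY_UNSELECTED, "all", environment_id, epi, wt, yield_col, line_col
        )
    ]
    for g in LINE_GROUPS:
        rows.append(
            _group_result(
                STRATEGY_LINE, g, environment_id,
                epi[epi["_line_group"] == g], wt, yield_col, line_col,
            )
        )
    for cat in COMBINED_CATEGORIES:
        rows.append(
            _group_result(
                STRATEGY_LINE_INDIVIDUAL, cat, environment_id,
                epi[epi["_category"] == cat], wt, yield_col, line_col,
            )
        )
    out = pd.DataFrame(rows)

    if means == "lsmeans":
        out = _lsmean_adjust(out, epi, wt, environment_id, yield_col, alpha)
    return out


def _lsmean_adjust(
    out: pd.DataFrame,
    epi: pd.DataFrame,
    wt: pd.DataFrame,
    env: str,
    yield_col: str,
    alpha: float,
) -> pd.DataFrame:
    """Replace raw group means/p-values with mixed-model LS-means where
    estimable, one model per strategy (group as genotype, block random)."""
    spec = trial_stats.TraitModelSpec(trait=yield_col, alpha=alpha)
    plan = [
        (STRATEGY_UNSELECTED, "_all"),
        (STRATEGY_LINE, "_line_group"),
        (STRATEGY_LINE_INDIVIDUAL, "_category"),
    ]
    for strategy, col in plan:
        epi_s = epi.copy()
        epi_s["genotype"] = "all" if col == "_all" else epi_s[col]
        wt_s = wt.copy()
        wt_s["genotype"] = "WT"
        data = pd.concat([epi_s, wt_s], ignore_index=True)
        if data["genotype"].nunique() < 2:
            continue
        fit = trial_stats.fit_trait_model(data, spec, reference="WT")
        contrasts = trial_stats.contrast_lines_vs_wt(fit, alpha=alpha)
        by_group = contrasts.set_index("line_id")
        mask = out["strategy"] == strategy
        for i in out.index[mask]:
            g = out.at[i, "group"] if col != "_all" else "all"
            if g not in by_group.index:
                continue
            row = by_group.loc[g]
            out.at[i, "group_mean_yield"] = row["ls_mean"]
            out.at[i, "wt_mean_yield"] = row["wt_ls_mean"]
            out.at[i, "percent_increase"] = percent_increase(row["ls_mean"], row["wt_ls_mean"])
            out.at[i, "p_value"] = row["p_value"]
            out.at[i, "significance"] = _stars(row["p_value"])
    return out
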