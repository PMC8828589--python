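"""Per-line and per-group GxE resilience statistics.

The resilience metric is the percent yield differential between a favorable
and a stress environment; lines are called stable (<30% loss), dynamic
(>70% loss) or intermediate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import trial_stats
from ._util import DataError, round_half_up
from .selection_engine import CategoryLabel

STABLE_MAX_DEFAULT = 30.0
DYNAMIC_MIN_DEFAULT = 70.0


@dataclass(frozen=True)
class LineEnvYield:
    line_id: str
    cohort: str
    yield_normal: float
    yield_low: float


@dataclass(frozen=True)
class StabilityCall:
    line_id: str
    differential: float
    call: str  # stable | intermediate | dynamic


def yield_differential(y_normal: float, y_low: float, ndigits: int | None = 1) -> float:
    """Percent yield loss between environments: 100 * (normal - low) / normal.

    Negative when the stress-environment yield exceeds the favorable one.
    """
    if y_normal <= 0:
        raise DataError("normal-environment yield must be positive")
    pct = 100.0 * (y_normal - y_low) / y_normal
    return round_half_up(pct, ndigits) if ndigits is not None else pct


def classify_stability(
    differential: float,
    stable_max: float = STABLE_MAX_DEFAULT,
    dynamic_min: float = DYNAMIC_MIN_DEFAULT,
) -> str:
    """stable iff differential < stable_max; dynamic iff > dynamic_min."""
    if stable_max > dynamic_min:
        raise ValueError("stable_max must not exceed dynamic_min")
    if differential < stable_max:
        return "stable"
    if differential > dynamic_min:
        return "dynamic"
    return "intermediate"


def line_env_yields(
    plots: pd.DataFrame,
    env_normal: str,
    env_low: str,
    yield_col: str = "yield_kg_ha_std",
    means: str = "lsmeans",
) -> pd.DataFrame:
    """One yield per line per environment (LineEnvYield rows).

    ``means='lsmeans'`` fits the genotype+block mixed model within each
    location and takes line LS-means; ``means='raw'`` takes arithmetic
    means over replications.  Lines absent from either environment are
    dropped.
    """
    if means not in ("raw", "lsmeans"):
        raise ValueError("means must be 'raw' or 'lsmeans'")
    per_env = {}
    for env in (env_normal, env_low):
        sub = plots[plots["environment_id"].astype(str) == str(env)]
        if sub.empty:
            raise DataError(f"no plots for environment {env!r}")
        if means == "raw" or sub["block"].nunique() < 2:
            per_env[env] = sub.groupby("line_id")[yield_col].mean()
        else:
            df = sub.rename(columns={"line_id": "genotype"})
            ref = str(df["genotype"].iloc[0])
            fit = trial_stats.fit_trait_model(
                df, trial_stats.TraitModelSpec(trait=yield_col), reference=ref
            )
            per_env[env] = fit.ls_means
    cohort = plots.groupby("line_id")["cohort"].first() if "cohort" in plots else None
    rows = []
    for line in sorted(set(per_env[env_normal].index) & set(per_env[env_low].index)):
        rows.append(
            LineEnvYield(
                line_id=str(line),
                cohort=str(cohort[line]) if cohort is not None else "",
                yield_normal=float(per_env[env_normal][line]),
                yield_low=float(per_env[env_low][line]),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def stability_calls(
    line_yields: pd.DataFrame,
    stable_max: float = STABLE_MAX_DEFAULT,
    dynamic_min: float = DYNAMIC_MIN_DEFAULT,
) -> pd.DataFrame:
    """Per-line differential and stable/intermediate/dynamic call."""
    rows = []
    for rec in line_yields.itertuples(index=False):
        diff = yield_differential(rec.yield_normal, rec.yield_low, ndigits=None)
        rows.append(
            StabilityCall(
                line_id=rec.line_id,
                differential=diff,
                call=classify_stability(diff, stable_max, dynamic_min),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def group_differential_profile(
    line_yields: pd.DataFrame,
    grouping: Mapping[str, CategoryLabel | str],
) -> pd.DataFrame:
    """Per-category mean yield in each environment and differential of means.

    Every line must appear in ``grouping``; categories with no lines are
    flagged not-estimable.  Suitable for the two-environment slope plot.
    """
    labels = {
        str(k): (v.render() if isinstance(v, CategoryLabel) else str(v))
        for k, v in grouping.items()
    }
    missing = sorted(set(line_yields["line_id"].astype(str)) - set(labels))
    if missing:
        raise DataError(f"ungrouped line(s): {missing[:5]}")
    df = line_yields.copy()
    df["group"] = [labels[str(l)] for l in df["line_id"]]
    rows = []
    for g in sorted(set(labels.values())):
        sub = df[df["group"] == g]
        if sub.empty:
            rows.append(
                dict(group=g, n_lines=0, mean_yield_normal=np.nan,
                     mean_yield_low=np.nan, differential=np.nan, estimable=False)
            )
            continue
        mn, ml = float(sub["yield_normal"].mean()), float(sub["yield_low"].mean())
        rows.append(
            dict(group=g, n_lines=len(sub), mean_yield_normal=mn, mean_yield_low=ml,
                 differential=yield_differential(mn, ml, ndigits=None), estimable=True)
        )
    return pd.DataFrame(rows)
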