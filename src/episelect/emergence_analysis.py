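"""Cold-stress emergence curves: adjusted emergence, AUPEC and group contrasts.

Adjusted emergence divides the early (cold) planting counts by the standard
planting's emergence, controlling for per-line seed quality.  AUPEC is the
trapezoidal area under the adjusted emergence curve over days after
planting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import trial_stats
from ._util import DataError

logger = logging.getLogger(__name__)

#: Observation grid used by the field protocol (days after planting).
DEFAULT_DAY_GRID = (13, 14, 15, 16, 17, 18, 20, 22, 25, 27, 32, 39, 46)

PLANTINGS = ("early", "standard")


@dataclass(frozen=True)
class EmergenceSeries:
    """Cumulative emerged-plant counts for one line and planting date."""

    line_id: str
    planting: str  # early | standard
    days: tuple
    counts: tuple

    def __post_init__(self) -> None:
        if self.planting not in PLANTINGS:
            raise DataError(f"planting must be one of {PLANTINGS}")
        days = np.asarray(self.days, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        if days.size != counts.size:
            raise DataError("days and counts must have equal length")
        if days.size and (np.any(days <= 0) or np.any(np.diff(days) <= 0)):
            raise DataError("days must be strictly increasing and positive")
        if np.any(counts < 0):
            raise DataError("counts must be non-negative")
        if np.any(np.diff(counts) < 0):
            raise DataError("cumulative counts must be non-decreasing")


def adjusted_emergence(
    early: EmergenceSeries,
    standard: EmergenceSeries,
    mode: str = "final",
) -> tuple[np.ndarray, np.ndarray]:
    """Early-planting emergence divided by the standard planting's.

    ``mode='final'`` (default) divides every early count by the standard
    planting's final emergence — a per-line seed-quality denominator.
    ``mode='daywise'`` divides day by day on the shared grid.  Values above
    one are retained.  Returns ``(days, ratios)`` on early's day grid.
    """
    if early.line_id != standard.line_id:
        raise DataError("series belong to different lines")
    days = np.asarray(early.days, dtype=float)
    counts = np.asarray(early.counts, dtype=float)
    if mode == "final":
        denom = float(standard.counts[-1]) if len(standard.counts) else 0.0
        if denom <= 0:
            raise DataError(f"line {early.line_id}: standard planting has zero final emergence")
        return days, counts / denom
    if mode == "daywise":
        sdays = np.asarray(standard.days, dtype=float)
        scounts = np.asarray(standard.counts, dtype=float)
        if days.size != sdays.size or np.any(days != sdays):
            raise DataError("daywise mode requires matching day grids")
        if np.any(scounts <= 0):
            raise DataError(f"line {early.line_id}: zero standard emergence on some day")
        return days, counts / scounts
    raise ValueError("mode must be 'final' or 'daywise'")


def aupec(days: Sequence[float], values: Sequence[float]) -> float:
    """Area under the emergence curve by the trapezoid rule.

    Sums (PE_n + PE_{n+1})/2 * (Y_{n+1} - Y_n) over consecutive observation
    days; units are (emergence fraction) x days.
    """
    d = np.asarray(days, dtype=float)
    v = np.asarray(values, dtype=float)
    if d.size != v.size:
        raise DataError("days and values must have equal length")
    if d.size < 2:
        raise DataError("need at least 2 points")
    if np.any(np.diff(d) <= 0):
        raise DataError("days must be strictly increasing")
    return float(np.trapezoid(v, d))


def emergence_rate(days: Sequence[float], values: Sequence[float]) -> float:
    """Least-squares slope of adjusted emergence vs day (per-day rate)."""
    d = np.asarray(days, dtype=float)
    v = np.asarray(values, dtype=float)
    if d.size != v.size or d.size < 2:
        raise DataError("need at least 2 aligned points")
    slope, _ = np.polyfit(d, v, 1)
    return float(slope)


def aupec_by_line(
    series: Sequence[EmergenceSeries], mode: str = "final"
) -> dict[str, float]:
    """Per-line AUPEC of adjusted emergence; lines whose standard planting
    never emerged are excluded with a logged warning."""
    by_line: dict[str, dict[str, EmergenceSeries]] = {}
    for s in series:
        by_line.setdefault(s.line_id, {})[s.planting] = s
    out: dict[str, float] = {}
    for line, pair in sorted(by_line.items()):
        if set(pair) != set(PLANTINGS):
            logger.warning("line %s: missing %s planting; skipped", line,
                           set(PLANTINGS) - set(pair))
            continue
        try:
            days, adj = adjusted_emergence(pair["early"], pair["standard"], mode=mode)
        except DataError as exc:
            logger.warning("line %s excluded: %s", line, exc)
            continue
        out[line] = aupec(days, adj)
    return out


def compare_emergence_groups(
    aupec_of_line: Mapping[str, float],
    grouping: Mapping[str, str],
    wt_lines: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-group AUPEC mean and contrast vs the pooled wild-type lines.

    Reuses the trial-stats contrast machinery with group as the genotype
    term (one AUPEC value per line, no blocking, so the model degrades to
    fixed effects).
    """
    wt = set(map(str, wt_lines))
    rows = []
    for line, value in aupec_of_line.items():
        line = str(line)
        if line in wt:
            g = "WT"
        elif line in grouping:
            g = str(grouping[line])
        else:
            logger.warning("line %s has no group; skipped", line)
            continue
        rows.append((line, g, value))
    df = pd.DataFrame(rows, columns=["line_id", "genotype", "aupec"])
    if "WT" not in set(df["genotype"]):
        raise DataError("no wild-type lines with AUPEC values")
    df["block"] = 0  # single stratum -> fixed-effects fallback in the fitter
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        fit = trial_stats.fit_trait_model(
            df, trial_stats.TraitModelSpec(trait="aupec", alpha=alpha), reference="WT"
        )
    return trial_stats.contrast_lines_vs_wt(fit, alpha=alpha).rename(
        columns={"line_id": "group"}
    )
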